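"""Seeded strict-clock tree simulator with known ground truth.

Generates rooted trees whose branch lengths are substitutions/site accrued
at a constant rate over elapsed calendar time, with tips sampled
heterochronously inside a sampling window. Because the construction is
exact, every node-to-tip distance equals rate x (tip date - node date), so
a scan of a noise-free tree must recover the rate as the slope and each
node's own date as the x-intercept — this is what makes scan accuracy
testable without any external dataset.

Topology is produced by recursive random splitting of the tip set (a simple
Yule-like scheme); the scan's correctness does not depend on topological
realism, so nothing fancier is warranted. Optional per-branch noise
(additive Gaussian or mean-preserving multiplicative Gamma) breaks the
exact clock, and an optional per-clade rate map emulates trees in which
temporal signal exists only at reduced timescales: some subtrees evolve
measurably, others not at all.

All randomness flows from a single integer seed; the same config is
guaranteed to produce a byte-identical Newick string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from ._errors import ValidationError
from .tree_io import DatedTree

__all__ = ["ClockSimConfig", "simulate_clock_tree", "permute_dates"]


@dataclass
class ClockSimConfig:
    """Simulation settings.

    ``rate`` is substitutions/site/year. ``root_date`` is the (decimal-year)
    time of the root; tips are sampled uniformly within the last
    ``sampling_window`` years of a tree spanning ``tree_height`` years, so
    every tip date lies in [root_date + tree_height - sampling_window,
    root_date + tree_height]. Defaults describe a measurably evolving
    pathogen-like dataset: 50 tips, 1e-3 subst/site/year, a 30-year tree
    sampled over its last 20 years.

    ``noise`` is None, ``("gaussian", sd_frac)`` — additive Gaussian noise
    per branch with sd equal to sd_frac times the mean noise-free branch
    length, clamped at zero — or ``("gamma", shape)`` — multiplicative
    Gamma(shape, 1/shape) noise with mean 1, preserving expected lengths.

    ``clade_rates``, when given, assigns one rate per child subtree of the
    root (tips split as evenly as possible), overriding ``rate`` inside each
    subtree; a rate of exactly 0 yields a clade with no evolution at all.
    """

    n_tips: int = 50
    rate: float = 1e-3
    root_date: float = 1990.0
    sampling_window: float = 20.0
    tree_height: float = 30.0
    noise: Optional[tuple] = None
    clade_rates: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValidationError("n_tips must be at least 3")
        if self.rate <= 0 and not self.clade_rates:
            raise ValidationError("rate must be positive")
        if self.sampling_window <= 0:
            raise ValidationError(
                "sampling_window must be positive: identical tip dates can "
                "never satisfy the distinct-dates eligibility condition"
            )
        if self.tree_height <= self.sampling_window:
            raise ValidationError("tree_height must exceed sampling_window")
        if self.noise is not None:
            kind = self.noise[0]
            if kind not in ("gaussian", "gamma") or len(self.noise) != 2:
                raise ValidationError(f"unknown noise spec: {self.noise!r}")
            if self.noise[1] <= 0:
                raise ValidationError("noise parameter must be positive")
        if self.clade_rates is not None:
            if len(self.clade_rates) < 2:
                raise ValidationError("clade_rates needs at least two clades")
            if any(r < 0 for r in self.clade_rates):
                raise ValidationError("clade rates must be non-negative")
            if self.n_tips < 3 * len(self.clade_rates):
                raise ValidationError(
                    "need at least 3 tips per clade for eligible clades"
                )


def _split_topology(
    parent: dendropy.Node,
    parent_time: float,
    tip_dates: list[float],
    tip_names: list[str],
    rate: float,
    rng: np.random.Generator,
) -> None:
    """Recursively attach a random binary subtree for the given tips.

    Each internal node's time is drawn uniformly between its parent's time
    and the earliest tip date of its subtree; each branch length is
    rate x elapsed time.
    """
    n = len(tip_dates)
    if n == 1:
        leaf = dendropy.Node()
        leaf.taxon = dendropy.Taxon(label=tip_names[0])
        leaf.sim_time = tip_dates[0]
        leaf.sim_rate = rate
        parent.add_child(leaf)
        leaf.edge.length = rate * (tip_dates[0] - parent_time)
        return
    k = int(rng.integers(1, n))
    for dates, names in (
        (tip_dates[:k], tip_names[:k]),
        (tip_dates[k:], tip_names[k:]),
    ):
        if len(dates) == 1:
            _split_topology(parent, parent_time, dates, names, rate, rng)
        else:
            t = float(rng.uniform(parent_time, min(dates)))
            child = dendropy.Node()
            child.sim_time = t
            child.sim_rate = rate
            parent.add_child(child)
            child.edge.length = rate * (t - parent_time)
            _split_topology(child, t, dates, names, rate, rng)


def simulate_clock_tree(config: ClockSimConfig) -> tuple[DatedTree, dict]:
    """Simulate a dated tree; return it with its ground-truth record.

    The truth record maps node_id -> true node date (``node_dates``), gives
    the generating rate (``rate``, or ``clade_rates`` keyed by the node_id
    of each clade root) and the root date, and echoes the config seed.
    """
    rng = np.random.default_rng(config.seed)
    end = config.root_date + config.tree_height

    if config.clade_rates is not None:
        groups = np.array_split(np.arange(config.n_tips), len(config.clade_rates))
        clades = [
            (list(g), r, f"c{ci}") for ci, (g, r) in
            enumerate(zip(groups, config.clade_rates))
        ]
    else:
        clades = None

    tip_dates = rng.uniform(end - config.sampling_window, end, size=config.n_tips)
    tip_dates = [float(d) for d in tip_dates]

    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.sim_time = config.root_date
    root.sim_rate = config.rate

    if clades is None:
        names = [f"t{i}_{tip_dates[i]!r}" for i in range(config.n_tips)]
        # the root itself is the first split: force >= 2 children
        k = int(rng.integers(1, config.n_tips))
        for dates, nm in (
            (tip_dates[:k], names[:k]),
            (tip_dates[k:], names[k:]),
        ):
            if len(dates) == 1:
                _split_topology(root, config.root_date, dates, nm, config.rate, rng)
            else:
                t = float(rng.uniform(config.root_date, min(dates)))
                child = dendropy.Node()
                child.sim_time = t
                child.sim_rate = config.rate
                root.add_child(child)
                child.edge.length = config.rate * (t - config.root_date)
                _split_topology(child, t, dates, nm, config.rate, rng)
        clade_root_nodes = []
    else:
        clade_root_nodes = []
        for idx, rate, prefix in clades:
            dates = [tip_dates[i] for i in idx]
            names = [f"{prefix}t{i}_{tip_dates[i]!r}" for i in idx]
            t = float(rng.uniform(config.root_date, min(dates)))
            child = dendropy.Node()
            child.sim_time = t
            child.sim_rate = rate
            root.add_child(child)
            child.edge.length = rate * (t - config.root_date)
            _split_topology(child, t, dates, names, rate, rng)
            clade_root_nodes.append((child, rate))

    if config.noise is not None:
        _apply_noise(tree, config.noise, rng)

    dates_map = {
        leaf.taxon.label: leaf.sim_time for leaf in tree.leaf_node_iter()
    }
    dated = DatedTree(tree, dates_map)

    truth: dict = {
        "seed": config.seed,
        "root_date": config.root_date,
        "rate": config.rate,
        "node_dates": {
            n.node_id: n.sim_time for n in dated.preorder_nodes() if not n.is_leaf()
        },
        "node_rates": {
            n.node_id: n.sim_rate for n in dated.preorder_nodes() if not n.is_leaf()
        },
    }
    if clade_root_nodes:
        truth["clade_rates"] = {
            node.node_id: rate for node, rate in clade_root_nodes
        }
    return dated, truth


def _apply_noise(tree: dendropy.Tree, noise: tuple, rng: np.random.Generator) -> None:
    kind, param = noise
    edges = [
        n.edge for n in tree.preorder_node_iter()
        if n is not tree.seed_node and n.edge.length is not None
    ]
    if kind == "gaussian":
        mean_len = float(np.mean([e.length for e in edges]))
        sd = param * mean_len
        for e in edges:
            e.length = max(0.0, e.length + float(rng.normal(0.0, sd)))
    else:  # gamma-multiplicative, mean 1
        for e in edges:
            e.length = e.length * float(rng.gamma(param, 1.0 / param))


def permute_dates(tree: DatedTree, seed: int) -> DatedTree:
    """Shuffle tip dates uniformly among tips; topology and lengths untouched.

    The returned tree shares topology with the input but carries a permuted
    label -> date mapping (labels keep their original embedded date text,
    which no longer reflects the assigned date). This is the null model in
    which sampling dates carry no information about divergence.
    """
    if tree.tip_dates is None:
        raise ValidationError("tree has no tip dates to permute")
    if len(set(tree.tip_dates.values())) < 2:
        raise ValidationError("permutation needs at least 2 distinct dates")
    rng = np.random.default_rng(seed)
    labels = list(tree.tip_dates)
    values = [tree.tip_dates[t] for t in labels]
    perm = rng.permutation(len(values))
    return tree.with_dates({labels[i]: values[perm[i]] for i in range(len(labels))})
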