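"""Per-node temporal-signal scan via root-to-tip linear regression.

For every internal node of a dated tree (root included) we regress the
genetic distance from that node to each of its descendant tips on the tips'
sampling dates. Under a strict molecular clock the slope estimates the
substitution rate (substitutions/site/year), the x-intercept estimates the
date of the node itself, and R² measures how clock-like the clade is.

A node is only fitted when it passes three eligibility conditions, checked
in this order:

1. it is the parent of at least 3 tips;
2. there are at least 3 distinct (date, distance) combinations;
3. there are at least 2 different sampling dates.

A node "has temporal signal" when it is eligible, the slope is positive and
the slope's p-value is at or below ``alpha`` (default 0.05).

Distances are measured from the focal node, not the global root. The two
conventions differ only by a constant offset per clade, which leaves slope,
p-value and R² untouched; the local convention makes each clade's
x-intercept an estimate of that clade's own root date.

The scan is fully deterministic: no randomness anywhere in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._errors import ValidationError
from .tree_io import DatedTree

__all__ = [
    "RegressionFit",
    "NodeReport",
    "ScanConfig",
    "ScanResult",
    "node_to_tip_distances",
    "all_node_tip_distances",
    "check_eligibility",
    "fit_rtt_regression",
    "scan_tree",
    "residual_outliers",
]

# SSE below this fraction of SStot is numerically indistinguishable from a
# perfect fit; the conventions p=0, adj_r2=1 then apply.
_PERFECT_FIT_RTOL = 1e-14

REASON_NONE = "none"
REASON_TOO_FEW_TIPS = "too-few-tips"
REASON_TOO_FEW_COMBOS = "too-few-distinct-combinations"
REASON_TOO_FEW_DATES = "too-few-distinct-dates"


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary-least-squares fit of distance (response) on date (predictor).

    ``slope`` is in substitutions/site/year, ``intercept`` in
    substitutions/site at year 0, ``p_value`` is the two-sided slope t-test
    with n-2 degrees of freedom, and ``x_intercept`` (= -intercept/slope) is
    the estimated date at which the regression line crosses zero distance —
    absent when the slope is zero.
    """

    n: int
    slope: float
    intercept: float
    p_value: float
    r2: float
    adj_r2: float
    x_intercept: Optional[float]

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


@dataclass(frozen=True)
class NodeReport:
    """Eligibility verdict and (when eligible) the fit for one internal node."""

    node_id: int
    anchor: str  # lexicographically smallest descendant tip label
    n_tips: int
    eligible: bool
    ineligibility_reason: str
    fit: Optional[RegressionFit]
    significant: bool
    p_adjusted: Optional[float] = None


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of the scan.

    ``alpha`` is the significance threshold on the slope p-value (0.05 by
    default). ``one_sided`` tests H1: slope > 0 instead of the default
    two-sided test (either way a node is only flagged when the slope is
    positive). ``correction='benjamini-hochberg'`` adjusts p-values across
    all eligible nodes before flagging. ``combo_tolerance`` is the absolute
    tolerance below which two (date, distance) pairs count as identical for
    the distinct-combination condition; 0 means exact equality.
    """

    alpha: float = 0.05
    min_tips: int = 3
    min_distinct_combos: int = 3
    min_distinct_dates: int = 2
    correction: str = "none"
    combo_tolerance: float = 0.0
    one_sided: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_tips < 3:
            raise ValidationError("min_tips must be at least 3")
        if self.correction not in ("none", "benjamini-hochberg"):
            raise ValidationError(f"unknown correction: {self.correction!r}")
        if self.combo_tolerance < 0:
            raise ValidationError("combo_tolerance must be >= 0")


@dataclass
class ScanResult:
    """One NodeReport per internal node, in preorder, plus provenance."""

    config: ScanConfig
    reports: list[NodeReport]
    tree_fingerprint: str

    def significant_reports(self) -> list[NodeReport]:
        return [r for r in self.reports if r.significant]

    def report_for(self, node_id: int) -> NodeReport:
        for r in self.reports:
            if r.node_id == node_id:
                return r
        raise ValidationError(f"no report for node {node_id}")


# -- distances ---------------------------------------------------------------


def all_node_tip_distances(tree: DatedTree) -> dict[int, dict[str, float]]:
    """Distance from every internal node to each of its descendant tips.

    Single postorder pass: each node's map is the union of its children's
    maps shifted by the child edge lengths, so the total cost is linear in
    (number of tips x tree depth) rather than quadratic traversals.
    """
    dist: dict[int, dict[str, float]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            continue
        acc: dict[str, float] = {}
        for child in node.child_nodes():
            elen = child.edge.length
            if child.is_leaf():
                acc[child.taxon.label] = elen
            else:
                for tip, d in dist[child.node_id].items():
                    acc[tip] = d + elen
        dist[node.node_id] = acc
    return dist


def node_to_tip_distances(tree: DatedTree, node_id: int) -> dict[str, float]:
    """Path length from *node_id* to each descendant tip."""
    node = tree.node(node_id)
    if node.is_leaf():
        raise ValidationError(f"node {node_id} is a tip; distances need an internal node")
    return all_node_tip_distances(tree)[node_id]


# -- eligibility --------------------------------------------------------------


def _distinct_count(values: Sequence, tol: float) -> int:
    """Number of distinct values / pairs under an absolute tolerance.

    With tol = 0 this is exact set cardinality. With tol > 0, values are
    greedily clustered: a value joins the first existing representative
    within tol (componentwise for pairs).
    """
    if tol == 0.0:
        return len(set(values))
    reps: list = []
    for v in values:
        if isinstance(v, tuple):
            hit = any(all(abs(a - b) <= tol for a, b in zip(v, r)) for r in reps)
        else:
            hit = any(abs(v - r) <= tol for r in reps)
        if not hit:
            reps.append(v)
    return len(reps)


def check_eligibility(
    dates: Sequence[float],
    distances: Sequence[float],
    config: Optional[ScanConfig] = None,
) -> tuple[bool, str]:
    """Apply the three eligibility conditions, in order; first failure wins."""
    if config is None:
        config = ScanConfig()
    if len(dates) != len(distances):
        raise ValidationError(
            f"dates ({len(dates)}) and distances ({len(distances)}) differ in length"
        )
    if len(dates) < config.min_tips:
        return False, REASON_TOO_FEW_TIPS
    pairs = list(zip(dates, distances))
    if _distinct_count(pairs, config.combo_tolerance) < config.min_distinct_combos:
        return False, REASON_TOO_FEW_COMBOS
    if _distinct_count(list(dates), config.combo_tolerance) < config.min_distinct_dates:
        return False, REASON_TOO_FEW_DATES
    return True, REASON_NONE


# -- regression ---------------------------------------------------------------


def fit_rtt_regression(
    dates: Sequence[float], distances: Sequence[float]
) -> RegressionFit:
    """OLS of distance on date, from raw sums.

    slope = Sxy/Sxx; intercept = ybar - slope*xbar;
    r2 = 1 - SSE/SStot; adj_r2 = 1 - (1 - r2)(n-1)/(n-2);
    p = two-sided Student-t tail at t = slope/SE, SE = sqrt(SSE/((n-2) Sxx)).

    Degenerate conventions: a perfect fit (SSE = 0) gives p = 0 and
    adj_r2 = 1; constant distances (SStot = 0) give slope = 0, r2 = adj_r2 =
    0, p = 1 and no x-intercept.
    """
    x = np.asarray(dates, dtype=float)
    y = np.asarray(distances, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError(f"regression needs at least 3 points, got {n}")
    if y.size != n:
        raise ValidationError("dates and distances differ in length")

    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    dy = y - ybar
    sxx = float(dx @ dx)
    sxy = float(dx @ dy)
    sstot = float(dy @ dy)
    if sxx == 0.0:
        raise ValidationError(
            "all dates identical (Sxx = 0): eligibility should have excluded this"
        )

    if sstot == 0.0 or bool(np.all(y == y[0])):
        return RegressionFit(
            n=n, slope=0.0, intercept=float(ybar), p_value=1.0, r2=0.0,
            adj_r2=0.0, x_intercept=None,
        )

    slope = float(sxy / sxx)
    intercept = float(ybar - slope * xbar)
    sse = float(np.sum((y - (intercept + slope * x)) ** 2))

    if sse <= _PERFECT_FIT_RTOL * sstot:
        r2 = 1.0
        adj_r2 = 1.0
        p = 0.0
    else:
        r2 = 1.0 - sse / sstot
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        se = math.sqrt(sse / ((n - 2) * sxx))
        t = slope / se
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
        p = min(p, 1.0)

    x_intercept = float(-intercept / slope) if slope != 0.0 else None
    return RegressionFit(
        n=n, slope=slope, intercept=intercept, p_value=p, r2=r2, adj_r2=adj_r2,
        x_intercept=x_intercept,
    )


def _effective_p(fit: RegressionFit, one_sided: bool) -> float:
    """p-value used for the significance decision.

    One-sided (H1: slope > 0) halves the two-sided p when the slope is
    positive; non-positive slopes can never be flagged, so their one-sided
    p is left at >= 0.5 equivalent (we report 1 - p/2).
    """
    if not one_sided:
        return fit.p_value
    if fit.slope > 0:
        return fit.p_value / 2.0
    return 1.0 - fit.p_value / 2.0


def _bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


# -- the scan -----------------------------------------------------------------


def scan_tree(tree: DatedTree, config: Optional[ScanConfig] = None) -> ScanResult:
    """Test temporal signal at every internal node of *tree* (root included).

    Returns one :class:`NodeReport` per internal node in preorder. With
    ``correction='benjamini-hochberg'`` the significance flags use p-values
    adjusted across all eligible nodes.
    """
    if config is None:
        config = ScanConfig()
    if tree.tip_dates is None:
        raise ValidationError("tree has no tip dates; run parse_tip_dates first")
    if tree.n_tips < 3:
        raise ValidationError(f"tree has {tree.n_tips} tips; at least 3 required")

    distances = all_node_tip_distances(tree)
    reports: list[NodeReport] = []
    eligible_idx: list[int] = []
    eff_pvals: list[float] = []

    for node in tree.preorder_nodes():
        if node.is_leaf():
            continue
        node_id = node.node_id
        dmap = distances[node_id]
        tips = tree.descendant_tip_labels(node_id)
        dates = [tree.tip_dates[t] for t in tips]
        dists = [dmap[t] for t in tips]
        anchor = min(tips)

        ok, reason = check_eligibility(dates, dists, config)
        if not ok:
            reports.append(
                NodeReport(
                    node_id=node_id, anchor=anchor, n_tips=len(tips),
                    eligible=False, ineligibility_reason=reason, fit=None,
                    significant=False,
                )
            )
            continue

        fit = fit_rtt_regression(dates, dists)
        reports.append(
            NodeReport(
                node_id=node_id, anchor=anchor, n_tips=len(tips), eligible=True,
                ineligibility_reason=REASON_NONE, fit=fit, significant=False,
            )
        )
        eligible_idx.append(len(reports) - 1)
        eff_pvals.append(_effective_p(fit, config.one_sided))

    if config.correction == "benjamini-hochberg" and eligible_idx:
        decision_pvals = _bh_adjust(eff_pvals)
    else:
        decision_pvals = eff_pvals

    from dataclasses import replace

    for idx, p_dec in zip(eligible_idx, decision_pvals):
        rep = reports[idx]
        assert rep.fit is not None
        sig = rep.fit.slope > 0 and p_dec <= config.alpha
        reports[idx] = replace(
            rep,
            significant=sig,
            p_adjusted=(p_dec if config.correction != "none" else None),
        )

    return ScanResult(
        config=config, reports=reports, tree_fingerprint=tree.fingerprint()
    )


# -- outliers -----------------------------------------------------------------


def residual_outliers(
    fit: RegressionFit,
    dates: Sequence[float],
    distances: Sequence[float],
    labels: Sequence[str],
    k: float = 3.0,
) -> list[str]:
    """Tips whose externally studentized residual exceeds *k* in magnitude.

    Each residual r_i is scaled by s_(i) * sqrt(1 - h_i), where the error
    variance s_(i)^2 = (SSE - r_i^2/(1 - h_i)) / (n - 3) excludes point i
    itself and the leverage is h_i = 1/n + (x_i - xbar)^2 / Sxx. The
    deletion form is used because internally studentized residuals are
    bounded by sqrt(n - 2), which would make a threshold like k = 3
    unreachable on small clades no matter how gross the outlier. Needs
    n >= 4; below that the studentization is unstable and an empty list is
    returned with a warning. A perfect fit has no outliers by definition.
    """
    import warnings

    x = np.asarray(dates, dtype=float)
    y = np.asarray(distances, dtype=float)
    n = x.size
    if not (y.size == n == len(labels)):
        raise ValidationError("dates, distances and labels must have equal length")
    if n < 4:
        warnings.warn(
            "residual studentization needs at least 4 points; returning no outliers",
            UserWarning,
            stacklevel=2,
        )
        return []

    resid = y - (fit.intercept + fit.slope * x)
    sse = float(resid @ resid)
    dy = y - y.mean()
    sstot = float(dy @ dy)
    if sse <= _PERFECT_FIT_RTOL * sstot:
        return []
    dx = x - x.mean()
    sxx = float(dx @ dx)
    h = 1.0 / n + dx**2 / sxx
    one_minus_h = np.clip(1.0 - h, 1e-12, None)
    s2_del = np.clip(sse - resid**2 / one_minus_h, 0.0, None) / (n - 3)
    out = []
    for lab, r, s2, omh in zip(labels, resid, s2_del, one_minus_h):
        denom = math.sqrt(s2 * omh)
        t_i = math.inf if denom == 0.0 and r != 0.0 else (
            0.0 if denom == 0.0 else r / denom
        )
        if abs(t_i) > k:
            out.append(lab)
    return out
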