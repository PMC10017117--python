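# Methods

## Model and procedure

`temposcan` screens a rooted phylogeny for measurably evolving clades. The
input tree must have branch lengths in expected substitutions per site
(e.g. an ML tree); it must *not* be a chronogram, and the package never
re-roots it — the rooting is taken as given, and a basal polytomy only
triggers a warning that root-level statistics may be arbitrary.

For every internal node v (preorder, root first) the scanner collects the
descendant tips' sampling dates t_i (decimal years) and the path lengths
d_i from v to each tip, and fits ordinary least squares d = β₀ + β₁ t.
Under a strict molecular clock operating within the clade, E[d_i] =
μ (t_i − t_v), so β₁ estimates the within-clade substitution rate μ and the
x-intercept −β₀/β₁ estimates the clade root's date t_v. The slope is tested
with a two-sided Student t-test on n − 2 degrees of freedom; a node is
flagged as having temporal signal when the slope is positive and p ≤ α.

Eligibility gates the fit, in this order: (i) ≥ 3 descendant tips,
(ii) ≥ 3 distinct (date, distance) pairs, (iii) ≥ 2 distinct dates. The
first failing condition is the one reported. Distinctness is exact equality
by default; `combo_tolerance` clusters values within an absolute tolerance
for trees serialized with truncated precision.

### Distance origin

Distances are measured from the focal node, not the global root. The two
conventions differ per clade by a constant offset in the response, which
OLS absorbs entirely into β₀: slope, p-value, R² and adjusted R² are
identical either way (this offset invariance is asserted in the tests).
The local convention was chosen because it makes each clade's x-intercept
an estimate of that clade's own root date, which is the quantity a user
planning a clade-level tip-dating run wants. When comparing x-intercepts
against tools using global-root distances, account for this.

### Significance details

The default test is two-sided combined with the positivity requirement on
the slope; `one_sided=True` instead uses the one-sided p (half the
two-sided value when the slope is positive). No multiple-testing
correction is applied by default — the scan is an exploration device whose
per-node p-values are already optimistic because root-to-tip points share
ancestry and are positively correlated; Benjamini–Hochberg across eligible
nodes is available as an opt-in (`correction="benjamini-hochberg"`). Screen
first, then validate candidate clades with a date-randomization test or
formal model comparison.

### Degenerate fits

Numerical conventions, chosen so every input produces defined, testable
output:

* perfect fit (SSE ≤ 1e−14 × SStot, the float-noise floor): p = 0,
  R² = adjusted R² = 1;
* constant distances (all responses identical): slope = 0, p = 1,
  R² = adjusted R² = 0, no x-intercept;
* zero slope otherwise: x-intercept undefined (reported as absent);
* all dates identical cannot reach the fit (eligibility excludes it); it
  raises a defensive error if called directly.

### Outlier flagging

Tips deviating grossly from a clade's regression line (wrong dates,
contamination, recombination) are flagged by externally studentized
(deletion) residuals: residual r_i scaled by s₍ᵢ₎ √(1 − h_i), with leverage
h_i = 1/n + (x_i − x̄)²/S_xx and the error variance s₍ᵢ₎² estimated with
point i removed. The deletion form is essential at clade sizes this scan
routinely meets: internally studentized residuals are bounded by √(n − 2),
so the conventional |t| > 3 rule could never fire on a five-tip clade no
matter how extreme the outlier. Flagging needs n ≥ 4 (df = n − 3 ≥ 1);
smaller clades return no outliers, with a warning. This operationalizes
what is otherwise a visual inspection of the regression plot, and is an
extension beyond the scan proper.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `alpha` | 0.05 | — | significance threshold on the slope p-value |
| `min_tips` | 3 | tips | eligibility condition (i) |
| `min_distinct_combos` | 3 | pairs | eligibility condition (ii) |
| `min_distinct_dates` | 2 | dates | eligibility condition (iii) |
| `combo_tolerance` | 0 | mixed | absolute tolerance for treating pairs as identical |
| `correction` | none | — | optional BH adjustment across eligible nodes |
| `one_sided` | False | — | test H1: slope > 0 instead of two-sided |
| outlier `k` | 3 | sd | threshold on the externally studentized residual |

Dates are decimal years extracted from tip labels (default: last
`_`-delimited field; configurable delimiter/index, or a regex capture
group). Calendar dates can be converted with
`calendar_to_decimal_year(y, m, d)` = y + (day_of_year − 0.5)/days_in_year.
Undated tips abort by default; with pruning enabled they are removed and
the resulting unifurcations collapsed with branch lengths summed, which
provably preserves all remaining patristic distances (tested).

## The simulator

`simulate_clock_tree` generates the validation fixtures. Topology comes
from recursive random splitting of the tip set (Yule-like); node times are
drawn uniformly between the parent's time and the subtree's earliest tip
date; tip dates are uniform in the last `sampling_window` years of a
`tree_height`-year tree; each branch length is rate × elapsed time.
Defaults — 50 tips, rate 10⁻³ substitutions/site/year, root at 1990, a
30-year tree sampled over its last 20 years — describe a typical measurably
evolving RNA-virus dataset, where rates of 10⁻⁴–10⁻² substitutions/site/year
and multi-decade sampling are the norm. By construction every node-to-tip
distance equals rate × elapsed time exactly, so a noise-free tree must
yield adjusted R² = 1, p = 0, slope = rate and x-intercept = the node's own
date at every eligible node; this is the simulator's central testable
guarantee.

Options: `noise=("gaussian", f)` adds per-branch Gaussian noise with sd
equal to f × the mean noise-free branch length, clamped at zero;
`noise=("gamma", k)` multiplies each branch by a Gamma(k, 1/k) variate
(mean 1, expectation-preserving). `clade_rates=[r₁, …, r_k]` gives the root
k child subtrees with their own rates (tips split evenly), emulating trees
whose temporal signal exists only at reduced timescales — a rate of 0
produces a clade with exactly zero signal. `permute_dates` shuffles dates
among tips for permutation-null experiments. All randomness derives from
one integer seed; identical configs produce byte-identical Newick.

What the simulator does **not** emulate: sequence-level evolution (no
substitution models or alignments), rate autocorrelation or lognormal
relaxed clocks, sampling biased by clade or time, measurement error in
dates, or realistic (e.g. coalescent) topologies. Passing tests therefore
demonstrate correctness of the scan arithmetic and its behaviour under
idealized clock violations, not performance on any particular empirical
dataset.

## Variant-site extraction

A column is variant within a sequence set when it shows ≥ 2 distinct
unambiguous nucleotide states (A/C/G/T after upper-casing, U→T). Gaps
(`-`, `.`) and IUPAC ambiguity codes are ignored so missing data cannot
create spurious variation; `gaps_as_state=True` counts the gap as a fifth
state. Variance is computed *within the selected clade*, after subsetting —
a column variant across the full alignment but constant among the clade's
tips is dropped. Output records follow the tree's left-to-right tip order;
column indices are 0-based internally and 1-based in the human-readable
sidecar file (stated explicitly to prevent off-by-one drift). FASTA output
wraps at 60 columns with LF endings.

## Determinism and numerics

The scan contains no randomness. All floats are serialized in shortest
round-trip form (`repr`), so summary TSV/JSON, simulated Newick and
annotated Nexus files are byte-identical across runs and survive
write→read round trips bit-exactly. Per-node distances are accumulated in
one postorder pass (child maps shifted by the child edge length), linear in
tips × depth. The regression uses centered sums, which are numerically
stable at date magnitudes ~2000 where raw-sum textbook formulas lose ~10
digits to cancellation — the test-suite oracle therefore evaluates the
raw-sum algebra in exact rational arithmetic.

## Problem sizes used in validation

The shipped checks use trees of 10–200 tips, 200-replicate noise studies at
50 tips, 1000-replicate permutation nulls at 20 tips, 1000 random
regression datasets and 500 random alignments — sizes at which every
property being asserted is already fully expressed while the whole suite
runs in seconds.

## Known limitations

* p-values are anti-conservative under phylogenetic correlation; the
  permutation-null check bounds the inflation empirically (observed ~3–8%
  at nominal 5% on simulated clock trees) but no analytical correction is
  applied.
* No best-fitting-root search: an incorrectly rooted input yields an
  incorrect root-level verdict (subclades are unaffected).
* Chronograms (time-scaled trees) are silently meaningless as input: the
  regression would recover slope ≈ 1/year trivially. The package cannot
  detect this from the file alone.
* The eligibility minimum of 3 tips admits fits with a single residual
  degree of freedom, whose p-values are extremely weak evidence either way.
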