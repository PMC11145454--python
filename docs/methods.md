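# Methods

## Model and assumptions

Per hashtag, the normalized signal across cells is modeled as a
two-component Gaussian mixture: a background component (cells not stained
with this hashtag, plus ambient tag) and a positive component (the
hashtag's own cells, plus doublets containing them). The model assumes the
two modes are separable in the normalized space; it makes no assumption
about the counts' marginal distribution beyond that. Hashtags are treated
independently, which is what makes the method robust to imbalanced sample
sizes: one rare sample only affects its own hashtag's mixture weights, not
the other cutoffs.

The hybrid integration assumes the genotype channel's *clustering* is
trustworthy whenever the convergence score is high, while remaining
agnostic about cluster *names* — names are inferred from the hashing
overlap. Its failure mode (SNP clustering corrupted by a high true-doublet
rate) is exactly what a low convergence score detects, triggering the
fallback to hashing-only labels.

## Normalization

CLR is the default: `log((w_i + p)/g(w + p))`, computed per hashtag across
cells, natural log, geometric mean `g`. The transform is defined without a
pseudocount only for strictly positive vectors; real HTO matrices contain
zeros, so the package adds `p = 1` by default, refuses `p = 0` on data
containing zeros, and records the pseudocount on the output. `log`
normalization is `log1p`. Both are strictly monotone per column, so they
never reorder cells within a hashtag.

## Low-signal reshaping

For pools of more than four hashtags, a hashtag's positives are roughly
`1/N` of cells and the background peak dominates the likelihood. Values
below the empirical bound `c` (1.5 CLR / 3 log — the same constants used as
cutoff floors) are sorted ascending and the values at 1-based positions
`1, 1+θ, 1+2θ, …` with `θ = floor(N/2)` are kept, positions running up to
and including the number of low values; all values at or above `c` are
kept. The inclusive position bound is a deliberate reading: a strict bound
would unconditionally discard the largest retained low value, which has no
statistical motivation. Because the thinning is an order-statistic
subsample, it preserves the shape of the low-signal distribution while
rebalancing the two components — *provided* the background sits below `c`.
With log normalization and background centred near `c = 3` the thinning
truncates the background asymmetrically; CLR (background well below 1.5)
does not have this issue, which is one reason it is the default.

## Mixture fitting

EM on the (possibly reshaped) signal, at least 20 points required.
Initialization is a hard split at the median with closed-form moment
estimates per half — deterministic by construction, no random restarts.
Convergence: relative log-likelihood change `|Δll| / max(1, |ll|) < 1e-8`,
at most 1000 iterations. Components are relabeled after fitting so
`μ₁ < μ₂`. A component SD collapsing below `1e-6 ×` the signal SD or a
weight below `1e-3` aborts the fit with a degenerate-fit signal carrying
the single-Gaussian fallback; the calling pipeline then uses the empirical
floor as that hashtag's cutoff and flags it.

## Cutoff and validation

`cutoff = μ₁ + (σ₁^(1/n)/(σ₁^(1/n)+σ₂^(1/n)))(μ₂−μ₁)`, rank `n = 2` by
default (the n-th roots pull the cutoff toward the tighter component; as
`n → ∞` it tends to the midpoint). The mixing factor is strictly inside
(0, 1), so `μ₁ < cutoff < μ₂` always.

A cutoff below the empirical floor triggers the density check: the full
(unreshaped) signal restricted to `[μ₁, μ₂]` is histogrammed with Sturges
bins, counts are linearly interpolated between bin centers onto a 512-point
even grid over `[μ₁, μ₂]`, and the grid point of minimum density becomes
the cutoff. The full signal is used rather than the reshaped one because
the valley location is a property of the data, not of the rebalanced fit
sample. With fewer than 10 values in the window the floor itself is used,
with a warning. Ties in the density argmin resolve to the leftmost grid
point.

A signal exactly equal to the cutoff counts as positive; the convention is
arbitrary but pinned by tests.

## Hybrid integration

Pairing maximizes shared-cell counts on the hashing-singlet × genotype-
singlet contingency block: pairs are visited in descending count order
(ties lexicographic by cluster then group) and matched one-to-one. Count
overlap is used as the correlation measure because it is the quantity the
contingency table defines exactly; one-to-one matching prevents two
clusters from claiming the same sample. A cluster beaten to its best group
is conflict-flagged; clusters left over when groups run out (the supported
up-to-one-unlabeled-sample design) are reported unmatched and their cells
become `Unassigned`.

`C = N1/(N1+N2)` over both-singlet cells; `C` is defined as 1 (with a
warning) when no such cells exist, since there is no evidence of
disagreement. The resolution cases follow the table in the README. Cells
present in only one input are resolved from that side — notably,
genotype-only singlets receive their cluster's paired sample label, the
mechanism that lets an experiment hashtag only a small aliquot per donor.
These cells carry `genotype_only`/`hashing_only` case tags, kept distinct
from the joined-population cases so the case counts still partition the
joined cells exactly.

## Evaluation

Singlet-oriented confusion counts; by default a true positive requires the
predicted sample identity to equal the truth, and a truth singlet predicted
as a *different* sample counts as a false negative. This is the stricter of
the two readings of "singlets correctly identified as singlets" and is the
safer default for benchmarking; `require_identity_match=False` relaxes to
status-only. Ratios with empty denominators (and the wholly uninformative
TP = 0 case) are reported as 0 with a `degenerate` flag.

## Synthetic data generator

The generator emulates: bimodal per-hashtag counts (lognormal background ×
lognormal positive), configurable doublet rate with doublets formed by
summing two cells' count vectors (physical co-encapsulation), imbalanced
sample sizes, per-hashtag staining failure (multiplicative suppression of
the positive draws), an unhashed fraction (background-only hashtags, valid
genotype), and a genotype channel derived from the truth with independent
doublet/unassigned corruption rates.

Defaults describe a well-stained eight-donor pool at a scale a desk
analysis can iterate on: 8 × 625 = 5000 cells; background lognormal
meanlog 2.5, sdlog 0.6 (~12 UMIs); positive meanlog 6.0, sdlog 0.5
(~400 UMIs) — about a 30-fold separation, typical of a good staining;
doublet rate 5% (routine 10x super-loading); genotype-doublet rate 5% and
unassigned rate 0.5% (souporcell-like error levels). Lognormal rather than
negative-binomial counts keeps the normalized-space bimodality and the
generating valley analytically accessible; it does not model ambient-tag
correlation across hashtags, UMI saturation, or transcriptome content, so
passing recovery tests demonstrates correctness of the calling machinery
on cleanly bimodal signal, not performance on every pathological real
dataset.

## Known limitations

* A *completely* failed hashtag (positives indistinguishable from
  background) yields a mixture fit entirely inside the background; the
  density-minimum adjustment then still places a low cutoff and the
  hashtag produces spurious positives, deflating the hashing-only singlet
  rate (see `examples/03_staining_failure_rescue.py`). The hybrid mode
  recovers these cells; hashing-only users should treat a flagged,
  near-floor cutoff with suspicion.
* The empirical floors are constants in normalized units; datasets with
  unusually high ambient tag levels may need them raised.
* The convergence threshold 0.7 is a quality gate, not a fitted quantity;
  between ~0.7 and ~0.95 the case-3 conflict count is worth inspecting
  before trusting rescues.
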