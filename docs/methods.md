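# Methods

This note documents the statistical model, the algorithms, the defaults
and the numerical conventions of `pcfseg`, and what the synthetic-data
generators do and do not emulate.

## Model and criterion

Observations on one chromosome arm are y_j = z_j + ε_j, j = 1..p, with z
piecewise constant.  A segmentation S = {I_1, …, I_M} is scored by the
penalized least-squares criterion

    L(S | y, γ) = Σ_{I∈S} Σ_{j∈I} (y_j − ȳ_I)² + γ·|S|,

whose minimizer over z, given S, is the segment average on each segment.
Expanding the square shows L differs from the reduced form

    L′(S | y, γ) = − Σ_{I∈S} (Σ_{j∈I} y_j)² / n_I + γ·|S|

by the constant Σ y_j², so the dynamic program optimizes L′.  Segmentation
is always per arm: breakpoints never cross a centromere.

## Exact dynamic program

Let e_k be the optimal L′ of the first k probes (e_0 = 0) and d_jk =
−(Σ_{r=j..k} y_r)²/(k−j+1) the reduced cost of a final segment j..k.  Then

    e_k = min_{j ≤ k} ( d_jk + e_{j−1} + γ ),

and the argmin t_k is stored for backtracking.  The whole vector
(d_1k, …, d_kk) is updated in O(k) from the running-sum vector
a_k = [a_{k−1} 0] + y_k via d_k = −a_k ∗ a_k / (k:1), giving O(p²) total
work with vectorized inner steps (double precision; no compensated
summation — at the p ≲ 10⁵ arm lengths of current arrays the accumulated
rounding is far below all tolerances used).  A naive double-loop
implementation of the same recursion is kept in `simulate.dp_reference`
and tested to produce identical e and t arrays.

Minimum segment length (`kmin`, default 5): the inner minimum is
restricted to j with k−j+1 ≥ kmin, and prefixes that cannot themselves be
legally segmented carry cost +∞.  `kmin=1` recovers the unconstrained
algorithm.  Sequences shorter than kmin return one segment with a warning.
Ties in the argmin break toward the smallest j (longest final segment),
making results deterministic.

Penalty scaling: with `normalize=True` (the default in `PenaltySpec`) the
penalty becomes γ·σ̂², where σ̂ is the difference-based robust residual SD
of the arm (below).  This is algebraically identical to dividing the data
by σ̂ before fitting and rescaling the means after, and makes a single γ
comparable across samples with different noise levels.  The conservative
default is γ = 40; null simulations (see the acceptance script) locate a
specificity-motivated lower bound at γ ≈ 8–12, where the rate of falsely
called aberrations per 10,000 pure-noise probes is roughly 10, 2 and 0.5
at γ = 8, 10 and 12.  Automatic penalty selection (AIC/BIC/CV) is
deliberately not offered; `gamma_diagnostics` tabulates segment counts and
residual variance over a γ grid instead.

## Multi-sample and allele-specific variants

The joint criterion for n samples on a shared grid is the sum of the
per-sample criteria at one common segmentation, so each segment costs nγ.
The recursion is unchanged except that the running sums form an n×k matrix
and the candidate costs are summed over samples.  Because noise levels
differ, each sample is pre-scaled by w_i/σ̂_i by default (weights w_i = 1
unless supplied); segment means are always reported as arithmetic averages
of the input values.

Allele-specific segmentation preprocesses paired logR/BAF tracks:

1. BAF is mirrored around 0.5 (b → 1−b for b > 0.5);
2. mirrored values below θ_baf (default 0.1) are treated as germline
   homozygous and dropped, as are missing values; θ_baf = 0 is for data
   where homozygotes were already set to NA from a matched normal;
3. every logR probe is paired with the nearest retained BAF probe
   (equidistant ties to the leftward probe — an arbitrary but
   deterministic choice) and logR values sharing a BAF probe are averaged.

The reduced two-track matrix is then segmented jointly (penalty 2γ per
segment) with per-track variance normalization — necessary because BAF and
logR live on different scales and the joint criterion would otherwise be
dominated by the wider track.  The allele-specific default penalty follows
the single-sample default (γ = 40) and is exposed as a flag.  Segment
boundaries are mapped back to original coordinates as the position of the
first logR probe paired into the segment's first BAF probe; this mapping
is a convention (the reduced grid does not uniquely invert).

## Fast heuristic

High-pass filters score each position by the difference between weighted
sums of the k observations after and before it, with the outer ⌊k/3⌋
observations of each window down-weighted to 0.5 (softening edge
artifacts).  Widths 3 and 12 are used, plus a width equal to kmin so
aberrations at the minimum accepted length have a matched detector (the
kmin-matched filter is used in the single-sample variant only).
Candidates are local maxima of |score| (plateaus keep their leftmost
position) above per-filter thresholds; a shared quantile level is chosen
by bisection so the union covers `target_fraction` of positions (default
0.15).  The quantile mechanism makes the operating point data-adaptive:
on pure noise it yields the target fraction by construction, while strong
breakpoints always score at the top of the ranking.  A sufficiently strong
step is essentially always nominated, though noise can shift the selected
peak by one probe.

The restricted dynamic program then works on per-block aggregates (block
sums u_k and probe counts c_k between consecutive candidates), costing
O(q²) for q candidates; with the full candidate set it reproduces the
exact algorithm bit-for-bit, and in general its cost can only exceed the
exact optimum.  Arms longer than 15,000 probes are processed in
subsequences of 5,000 probes overlapping by 1,000: each pass re-segments
the prefix seen so far using the breakpoints already accepted plus fresh
filter candidates from the new window, and segment means are recomputed
from the full sequence at the end.  On synthetic 20,000-probe profiles
with twenty segments (unit noise SD, jump heights 0.5–2) the fast fit's
loss in variance reduction relative to the exact fit is below 10⁻⁴ in
aggregate across profiles; the acceptance test asserts the mean gap over
its 20 replicates, the dataset-level form of the statement, since an
individual replicate with an unluckily weak 0.5-SD jump can occasionally
exceed the bound alone.

## Winsorization and scale estimation

Outliers are handled by clipping residuals around a trend: the trend is a
running median with half-width `k_trend` = 25 (windows shrink at arm
boundaries — no padding is invented; even-sized windows use the midpoint
average, the standard deterministic choice), the residual scale is
s = 1.4826·MAD, and values become trend + clip(residual, ±τ·s).  τ
defaults to 2.5, the midpoint of the conventional 1.5–3 range.  A zero
scale (noiseless fixtures) is floored at 10⁻¹² with a warning, which pulls
any spike to the trend.  An optional iterative mode re-estimates the trend
from a PCF fit to the Winsorized values and clips again (`n_iter` times,
default 1); the plain single pass is the default and is sufficient in
practice.

The residual SD used for penalty scaling is `mad(diff(y))/√2`, aggregated
over a sample's arms by the median.  Lag-1 differencing cancels the
piecewise constant signal except at the few true breakpoints, which the
MAD ignores, so the estimate tracks the noise SD rather than segment
structure; a raw MAD of the values would be inflated by genuine segments.

Missing values are imputed as the mean of the nearest observed probe on
each side within the arm (one-sided at edges) — adequate for the short
gaps typical of filtered arrays, not a general imputation model.

## Aberration calling

Fitted probe values above θ₊ are gains, below −θ₋ losses, otherwise
normal; inequalities are strict, so exact threshold equality is normal.
Defaults θ₊ = θ₋ = 0.1 in log2 units; smaller thresholds (0.05) suit
high-frequency summaries over many samples.  Frequencies are per-probe
fractions of samples called in each state.

## Synthetic data and what the tests show

The generators produce: (a) null sequences of iid noise, optionally from
the contaminated normal (1−α)·N(0,σ²) + α·N(0,d²σ²) with the classical
α = 0.05, d = 3; (b) piecewise constant profiles with recorded truth; and
(c) paired logR/BAF tracks for balanced, hemizygous-loss, single-copy-gain
and copy-neutral-LOH events, with an aberrant-cell fraction (default 0.5)
attenuating both tracks as tumor/normal admixture does, a configurable
germline-homozygote fraction (default 0.33) parked near BAF 0/1, and BAF
noise (SD 0.03) clipped to [0,1].  All generators take explicit integer
seeds and use no global random state.

These designs capture the features the algorithms are built for —
piecewise constant signal, heavy-tailed noise, allelic geometry — but not
GC-content waves, probe-specific biases, spatially correlated noise or
platform-dependent signal compression.  Passing tests therefore establish
algorithmic correctness and the stated statistical operating points, not
end-to-end performance on any particular platform.

Correctness is anchored in exhaustive enumeration: for p ≤ 16 every
segmentation honoring kmin is enumerated and the best is compared with the
dynamic programs (single, multi, candidate-restricted and allele-specific)
on hundreds of random instances, with cost agreement to 10⁻⁹.  The
"falsely called aberrations" measure counts every fitted segment beyond
the first on a null sequence as one false aberration — the simplest
reading; counting breakpoint pairs instead would roughly halve the rates,
and the benchmark's factor-two tolerance absorbs this ambiguity.  The
Winsorization benchmark plants broad aberrations (heights ±0.8–1 at noise
SD 0.3, 2,000 probes) and counts fitted breakpoints farther than 3 probes
from any true breakpoint, at γ = 8 where contamination visibly inflates
false detection; Winsorizing first restores near-clean rates.

## Problem sizes

Defaults throughout the tests and the acceptance script are chosen to
exercise realistic regimes at interactive cost: null specificity uses 20
sequences of 10,000 probes (a typical long arm at 244K resolution), the
fast-vs-exact comparison 20 profiles of 20,000 probes (engaging the
subsequence path), and tail calibration 10⁶ draws.  The exact dynamic
program processes a 10,000-probe arm in ~0.2 s and a 20,000-probe arm in
~0.6 s on one CPU; the fast variant is an order of magnitude quicker at
those lengths.

## Known limitations

- The O(p²) exact algorithm is impractical beyond ~10⁵ probes per arm;
  use the fast variant (the default above 15,000).
- Winsorization's iterative mode uses a fixed iteration count, not a
  convergence criterion.
- The allele-specific variant segments; it does not call allele-specific
  copy numbers, ploidy or aberrant-cell fraction.
- Imputation is local averaging only; arms entirely missing for a sample
  are an error.
- No GC-wave correction; in wavy data the penalty should be raised above
  the null-simulation lower bound.
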