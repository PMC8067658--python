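# Methods

## The extended similarity model

A set of N dichotomous fingerprints of common length m is an N × m table of
bits.  For a subset of n ≥ 2 fingerprints, the coincidence counters

    C_n(k) = #{ positions with exactly k ones among the n fingerprints },  k = 0..n

summarize everything an *additive* similarity coefficient can see (additive
means depending on b and c only through b + c in the pairwise case; the
framework does not cover non-additive coefficients such as Kulczynski, whose
n-ary generalization is left open).  At n = 2 the counters recover the
classical contingency quantities: C₂(2) = a, C₂(1) = b + c, C₂(0) = d.

Each counter is classified by the indicator Δ_n(k) = |2k − n| against a
coincidence threshold γ:

* 1-similarity if 2k − n > γ,
* 0-similarity if n − 2k > γ,
* dissimilarity if |2k − n| ≤ γ.

Counters are graded by weight functions with the normalization
f_s(n) = f_d(n mod 2) = 1.  The resulting six sums — weighted and raw totals
of the 1-similarity, 0-similarity and dissimilarity counters — are the sole
input to every extended coefficient.  Each coefficient exists in a
weighted-denominator (`*_wd`, reported as "w") and an
unweighted-denominator (`*_d`, "nw") variant; numerators are always
weighted.  Asymmetric bases (those ignoring d) additionally exist in a
1-similarity (`1s_*`) and an all-similarity (`s_*`) form; at n = 2 the
latter is the substitution a → a + d, which maps six of the seven asymmetric
bases onto known additive coefficients and maps Jaccard onto the new
coefficient Ja0 = (3a + 3d)/(p + 2a + 2d).

Exactness properties enforced by the test suite: every variant reduces to
its classical binary formula at n = 2 (tolerance 1e−12); the three counter
classes partition {0..n}; Σ_k C_n(k) = m; all coefficients except
Goodman–Kruskal lie in [0, 1] where defined (GK in [−1, 1]).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| γ (coincidence threshold) | n mod 2 | maximizes the number of similarity counters; a position is "similar" when more than half the bits agree.  ⌈n/2⌉ and fixed values are available for experimentation but never default. |
| weight scheme | `fraction` (f_s = Δ/n, f_d = 1 − (Δ − n mod 2)/n) | smooth grading of partial agreement.  `power2` (2^−(n−Δ)) is available but penalizes partial coincidence very harshly; `none` disables grading. |
| p_on (generator bit density) | 0.5 | maximum-entropy choice for unconstrained random dichotomous vectors; all stochastic checks assume it. |
| grid factors | n = 2..15; m ∈ {10, 100, 1000, 100000}; w/nw; 19 coefficients; N = 16 | the full factorial design (2128 cells). |
| subsample | None (exhaustive) | optional seeded cap on combinations per n; 2000 keeps the m = 100000 level to well under a minute with negligible Monte-Carlo error (across-seed spread of the grand mean ≈ 3e−4). |
| SRD reference | row mean | data-fusion consensus; row min/max suit error-like/rate-like columns; an external gold standard can be supplied. |
| CRRN permutations | 10000 | Monte-Carlo null; a Gaussian fit is additionally reported for R > 13, where it is known to approximate the discrete distribution well. |
| cross-validation | k = 7, contiguous | sevenfold is the recommended middle of the 5 < k < 10 range; the randomized mode draws rows with replacement to the same retained size so the two modes are comparable. |

With the default γ and fraction weights, every populated counter at n ≤ 3
has weight exactly 1, so weighting is provably inert for binary and ternary
comparisons — the w/nw grid cells coincide there.

## Numerical choices

* Undefined coefficients (vanishing denominators, e.g. Jaccard–Tanimoto on
  two all-zero fingerprints) raise a typed error in the scalar API and
  propagate as NaN in vectorized paths; grid cells exclude them from the
  mean and report an exclusion count.  Silent 0/1 defaults would bias the
  grid means.
* Curve and grid means are taken over |s|, so the sign-indefinite
  Goodman–Kruskal coefficient is averaged by magnitude like the others.
* Batch coincidence counting uses a chunked float32 selection-matrix
  product (BLAS) followed by an offset bincount; intermediates are kept
  near 100 MB.  Counter values (≤ n ≤ 16) are exact in float32.
* Logarithmic coefficients (the Consonni–Todeschini family) use log1p,
  keeping the "1 +" guards of the closed forms.
* The eSS2 unweighted row and the all-similarity Jaccard unweighted form
  follow the structurally consistent reading (unweighted denominator sums,
  all-similarity sums for eJa_0), which is the only reading that preserves
  the exact n = 2 reduction to SS2 and Ja0.  The Rogot–Goldberg unweighted
  variant weights only its numerators, with both denominators raw.
* SRD: ties receive average (fractional) ranks — the standard
  footrule-compatible convention.  The 0–100 scaling constant is the
  footrule distance between the reference ranking and its reversal
  (2⌊R²/4⌋ untied), which handles ties naturally and makes 100 attainable
  by exact reversal.  Cross-validation rebuilds the reference inside each
  fold so every fold is a complete, self-contained SRD run.

## What the synthetic generator does and does not emulate

The generator draws independent Bernoulli(p_on) bits.  This matches the
random dichotomous vectors of the simulation design and is the right null
model for studying the intrinsic behavior of the coefficients (zigzag
parity effects, weighting gaps, length saturation).  It does **not** emulate
real molecular fingerprints, which have structured, correlated and typically
sparse bit patterns (ECFP-like densities are far below 0.5) and batch
effects between compound series.  Passing the simulation checks therefore
validates the mathematics and the harness, not any claim about ranking
coefficients on a particular chemical library.

## Problem sizes used by the shipped checks

The zigzag check enumerates all C(16, n) subsets (65 518 combinations) at
m = 1000.  The saturation check runs the m = 100000 grid level with the
seeded 2000-per-n subsample cap; subsampling is unbiased and the resulting
grand-mean spread across seeds is ≈ 3e−4.  The full default grid (all four
lengths) runs in about 40 s on one core with the same cap, and exhaustively
at the three smaller lengths.

## Known limitations

* Only dichotomous fingerprints; count/real-valued vectors are out of scope.
* Non-additive coefficients (Kulczynski and relatives) have no extended
  form here.
* CRRN is Monte-Carlo; exact finite-R null distributions are not
  implemented (the tests validate against exhaustive permutation
  enumeration for R ≤ 6).
* The factorial ANOVA on the grid/SRD outputs is deliberately not included:
  the grid CSV and fold-level SRD tables are the hand-off points to any
  statistics package.
* The computed saturation plateau of the grand mean at m = 100000 is
  ≈ 0.374 under the defaults (16 fingerprints, p_on = 0.5), stable to
  ±0.0003 across seeds.
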