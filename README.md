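# extsim — extended (n-ary) similarity indices for binary fingerprints

Classical molecular similarity compares fingerprints two at a time: a pair of
dichotomous (0/1) bit strings is collapsed into the contingency counters
*a* (coincident 1s), *b*, *c* (1s unique to either fingerprint) and *d*
(coincident 0s), which feed coefficients such as the Jaccard–Tanimoto index
*a*/(*a*+*b*+*c*) or the Sokal–Michener index (*a*+*d*)/*p*.  Quantifying the
diversity of a compound set this way needs all O(N²) pairwise comparisons.

`extsim` implements the *extended* similarity framework, which compares an
arbitrary number *n* of fingerprints simultaneously — an O(N) alternative for
set similarity and chemical diversity.  The key objects are the coincidence
counters C<sub>n(k)</sub> (number of bit positions where exactly *k* of the
*n* fingerprints have a 1), classified by the indicator
Δ<sub>n(k)</sub> = |2k − n| and a coincidence threshold γ (default *n* mod 2)
into 1-similarity (2k − n > γ), 0-similarity (n − 2k > γ) and dissimilarity
counters, then graded by weight functions f<sub>s</sub>(Δ) = Δ/n and
f<sub>d</sub>(Δ) = 1 − (Δ − n mod 2)/n.  Every classical additive coefficient
generalizes to closed forms in these weighted counter sums, in weighted- and
unweighted-denominator variants (w/nw); at n = 2 all of them reduce exactly
to the familiar pairwise formulas.

The package also provides:

* an 18-base coefficient registry (Austin–Colwell, Baroni–Urbani–Buser,
  Consonni–Todeschini 1–4, Faith, Gleason, Goodman–Kruskal, Hawkins–Dotson,
  Jaccard, Jaccard–Tanimoto, Rogers–Tanimoto, Rogot–Goldberg, Russel–Rao,
  Simple Matching/Sokal–Michener, Sokal–Sneath 1–2) in all defined variants,
  including the new Ja0 = (3a + 3d)/(p + 2a + 2d) coefficient;
* a simulation harness: mean-|s|-versus-n curves (the parity-driven zigzag
  s<sub>2l</sub> > s<sub>2l+1</sub> < s<sub>2l+2</sub>), and the factorial
  grid over n = 2..15, fingerprint lengths 10–100000, both weightings and
  the 19-coefficient default set (2128 cells);
* the SRD (sum of ranking differences) procedure for ranking coefficients
  against a data-fusion consensus: footrule distance on tied ranks, 0–100
  scaling, CRRN permutation validation, and contiguous/randomized sevenfold
  cross-validation.

## Worked example

```python
import numpy as np
from extsim import (BinaryFingerprintSet, pair_counters, binary_similarity,
                    coincidence_counters, classify_counters, summarize,
                    extended_similarity, IndexSpec)

A = [1, 0, 1, 1, 0, 1, 0, 0]
B = [0, 0, 1, 0, 0, 1, 0, 1]
pc = pair_counters(A, B)
print(pc)                                  # PairCounters(a=2, b=2, c=1, d=3)
print(binary_similarity(pc, "SM"))         # 0.625
print(binary_similarity(pc, "Ja0"))        # 0.8333333333333334

quad = BinaryFingerprintSet(np.array([[1,1,0,0],[1,0,1,0],[1,1,0,1],[1,1,1,0]]))
cc = coincidence_counters(quad, range(4))
print(cc.counts)                           # (0, 1, 1, 1, 1)
s = summarize(cc, classify_counters(4, 0))
print(s.w1s, s.w0s, s.wd)                  # 1.5 0.5 1.0
print(extended_similarity(s, IndexSpec("SM", "1s_wd")))  # 0.6666666666666666
print(extended_similarity(s, IndexSpec("SM", "1s_d")))   # 0.5
```

The four fingerprints have column sums 4, 3, 2, 1, so one position is fully
coincident (C₄(4) = 1, weight 1), one has 75 % agreement on 1s (C₄(3) = 1,
weight 0.5), one is dissimilar (C₄(2) = 1) and one agrees mostly on 0s
(C₄(1) = 1, weight 0.5).  The weighted extended Sokal–Michener value 2/3 uses
the weighted dissimilarity in the denominator; the non-weighted variant
divides the same weighted numerator by the full length m = 4, giving 0.5.

From the shell:

```bash
extsim generate --n 16 --m 1000 --seed 7 --out fps.txt
extsim similarity fps.txt --n 8 --indices paper --weighting w --out sim.csv
extsim grid --subsample 2000 --seed 1 --out grid.csv
extsim srd sim.csv --k 7 --cv contiguous --permutations 10000 --seed 1
extsim list-indices
```

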