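"""Coincidence counters, similarity/dissimilarity classification and weighting.

The n-ary comparison machinery rests on the coincidence counters
C_n(k): the number of bit positions at which exactly k of the n compared
fingerprints carry a 1 (k = 0..n).  For a pair (n = 2) these collapse to the
classical contingency quantities: C_2(2) = a, C_2(1) = b + c, C_2(0) = d.

Each counter is classified with the indicator Delta_n(k) = |2k - n| and a
coincidence threshold gamma:

* 1-similarity counter if 2k - n > gamma (agreement on 1s),
* 0-similarity counter if n - 2k > gamma (agreement on 0s),
* dissimilarity counter otherwise (|2k - n| <= gamma).

The default gamma = n mod 2 maximizes the number of similarity counters:
a position counts as "similar" whenever more than half of the bits agree.

Counters of different quality are graded by weight functions f_s (increasing
in Delta, applied to similarity counters) and f_d (decreasing in Delta,
applied to dissimilarity counters), normalized so that f_s(n) = 1 and
f_d(n mod 2) = 1.  The default "fraction" scheme is

    f_s(Delta) = Delta / n,      f_d(Delta) = 1 - (Delta - n mod 2) / n.

A "power2" alternative (f_s = 2^-(n-Delta), f_d = 2^-(Delta - n mod 2)) is
available but penalizes partial agreement much more harshly and is never the
default.  Note that for n <= 3 with the default gamma every populated counter
has weight 1, so weighting is inert for binary and ternary comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .fingerprints import BinaryFingerprintSet

__all__ = [
    "PairCounters",
    "CoincidenceCounters",
    "CounterClassification",
    "CounterSummary",
    "SummaryArrays",
    "pair_counters",
    "coincidence_counters",
    "coincidence_count_matrix",
    "delta",
    "coincidence_threshold",
    "classify_counters",
    "weight_functions",
    "weight_vector",
    "summarize",
    "batch_summaries",
]

WEIGHT_SCHEMES = ("fraction", "power2", "none")
GAMMA_MODES = ("mod2", "ceil-half")


@dataclass(frozen=True)
class PairCounters:
    """The four classical binary-comparison counters.

    a: coincident 1s; b: 1s in the first fingerprint only; c: 1s in the
    second only; d: coincident 0s.  p = a + b + c + d is the common length.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def p(self) -> int:
        return self.a + self.b + self.c + self.d

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"counter {name} must be a non-negative integer, got {v}")


@dataclass(frozen=True)
class CoincidenceCounters:
    """The vector C_n(k), k = 0..n, for one subset of n fingerprints."""

    n: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != self.n + 1:
            raise ValueError(
                f"expected {self.n + 1} counters for n={self.n}, got {len(self.counts)}"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError("coincidence counters must be non-negative")

    @property
    def m(self) -> int:
        """Total fingerprint length; every position is counted exactly once."""
        return int(sum(self.counts))

    def __getitem__(self, k: int) -> int:
        return self.counts[k]


@dataclass(frozen=True)
class CounterClassification:
    """Partition of k = 0..n into 1-similarity, 0-similarity and dissimilarity."""

    n: int
    gamma: int
    one_sim_ks: frozenset[int]
    zero_sim_ks: frozenset[int]
    dissim_ks: frozenset[int]

    @property
    def sim_ks(self) -> frozenset[int]:
        return self.one_sim_ks | self.zero_sim_ks


@dataclass(frozen=True)
class CounterSummary:
    """Classified and weighted counter sums — the sole input to every extended index.

    ``w1s``/``w0s``/``wd`` are the f-weighted sums over 1-similarity,
    0-similarity and dissimilarity counters; ``u1s``/``u0s``/``ud`` are the
    corresponding raw (unweighted) totals.  u1s + u0s + ud = m always.
    """

    n: int
    m: int
    w1s: float
    w0s: float
    wd: float
    u1s: int
    u0s: int
    ud: int


@dataclass(frozen=True)
class SummaryArrays:
    """Vectorized counter summaries for a batch of same-size subsets."""

    n: int
    m: int
    w1s: np.ndarray
    w0s: np.ndarray
    wd: np.ndarray
    u1s: np.ndarray
    u0s: np.ndarray
    ud: np.ndarray


def pair_counters(fp1, fp2) -> PairCounters:
    """Compute a, b, c, d for a pair of equal-length bit vectors."""
    x = np.asarray(fp1, dtype=np.uint8).ravel()
    y = np.asarray(fp2, dtype=np.uint8).ravel()
    if x.shape != y.shape:
        raise ValueError(
            f"fingerprint lengths differ: {x.shape[0]} vs {y.shape[0]}"
        )
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return PairCounters(a, b, c, d)


def _as_data(fps) -> np.ndarray:
    if isinstance(fps, BinaryFingerprintSet):
        return fps.data
    return np.asarray(fps, dtype=np.uint8)


def _check_subset(subset: Sequence[int], n_rows: int) -> tuple[int, ...]:
    idx = tuple(int(i) for i in subset)
    if len(idx) < 2:
        raise ValueError(f"an n-ary comparison needs n >= 2 fingerprints, got {len(idx)}")
    if len(set(idx)) != len(idx):
        raise ValueError(f"subset contains duplicate indices: {idx}")
    if any(i < 0 or i >= n_rows for i in idx):
        raise ValueError(f"subset index out of range [0, {n_rows}): {idx}")
    return idx


def coincidence_counters(fps, subset: Sequence[int] | None = None) -> CoincidenceCounters:
    """C_n(k) for the given subset of fingerprints (all of them if omitted).

    counts[k] is the number of bit positions whose column sum over the subset
    equals k; the order of the subset is irrelevant and sum_k counts[k] = m.
    """
    data = _as_data(fps)
    if subset is None:
        subset = range(data.shape[0])
    idx = _check_subset(subset, data.shape[0])
    col_sums = data[list(idx)].sum(axis=0, dtype=np.int64)
    counts = np.bincount(col_sums, minlength=len(idx) + 1)
    return CoincidenceCounters(len(idx), tuple(int(c) for c in counts))


def coincidence_count_matrix(fps, subsets: Sequence[Sequence[int]]) -> np.ndarray:
    """C_n(k) for many same-size subsets at once; returns a (B, n+1) int matrix.

    Column sums are obtained through a float32 selection-matrix product
    (chunked so intermediates stay small), which is substantially faster than
    a per-subset Python loop for the full combinatorial enumerations used in
    the experiment grid.
    """
    data = _as_data(fps)
    n_rows, m = data.shape
    subs = np.asarray([list(s) for s in subsets], dtype=np.intp)
    if subs.ndim != 2:
        raise ValueError("subsets must all have the same size")
    b, n = subs.shape
    for s in subsets:
        _check_subset(s, n_rows)
    dataf = np.ascontiguousarray(data, dtype=np.float32)
    out = np.empty((b, n + 1), dtype=np.int64)
    chunk = max(1, int(2.5e7 // max(m, 1)))  # keep the product matrix ~100 MB
    for start in range(0, b, chunk):
        block = subs[start : start + chunk]
        sel = np.zeros((block.shape[0], n_rows), dtype=np.float32)
        sel[np.arange(block.shape[0])[:, None], block] = 1.0
        sums = np.rint(sel @ dataf).astype(np.int64)
        offset = np.arange(block.shape[0])[:, None] * (n + 1)
        binc = np.bincount((sums + offset).ravel(), minlength=block.shape[0] * (n + 1))
        out[start : start + block.shape[0]] = binc.reshape(block.shape[0], n + 1)
    return out


def delta(n: int, k: int) -> int:
    """The coincidence indicator Delta_n(k) = |2k - n|."""
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}], got {k}")
    return abs(2 * k - n)


def coincidence_threshold(n: int, mode: str | int = "mod2") -> int:
    """The coincidence threshold gamma separating similarity from dissimilarity.

    ``mode``: ``"mod2"`` (default, gamma = n mod 2 — maximizes the number of
    similarity counters), ``"ceil-half"`` (gamma = ceil(n/2)), an integer, or
    the string ``"fixed:<value>"``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if mode == "mod2":
        return n % 2
    if mode == "ceil-half":
        return math.ceil(n / 2)
    if isinstance(mode, str) and mode.startswith("fixed:"):
        mode = int(mode.split(":", 1)[1])
    if isinstance(mode, (int, np.integer)):
        gamma = int(mode)
        if not 0 <= gamma < n:
            raise ValueError(f"fixed gamma must satisfy 0 <= gamma < n, got {gamma}")
        return gamma
    raise ValueError(f"unknown coincidence-threshold mode: {mode!r}")


def classify_counters(n: int, gamma: int) -> CounterClassification:
    """Partition k = 0..n by the rules 2k-n > gamma / n-2k > gamma / |2k-n| <= gamma."""
    if not 0 <= gamma < n:
        raise ValueError(f"gamma must satisfy 0 <= gamma < n, got {gamma} (n={n})")
    one, zero, dis = set(), set(), set()
    for k in range(n + 1):
        if 2 * k - n > gamma:
            one.add(k)
        elif n - 2 * k > gamma:
            zero.add(k)
        else:
            dis.add(k)
    return CounterClassification(n, gamma, frozenset(one), frozenset(zero), frozenset(dis))


def weight_functions(
    n: int, scheme: str = "fraction"
) -> tuple[Callable[[int], float], Callable[[int], float]]:
    """Return (f_s, f_d) as functions of Delta for the given scheme.

    All schemes satisfy the normalization f_s(n) = 1 and f_d(n mod 2) = 1.
    """
    if scheme == "fraction":
        return (lambda d: d / n, lambda d: 1.0 - (d - n % 2) / n)
    if scheme == "power2":
        return (lambda d: 2.0 ** (-(n - d)), lambda d: 2.0 ** (-(d - n % 2)))
    if scheme == "none":
        return (lambda d: 1.0, lambda d: 1.0)
    raise ValueError(f"unknown weight scheme: {scheme!r} (expected one of {WEIGHT_SCHEMES})")


def weight_vector(
    classification: CounterClassification, scheme: str = "fraction"
) -> np.ndarray:
    """Per-k weight: f_s(Delta_n(k)) on similarity counters, f_d on dissimilarity."""
    n = classification.n
    f_s, f_d = weight_functions(n, scheme)
    w = np.empty(n + 1, dtype=np.float64)
    for k in range(n + 1):
        d = delta(n, k)
        w[k] = f_s(d) if k in classification.sim_ks else f_d(d)
    return w


def summarize(
    counters: CoincidenceCounters,
    classification: CounterClassification,
    scheme: str = "fraction",
) -> CounterSummary:
    """Collapse C_n(k) into the weighted/unweighted 1-s, 0-s and d sums."""
    if counters.n != classification.n:
        raise ValueError(
            f"inconsistent n: counters have n={counters.n}, "
            f"classification has n={classification.n}"
        )
    w = weight_vector(classification, scheme)
    c = np.asarray(counters.counts, dtype=np.float64)
    one = sorted(classification.one_sim_ks)
    zero = sorted(classification.zero_sim_ks)
    dis = sorted(classification.dissim_ks)
    return CounterSummary(
        n=counters.n,
        m=counters.m,
        w1s=float(np.dot(c[one], w[one])),
        w0s=float(np.dot(c[zero], w[zero])),
        wd=float(np.dot(c[dis], w[dis])),
        u1s=int(c[one].sum()),
        u0s=int(c[zero].sum()),
        ud=int(c[dis].sum()),
    )


def batch_summaries(
    fps,
    subsets: Sequence[Sequence[int]],
    gamma_mode: str | int = "mod2",
    scheme: str = "fraction",
) -> SummaryArrays:
    """Counter summaries for many same-size subsets at once (vectorized)."""
    data = _as_data(fps)
    counts = coincidence_count_matrix(data, subsets)
    n = counts.shape[1] - 1
    cls = classify_counters(n, coincidence_threshold(n, gamma_mode))
    w = weight_vector(cls, scheme)
    one = sorted(cls.one_sim_ks)
    zero = sorted(cls.zero_sim_ks)
    dis = sorted(cls.dissim_ks)
    cf = counts.astype(np.float64)
    return SummaryArrays(
        n=n,
        m=data.shape[1],
        w1s=cf[:, one] @ w[one],
        w0s=cf[:, zero] @ w[zero],
        wd=cf[:, dis] @ w[dis],
        u1s=counts[:, one].sum(axis=1),
        u0s=counts[:, zero].sum(axis=1),
        ud=counts[:, dis].sum(axis=1),
    )


def summaries_iterable(summary: CounterSummary) -> SummaryArrays:
    """View a single summary as a length-1 batch (internal helper)."""
    return SummaryArrays(
        n=summary.n,
        m=summary.m,
        w1s=np.array([summary.w1s]),
        w0s=np.array([summary.w0s]),
        wd=np.array([summary.wd]),
        u1s=np.array([summary.u1s]),
        u0s=np.array([summary.u0s]),
        ud=np.array([summary.ud]),
    )
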