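"""Registry and evaluation of binary and extended (n-ary) similarity coefficients.

Eighteen additive similarity coefficients are covered: eleven fully additive
bases (AC, BUB, CT1, CT2, Fai, GK, HD, RT, RG, SM, SS2) and seven asymmetric
bases (CT3, CT4, Gle, Ja, RR, SS1, JT), the latter depending on the
1-similarity sums but not the 0-similarity sums.  Every extended formula is
a closed form in the classified counter sums of
:class:`~extsim.counters.CounterSummary`:

* numerators always use the f-weighted sums;
* ``*_wd`` variants also weight the denominator sums, ``*_d`` variants use
  the raw (unweighted) totals there;
* ``1s_*`` variants restrict the designated sums to 1-similarity counters,
  ``s_*`` variants (asymmetric bases only) use all similarity counters.

At n = 2 every variant reduces exactly to its classical pairwise formula.
Replacing the 1-similarity sum by the all-similarity sum is, at n = 2, the
substitution a -> a + d; for six of the seven asymmetric bases this lands on
an already known additive index (CT3, CT4 -> CT1; Gle -> SS2; RR, JT -> SM;
SS1 -> RT), while Jaccard yields the genuinely new coefficient

    Ja0 = (3a + 3d) / (p + 2a + 2d).

All coefficients are bounded in [0, 1] except Goodman-Kruskal (GK), which
ranges over [-1, 1].  A vanishing denominator raises
:class:`UndefinedSimilarityError` (vectorized paths yield NaN instead) —
silently returning 0 or 1 would corrupt the means of the experiment grid.

The default "paper set" used throughout the simulation study has 19 members:
the 11 additive bases, the 7 asymmetric bases in 1s form, and Jaccard in its
all-similarity form (eJa_0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .counters import (
    CounterSummary,
    PairCounters,
    SummaryArrays,
    batch_summaries,
    classify_counters,
    coincidence_counters,
    coincidence_threshold,
    summarize,
)
from .fingerprints import BinaryFingerprintSet

__all__ = [
    "ADDITIVE_BASES",
    "ASYMMETRIC_BASES",
    "BINARY_BASES",
    "REDUCTION_MAP",
    "VARIANTS",
    "IndexSpec",
    "SimilarityValue",
    "UndefinedSimilarityError",
    "binary_similarity",
    "extended_similarity",
    "extended_similarity_array",
    "evaluate_suite",
    "paper_specs",
    "verify_reduction",
    "registry_catalogue",
]

VARIANTS = ("1s_wd", "1s_d", "s_wd", "s_d")


class UndefinedSimilarityError(ArithmeticError):
    """A similarity coefficient is undefined (vanishing denominator)."""

    def __init__(self, label: str, detail: str = "denominator is zero"):
        self.label = label
        super().__init__(f"{label}: {detail}")


# --------------------------------------------------------------------------
# Extended formulas.  Each receives the weighted sums (s1w, s0w, dw), the
# unweighted sums (s1u, s0u, du) and the flags (use_all, wd); all arithmetic
# is elementwise so scalars and arrays work alike.  sw/su are the
# all-similarity sums; m = s1u + s0u + du.
# --------------------------------------------------------------------------


def _sums(z: SummaryArrays):
    sw = z.w1s + z.w0s
    su = z.u1s + z.u0s
    mtot = z.u1s + z.u0s + z.ud
    return sw, su, mtot


def _e_ac(z, use_all, wd):
    sw, su, mtot = _sums(z)
    den = (sw + z.wd) if wd else mtot
    with np.errstate(divide="ignore", invalid="ignore"):
        return (2.0 / math.pi) * np.arcsin(np.sqrt(sw / den))


def _e_bub(z, use_all, wd):
    cross_w = np.sqrt(z.w1s * z.w0s)
    num = cross_w + z.w1s
    if wd:
        den = cross_w + z.w1s + z.wd
    else:
        den = np.sqrt(z.u1s * z.u0s) + z.u1s + z.ud
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def _e_ct1(z, use_all, wd):
    sw, su, mtot = _sums(z)
    den = np.log1p(sw + z.wd) if wd else np.log1p(mtot)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log1p(sw) / den


def _e_ct2(z, use_all, wd):
    sw, su, mtot = _sums(z)
    num = np.log1p(sw + z.wd) - np.log1p(z.wd)
    den = np.log1p(sw + z.wd) if wd else np.log1p(mtot)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def _e_fai(z, use_all, wd):
    sw, su, mtot = _sums(z)
    den = (sw + z.wd) if wd else mtot
    with np.errstate(divide="ignore", invalid="ignore"):
        return (z.w1s + 0.5 * z.w0s) / den


def _e_gk(z, use_all, wd):
    min_w = np.minimum(z.w1s, z.w0s)
    num = 2.0 * min_w - z.wd
    den = (2.0 * min_w + z.wd) if wd else (2.0 * np.minimum(z.u1s, z.u0s) + z.ud)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def _e_hd(z, use_all, wd):
    if wd:
        den1, den0 = z.w1s + z.wd, z.w0s + z.wd
    else:
        den1, den0 = z.u1s + z.ud, z.u0s + z.ud
    with np.errstate(divide="ignore", invalid="ignore"):
        return 0.5 * (z.w1s / den1 + z.w0s / den0)


def _e_rt(z, use_all, wd):
    sw, su, mtot = _sums(z)
    den = (sw + 2.0 * z.wd) if wd else (su + 2.0 * z.ud)
    with np.errstate(divide="ignore", invalid="ignore"):
        return sw / den


def _e_rg(z, use_all, wd):
    # The 1s_d row weights only the numerators; both denominators stay raw.
    if wd:
        den1, den0 = 2.0 * z.w1s + z.wd, 2.0 * z.w0s + z.wd
    else:
        den1, den0 = 2.0 * z.u1s + z.ud, 2.0 * z.u0s + z.ud
    with np.errstate(divide="ignore", invalid="ignore"):
        return z.w1s / den1 + z.w0s / den0


def _e_sm(z, use_all, wd):
    sw, su, mtot = _sums(z)
    den = (sw + z.wd) if wd else mtot
    with np.errstate(divide="ignore", invalid="ignore"):
        return sw / den


def _e_ss2(z, use_all, wd):
    sw, su, mtot = _sums(z)
    den = (2.0 * sw + z.wd) if wd else (2.0 * su + z.ud)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 2.0 * sw / den


def _num_sums(z, use_all):
    """(weighted, unweighted) numerator similarity sums for asymmetric bases."""
    if use_all:
        return z.w1s + z.w0s, z.u1s + z.u0s
    return z.w1s, z.u1s


def _e_ct3(z, use_all, wd):
    sw, su, mtot = _sums(z)
    x, _ = _num_sums(z, use_all)
    den = np.log1p(sw + z.wd) if wd else np.log1p(mtot)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log1p(x) / den


def _e_ct4(z, use_all, wd):
    x, xu = _num_sums(z, use_all)
    den = np.log1p(x + z.wd) if wd else np.log1p(xu + z.ud)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log1p(x) / den


def _e_gle(z, use_all, wd):
    x, xu = _num_sums(z, use_all)
    den = (2.0 * x + z.wd) if wd else (2.0 * xu + z.ud)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 2.0 * x / den


def _e_ja(z, use_all, wd):
    x, xu = _num_sums(z, use_all)
    den = (3.0 * x + z.wd) if wd else (3.0 * xu + z.ud)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 3.0 * x / den


def _e_rr(z, use_all, wd):
    sw, su, mtot = _sums(z)
    x, _ = _num_sums(z, use_all)
    den = (sw + z.wd) if wd else mtot
    with np.errstate(divide="ignore", invalid="ignore"):
        return x / den


def _e_ss1(z, use_all, wd):
    x, xu = _num_sums(z, use_all)
    den = (x + 2.0 * z.wd) if wd else (xu + 2.0 * z.ud)
    with np.errstate(divide="ignore", invalid="ignore"):
        return x / den


def _e_jt(z, use_all, wd):
    x, xu = _num_sums(z, use_all)
    den = (x + z.wd) if wd else (xu + z.ud)
    with np.errstate(divide="ignore", invalid="ignore"):
        return x / den


ADDITIVE_BASES: dict[str, Callable] = {
    "AC": _e_ac,
    "BUB": _e_bub,
    "CT1": _e_ct1,
    "CT2": _e_ct2,
    "Fai": _e_fai,
    "GK": _e_gk,
    "HD": _e_hd,
    "RT": _e_rt,
    "RG": _e_rg,
    "SM": _e_sm,
    "SS2": _e_ss2,
}

ASYMMETRIC_BASES: dict[str, Callable] = {
    "CT3": _e_ct3,
    "CT4": _e_ct4,
    "Gle": _e_gle,
    "Ja": _e_ja,
    "RR": _e_rr,
    "SS1": _e_ss1,
    "JT": _e_jt,
}

BASE_NAMES: dict[str, str] = {
    "AC": "Austin-Colwell",
    "BUB": "Baroni-Urbani-Buser",
    "CT1": "Consonni-Todeschini (1)",
    "CT2": "Consonni-Todeschini (2)",
    "Fai": "Faith",
    "GK": "Goodman-Kruskal",
    "HD": "Hawkins-Dotson",
    "RT": "Rogers-Tanimoto",
    "RG": "Rogot-Goldberg",
    "SM": "Sokal-Michener",
    "SS2": "Sokal-Sneath (2)",
    "CT3": "Consonni-Todeschini (3)",
    "CT4": "Consonni-Todeschini (4)",
    "Gle": "Gleason",
    "Ja": "Jaccard",
    "RR": "Russel-Rao",
    "SS1": "Sokal-Sneath (1)",
    "JT": "Jaccard-Tanimoto",
}

#: Substitution a -> a + d maps each asymmetric base onto an additive one;
#: only Jaccard produces a new coefficient (Ja0).
REDUCTION_MAP: dict[str, str] = {
    "CT3": "CT1",
    "CT4": "CT1",
    "Gle": "SS2",
    "RR": "SM",
    "JT": "SM",
    "SS1": "RT",
    "Ja": "Ja0",
}


# --------------------------------------------------------------------------
# Classical binary (pairwise) formulas, keyed by base name.  These include
# the non-additive Kulczynski index and the Ja0 coefficient obtained from the
# Jaccard index under the a -> a + d substitution.
# --------------------------------------------------------------------------

BINARY_BASES: dict[str, Callable] = {
    "AC": lambda a, b, c, d, p: ((2.0 / math.pi) * math.asin(math.sqrt((a + d) / p)), 1.0),
    "BUB": lambda a, b, c, d, p: (math.sqrt(a * d) + a, math.sqrt(a * d) + a + b + c),
    "CT1": lambda a, b, c, d, p: (math.log1p(a + d), math.log1p(p)),
    "CT2": lambda a, b, c, d, p: (math.log1p(p) - math.log1p(b + c), math.log1p(p)),
    "Fai": lambda a, b, c, d, p: (a + 0.5 * d, p),
    "GK": lambda a, b, c, d, p: (2 * min(a, d) - b - c, 2 * min(a, d) + b + c),
    "HD": lambda a, b, c, d, p: _hd_binary(a, b, c, d),
    "RT": lambda a, b, c, d, p: (a + d, p + b + c),
    "RG": lambda a, b, c, d, p: _rg_binary(a, b, c, d),
    "SM": lambda a, b, c, d, p: (a + d, p),
    "SS2": lambda a, b, c, d, p: (2 * (a + d), p + a + d),
    "CT3": lambda a, b, c, d, p: (math.log1p(a), math.log1p(p)),
    "CT4": lambda a, b, c, d, p: (math.log1p(a), math.log1p(a + b + c)),
    "Gle": lambda a, b, c, d, p: (2 * a, 2 * a + b + c),
    "Ja": lambda a, b, c, d, p: (3 * a, 3 * a + b + c),
    "RR": lambda a, b, c, d, p: (a, p),
    "SS1": lambda a, b, c, d, p: (a, a + 2 * b + 2 * c),
    "JT": lambda a, b, c, d, p: (a, a + b + c),
    "Ja0": lambda a, b, c, d, p: (3 * a + 3 * d, p + 2 * a + 2 * d),
    "Kul": lambda a, b, c, d, p: _kul_binary(a, b, c),
}


def _hd_binary(a, b, c, d):
    if a + b + c == 0 or b + c + d == 0:
        return (float("nan"), 0.0)
    return (0.5 * (a / (a + b + c) + d / (b + c + d)), 1.0)


def _rg_binary(a, b, c, d):
    if 2 * a + b + c == 0 or 2 * d + b + c == 0:
        return (float("nan"), 0.0)
    return (a / (2 * a + b + c) + d / (2 * d + b + c), 1.0)


def _kul_binary(a, b, c):
    if a + b == 0 or a + c == 0:
        return (float("nan"), 0.0)
    return (0.5 * (a / (a + b) + a / (a + c)), 1.0)


def binary_similarity(counters: PairCounters, base: str) -> float:
    """Evaluate a classical pairwise coefficient on (a, b, c, d)."""
    if base not in BINARY_BASES:
        raise ValueError(f"unknown binary coefficient: {base!r}")
    if counters.p <= 0:
        raise UndefinedSimilarityError(base, "empty fingerprints (p = 0)")
    num, den = BINARY_BASES[base](
        counters.a, counters.b, counters.c, counters.d, counters.p
    )
    if den == 0 or math.isnan(num):
        raise UndefinedSimilarityError(base)
    return num / den


# --------------------------------------------------------------------------
# Index specifications and evaluation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexSpec:
    """Identity of one extended coefficient: base name plus variant.

    ``variant`` is one of ``1s_wd``, ``1s_d`` (all bases) or ``s_wd``,
    ``s_d`` (asymmetric bases only: additive bases already use all
    similarity counters, so an all-similarity variant is not defined).
    """

    base: str
    variant: str = "1s_wd"

    def __post_init__(self) -> None:
        if self.base not in ADDITIVE_BASES and self.base not in ASYMMETRIC_BASES:
            raise ValueError(f"unknown extended base: {self.base!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant: {self.variant!r} (expected one of {VARIANTS})")
        if self.variant.startswith("s_") and self.base in ADDITIVE_BASES:
            raise ValueError(
                f"all-similarity variant {self.variant!r} is undefined for the "
                f"additive base {self.base!r}"
            )

    @property
    def family(self) -> str:
        return "additive" if self.base in ADDITIVE_BASES else "asymmetric"

    @property
    def use_all(self) -> bool:
        return self.variant.startswith("s_")

    @property
    def weighted_denominator(self) -> bool:
        return self.variant.endswith("wd")

    @property
    def display(self) -> str:
        """Figure-style coefficient name, e.g. ``eBUB_1`` or ``eJa_0``."""
        suffix = "0" if self.use_all else "1"
        return f"e{self.base}_{suffix}"

    @property
    def label(self) -> str:
        """Display name with the w/nw weighting suffix, e.g. ``eBUB_1 w``."""
        return f"{self.display} {'w' if self.weighted_denominator else 'nw'}"


@dataclass(frozen=True)
class SimilarityValue:
    """One coefficient value with its provenance; NaN marks an undefined value."""

    value: float
    spec: IndexSpec
    n: int
    m: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def _formula(base: str) -> Callable:
    return ADDITIVE_BASES.get(base) or ASYMMETRIC_BASES[base]


def extended_similarity_array(summaries: SummaryArrays, spec: IndexSpec) -> np.ndarray:
    """Vectorized evaluation over a batch of summaries; undefined cells are NaN."""
    fn = _formula(spec.base)
    out = fn(summaries, spec.use_all, spec.weighted_denominator)
    return np.asarray(out, dtype=np.float64)


def extended_similarity(summary: CounterSummary, spec: IndexSpec) -> float:
    """Evaluate one extended coefficient on a counter summary.

    Raises :class:`UndefinedSimilarityError` when the closed form has a
    vanishing denominator for this summary.
    """
    from .counters import summaries_iterable

    value = float(extended_similarity_array(summaries_iterable(summary), spec)[0])
    if math.isnan(value):
        raise UndefinedSimilarityError(spec.label)
    return value


def evaluate_suite(
    fps: BinaryFingerprintSet,
    subset: Sequence[int] | None,
    specs: Sequence[IndexSpec],
    gamma_mode: str | int = "mod2",
    weight_scheme: str = "fraction",
) -> list[SimilarityValue]:
    """Compute counters once and evaluate all requested coefficients.

    Undefined values are carried through as NaN (``SimilarityValue.defined``
    is False) rather than aborting the suite.
    """
    if not specs:
        return []
    counters = coincidence_counters(fps, subset)
    cls = classify_counters(counters.n, coincidence_threshold(counters.n, gamma_mode))
    summary = summarize(counters, cls, weight_scheme)
    out = []
    for spec in specs:
        try:
            value = extended_similarity(summary, spec)
        except UndefinedSimilarityError:
            value = float("nan")
        out.append(SimilarityValue(value, spec, counters.n, counters.m))
    return out


#: Base/variant composition of the 19-coefficient default set: all 11
#: additive bases, the 7 asymmetric bases in 1s form, plus eJa_0.
_PAPER_SET: tuple[tuple[str, bool], ...] = tuple(
    [(b, False) for b in ADDITIVE_BASES]
    + [(b, False) for b in ASYMMETRIC_BASES]
    + [("Ja", True)]
)


def paper_specs(weighting: str = "w") -> list[IndexSpec]:
    """The 19-member default coefficient set, in ``w`` or ``nw`` form.

    ``w`` selects the weighted-denominator variants (1s_wd / s_wd), ``nw``
    the unweighted-denominator variants (1s_d / s_d).
    """
    if weighting not in ("w", "nw"):
        raise ValueError(f"weighting must be 'w' or 'nw', got {weighting!r}")
    wd = "wd" if weighting == "w" else "d"
    return [
        IndexSpec(base, f"{'s' if use_all else '1s'}_{wd}") for base, use_all in _PAPER_SET
    ]


def verify_reduction(base: str) -> str:
    """Additive index obtained from an asymmetric base under a -> a + d at n = 2."""
    if base not in ASYMMETRIC_BASES:
        raise ValueError(f"{base!r} is not an asymmetric base")
    return REDUCTION_MAP[base]


def registry_catalogue() -> list[dict[str, str]]:
    """Machine-readable catalogue of every base/variant combination."""
    rows = []
    for base in list(ADDITIVE_BASES) + list(ASYMMETRIC_BASES):
        variants = VARIANTS if base in ASYMMETRIC_BASES else VARIANTS[:2]
        for variant in variants:
            spec = IndexSpec(base, variant)
            rows.append(
                {
                    "label": spec.label,
                    "base": base,
                    "name": BASE_NAMES[base],
                    "family": spec.family,
                    "variant": variant,
                }
            )
    return rows
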