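"""Simulation harness: average-|s| curves, zigzag checks, and the factorial grid.

The study design: generate N = 16 random dichotomous fingerprints of length
m (levels 10, 100, 1000, 100000), and for each n = 2..15 average the absolute
value of every extended coefficient over all C(16, n) n-ary combinations, in
both the weighted (w) and non-weighted (nw) forms of the 19-coefficient
default set.  The resulting 14 x 2 x 19 x 4 = 2128 cell means form the grid
handed off to variance analysis; the per-coefficient curves of mean |s|
versus n exhibit the characteristic zigzag

    s_{2l} > s_{2l+1} < s_{2l+2}

driven by the parity of gamma = n mod 2 (odd n carries two kinds of
dissimilarity counters, even n only one).  The Goodman-Kruskal coefficient
shows the inverted pattern (odd-n local maxima).

Exhaustive enumeration of all subsets is the default; a seeded subsample cap
(``subsample``) bounds the number of combinations per n for the largest
fingerprint lengths, and every cell reports the number of combinations used
plus a count of excluded undefined values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .counters import batch_summaries
from .fingerprints import BinaryFingerprintSet, GeneratorConfig, generate_random
from .indices import IndexSpec, extended_similarity_array, paper_specs

__all__ = [
    "GridConfig",
    "GridCell",
    "enumerate_combinations",
    "sample_combinations",
    "average_abs_similarity_curve",
    "run_grid",
    "grid_to_csv",
    "zigzag_report",
    "enumerate_srd_design",
]

DEFAULT_N_VALUES = tuple(range(2, 16))
DEFAULT_LENGTHS = (10, 100, 1000, 100000)


def enumerate_combinations(n_total: int, n: int) -> Iterator[tuple[int, ...]]:
    """All C(N, n) index subsets in deterministic lexicographic order."""
    if not 2 <= n <= n_total:
        raise ValueError(f"subset size must satisfy 2 <= n <= {n_total}, got {n}")
    return itertools.combinations(range(n_total), n)


def sample_combinations(
    n_total: int, n: int, cap: int | None, rng: np.random.Generator | None = None
) -> list[tuple[int, ...]]:
    """All subsets if C(N, n) <= cap (or cap is None), else ``cap`` distinct
    subsets drawn uniformly without replacement (seeded, deterministic)."""
    total = math.comb(n_total, n)
    if cap is None or total <= cap:
        return list(enumerate_combinations(n_total, n))
    if rng is None:
        rng = np.random.default_rng(0)
    seen: set[tuple[int, ...]] = set()
    picked: list[tuple[int, ...]] = []
    while len(picked) < cap:
        t = tuple(sorted(rng.choice(n_total, size=n, replace=False).tolist()))
        if t not in seen:
            seen.add(t)
            picked.append(t)
    return picked


def _mean_abs_table(
    fps: BinaryFingerprintSet,
    specs_by_weighting: Mapping[str, Sequence[IndexSpec]],
    n_values: Sequence[int],
    gamma_mode: str | int,
    weight_scheme: str,
    subsample: int | None,
    seed_seq: np.random.SeedSequence | None,
) -> list[dict]:
    """Mean |s| per (n, weighting, spec); counters are computed once per n."""
    rows = []
    children = (
        seed_seq.spawn(len(n_values)) if seed_seq is not None else [None] * len(n_values)
    )
    for n, child in zip(n_values, children):
        rng = np.random.default_rng(child) if child is not None else None
        subsets = sample_combinations(fps.n_fingerprints, n, subsample, rng)
        summaries = batch_summaries(fps, subsets, gamma_mode, weight_scheme)
        for weighting, specs in specs_by_weighting.items():
            for spec in specs:
                values = extended_similarity_array(summaries, spec)
                defined = values[~np.isnan(values)]
                rows.append(
                    {
                        "n": n,
                        "weighting": weighting,
                        "spec": spec,
                        "mean_abs_s": float(np.abs(defined).mean()) if defined.size else float("nan"),
                        "n_combinations": len(subsets),
                        "n_undefined": int(np.isnan(values).sum()),
                    }
                )
    return rows


def average_abs_similarity_curve(
    fps: BinaryFingerprintSet,
    spec: IndexSpec,
    gamma_mode: str | int = "mod2",
    weight_scheme: str = "fraction",
    n_values: Sequence[int] = DEFAULT_N_VALUES,
    subsample: int | None = None,
    seed: int | None = None,
) -> dict[int, float]:
    """Mean of |s| over all (or subsampled) n-ary combinations, per n.

    Undefined coefficient values are excluded from each mean; if every
    combination is undefined for some n the cell is NaN.
    """
    seed_seq = np.random.SeedSequence(seed) if seed is not None else None
    rows = _mean_abs_table(
        fps, {"": [spec]}, n_values, gamma_mode, weight_scheme, subsample, seed_seq
    )
    return {r["n"]: r["mean_abs_s"] for r in rows}


@dataclass(frozen=True)
class GridCell:
    """One cell of the factorial grid: mean |s| at fixed (n, m, weighting, index)."""

    n: int
    m: int
    weighting: str
    spec: IndexSpec
    mean_abs_s: float
    n_combinations: int
    n_undefined: int


@dataclass(frozen=True)
class GridConfig:
    """Factor levels of the simulation grid.

    Defaults reproduce the full design: n = 2..15, m in (10, 100, 1000,
    100000), both weightings of the 19-coefficient set, 16 fingerprints.
    ``subsample`` caps the combinations per n (seeded); None enumerates all.
    """

    n_values: tuple[int, ...] = DEFAULT_N_VALUES
    lengths: tuple[int, ...] = DEFAULT_LENGTHS
    weightings: tuple[str, ...] = ("w", "nw")
    n_fingerprints: int = 16
    p_on: float = 0.5
    seed: int = 0
    subsample: int | None = None
    gamma_mode: str = "mod2"
    weight_scheme: str = "fraction"

    def __post_init__(self) -> None:
        if max(self.n_values) > self.n_fingerprints:
            raise ValueError(
                f"max n ({max(self.n_values)}) exceeds the number of fingerprints "
                f"({self.n_fingerprints})"
            )

    def specs(self, weighting: str) -> list[IndexSpec]:
        return paper_specs(weighting)

    def cells(self) -> Iterator[tuple[int, int, str, str]]:
        """Keys (n, m, weighting, index label) of every grid cell, in output order."""
        for n in self.n_values:
            for m in self.lengths:
                for weighting in self.weightings:
                    for spec in self.specs(weighting):
                        yield (n, m, weighting, spec.label)

    @property
    def n_cells(self) -> int:
        return (
            len(self.n_values)
            * len(self.lengths)
            * len(self.weightings)
            * len(paper_specs("w"))
        )


def run_grid(config: GridConfig) -> pd.DataFrame:
    """Compute every grid cell; returns a tidy frame keyed by (n, m, weighting, index).

    One fingerprint set is generated per length m (sub-seeded from
    ``config.seed``), so all cells at a given m share the same data, as do
    the w/nw variants of each coefficient (identical counters, different
    denominators).  Undefined values never abort the grid; they are excluded
    from the mean and counted in ``n_undefined``.
    """
    root = np.random.SeedSequence(config.seed)
    gen_seeds, sub_seeds = root.spawn(2)
    gen_children = gen_seeds.spawn(len(config.lengths))
    sub_children = sub_seeds.spawn(len(config.lengths))
    specs_by_weighting = {w: config.specs(w) for w in config.weightings}
    frames = []
    for m, gseed, sseed in zip(config.lengths, gen_children, sub_children):
        fps = BinaryFingerprintSet(
            (np.random.default_rng(gseed).random((config.n_fingerprints, m)) < config.p_on
             ).astype(np.uint8)
        )
        rows = _mean_abs_table(
            fps,
            specs_by_weighting,
            config.n_values,
            config.gamma_mode,
            config.weight_scheme,
            config.subsample,
            sseed,
        )
        for r in rows:
            r["m"] = m
        frames.append(pd.DataFrame(rows))
    df = pd.concat(frames, ignore_index=True)
    df["index"] = [spec.label for spec in df["spec"]]
    df = df[["n", "m", "weighting", "index", "mean_abs_s", "n_combinations", "n_undefined"]]
    df = df.sort_values(["n", "m", "weighting", "index"], kind="stable").reset_index(drop=True)
    return df


def grid_to_csv(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    """Write the grid as CSV, optionally preceded by '#' provenance comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def zigzag_report(
    curve: Mapping[int, float], inverted: bool = False
) -> list[tuple[int, bool]]:
    """Check the alternating pattern s_{2l} > s_{2l+1} < s_{2l+2}.

    For every even n with both n+1 and n+2 present, reports whether the
    odd-n local minimum holds.  With ``inverted=True`` the opposite pattern
    (odd-n local maximum, as the Goodman-Kruskal coefficient shows) is tested.
    """
    out = []
    for n in sorted(curve):
        if n % 2 != 0 or n + 1 not in curve or n + 2 not in curve:
            continue
        lo, mid, hi = curve[n], curve[n + 1], curve[n + 2]
        if inverted:
            ok = lo < mid > hi
        else:
            ok = lo > mid < hi
        out.append((n, bool(ok)))
    return out


def enumerate_srd_design(
    cv_modes: Sequence[str] = ("contiguous", "randomized"),
    n_folds: int = 7,
    n_values: Sequence[int] = DEFAULT_N_VALUES,
    weightings: Sequence[str] = ("w", "nw"),
    n_indices: int = 19,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> Iterator[tuple[str, int, int, str, int, int]]:
    """Enumerate the fold-level SRD design (cv mode, fold, n, weighting, index, m).

    With the defaults this yields 2*7*14*2*19*4 = 29792 design points, one
    per cross-validated SRD value entering the variance analysis.
    """
    for mode in cv_modes:
        for fold in range(n_folds):
            for n in n_values:
                for weighting in weightings:
                    for idx in range(n_indices):
                        for m in lengths:
                            yield (mode, fold, n, weighting, idx, m)
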