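"""Reading, writing, validating and synthesizing sets of dichotomous fingerprints.

A *dichotomous* (binary) fingerprint is a fixed-length string of 0/1 bits,
the standard presence/absence encoding of molecular features used throughout
cheminformatics.  Every operation in this package consumes a
:class:`BinaryFingerprintSet`: an N x m table of bits in which all N
fingerprints share the common length m.

Two plain-text formats are supported:

``bitstring``
    One contiguous run of ``0``/``1`` characters per line, optionally
    preceded by ``label<TAB>``.  Self-describing and diff-friendly; this is
    the canonical format.
``matrix``
    Comma- or whitespace-separated 0/1 integers, one fingerprint per row.
    A non-numeric first row is treated as a header and skipped.

Random sets are generated as independent Bernoulli(p_on) bits, emulating
random dichotomous vectors of length m; a single integer seed makes the
whole set bit-for-bit reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BinaryFingerprintSet",
    "GeneratorConfig",
    "FingerprintFormatError",
    "FingerprintValidationError",
    "read_fingerprints",
    "write_fingerprints",
    "generate_random",
]

_BITSTRING_RE = re.compile(r"^[01]+$")


class FingerprintFormatError(ValueError):
    """A file could not be decoded as fingerprints (ragged rows, bad characters)."""


class FingerprintValidationError(ValueError):
    """In-memory fingerprint data violates the 0/1 table contract."""


@dataclass(eq=False)
class BinaryFingerprintSet:
    """N fingerprints of common length m with entries in {0, 1}.

    Parameters
    ----------
    data
        Array-like of shape (N, m); a single 1-D vector is promoted to a
        1 x m set.  Entries must be exactly 0 or 1.
    labels
        Optional per-fingerprint identifiers; must be unique and of length N.
    """

    data: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise FingerprintValidationError(
                f"fingerprint data must be a non-empty 2-D table, got shape {arr.shape}"
            )
        if not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))].flat[0]
            raise FingerprintValidationError(
                f"fingerprint entries must be 0 or 1, found {bad!r}"
            )
        self.data = arr.astype(np.uint8)
        if self.labels is not None:
            self.labels = tuple(str(x) for x in self.labels)
            if len(self.labels) != self.data.shape[0]:
                raise FingerprintValidationError(
                    f"{len(self.labels)} labels for {self.data.shape[0]} fingerprints"
                )
            if len(set(self.labels)) != len(self.labels):
                raise FingerprintValidationError("fingerprint labels must be unique")

    @property
    def n_fingerprints(self) -> int:
        """N, the number of fingerprints."""
        return self.data.shape[0]

    @property
    def length(self) -> int:
        """m, the common fingerprint length in bits."""
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.n_fingerprints

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryFingerprintSet):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and bool(np.array_equal(self.data, other.data))
            and self.labels == other.labels
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BinaryFingerprintSet(N={self.n_fingerprints}, m={self.length}, "
            f"labels={'yes' if self.labels else 'no'})"
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the random fingerprint generator.

    ``p_on`` is the probability that any given bit is 1 (default 0.5, the
    maximum-entropy choice for unconstrained random dichotomous vectors).
    The same ``seed`` with the same configuration reproduces the identical
    set bit-for-bit.
    """

    n_fingerprints: int
    length: int
    p_on: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fingerprints < 1:
            raise ValueError(f"n_fingerprints must be >= 1, got {self.n_fingerprints}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError(f"p_on must lie in [0, 1], got {self.p_on}")


def generate_random(config: GeneratorConfig) -> BinaryFingerprintSet:
    """Generate ``config.n_fingerprints`` random dichotomous vectors of length m.

    Bits are independent Bernoulli(``p_on``).  Deterministic under a fixed
    seed; the generator stream is derived from a :class:`numpy.random.SeedSequence`
    so sub-streams (e.g. per-length sets in an experiment grid) can be spawned
    reproducibly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    data = rng.random((config.n_fingerprints, config.length)) < config.p_on
    return BinaryFingerprintSet(data.astype(np.uint8))


def _parse_bitstring(lines: Sequence[str]) -> BinaryFingerprintSet:
    rows: list[np.ndarray] = []
    labels: list[str] = []
    saw_label = False
    m: int | None = None
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line:
            continue
        if "\t" in line:
            label, bits = line.split("\t", 1)
            labels.append(label)
            saw_label = True
        else:
            bits = line
            labels.append(str(len(labels)))
        if not _BITSTRING_RE.match(bits):
            raise FingerprintFormatError(
                f"line {i}: expected a string of 0/1 characters, got {bits!r}"
            )
        if m is None:
            m = len(bits)
        elif len(bits) != m:
            raise FingerprintFormatError(
                f"line {i}: fingerprint length {len(bits)} differs from length {m} "
                f"of the first record"
            )
        rows.append(np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0"))
    if not rows:
        raise FingerprintFormatError("no fingerprints found in input")
    return BinaryFingerprintSet(
        np.vstack(rows), tuple(labels) if saw_label else None
    )


def _parse_matrix(lines: Sequence[str]) -> BinaryFingerprintSet:
    rows: list[list[int]] = []
    m: int | None = None
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.replace(",", " ").split()
        try:
            values = [int(t) for t in tokens]
        except ValueError:
            if not rows and m is None:
                continue  # header row of labels
            raise FingerprintFormatError(
                f"line {i}: non-numeric token in matrix row: {line!r}"
            ) from None
        if any(v not in (0, 1) for v in values):
            bad = next(v for v in values if v not in (0, 1))
            raise FingerprintFormatError(f"line {i}: value {bad} outside {{0, 1}}")
        if m is None:
            m = len(values)
        elif len(values) != m:
            raise FingerprintFormatError(
                f"line {i}: row has {len(values)} values, expected {m}"
            )
        rows.append(values)
    if not rows:
        raise FingerprintFormatError("no fingerprints found in input")
    return BinaryFingerprintSet(np.asarray(rows, dtype=np.uint8))


def read_fingerprints(path: str | Path, format: str = "bitstring") -> BinaryFingerprintSet:
    """Read a fingerprint set from a text file.

    ``format`` is ``"bitstring"`` (default) or ``"matrix"``.  The length m is
    inferred from the first record; ragged rows and characters/values outside
    {0, 1} raise :class:`FingerprintFormatError` naming the offending line.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if format == "bitstring":
        return _parse_bitstring(lines)
    if format in ("matrix", "delimited-matrix"):
        return _parse_matrix(lines)
    raise ValueError(f"unknown fingerprint format: {format!r}")


def write_fingerprints(
    fps: BinaryFingerprintSet, path: str | Path, format: str = "bitstring"
) -> None:
    """Write a fingerprint set; ``read_fingerprints`` round-trips it exactly.

    Bitstring files are written with LF line endings; labels, when present,
    are emitted as a leading ``label<TAB>`` field (bitstring format only).
    """
    out: list[str] = []
    if format == "bitstring":
        for i, row in enumerate(fps.data):
            bits = "".join("1" if b else "0" for b in row)
            if fps.labels is not None:
                out.append(f"{fps.labels[i]}\t{bits}")
            else:
                out.append(bits)
    elif format in ("matrix", "delimited-matrix"):
        for row in fps.data:
            out.append(",".join(str(int(b)) for b in row))
    else:
        raise ValueError(f"unknown fingerprint format: {format!r}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
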