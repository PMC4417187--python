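"""Exhaustive enumeration of maximal direct-repeat pairs and mutagenicity scoring.

A direct repeat (DR) is a pair of identical same-strand subsequences at two
positions of one molecule. The counting unit is the *maximal pair*
``(pos1, pos2, length)``: extending the matched copies by one base on either
side breaks the identity or hits a sequence boundary. A motif occurring k
times yields k(k-1)/2 candidate pairs, each assessed for maximality
independently; each maximal pair is reported exactly once at its maximal
length, and its internal sub-repeats are not counted separately.

Pairs whose two copies overlap (``pos2 - pos1 < length``) are included by
default and carry an ``overlapping`` flag; they can be excluded.

The scanner seeds on shared k-mers (k = minimum length) and extends each
left-maximal seed to its maximal length; it is validated bit-exactly against
an independent brute-force enumeration in the test suite.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i


class AlphabetError(ValueError):
    """Sequence contains symbols outside {A,C,G,T} and masking is disabled."""


@dataclass(frozen=True, order=True)
class DirectRepeatPair:
    """One maximal repeated pair; positions are 0-based, ``pos1 < pos2``."""

    pos1: int
    pos2: int
    length: int
    motif: str = field(compare=False)

    @property
    def overlapping(self) -> bool:
        return self.pos2 - self.pos1 < self.length


def _encode(seq: str, mask_ambiguous: bool) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    arr = _LUT[raw]
    bad = arr < 0
    if bad.any():
        if not mask_ambiguous:
            raise AlphabetError(
                f"sequence contains {int(bad.sum())} non-ACGT symbols; "
                "enable masking to exclude them from scanning"
            )
        # unique negative codes: a masked base never matches anything
        arr[bad] = -(np.arange(int(bad.sum()), dtype=np.int64) + 2)
    return arr


def find_direct_repeats(
    seq: str,
    min_len: int = 5,
    include_overlapping: bool = True,
    mask_ambiguous: bool = False,
) -> list[DirectRepeatPair]:
    """Every maximal same-strand repeat pair of length >= ``min_len``.

    Returns pairs sorted by (pos1, pos2). The scan is same-strand only
    (direct repeats, not inverted repeats).
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    n = len(seq)
    if n < min_len + 1:
        return []
    seq = seq.upper()
    arr = _encode(seq, mask_ambiguous)
    k = min_len

    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    starts = np.flatnonzero(valid)
    if starts.size == 0:
        return []
    codes = codes[starts]
    order = np.argsort(codes, kind="stable")
    codes_sorted = codes[order]
    starts_sorted = starts[order]
    group_bounds = np.flatnonzero(np.diff(codes_sorted)) + 1
    groups = np.split(starts_sorted, group_bounds)

    pairs: list[DirectRepeatPair] = []
    a = arr  # local alias for speed
    for grp in groups:
        m = grp.size
        if m < 2:
            continue
        positions = grp.tolist()  # ascending (stable sort of ascending starts)
        for x in range(m - 1):
            i = positions[x]
            for y in range(x + 1, m):
                j = positions[y]
                # left-maximal seed: the pair's leftmost shared k-mer
                if i > 0 and a[i - 1] == a[j - 1]:
                    continue
                t, u = i + k, j + k
                while u < n and a[t] == a[u]:
                    t += 1
                    u += 1
                length = t - i
                pairs.append(DirectRepeatPair(i, j, length, seq[i : i + length]))
    if not include_overlapping:
        pairs = [p for p in pairs if not p.overlapping]
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class DRSpectrum:
    """Counts of maximal DR pairs per exact length."""

    counts: dict[int, int]
    min_len: int = 5

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count in spectrum")

    def count(self, length: int) -> int:
        return self.counts.get(length, 0)

    def total(self, min_len: int | None = None) -> int:
        """Total number of pairs of length >= ``min_len`` (default: all)."""
        lo = self.min_len if min_len is None else min_len
        return sum(c for length, c in self.counts.items() if length >= lo)

    @property
    def max_length(self) -> int:
        return max((length for length, c in self.counts.items() if c), default=0)

    def as_dict(self) -> dict[int, int]:
        return dict(sorted(self.counts.items()))


def dr_spectrum(pairs: list[DirectRepeatPair], min_len: int = 5) -> DRSpectrum:
    """Exact-length histogram of maximal pairs with length >= ``min_len``."""
    counts = Counter(p.length for p in pairs if p.length >= min_len)
    return DRSpectrum(counts=dict(counts), min_len=min_len)


def scan_genome(genome, min_len: int = 5, include_overlapping: bool = True,
                mask_ambiguous: bool = False) -> tuple[list[DirectRepeatPair], DRSpectrum]:
    """Scan a genome's non-D-loop arc; convenience wrapper."""
    from .genome_io import non_dloop_sequence

    pairs = find_direct_repeats(non_dloop_sequence(genome), min_len=min_len,
                                include_overlapping=include_overlapping,
                                mask_ambiguous=mask_ambiguous)
    return pairs, dr_spectrum(pairs, min_len=min_len)


# ---------------------------------------------------------------------------
# Mutagenicity scoring
# ---------------------------------------------------------------------------

@dataclass
class MutagenicityModel:
    """Length-dependent deletion-propensity weights for long DRs.

    ``weights`` maps repeat length (bp) to a relative deletion frequency;
    ``log10_slope``/``log10_intercept`` record the fitted log-linear trend
    used to extrapolate beyond the calibration support. Two calibrations are
    bundled, derived from DR-mediated deletion assays in engineered phage
    lambda DNA and in yeast mtDNA; both ship as editable TSV tables.
    """

    name: str
    weights: dict[int, float]
    min_len: int = 10
    log10_slope: float | None = None
    log10_intercept: float | None = None

    def __post_init__(self) -> None:
        lengths = sorted(self.weights)
        vals = [self.weights[L] for L in lengths]
        if any(v <= 0 for v in vals):
            raise ValueError(f"{self.name}: weights must be positive")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"{self.name}: weights must be non-decreasing in length")

    def weight(self, length: int) -> float:
        if length < self.min_len:
            return 0.0
        if length in self.weights:
            return self.weights[length]
        if self.log10_slope is None or self.log10_intercept is None:
            raise ValueError(
                f"{self.name}: length {length} outside calibration support and no fitted trend"
            )
        logger.warning("%s: extrapolating weight for length %d beyond calibration support",
                       self.name, length)
        return 10.0 ** (self.log10_intercept + self.log10_slope * length)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None,
                 min_len: int | None = None) -> "MutagenicityModel":
        """Load a weight table: comment header (# key: value) + length\tweight rows."""
        meta: dict[str, str] = {}
        weights: dict[int, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            cols = line.split("\t")
            if cols[0].lower() in ("length", "l"):
                continue
            weights[int(cols[0])] = float(cols[1])
        return cls(
            name=name or meta.get("name", Path(path).stem),
            weights=weights,
            min_len=min_len if min_len is not None else int(meta.get("min_len", 10)),
            log10_slope=float(meta["log10_slope"]) if "log10_slope" in meta else None,
            log10_intercept=float(meta["log10_intercept"]) if "log10_intercept" in meta else None,
        )

    @classmethod
    def bundled(cls, name: str) -> "MutagenicityModel":
        """Load one of the bundled calibrations: ``lambda_phage`` or ``yeast``."""
        from importlib.resources import files

        if name not in ("lambda_phage", "yeast"):
            raise ValueError(f"no bundled model {name!r}")
        return cls.from_tsv(files("drscan.data") / f"tms_{name}.tsv", name=name)


def total_mutagenicity_score(spectrum: DRSpectrum, model: MutagenicityModel) -> float:
    """TMS = sum over scored lengths of count(L) * w(L)."""
    score = 0.0
    for length, count in spectrum.counts.items():
        if length >= model.min_len and count:
            score += count * model.weight(length)
    return score
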