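"""Synonymous codon usage bias, Wright's N_c, GC3 and strand-asymmetry skews.

Wright's effective number of codons N_c measures how evenly a coding
sequence uses the synonymous codons of each amino acid: N_c = 20 when one
codon per amino acid is used exclusively (maximal bias) and equals the
number of sense codons of the genetic code (61 standard, 60 vertebrate
mitochondrial) when usage is perfectly uniform.

Per synonymous family with n counted codons and observed frequencies p_i,
the homozygosity estimate is

    F_hat = (n * sum(p_i^2) - 1) / (n - 1)

and N_c sums, over degeneracy classes k (families with k synonymous
codons), N_k / mean(F_hat of class k), with single-codon families each
contributing 1. The mutational-bias expectation N_c*(GC3) is Wright's
curve  N_c* = 2 + s + 29 / (s^2 + (1-s)^2).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from ._codes import GeneticCode, get_code
from .genome_io import CodingSequence

logger = logging.getLogger(__name__)


@dataclass
class CodonUsageTable:
    """Per-codon counts over the sense codons of one genetic code."""

    counts: dict[str, int]
    code: GeneticCode = field(repr=False)

    def __post_init__(self) -> None:
        for codon, c in self.counts.items():
            if codon not in self.code.codon_to_aa:
                raise ValueError(f"{codon!r} is not a sense codon of the {self.code.name} code")
            if c < 0:
                raise ValueError(f"negative count for {codon}")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def family_frequencies(self, codonw_compat: bool = False) -> dict[str, dict[str, float]]:
        """Relative synonymous-codon frequencies per family (sums to 1 where used)."""
        out: dict[str, dict[str, float]] = {}
        for fam, codons in self.code.families(codonw_compat).items():
            tot = sum(self.counts.get(c, 0) for c in codons)
            if tot:
                out[fam] = {c: self.counts.get(c, 0) / tot for c in codons}
        return out


class CodonUsageError(ValueError):
    pass


def codon_usage(cds: CodingSequence | str, code: GeneticCode | str | None = None) -> CodonUsageTable:
    """Count codons of an in-frame coding sequence (terminal codons trimmed upstream).

    An in-frame stop codon is a validation error naming its position.
    """
    if isinstance(cds, CodingSequence):
        seq = cds.nucleotides
        code = code or cds.genetic_code
    else:
        seq = cds
        code = code or "vertebrate_mitochondrial"
    if isinstance(code, str):
        code = get_code(code)
    seq = seq.upper()
    if len(seq) % 3:
        raise CodonUsageError(f"sequence length {len(seq)} not divisible by 3")
    counts: Counter[str] = Counter()
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in code.stop_codons:
            raise CodonUsageError(f"in-frame stop codon {codon} at nucleotide position {i}")
        if codon not in code.codon_to_aa:
            raise CodonUsageError(f"unrecognized codon {codon!r} at nucleotide position {i}")
        counts[codon] += 1
    return CodonUsageTable(counts=dict(counts), code=code)


def _family_homozygosity(counts: list[int]) -> float | None:
    """F_hat for one family; None when inestimable (n < 2 or degenerate)."""
    n = sum(counts)
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts)
    f_hat = (n * sum_p2 - 1) / (n - 1)
    if f_hat <= 0:
        return None  # finite-sample artifact at tiny n; impute from class mean
    return f_hat


def effective_number_of_codons(table: CodonUsageTable, codonw_compat: bool = False) -> float:
    """Wright's N_c, capped at the code's sense-codon count.

    Families with fewer than 2 counted codons (or a non-positive finite-sample
    F_hat) are imputed at their degeneracy-class mean; an empty degeneracy
    class falls back to the average of the neighbouring 2- and 4-fold class
    means (3-fold) or to the theoretical 1/k. ``codonw_compat`` splits
    six-fold families into 2+4, matching CodonW's degeneracy classes (the
    convention behind published mtDNA N_c values).
    """
    if table.n == 0:
        raise CodonUsageError("empty codon usage table: N_c undefined")
    fams = table.code.families(codonw_compat)
    by_class: dict[int, list[float | None]] = {}
    for fam, codons in fams.items():
        k = len(codons)
        f_hat = _family_homozygosity([table.counts.get(c, 0) for c in codons])
        by_class.setdefault(k, []).append(f_hat)

    class_means: dict[int, float | None] = {}
    for k, vals in by_class.items():
        est = [v for v in vals if v is not None]
        class_means[k] = sum(est) / len(est) if est else None

    nc = 0.0
    for k, vals in sorted(by_class.items()):
        n_k = len(vals)
        if k == 1:
            nc += n_k
            continue
        mean_f = class_means[k]
        if mean_f is None:
            if k == 3 and class_means.get(2) and class_means.get(4):
                mean_f = (class_means[2] + class_means[4]) / 2
                logger.info("empty %d-fold class: imputed F from 2- and 4-fold means", k)
            else:
                mean_f = 1.0 / k
                logger.info("empty %d-fold class: imputed theoretical F = 1/%d", k, k)
        nc += n_k / mean_f
    return min(nc, float(table.code.n_sense))


def expected_nc(gc3: float) -> float:
    """Wright's mutational-bias expectation N_c*(s) = 2 + s + 29/(s^2 + (1-s)^2)."""
    if not 0.0 < gc3 < 1.0:
        raise ValueError(f"GC3 must lie strictly within (0, 1), got {gc3}")
    return 2.0 + gc3 + 29.0 / (gc3 ** 2 + (1.0 - gc3) ** 2)


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

class SkewUndefinedError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class SkewStats:
    """Strand-asymmetry and composition summary of one sequence.

    Each skew is evaluated lazily so that e.g. the GC-skew of an AT-free
    sequence is still available; accessing a skew whose denominator is zero
    raises :class:`SkewUndefinedError`.
    """

    a: int
    c: int
    g: int
    t: int
    length: int

    @property
    def gc_skew(self) -> float:
        if self.g + self.c == 0:
            raise SkewUndefinedError("GC-skew undefined: no G or C bases")
        return (self.g - self.c) / (self.g + self.c)

    @property
    def at_skew(self) -> float:
        if self.a + self.t == 0:
            raise SkewUndefinedError("AT-skew undefined: no A or T bases")
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_content(self) -> float:
        return (self.g + self.c) / self.length


def skews(seq: str) -> SkewStats:
    """GC-skew (G-C)/(G+C), AT-skew (A-T)/(A+T) and GC content of ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    a, c, g, t = (seq.count(b) for b in "ACGT")
    return SkewStats(a=a, c=c, g=g, t=t, length=len(seq))


def gc3(cds: CodingSequence | str) -> float:
    """Fraction of G+C at third codon positions of an in-frame sequence."""
    seq = cds.nucleotides if isinstance(cds, CodingSequence) else cds
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    thirds = seq[2::3]
    return sum(1 for b in thirds if b in "GC") / len(thirds)
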