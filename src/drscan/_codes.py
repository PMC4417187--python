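"""Genetic-code tables and translation helpers.

Thin wrapper around :mod:`Bio.Data.CodonTable` exposing the two codes used
throughout the package (the standard nuclear code and the vertebrate
mitochondrial code) plus the synonymous-family groupings that the effective
number of codons and the codon-randomization schemes operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

_BASES = "TCAG"

#: Registry of supported codes: name -> NCBI translation table id.
CODE_IDS = {
    "standard": 1,
    "vertebrate_mitochondrial": 2,
}


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon -> amino-acid map plus derived groupings."""

    name: str
    table_id: int
    codon_to_aa: dict[str, str]  # sense codons only
    stop_codons: frozenset[str]
    start_codons: frozenset[str]
    aa_to_codons: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(self.codon_to_aa)

    @property
    def n_sense(self) -> int:
        return len(self.codon_to_aa)

    def families(self, codonw_compat: bool = False) -> dict[str, tuple[str, ...]]:
        """Synonymous families keyed by a stable family id.

        With ``codonw_compat`` six-fold families are split into their
        two-fold and four-fold halves by the first two codon positions
        (e.g. standard-code Leu -> TTR + CTN), matching CodonW's degeneracy
        classes.
        """
        fams: dict[str, tuple[str, ...]] = {}
        for aa, codons in self.aa_to_codons.items():
            prefixes = {c[:2] for c in codons}
            if codonw_compat and len(codons) == 6:
                for pre in sorted(prefixes):
                    sub = tuple(c for c in codons if c[:2] == pre)
                    fams[f"{aa}/{pre}"] = sub
            else:
                fams[aa] = codons
        return fams

    def translate(self, seq: str, first_is_start: bool = False) -> str:
        """Translate an in-frame sequence of complete codons.

        ``first_is_start`` renders the first codon as Met when it is an
        annotated initiation codon of this code (mitochondrial genes often
        start with ATA/ATT etc.).
        """
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
        seq = seq.upper()
        out = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in self.stop_codons:
                out.append("*")
            elif codon in self.codon_to_aa:
                aa = self.codon_to_aa[codon]
                if i == 0 and first_is_start and codon in self.start_codons:
                    aa = "M"
                out.append(aa)
            else:
                raise ValueError(f"unknown codon {codon!r} at position {i}")
        return "".join(out)


@lru_cache(maxsize=None)
def get_code(name: str = "vertebrate_mitochondrial") -> GeneticCode:
    if name not in CODE_IDS:
        raise ValueError(f"unknown genetic code {name!r}; choose from {sorted(CODE_IDS)}")
    table = CodonTable.unambiguous_dna_by_id[CODE_IDS[name]]
    codon_to_aa = {c: aa for c, aa in table.forward_table.items()}
    aa_to_codons: dict[str, list[str]] = {}
    for codon in sorted(codon_to_aa):
        aa_to_codons.setdefault(codon_to_aa[codon], []).append(codon)
    return GeneticCode(
        name=name,
        table_id=table.id,
        codon_to_aa=codon_to_aa,
        stop_codons=frozenset(table.stop_codons),
        start_codons=frozenset(table.start_codons),
        aa_to_codons={aa: tuple(cs) for aa, cs in aa_to_codons.items()},
    )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
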