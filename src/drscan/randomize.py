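"""Selective sequence randomization: eight null models for DR counts.

Each scheme destroys exactly one class of sequence structure while
preserving the rest, so that comparing DR counts between the native
non-D-loop sequence and an ensemble of randomized replicates attributes the
repeat load to specific genome attributes:

==================  =====================================================
RGO                 permute whole-gene blocks (gene order), sequences intact
RRNA_SHUFFLE        permute nucleotides within each rRNA gene
TRNA_SHUFFLE        permute nucleotides within each tRNA gene
PROTEIN_SHUFFLE     permute nucleotides within each protein-coding gene
FULL                permute all non-D-loop nucleotides
CODON_SHUFFLE       permute codons within each protein-coding gene
USCU                re-encode each protein with equal-frequency synonymous
                    codons (amino-acid sequence exactly preserved)
NU                  i.i.d. uniform A/C/G/T sequence of the same length
==================  =====================================================

All schemes operate on the non-D-loop arc and return a plain DNA string of
unchanged length. Non-coding, non-D-loop bases are untouched by gene-scoped
schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._codes import GeneticCode, get_code, reverse_complement
from .dr_scan import DRSpectrum, dr_spectrum, find_direct_repeats
from .genome_io import Feature, MtGenome, non_dloop_arc

logger = logging.getLogger(__name__)


class RandomizationScheme(str, Enum):
    RGO = "RGO"
    RRNA_SHUFFLE = "RRNA_SHUFFLE"
    TRNA_SHUFFLE = "TRNA_SHUFFLE"
    PROTEIN_SHUFFLE = "PROTEIN_SHUFFLE"
    FULL = "FULL"
    CODON_SHUFFLE = "CODON_SHUFFLE"
    USCU = "USCU"
    NU = "NU"


class RandomizationError(ValueError):
    pass


_CLASS_OF_SCHEME = {
    RandomizationScheme.RRNA_SHUFFLE: "rRNA",
    RandomizationScheme.TRNA_SHUFFLE: "tRNA",
    RandomizationScheme.PROTEIN_SHUFFLE: "CDS",
}


def _shuffle_string(s: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def _replace_feature(arc: list[str], feat: Feature, new_coding: str) -> None:
    """Write a coding-strand sequence back into the arc, respecting strand."""
    ins = reverse_complement(new_coding) if feat.strand == "-" else new_coding
    arc[feat.start - 1 : feat.end] = list(ins)


def _gene_blocks(arc_len: int, feats: list[Feature]) -> list[tuple[int, int]]:
    """Split the arc into gene blocks with trailing intergenic spacers attached.

    Bases before the first gene stay fixed at the front of the arc.
    """
    genes = sorted((f for f in feats), key=lambda f: f.start)
    blocks = []
    for idx, f in enumerate(genes):
        end = genes[idx + 1].start - 1 if idx + 1 < len(genes) else arc_len
        blocks.append((f.start - 1, end))  # 0-based half-open
    return blocks


def _uscu_recode(body: str, code: GeneticCode, rng: np.random.Generator,
                 balanced: bool, gene: str,
                 reference_protein: str | None = None) -> str:
    """Re-encode internal codons with unbiased synonymous usage.

    The initiation codon and the (possibly incomplete) stop are kept as-is;
    internal codons are translated and re-drawn. With ``balanced`` a
    maximally even synonymous multiset is assigned per family and permuted,
    instead of per-site i.i.d. uniform draws.
    """
    rem = len(body) % 3
    stop = body[len(body) - (3 if rem == 0 else rem):]
    inner = body[3 : len(body) - len(stop)]
    aas = []
    for i in range(0, len(inner), 3):
        codon = inner[i : i + 3]
        if codon in code.stop_codons:
            raise RandomizationError(
                f"USCU: in-frame stop codon {codon} in gene {gene} at codon {i // 3 + 1}"
            )
        if codon not in code.codon_to_aa:
            raise RandomizationError(f"USCU: unknown codon {codon!r} in gene {gene}")
        aas.append(code.codon_to_aa[codon])
    if reference_protein is not None:
        ref_inner = reference_protein[1 : 1 + len(aas)]
        for pos, (got, ref) in enumerate(zip(aas, ref_inner), start=2):
            if got != ref:
                raise RandomizationError(
                    f"USCU: translation mismatch in gene {gene} at residue {pos}: "
                    f"{got} != reference {ref}"
                )
    if balanced:
        new_codons: list[str | None] = [None] * len(aas)
        by_aa: dict[str, list[int]] = {}
        for idx, aa in enumerate(aas):
            by_aa.setdefault(aa, []).append(idx)
        for aa, idxs in by_aa.items():
            codons = code.aa_to_codons[aa]
            # maximally even multiset over the family, then a random assignment
            pool = [codons[i % len(codons)] for i in range(len(idxs))]
            perm = rng.permutation(len(pool))
            for slot, p in zip(idxs, perm):
                new_codons[slot] = pool[p]
        inner_new = "".join(new_codons)  # type: ignore[arg-type]
    else:
        parts = []
        for aa in aas:
            codons = code.aa_to_codons[aa]
            parts.append(codons[rng.integers(len(codons))])
        inner_new = "".join(parts)
    return body[:3] + inner_new + stop


def randomize_genome(
    genome: MtGenome,
    scheme: RandomizationScheme | str,
    rng: np.random.Generator,
    balanced_uscu: bool = False,
) -> str:
    """One randomized replicate of the genome's non-D-loop arc."""
    scheme = RandomizationScheme(scheme)
    arc_seq, feats = non_dloop_arc(genome)
    n = len(arc_seq)

    if scheme is RandomizationScheme.NU:
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
    if scheme is RandomizationScheme.FULL:
        return _shuffle_string(arc_seq, rng)

    if scheme is RandomizationScheme.RGO:
        gene_feats = [f for f in feats if f.ftype in ("rRNA", "tRNA", "CDS")]
        if not gene_feats:
            raise RandomizationError("RGO requires annotated genes")
        blocks = _gene_blocks(n, gene_feats)
        prefix_end = blocks[0][0]
        order = rng.permutation(len(blocks))
        out = [arc_seq[:prefix_end]]
        out.extend(arc_seq[blocks[i][0] : blocks[i][1]] for i in order)
        return "".join(out)

    arc = list(arc_seq)
    if scheme in _CLASS_OF_SCHEME:
        ftype = _CLASS_OF_SCHEME[scheme]
        targets = [f for f in feats if f.ftype == ftype]
        if not targets:
            raise RandomizationError(f"{scheme.value} requires {ftype} features")
        for f in targets:
            coding = arc_seq[f.start - 1 : f.end]
            if f.strand == "-":
                coding = reverse_complement(coding)
            _replace_feature(arc, f, _shuffle_string(coding, rng))
        return "".join(arc)

    # codon-level schemes
    code = get_code(genome.genetic_code)
    cds_feats = [f for f in feats if f.ftype == "CDS"]
    if not cds_feats:
        raise RandomizationError(f"{scheme.value} requires CDS features")
    for f in cds_feats:
        coding = arc_seq[f.start - 1 : f.end]
        if f.strand == "-":
            coding = reverse_complement(coding)
        if scheme is RandomizationScheme.CODON_SHUFFLE:
            rem = len(coding) % 3
            tail = coding[len(coding) - rem:] if rem else ""
            codons = [coding[i : i + 3] for i in range(0, len(coding) - rem, 3)]
            order = rng.permutation(len(codons))
            new = "".join(codons[i] for i in order) + tail
        else:  # USCU
            ref = None
            trans = f.qualifiers.get("translation") if f.qualifiers else None
            if trans:
                ref = str(trans[0])
            new = _uscu_recode(coding, code, rng, balanced_uscu, f.name,
                               reference_protein=ref)
        _replace_feature(arc, f, new)
    return "".join(arc)


# ---------------------------------------------------------------------------
# Null ensembles
# ---------------------------------------------------------------------------

_SCHEME_INDEX = {s: i for i, s in enumerate(RandomizationScheme)}


@dataclass
class NullEnsemble:
    """DR spectra of n independent randomized replicates of one genome."""

    scheme: RandomizationScheme
    n: int
    seed: int
    min_len: int
    spectra: list[DRSpectrum] = field(repr=False)
    totals: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.totals))

    @property
    def sd(self) -> float:
        return float(np.std(self.totals, ddof=1))


def build_null_ensemble(
    genome: MtGenome,
    scheme: RandomizationScheme | str,
    n: int,
    min_len: int = 5,
    seed: int = 0,
    include_overlapping: bool = True,
    balanced_uscu: bool = False,
) -> NullEnsemble:
    """Randomize ``n`` times and scan each replicate for direct repeats.

    Replicates use counter-derived substreams of the master seed, so an
    ensemble is fully reproducible and order-independent.
    """
    scheme = RandomizationScheme(scheme)
    if n < 2:
        raise ValueError("need n >= 2 replicates for ensemble variance")
    spectra = []
    totals = np.empty(n)
    for rep in range(n):
        rng = np.random.default_rng([seed, _SCHEME_INDEX[scheme], rep])
        seq = randomize_genome(genome, scheme, rng, balanced_uscu=balanced_uscu)
        pairs = find_direct_repeats(seq, min_len=min_len,
                                    include_overlapping=include_overlapping)
        spec = dr_spectrum(pairs, min_len=min_len)
        spectra.append(spec)
        totals[rep] = spec.total()
    return NullEnsemble(scheme=scheme, n=n, seed=seed, min_len=min_len,
                        spectra=spectra, totals=totals)
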