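"""Reading, validating and slicing annotated mitochondrial genomes.

Vertebrate mtDNA is a circular molecule of roughly 16.5 kb carrying one
non-coding control region (the D-loop), 2 rRNA genes, 22 tRNA genes and 13
protein-coding genes. This module parses GenBank flat files (or FASTA plus a
BED-like feature table) into :class:`MtGenome`, excises the D-loop arc that
all downstream repeat counting works on, and concatenates protein-coding
genes for codon statistics.

Coordinates are 1-based inclusive in :class:`Feature` (GenBank convention,
``start > end`` denotes a feature wrapping the circular origin); conversion
to 0-based half-open slices is centralized here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

from ._codes import get_code, reverse_complement

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("dloop", "rRNA", "tRNA", "CDS")

#: GenBank feature keys mapped onto the four feature types used here.
_GENBANK_KEYS = {"D-loop": "dloop", "rRNA": "rRNA", "tRNA": "tRNA", "CDS": "CDS"}
#: Keys that duplicate information carried by the keys above.
_SILENT_KEYS = {"source", "gene", "STS", "misc_structure"}


class GenomeValidationError(ValueError):
    """An annotated genome violates a structural invariant."""


class GenomeParseError(ValueError):
    """A record could not be parsed at all."""


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 1-based inclusive; may wrap the origin."""

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    qualifiers: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise GenomeValidationError(f"unknown feature type {self.ftype!r}")
        if self.start < 1 or self.end < 1:
            raise GenomeValidationError(f"{self.name}: coordinates must be >= 1")
        if self.strand not in "+-":
            raise GenomeValidationError(f"{self.name}: bad strand {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class MtGenome:
    """An annotated mitochondrial genome (heavy strand, as deposited)."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    genetic_code: str = "vertebrate_mitochondrial"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self, allow_ambiguous: bool = True) -> None:
        n = len(self.sequence)
        if n == 0:
            raise GenomeValidationError(f"{self.id}: empty sequence")
        if not allow_ambiguous and set(self.sequence) - set("ACGT"):
            raise GenomeValidationError(f"{self.id}: non-ACGT symbols in sequence")
        dloops = [f for f in self.features if f.ftype == "dloop"]
        if len(dloops) > 1:
            raise GenomeValidationError(f"{self.id}: {len(dloops)} D-loop features (at most one allowed)")
        for f in self.features:
            if f.start > n or f.end > n:
                raise GenomeValidationError(
                    f"{self.id}: feature {f.name} ({f.start}..{f.end}) outside sequence of length {n}"
                )
            if f.wraps and not self.circular:
                raise GenomeValidationError(
                    f"{self.id}: feature {f.name} wraps the origin of a linear molecule"
                )

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def dloop(self) -> Feature | None:
        for f in self.features:
            if f.ftype == "dloop":
                return f
        return None

    def features_of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    def feature_sequence(self, feature: Feature) -> str:
        """Coding-strand sequence of a feature (wrap- and strand-aware)."""
        if feature.wraps:
            raw = self.sequence[feature.start - 1 :] + self.sequence[: feature.end]
        else:
            raw = self.sequence[feature.start - 1 : feature.end]
        return reverse_complement(raw) if feature.strand == "-" else raw


@dataclass(frozen=True)
class CodingSequence:
    """Concatenated protein-coding genes of one genome, frame offset 0."""

    genome_id: str
    nucleotides: str
    boundaries: tuple[tuple[str, int], ...]  # (gene name, start index in concatenation)
    genetic_code: str = "vertebrate_mitochondrial"

    def __len__(self) -> int:
        return len(self.nucleotides)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _feature_name(sf: SeqFeature, default: str) -> str:
    for key in ("gene", "product", "standard_name", "note"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return default


def _location_to_coords(sf: SeqFeature, seq_len: int) -> tuple[int, int]:
    """GenBank location -> 1-based inclusive (start, end), wrap-aware."""
    loc = sf.location
    if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
        a, b = loc.parts
        if int(a.end) == seq_len and int(b.start) == 0:
            return int(a.start) + 1, int(b.end)
        raise GenomeValidationError(f"unsupported compound location {loc}")
    if isinstance(loc, CompoundLocation):
        raise GenomeValidationError(f"unsupported compound location {loc}")
    return int(loc.start) + 1, int(loc.end)


def parse_genbank(text: str, allow_ambiguous: bool = False) -> MtGenome:
    """Parse one GenBank flat-file record into an :class:`MtGenome`.

    The D-loop is recognized from a ``D-loop`` feature key or from a
    ``misc_feature`` whose qualifiers mention "control region". Unknown
    feature keys are ignored with a logged warning. Ambiguity codes in the
    sequence are rejected unless ``allow_ambiguous`` (in which case they can
    later be masked out of repeat scanning).
    """
    try:
        record = SeqIO.read(StringIO(text), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError subclasses
        raise GenomeParseError(f"could not parse GenBank record: {exc}") from exc
    try:
        seq = str(record.seq).upper()
    except Exception as exc:  # undefined/contentless ORIGIN block
        raise GenomeParseError(f"{record.id}: record has no usable sequence: {exc}") from exc
    if not seq:
        raise GenomeParseError(f"{record.id}: record has no ORIGIN sequence")
    circular = record.annotations.get("topology", "circular") == "circular"

    features: list[Feature] = []
    for sf in record.features:
        key = sf.type
        ftype = _GENBANK_KEYS.get(key)
        if ftype is None:
            quals = " ".join(str(v) for vs in sf.qualifiers.values() for v in vs).lower()
            if key in ("misc_feature", "regulatory") and "control region" in quals:
                ftype = "dloop"
            elif key in _SILENT_KEYS:
                continue
            else:
                logger.warning("%s: ignoring unknown feature key %r", record.id, key)
                continue
        start, end = _location_to_coords(sf, len(seq))
        strand = "-" if sf.location.strand == -1 else "+"
        name = _feature_name(sf, default=ftype)
        features.append(
            Feature(name=name, ftype=ftype, start=start, end=end, strand=strand,
                    qualifiers={k: list(v) for k, v in sf.qualifiers.items()})
        )

    genome = MtGenome(id=record.id or record.name, sequence=seq, circular=circular,
                      features=features)
    genome.validate(allow_ambiguous=allow_ambiguous)
    return genome


def read_genbank(path: str | Path, allow_ambiguous: bool = False) -> MtGenome:
    return parse_genbank(Path(path).read_text(), allow_ambiguous=allow_ambiguous)


def to_genbank(genome: MtGenome) -> str:
    """Serialize an :class:`MtGenome` back to GenBank flat-file text."""
    n = len(genome.sequence)
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    key_back = {v: k for k, v in _GENBANK_KEYS.items()}
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, n, strand), SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals = dict(f.qualifiers) if f.qualifiers else {"gene": [f.name]}
        record.features.append(SeqFeature(loc, type=key_back[f.ftype], qualifiers=quals))
    out = StringIO()
    SeqIO.write(record, out, "genbank")
    return out.getvalue()


def read_fasta_with_features(fasta_path: str | Path, table_path: str | Path,
                             circular: bool = True,
                             allow_ambiguous: bool = False) -> MtGenome:
    """Plain-FASTA input with a BED-like sidecar annotation table.

    The table is tab-separated with columns ``name ftype start end strand``
    (1-based inclusive coordinates; lines starting with ``#`` are skipped).
    """
    record = SeqIO.read(str(fasta_path), "fasta")
    features = []
    for line in Path(table_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, ftype, start, end, strand = line.split("\t")[:5]
        features.append(Feature(name=name, ftype=ftype, start=int(start),
                                end=int(end), strand=strand))
    genome = MtGenome(id=record.id, sequence=str(record.seq).upper(),
                      circular=circular, features=features)
    genome.validate(allow_ambiguous=allow_ambiguous)
    return genome


# ---------------------------------------------------------------------------
# D-loop excision
# ---------------------------------------------------------------------------

def non_dloop_sequence(genome: MtGenome) -> str:
    """The single linear arc left after excising the D-loop.

    Repeat counting deliberately ignores the D-loop: its tandem repeats are
    not implicated in the deletion classes studied here, and deletions
    removing the replication origin cannot clonally expand. For a circular
    genome the remainder of the molecule is one contiguous arc, which is
    treated as strictly linear (no repeats across the excision breakpoint).
    """
    arc, _ = non_dloop_arc(genome)
    return arc


def non_dloop_arc(genome: MtGenome) -> tuple[str, list[Feature]]:
    """Excised arc plus all non-D-loop features remapped into arc coordinates.

    Returned features use 1-based inclusive coordinates *within the arc* and
    never wrap. Features straddling the D-loop boundary are dropped with a
    warning (they cannot be represented on the arc).
    """
    dloop = genome.dloop
    seq = genome.sequence
    n = len(seq)
    if dloop is None:
        return seq, [f for f in genome.features]

    if dloop.wraps:
        # D-loop covers start..n and 1..end: the arc is already contiguous.
        arc = seq[dloop.end : dloop.start - 1]
        offset = dloop.end  # 0-based index of the arc's first base
    elif genome.circular:
        arc = seq[dloop.end :] + seq[: dloop.start - 1]
        offset = dloop.end
    else:
        # Linear molecule: join the two flanks at the cut.
        arc = seq[: dloop.start - 1] + seq[dloop.end :]
        offset = None

    remapped: list[Feature] = []
    for f in genome.features:
        if f.ftype == "dloop":
            continue
        if offset is None:
            if f.end < dloop.start:
                remapped.append(f)
            elif f.start > dloop.end:
                shift = dloop.length(n)
                remapped.append(replace(f, start=f.start - shift, end=f.end - shift))
            else:
                logger.warning("%s: feature %s straddles the D-loop; dropped from arc",
                               genome.id, f.name)
            continue
        # circular case: rotate so the arc starts right after the D-loop
        start0 = (f.start - 1 - offset) % n
        length = f.length(n)
        if start0 + length > len(arc):
            logger.warning("%s: feature %s straddles the D-loop; dropped from arc",
                           genome.id, f.name)
            continue
        remapped.append(replace(f, start=start0 + 1, end=start0 + length))
    return arc, remapped


# ---------------------------------------------------------------------------
# CDS concatenation
# ---------------------------------------------------------------------------

def concatenated_cds(genome: MtGenome, omit_terminal_codons: bool = True) -> CodingSequence:
    """Concatenate protein-coding genes in genome order.

    With ``omit_terminal_codons`` the initiation codon and the stop codon of
    each gene are dropped. A trailing 1-2 nt remainder is interpreted as an
    annotated incomplete stop codon (completed by polyadenylation, common in
    mammalian mtDNA) and dropped with the stop. Minus-strand genes are
    reverse-complemented before concatenation. Overlapping CDS annotations
    (e.g. ATP8/ATP6) are concatenated independently, duplicating the
    overlapped bases, and flagged in the log.
    """
    cds_features = sorted(genome.features_of_type("CDS"), key=lambda f: (f.start, f.end))
    n = len(genome.sequence)
    prev_end = None
    pieces: list[str] = []
    boundaries: list[tuple[str, int]] = []
    pos = 0
    for f in cds_features:
        if prev_end is not None and not f.wraps and f.start <= prev_end:
            logger.warning("%s: CDS %s overlaps the previous gene; overlapped bases duplicated",
                           genome.id, f.name)
        prev_end = f.end if not f.wraps else n
        body = genome.feature_sequence(f)
        if omit_terminal_codons:
            if len(body) < 9:
                raise GenomeValidationError(
                    f"{genome.id}: CDS {f.name} shorter than 9 nt cannot lose its terminal codons"
                )
            rem = len(body) % 3
            stop_len = 3 if rem == 0 else rem  # incomplete stop = trailing 1-2 nt
            body = body[3 : len(body) - stop_len]
        if len(body) % 3:
            raise GenomeValidationError(
                f"{genome.id}: CDS {f.name} length {len(body)} not a multiple of 3"
            )
        boundaries.append((f.name, pos))
        pieces.append(body)
        pos += len(body)
    return CodingSequence(genome_id=genome.id, nucleotides="".join(pieces),
                          boundaries=tuple(boundaries), genetic_code=genome.genetic_code)
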