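"""Synthetic annotated mtDNA-like genomes and trait-bearing phylogenies.

Every pipeline stage can be exercised without downloads: the generator
emits a circular ~16.5 kb genome with one D-loop, 2 rRNA, 22 tRNA and 13
protein-coding genes (counts and sizes configurable), with tunable base
composition/skew and tunable synonymous-codon-usage (SCU) bias, plus a
Yule phylogeny whose leaves carry log-lifespan and log-body-mass evolving
under correlated Brownian motion — optionally coupled to the genome's
direct-repeat count with a known effect size, so that hypothesis-testing
machinery can be validated against planted ground truth.

The SCU concentration parameter c in (0, 1] interpolates codon usage
within each synonymous family between uniform (c = 1, effective number of
codons near the code's cap) and degenerate single-codon usage (c -> 0,
N_c approaching the analytic floor of 20).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace as _dc_replace
from importlib.resources import files
from pathlib import Path

import dendropy
import numpy as np

from ._codes import GeneticCode, get_code, reverse_complement
from .codon_stats import codon_usage, effective_number_of_codons, gc3 as _gc3, skews as _skews
from .comparative import SpeciesRecord
from .dr_scan import MutagenicityModel, dr_spectrum, find_direct_repeats, total_mutagenicity_score
from .genome_io import Feature, MtGenome, concatenated_cds, non_dloop_sequence, to_genbank

logger = logging.getLogger(__name__)

#: Gene names and relative protein lengths used for the default 13-CDS layout.
_CDS_NAMES = ["ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
              "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB"]
_CDS_WEIGHTS = [318, 347, 513, 227, 68, 227, 261, 115, 98, 459, 603, 173, 380]


def _load_aa_frequencies() -> dict[str, float]:
    freqs: dict[str, float] = {}
    for line in (files("drscan.data") / "aa_frequencies.tsv").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        aa, f = line.split("\t")
        freqs[aa] = float(f)
    total = sum(freqs.values())
    return {aa: f / total for aa, f in freqs.items()}


@dataclass
class GenomeSpec:
    """Layout and composition of one synthetic mitochondrial genome."""

    length: int = 16500
    dloop_length: int = 1100
    n_rrna: int = 2
    rrna_lengths: tuple[int, ...] = (960, 1560)
    n_trna: int = 22
    trna_length: int = 70
    n_cds: int = 13
    #: heavy-strand base probabilities (A, C, G, T); default mimics the
    #: strongly skewed composition typical of mammalian mtDNA heavy strands.
    base_probs: tuple[float, float, float, float] = (0.31, 0.31, 0.13, 0.25)
    #: SCU concentration in (0, 1]: 1 = uniform synonymous usage, -> 0 = one
    #: codon per family. Default 0.5 gives a moderate bias comparable to
    #: mammalian mtDNA.
    scu_concentration: float = 0.5
    spacer_length: int = 2
    aa_frequencies: dict[str, float] | None = None
    genetic_code: str = "vertebrate_mitochondrial"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if not 0.0 < self.scu_concentration <= 1.0:
            raise ValueError("scu_concentration must lie in (0, 1]")
        if len(self.rrna_lengths) != self.n_rrna:
            raise ValueError("rrna_lengths must have n_rrna entries")


@dataclass
class CladeSpec:
    """A Yule clade with correlated Brownian traits at the leaves."""

    n_leaves: int = 32
    birth_rate: float = 1.0
    #: Brownian variances per unit branch length of log-lifespan / log-mass.
    var_log_lifespan: float = 0.2
    var_log_mass: float = 1.0
    correlation: float = 0.68  # lifespan-mass correlation typical of mammals
    #: linear effect of the (standardized) DR count on residual log-lifespan;
    #: 0 = the null world in which repeats do not constrain lifespan.
    coupling: float = 0.0
    coupling_dr_min_len: int = 5
    #: Brownian variance of log SCU concentration (0 = identical genomes spec).
    scu_drift_var: float = 0.0
    #: sd of i.i.d. non-heritable noise added to log-lifespan at the leaves
    #: (records of maximum lifespan are noisy); 0 = purely Brownian lifespans.
    lifespan_noise_sd: float = 0.0
    root_log_lifespan: float = float(np.log(20.0))
    root_log_mass: float = float(np.log(5000.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.var_log_lifespan <= 0 or self.var_log_mass <= 0:
            raise ValueError("Brownian variances must be > 0")
        if self.n_leaves < 3:
            raise ValueError("need at least 3 leaves")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _draw_bases(n: int, probs, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(probs))])


def _family_probs(code: GeneticCode, concentration: float) -> dict[str, np.ndarray]:
    """Per-family codon probabilities for a given SCU concentration.

    The preferred codon of each family (the A-ending codon where present,
    echoing the mammalian mtDNA preference) gets probability
    1/k + (1 - c)(1 - 1/k); the rest share the remainder equally.
    """
    out: dict[str, np.ndarray] = {}
    for aa, codons in code.aa_to_codons.items():
        k = len(codons)
        pref = next((i for i, c in enumerate(codons) if c.endswith("A")), 0)
        p = np.full(k, np.nan)
        p_pref = 1.0 / k + (1.0 - concentration) * (1.0 - 1.0 / k)
        p[:] = (1.0 - p_pref) / (k - 1) if k > 1 else 0.0
        p[pref] = p_pref
        out[aa] = p
    return out


def _synthesize_cds(n_codons: int, code: GeneticCode, fam_probs, aa_freqs,
                    rng: np.random.Generator) -> str:
    """One CDS of ``n_codons`` codons including start (ATG/ATA) and stop (TAA)."""
    aas = list(aa_freqs)
    probs = np.array([aa_freqs[a] for a in aas])
    start = "ATG" if rng.random() < 0.7 else "ATA"
    body = []
    for aa_idx in rng.choice(len(aas), size=n_codons - 2, p=probs):
        aa = aas[aa_idx]
        codons = code.aa_to_codons[aa]
        body.append(codons[rng.choice(len(codons), p=fam_probs[aa])])
    return start + "".join(body) + "TAA"


def generate_genome(spec: GenomeSpec, rng: np.random.Generator | None = None,
                    genome_id: str | None = None) -> MtGenome:
    """A fully annotated synthetic mitochondrial genome.

    Layout: D-loop first, then tRNA/rRNA/CDS blocks separated by short
    spacers, with one CDS (ND6-like) and every third tRNA on the minus
    strand. Coding sequences are built by drawing amino acids from the
    bundled composition table and codons from the spec's SCU distribution;
    non-coding bases are i.i.d. draws from ``base_probs``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    code = get_code(spec.genetic_code)
    aa_freqs = spec.aa_frequencies or _load_aa_frequencies()
    fam_probs = _family_probs(code, spec.scu_concentration)

    n_features = spec.n_rrna + spec.n_trna + spec.n_cds
    fixed = (spec.dloop_length + sum(spec.rrna_lengths)
             + spec.n_trna * spec.trna_length + n_features * spec.spacer_length)
    coding_budget = spec.length - fixed
    if coding_budget < spec.n_cds * 5 * 3:
        raise ValueError(
            f"infeasible layout: {coding_budget} nt left for {spec.n_cds} CDS "
            f"after {fixed} nt of fixed features"
        )
    weights = np.array(_CDS_WEIGHTS[: spec.n_cds], dtype=float)
    if spec.n_cds > len(_CDS_WEIGHTS):
        weights = np.concatenate([weights, np.full(spec.n_cds - len(_CDS_WEIGHTS), 250.0)])
    codons = np.maximum(5, np.floor(weights / weights.sum() * (coding_budget // 3))).astype(int)

    # interleave: t r t r t C t C t C ... with leftover tRNAs appended
    kinds: list[tuple[str, int]] = []
    trna_left, rrna_left, cds_left = spec.n_trna, spec.n_rrna, spec.n_cds
    while rrna_left or cds_left or trna_left:
        if trna_left:
            kinds.append(("tRNA", spec.n_trna - trna_left))
            trna_left -= 1
        if rrna_left:
            kinds.append(("rRNA", spec.n_rrna - rrna_left))
            rrna_left -= 1
        elif cds_left:
            kinds.append(("CDS", spec.n_cds - cds_left))
            cds_left -= 1

    pieces: list[str] = [_draw_bases(spec.dloop_length, spec.base_probs, rng)]
    features: list[Feature] = [
        Feature(name="D-loop", ftype="dloop", start=1, end=spec.dloop_length, strand="+")
    ]
    pos = spec.dloop_length
    n_trna_seen = 0
    for kind, idx in kinds:
        pieces.append(_draw_bases(spec.spacer_length, spec.base_probs, rng))
        pos += spec.spacer_length
        if kind == "tRNA":
            seq = _draw_bases(spec.trna_length, spec.base_probs, rng)
            strand = "-" if n_trna_seen % 3 == 2 else "+"
            n_trna_seen += 1
            name = f"tRNA-{n_trna_seen:02d}"
        elif kind == "rRNA":
            seq = _draw_bases(spec.rrna_lengths[idx], spec.base_probs, rng)
            strand = "+"
            name = ("12S" if idx == 0 else "16S") if spec.n_rrna == 2 else f"rRNA-{idx + 1}"
        else:
            coding = _synthesize_cds(int(codons[idx]), code, fam_probs, aa_freqs, rng)
            name = _CDS_NAMES[idx] if idx < len(_CDS_NAMES) else f"CDS{idx + 1}"
            strand = "-" if name == "ND6" else "+"
            seq = reverse_complement(coding) if strand == "-" else coding
        features.append(Feature(name=name, ftype=kind, start=pos + 1,
                                end=pos + len(seq), strand=strand))
        pieces.append(seq)
        pos += len(seq)
    if pos < spec.length:
        pieces.append(_draw_bases(spec.length - pos, spec.base_probs, rng))
    genome = MtGenome(id=genome_id or f"SYN-{spec.seed}", sequence="".join(pieces),
                      circular=True, features=features, genetic_code=spec.genetic_code)
    genome.validate(allow_ambiguous=False)
    return genome


# ---------------------------------------------------------------------------
# Clade generation
# ---------------------------------------------------------------------------

@dataclass
class CladeResult:
    tree: dendropy.Tree
    records: list[SpeciesRecord]
    genomes: dict[str, MtGenome]
    truth: dict = field(default_factory=dict)


def _yule_tree(n_leaves: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """A pure-birth tree with strictly positive branch lengths.

    Lineages split at rate ``birth_rate`` each; after the n-th lineage
    appears the process runs for one further exponential waiting time, so
    the youngest cherry never has zero-length terminal branches (which
    would make contrasts degenerate).
    """
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.seed_node.birth_time = 0.0
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_leaves:
        k = len(active)
        t += float(rng.exponential(1.0 / (birth_rate * k)))
        parent = active.pop(int(rng.integers(k)))
        parent.edge.length = t - parent.birth_time
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = t
            active.append(child)
    t += float(rng.exponential(1.0 / (birth_rate * n_leaves)))
    taxa = tree.taxon_namespace
    order = rng.permutation(len(active))
    for i, idx in enumerate(order, start=1):
        leaf = active[idx]
        leaf.edge.length = t - leaf.birth_time
        leaf.taxon = taxa.new_taxon(label=f"sp{i:03d}")
    return tree


def simulate_bm_traits(tree: dendropy.Tree, cov: np.ndarray, root: np.ndarray,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Correlated Brownian motion of len(root) traits down a tree."""
    chol = np.linalg.cholesky(cov)
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.asarray(root, dtype=float).copy()
        else:
            bl = node.edge.length or 0.0
            step = chol @ rng.standard_normal(len(root)) * np.sqrt(max(bl, 0.0))
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def generate_clade(cspec: CladeSpec, gspec: GenomeSpec | None = None,
                   with_genomes: bool = True) -> CladeResult:
    """Yule tree + correlated traits + (optionally) one genome per leaf.

    With a non-zero ``coupling`` the standardized non-D-loop DR count of
    each leaf genome is added (times the coupling coefficient) to that
    leaf's log-lifespan, planting a known repeat-longevity effect.
    Ground-truth parameters and raw trait values are recorded in ``truth``.
    """
    rng = np.random.default_rng(cspec.seed)
    tree = _yule_tree(cspec.n_leaves, cspec.birth_rate, seed=int(rng.integers(2 ** 31)))

    r = cspec.correlation
    s1, s2 = cspec.var_log_lifespan, cspec.var_log_mass
    cov = np.array([[s1, r * np.sqrt(s1 * s2)], [r * np.sqrt(s1 * s2), s2]])
    traits = simulate_bm_traits(tree, cov,
                                np.array([cspec.root_log_lifespan, cspec.root_log_mass]), rng)
    species = sorted(traits)
    log_ls = {s: traits[s][0] for s in species}
    log_m = {s: traits[s][1] for s in species}
    if cspec.lifespan_noise_sd > 0:
        noise = rng.normal(0.0, cspec.lifespan_noise_sd, size=len(species))
        for s, e in zip(species, noise):
            log_ls[s] = log_ls[s] + e

    conc: dict[str, float] = {}
    base_spec = gspec or GenomeSpec()
    if cspec.scu_drift_var > 0:
        drift = simulate_bm_traits(tree, np.array([[cspec.scu_drift_var]]),
                                   np.array([0.0]), rng)
        for s in species:
            conc[s] = float(np.clip(base_spec.scu_concentration * np.exp(drift[s][0]),
                                    0.02, 1.0))
    else:
        conc = {s: base_spec.scu_concentration for s in species}

    genomes: dict[str, MtGenome] = {}
    counts: dict[str, float] = {}
    tms_model = MutagenicityModel.bundled("lambda_phage")
    records: list[SpeciesRecord] = []
    if with_genomes:
        for s in species:
            leaf_spec = _dc_replace(base_spec, scu_concentration=conc[s])
            genomes[s] = generate_genome(leaf_spec, rng=np.random.default_rng(
                [cspec.seed, int(rng.integers(2 ** 31))]), genome_id=s)
            arc = non_dloop_sequence(genomes[s])
            pairs = find_direct_repeats(arc, min_len=min(5, cspec.coupling_dr_min_len))
            spec5 = dr_spectrum(pairs, min_len=min(5, cspec.coupling_dr_min_len))
            counts[s] = spec5.total(cspec.coupling_dr_min_len)
        if cspec.coupling != 0.0:
            vals = np.array([counts[s] for s in species], dtype=float)
            sd = vals.std()
            z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
            for s, zi in zip(species, z):
                log_ls[s] = log_ls[s] + cspec.coupling * zi

    # taxonomic "orders": the two subclades of the root
    order_of: dict[str, str] = {}
    root_children = tree.seed_node.child_nodes()
    for i, child in enumerate(root_children):
        label = chr(ord("A") + i)
        for leaf in child.leaf_iter():
            order_of[leaf.taxon.label] = f"Order{label}"

    for s in species:
        rec = SpeciesRecord(species=s, taxon_order=order_of.get(s, "OrderA"),
                            lifespan=float(np.exp(log_ls[s])),
                            body_mass=float(np.exp(log_m[s])))
        if with_genomes:
            g = genomes[s]
            cds = concatenated_cds(g, omit_terminal_codons=True)
            table = codon_usage(cds)
            arc = non_dloop_sequence(g)
            pairs = find_direct_repeats(arc, min_len=5)
            rec.dr_spectrum = dr_spectrum(pairs, min_len=5)
            rec.nc = effective_number_of_codons(table)
            rec.gc3 = _gc3(cds)
            sk = _skews(arc)
            rec.gc_content, rec.gc_skew, rec.at_skew = sk.gc_content, sk.gc_skew, sk.at_skew
            rec.tms = total_mutagenicity_score(rec.dr_spectrum, tms_model)
        records.append(rec)

    truth = {
        "seed": cspec.seed,
        "coupling": cspec.coupling,
        "correlation": cspec.correlation,
        "var_log_lifespan": cspec.var_log_lifespan,
        "var_log_mass": cspec.var_log_mass,
        "scu_concentration": conc,
        "log_lifespan": {s: float(log_ls[s]) for s in species},
        "log_mass": {s: float(log_m[s]) for s in species},
        "dr_count_for_coupling": counts,
    }
    return CladeResult(tree=tree, records=records, genomes=genomes, truth=truth)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_clade(result: CladeResult, outdir: str | Path) -> None:
    """GenBank per genome + Newick + traits TSV + ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for species, genome in result.genomes.items():
        (outdir / f"{species}.gb").write_text(to_genbank(genome))
    result.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    lines = ["species\ttaxon_order\tlifespan_y\tmass_g"]
    for r in result.records:
        lines.append(f"{r.species}\t{r.taxon_order}\t{r.lifespan:.6g}\t{r.body_mass:.6g}")
    (outdir / "traits.tsv").write_text("\n".join(lines) + "\n")
    (outdir / "truth.json").write_text(json.dumps(result.truth, indent=1, sort_keys=True))
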