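"""End-to-end orchestration: genomes + traits + tree -> report tables.

The full run reproduces the analysis battery on any consistent input set:
per-species DR spectra / codon statistics, null-ensemble comparisons,
SCU-bias-vs-DR-count correlation, N_c vs N_c*(GC3), and the longevity test
battery (residual -> contrast -> correlation chain, subpopulation tests,
pairwise order comparisons). All outputs are plain TSV/JSON; every table
carries the configuration hash and seed, and a rerun with identical inputs
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative, genome_io
from .codon_stats import codon_usage, effective_number_of_codons, expected_nc, gc3, skews
from .comparative import (
    SpeciesRecord,
    ensemble_z_test,
    load_tree,
    prepare_tree,
    subpopulation_tests,
)
from .dr_scan import MutagenicityModel, dr_spectrum, find_direct_repeats, total_mutagenicity_score
from .genome_io import MtGenome, concatenated_cds, non_dloop_sequence
from .randomize import RandomizationScheme, build_null_ensemble

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    genome_dir: str | None = None
    traits_path: str | None = None
    tree_path: str | None = None
    out_dir: str = "drscan_out"
    dr_min_len: int = 5
    long_dr_min_len: int = 13  # "long" DRs in the longevity analyses
    null_schemes: tuple[str, ...] = ("FULL", "USCU")
    null_n: int = 100
    reference_species: str | None = None  # all-scheme ensemble on this genome
    percentiles: tuple[float, ...] = (50.0, 75.0, 90.0)
    genetic_code: str = "vertebrate_mitochondrial"
    codonw_compat: bool = False
    tms_model: str = "lambda_phage"
    include_overlapping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.long_dr_min_len < self.dr_min_len:
            raise ValueError("long-DR threshold must be >= DR minimum length")
        if self.null_n < 2:
            raise ValueError("need at least 2 null replicates")

    def hash(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    metadata: dict
    out_dir: Path | None = None


def load_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "taxon_order", "lifespan_y", "mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traits table missing columns: {sorted(missing)}")
    return df


def _cross_reference(genomes: dict[str, MtGenome], traits: pd.DataFrame,
                     tree) -> list[str]:
    """Exhaustive list of cross-reference failures (empty = consistent)."""
    problems = []
    trait_species = set(traits["species"])
    leaf_species = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for s in sorted(leaf_species - trait_species):
        problems.append(f"tree leaf {s!r} has no traits row")
    for s in sorted(leaf_species - set(genomes)):
        problems.append(f"tree leaf {s!r} has no genome")
    return problems


def build_records(genomes: dict[str, MtGenome], traits: pd.DataFrame,
                  config: RunConfig) -> list[SpeciesRecord]:
    model = MutagenicityModel.bundled(config.tms_model)
    records = []
    for row in traits.itertuples(index=False):
        g = genomes[row.species]
        arc = non_dloop_sequence(g)
        pairs = find_direct_repeats(arc, min_len=config.dr_min_len,
                                    include_overlapping=config.include_overlapping)
        spec = dr_spectrum(pairs, min_len=config.dr_min_len)
        cds = concatenated_cds(g, omit_terminal_codons=True)
        table = codon_usage(cds)
        sk = skews(arc)
        records.append(SpeciesRecord(
            species=row.species, taxon_order=row.taxon_order,
            lifespan=float(row.lifespan_y), body_mass=float(row.mass_g),
            dr_spectrum=spec,
            nc=effective_number_of_codons(table, codonw_compat=config.codonw_compat),
            gc3=gc3(cds), gc_content=sk.gc_content,
            gc_skew=sk.gc_skew, at_skew=sk.at_skew,
            tms=total_mutagenicity_score(spec, model),
        ))
    return records


def species_table(records: list[SpeciesRecord], config: RunConfig) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "species": r.species, "taxon_order": r.taxon_order,
            "lifespan_y": r.lifespan, "mass_g": r.body_mass,
            f"dr_total_ge{config.dr_min_len}": r.dr_spectrum.total(config.dr_min_len),
            f"dr_total_ge{config.long_dr_min_len}": r.dr_spectrum.total(config.long_dr_min_len),
            "dr_max_len": r.dr_spectrum.max_length,
            "tms": r.tms, "nc": r.nc, "gc3": r.gc3,
            "nc_expected": expected_nc(r.gc3) if 0 < r.gc3 < 1 else np.nan,
            "gc_content": r.gc_content, "gc_skew": r.gc_skew, "at_skew": r.at_skew,
        })
    return pd.DataFrame(rows).sort_values("species").reset_index(drop=True)


def null_comparison_table(genomes: dict[str, MtGenome], records: list[SpeciesRecord],
                          config: RunConfig) -> pd.DataFrame:
    """Figure-3-style comparisons: native count vs null ensembles, Z-tests."""
    native = {r.species: r.dr_spectrum.total(config.dr_min_len) for r in records}
    rows = []
    jobs: list[tuple[str, str]] = [(s, sch) for s in sorted(genomes)
                                   for sch in config.null_schemes]
    if config.reference_species:
        jobs += [(config.reference_species, sch.value) for sch in RandomizationScheme
                 if sch.value not in config.null_schemes]
    for species, scheme in jobs:
        ens = build_null_ensemble(genomes[species], scheme, n=config.null_n,
                                  min_len=config.dr_min_len, seed=config.seed,
                                  include_overlapping=config.include_overlapping)
        z, p = ensemble_z_test(native[species], ens, sided="two")
        rows.append({
            "species": species, "scheme": scheme, "n": config.null_n,
            "native_total": native[species], "null_mean": ens.mean, "null_sd": ens.sd,
            "z": z, "p_two_sided": p,
        })
    columns = ["species", "scheme", "n", "native_total", "null_mean", "null_sd",
               "z", "p_two_sided"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows).sort_values(["species", "scheme"]).reset_index(drop=True)


def longevity_table(records: list[SpeciesRecord], tree, config: RunConfig) -> pd.DataFrame:
    """Residual -> PIC -> correlation chain plus subpopulation tests."""
    tree = prepare_tree(tree)
    sp = [r.species for r in records]
    lifespan = np.array([r.lifespan for r in records])
    mass = np.array([r.body_mass for r in records])
    rows = []
    for label, stat in (
        (f"dr_count_ge{config.long_dr_min_len}",
         np.array([r.dr_spectrum.total(config.long_dr_min_len) for r in records], float)),
        (f"dr_count_ge{config.dr_min_len}",
         np.array([r.dr_spectrum.total(config.dr_min_len) for r in records], float)),
        ("log_tms", np.array([np.log(r.tms) if r.tms and r.tms > 0 else np.nan
                              for r in records])),
    ):
        if np.isnan(stat).any():
            logger.warning("statistic %s has undefined values; skipped", label)
            continue
        rho, p, k = comparative.pic_partial_correlation(
            tree, dict(zip(sp, np.log(lifespan))), dict(zip(sp, stat)),
            controls=[dict(zip(sp, np.log(mass)))], resolve=False)
        rows.append({"analysis": "pic_partial_correlation", "statistic": label,
                     "percentile": np.nan, "estimate": rho, "p_value": p,
                     "detail": f"k={k} contrasts, control=log mass, through-origin"})
        for q in config.percentiles:
            rep = subpopulation_tests(lifespan, stat, percentile=q)
            for test, est, pv in (("t", rep.t_stat, rep.t_p),
                                  ("mwu", rep.mwu_stat, rep.mwu_p),
                                  ("ks", rep.ks_stat, rep.ks_p)):
                rows.append({"analysis": f"subpop_{test}", "statistic": label,
                             "percentile": q, "estimate": est, "p_value": pv,
                             "detail": f"n_short={rep.n_short}, n_long={rep.n_long}"})
    return pd.DataFrame(rows)


def scu_dr_table(records: list[SpeciesRecord], tree, config: RunConfig) -> pd.DataFrame:
    """Figure-5/6-style: N_c vs DR count (naive and PIC) and N_c vs GC3."""
    tree = prepare_tree(tree)
    sp = [r.species for r in records]
    nc = np.array([r.nc for r in records], float)
    gc3v = np.array([r.gc3 for r in records], float)
    total = np.array([r.dr_spectrum.total(config.dr_min_len) for r in records], float)
    from scipy import stats as _st

    rows = []
    rho_naive, p_naive = _st.pearsonr(nc, total)
    rows.append({"analysis": "nc_vs_dr_naive", "estimate": float(rho_naive),
                 "p_value": float(p_naive), "detail": f"n={len(nc)}"})
    controls = [dict(zip(sp, [r.gc_skew for r in records])),
                dict(zip(sp, [r.at_skew for r in records])),
                dict(zip(sp, [r.gc_content for r in records]))]
    rho_pic, p_pic, _ = comparative.pic_partial_correlation(
        tree, dict(zip(sp, nc)), dict(zip(sp, total)), controls=controls, resolve=False)
    rows.append({"analysis": "nc_vs_dr_partial_pic", "estimate": rho_pic,
                 "p_value": p_pic,
                 "detail": "controls: GC-skew, AT-skew, GC content; PIC through-origin"})
    rho_gc3, p_gc3 = _st.pearsonr(nc, gc3v)
    rows.append({"analysis": "nc_vs_gc3", "estimate": float(rho_gc3),
                 "p_value": float(p_gc3), "detail": f"n={len(nc)}"})
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig,
                      genomes: dict[str, MtGenome] | None = None,
                      traits: pd.DataFrame | None = None,
                      tree=None) -> ReportBundle:
    """Run every stage and (if ``config.out_dir``) write the TSV bundle.

    Inputs may be given in memory or loaded from the configured paths
    (a directory of ``.gb`` files, a traits TSV, a Newick tree).
    """
    if genomes is None:
        if not config.genome_dir:
            raise ValueError("no genomes given and no genome_dir configured")
        genomes = {}
        for path in sorted(Path(config.genome_dir).glob("*.gb")):
            g = genome_io.read_genbank(path)
            genomes[g.id] = g
    if traits is None:
        if not config.traits_path:
            raise ValueError("no traits given and no traits_path configured")
        traits = load_traits(config.traits_path)
    if tree is None:
        if not config.tree_path:
            raise ValueError("no tree given and no tree_path configured")
        tree = load_tree(config.tree_path)

    problems = _cross_reference(genomes, traits, tree)
    if problems:
        raise ValueError("cross-reference failures:\n  " + "\n  ".join(problems))

    records = build_records(genomes, traits, config)
    tables = {
        "species_summary": species_table(records, config),
        "null_comparison": null_comparison_table(genomes, records, config),
        "longevity_tests": longevity_table(records, tree, config),
        "scu_dr_correlation": scu_dr_table(records, tree, config),
    }
    metadata = {"config": asdict(config), "config_hash": config.hash(),
                "seed": config.seed, "n_species": len(records)}

    out_dir = None
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = f"# drscan run config_hash={config.hash()} seed={config.seed}\n"
        for name, df in tables.items():
            path = out_dir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
        (out_dir / "run_metadata.json").write_text(json.dumps(metadata, indent=1, sort_keys=True))
    return ReportBundle(tables=tables, metadata=metadata, out_dir=out_dir)
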