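from collections import Counter

import numpy as np
import pytest
from scipy import stats

from drscan._codes import get_code
from drscan.genome_io import Feature, MtGenome, non_dloop_arc
from drscan.randomize import (
    RandomizationError,
    RandomizationScheme,
    build_null_ensemble,
    randomize_genome,
)

VERT_MITO = get_code("vertebrate_mitochondrial")


def gene_composition(seq, feats, ftype):
    return [Counter(seq[f.start - 1 : f.end]) for f in feats if f.ftype == ftype]


def gene_sequences(seq, feats):
    return sorted(seq[f.start - 1 : f.end]
                  for f in feats if f.ftype in ("rRNA", "tRNA", "CDS"))


def cds_codon_multisets(seq, feats):
    out = []
    for f in feats:
        if f.ftype != "CDS":
            continue
        s = seq[f.start - 1 : f.end]
        from drscan._codes import reverse_complement
        if f.strand == "-":
            s = reverse_complement(s)
        rem = len(s) % 3
        out.append(Counter(s[i : i + 3] for i in range(0, len(s) - rem, 3)))
    return out


def translate_cds(seq, feats, code):
    out = []
    for f in feats:
        if f.ftype != "CDS":
            continue
        s = seq[f.start - 1 : f.end]
        from drscan._codes import reverse_complement
        if f.strand == "-":
            s = reverse_complement(s)
        rem = len(s) % 3
        body = s[: len(s) - (3 if rem == 0 else rem)]
        out.append(code.translate(body, first_is_start=True))
    return out


class TestConservationLedger:
    """Each scheme preserves exactly the attributes it declares."""

    def test_full_preserves_global_composition(self, small_genome, rng):
        arc, _ = non_dloop_arc(small_genome)
        out = randomize_genome(small_genome, "FULL", rng)
        assert len(out) == len(arc)
        assert Counter(out) == Counter(arc)
        assert out != arc  # astronomically unlikely to be identity

    def test_rgo_preserves_per_gene_sequences(self, small_genome, rng):
        arc, feats = non_dloop_arc(small_genome)
        out = randomize_genome(small_genome, "RGO", rng)
        assert len(out) == len(arc)
        assert Counter(out) == Counter(arc)
        # every gene sequence (plus attached spacer context) still occurs
        for f in feats:
            if f.ftype in ("rRNA", "tRNA", "CDS"):
                assert arc[f.start - 1 : f.end] in out

    @pytest.mark.parametrize("scheme,ftype", [
        ("RRNA_SHUFFLE", "rRNA"), ("TRNA_SHUFFLE", "tRNA"), ("PROTEIN_SHUFFLE", "CDS"),
    ])
    def test_class_shuffles_scope_and_composition(self, small_genome, rng, scheme, ftype):
        arc, feats = non_dloop_arc(small_genome)
        out = randomize_genome(small_genome, scheme, rng)
        assert len(out) == len(arc)
        assert gene_composition(out, feats, ftype) == gene_composition(arc, feats, ftype)
        # bases outside the target class untouched
        inside = np.zeros(len(arc), bool)
        for f in feats:
            if f.ftype == ftype:
                inside[f.start - 1 : f.end] = True
        for i in np.flatnonzero(~inside):
            assert out[i] == arc[i]

    def test_codon_shuffle_preserves_per_gene_codon_multisets(self, small_genome, rng):
        arc, feats = non_dloop_arc(small_genome)
        out = randomize_genome(small_genome, "CODON_SHUFFLE", rng)
        assert cds_codon_multisets(out, feats) == cds_codon_multisets(arc, feats)

    def test_uscu_preserves_amino_acid_sequences_exactly(self, small_genome, rng):
        arc, feats = non_dloop_arc(small_genome)
        out = randomize_genome(small_genome, "USCU", rng)
        assert translate_cds(out, feats, VERT_MITO) == translate_cds(arc, feats, VERT_MITO)
        # non-CDS bases untouched
        inside = np.zeros(len(arc), bool)
        for f in feats:
            if f.ftype == "CDS":
                inside[f.start - 1 : f.end] = True
        for i in np.flatnonzero(~inside):
            assert out[i] == arc[i]

    def test_nu_preserves_only_length(self, small_genome, rng):
        arc, _ = non_dloop_arc(small_genome)
        out = randomize_genome(small_genome, "NU", rng)
        assert len(out) == len(arc)
        assert set(out) <= set("ACGT")


class TestSchemeDistributions:
    def test_full_uniform_permutation_on_toy_string(self):
        # "AACG" has 4!/2! = 12 distinguishable arrangements
        g = MtGenome(id="toy", sequence="AACG", circular=False, features=[])
        tallies = Counter()
        for i in range(12000):
            tallies[randomize_genome(g, "FULL", np.random.default_rng(i))] += 1
        assert len(tallies) == 12
        chi2, p = stats.chisquare(list(tallies.values()))
        assert p > 0.001

    def test_nu_base_frequencies_near_quarter(self):
        g = MtGenome(id="nu", sequence="A" * 1000, circular=False, features=[])
        counts = Counter()
        n_reps = 100
        for i in range(n_reps):
            counts.update(randomize_genome(g, "NU", np.random.default_rng(i)))
        total = 1000 * n_reps
        se = np.sqrt(0.25 * 0.75 / total)
        for b in "ACGT":
            assert abs(counts[b] / total - 0.25) < 3 * se

    def test_uscu_equalizes_family_frequencies(self, rng):
        # a 300-codon Leu-rich gene; over 100 replicates each Leu codon
        # should be drawn with frequency 1/6 within binomial error
        body = "CTA" * 150 + "ATA" * 148  # Leu x150, Met(ATA) x148
        gene = "ATG" + body + "TAA"
        g = MtGenome(id="u", sequence=gene, circular=False,
                     features=[Feature("g", "CDS", 1, len(gene), "+")])
        leu_codons = Counter()
        for i in range(100):
            out = randomize_genome(g, "USCU", np.random.default_rng(i))
            for j in range(3, len(out) - 3, 3):
                codon = out[j : j + 3]
                if VERT_MITO.codon_to_aa.get(codon) == "L":
                    leu_codons[codon] += 1
        total = sum(leu_codons.values())
        assert total == 150 * 100
        p = 1 / 6
        se = np.sqrt(p * (1 - p) / total)
        for codon in VERT_MITO.aa_to_codons["L"]:
            assert abs(leu_codons[codon] / total - p) < 4 * se

    def test_uscu_balanced_mode_exactly_even_where_divisible(self):
        body = "CTA" * 120  # 120 Leu codons, 6-fold family -> 20 each
        gene = "ATG" + body + "TAA"
        g = MtGenome(id="b", sequence=gene, circular=False,
                     features=[Feature("g", "CDS", 1, len(gene), "+")])
        out = randomize_genome(g, "USCU", np.random.default_rng(5), balanced_uscu=True)
        tally = Counter(out[j : j + 3] for j in range(3, len(out) - 3, 3))
        assert all(tally[c] == 20 for c in VERT_MITO.aa_to_codons["L"])

    def test_uscu_translation_mismatch_names_gene_and_position(self):
        gene = "ATGCTATAA"  # Met-Leu-stop
        g = MtGenome(id="m", sequence=gene, circular=False,
                     features=[Feature("badgene", "CDS", 1, 9, "+",
                                       qualifiers={"translation": ["MK"]})])
        with pytest.raises(RandomizationError, match="badgene"):
            randomize_genome(g, "USCU", np.random.default_rng(0))

    def test_gene_scoped_scheme_requires_features(self):
        g = MtGenome(id="bare", sequence="ACGT" * 100, circular=False, features=[])
        with pytest.raises(RandomizationError):
            randomize_genome(g, "USCU", np.random.default_rng(0))


class TestNullEnsemble:
    def test_deterministic_under_seed(self, small_genome):
        a = build_null_ensemble(small_genome, "FULL", n=3, seed=99)
        b = build_null_ensemble(small_genome, "FULL", n=3, seed=99)
        assert np.array_equal(a.totals, b.totals)
        assert [s.as_dict() for s in a.spectra] == [s.as_dict() for s in b.spectra]

    def test_replicates_order_independent_prefix(self, small_genome):
        a = build_null_ensemble(small_genome, "FULL", n=4, seed=7)
        b = build_null_ensemble(small_genome, "FULL", n=2, seed=7)
        assert np.array_equal(a.totals[:2], b.totals)

    def test_needs_two_replicates(self, small_genome):
        with pytest.raises(ValueError):
            build_null_ensemble(small_genome, "FULL", n=1, seed=0)

    def test_full_null_reduces_counts_of_codon_biased_genome(self, small_genome):
        from drscan.dr_scan import dr_spectrum, find_direct_repeats
        from drscan.genome_io import non_dloop_sequence

        native = dr_spectrum(find_direct_repeats(non_dloop_sequence(small_genome), 5)).total()
        ens = build_null_ensemble(small_genome, "FULL", n=5, seed=3)
        assert ens.mean < native
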