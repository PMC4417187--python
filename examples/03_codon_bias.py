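"""Synonymous codon usage bias of a mitochondrial coding sequence.

Concatenates the 13 protein-coding genes (start/stop codons dropped),
computes Wright's effective number of codons N_c, the GC fraction at third
codon positions (GC3), the mutational-bias expectation N_c*(GC3), and the
strand-asymmetry skews. N_c below N_c* means codon usage is more biased
than base composition alone explains.
"""

from drscan import (
    GenomeSpec,
    codon_usage,
    concatenated_cds,
    effective_number_of_codons,
    expected_nc,
    gc3,
    generate_genome,
    non_dloop_sequence,
    skews,
)

genome = generate_genome(GenomeSpec(seed=7))  # moderate SCU bias by default
cds = concatenated_cds(genome, omit_terminal_codons=True)
table = codon_usage(cds)
nc = effective_number_of_codons(table)
s = gc3(cds)
sk = skews(non_dloop_sequence(genome))

print(f"concatenated CDS: {len(cds)} nt = {len(cds) // 3} codons over {len(cds.boundaries)} genes")
print(f"N_c           = {nc:.2f}   (20 = maximal bias, 60 = none for this code)")
print(f"GC3           = {s:.3f}")
print(f"N_c*(GC3)     = {expected_nc(s):.2f}   (expected from mutational bias alone)")
print(f"GC content    = {sk.gc_content:.3f}  GC-skew = {sk.gc_skew:+.3f}  AT-skew = {sk.at_skew:+.3f}")

print("\nLeucine codon frequencies (preferred codon dominates):")
for codon, freq in sorted(table.family_frequencies()["L"].items()):
    print(f"  {codon}: {freq:.3f}")
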