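"""Attribute repeat load to genome structure via selective randomization.

Compares the native direct-repeat count of a codon-biased synthetic genome
with null ensembles that each destroy one class of structure. A large drop
under USCU (equal-frequency synonymous re-encoding, protein unchanged) or
NU (uniform random bases) shows that codon-usage bias and base composition
are the main drivers of the repeat load.
"""

from drscan import GenomeSpec, build_null_ensemble, ensemble_z_test, generate_genome, scan_genome

genome = generate_genome(GenomeSpec(length=6000, dloop_length=400,
                                    rrna_lengths=(400, 600), seed=11))
_, spectrum = scan_genome(genome, min_len=5)
native = spectrum.total()
print(f"native non-D-loop DR count (>=5 bp): {native}")
print(f"{'scheme':<14}{'null mean':>10}{'null sd':>9}{'z':>8}{'p(two)':>10}")
for scheme in ("RGO", "FULL", "CODON_SHUFFLE", "USCU", "NU"):
    ens = build_null_ensemble(genome, scheme, n=50, min_len=5, seed=1)
    z, p = ensemble_z_test(native, ens, sided="two")
    print(f"{scheme:<14}{ens.mean:>10.1f}{ens.sd:>9.1f}{z:>8.2f}{p:>10.2g}")
print("Gene-order shuffling (RGO) barely moves the count; codon-usage and")
print("composition randomization (USCU, NU) remove the most repeats.")
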