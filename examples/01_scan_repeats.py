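"""Enumerate direct repeats in a synthetic mitochondrial genome.

Builds a ~16.5 kb annotated genome with mammalian-like composition, excises
the D-loop, enumerates every maximal direct-repeat pair of length >= 5 bp,
and scores the long-repeat deletion propensity (TMS). The per-size spectrum
should fall off roughly exponentially, like real mtDNA.
"""

from drscan import (
    GenomeSpec,
    MutagenicityModel,
    dr_spectrum,
    find_direct_repeats,
    generate_genome,
    non_dloop_sequence,
    total_mutagenicity_score,
)

genome = generate_genome(GenomeSpec(seed=42))
arc = non_dloop_sequence(genome)
print(f"genome {genome.id}: {len(genome)} bp, non-D-loop arc {len(arc)} bp")

pairs = find_direct_repeats(arc, min_len=5)
spectrum = dr_spectrum(pairs, min_len=5)
print(f"total DR pairs (>=5 bp): {spectrum.total()}")
print("size spectrum (length: count):")
for length, count in spectrum.as_dict().items():
    print(f"  {length:2d}: {count}")
print(f"longest repeat: {spectrum.max_length} bp")

for name in ("lambda_phage", "yeast"):
    model = MutagenicityModel.bundled(name)
    tms = total_mutagenicity_score(spectrum, model)
    print(f"TMS ({name} calibration, repeats >= {model.min_len} bp): {tms:.3g}")
print("Higher TMS = more weight on long, deletion-prone repeats.")
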