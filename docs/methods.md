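# Methods

This note documents the models, statistics and numerical choices behind
`drscan`, and what the synthetic test bed does and does not establish.

## Direct-repeat enumeration

A direct repeat (DR) is a pair of identical same-strand subsequences at two
positions of one DNA molecule. The counting unit throughout is the
**maximal pair** `(pos1, pos2, L)`: extending both copies by one base on
either side breaks the identity or hits a boundary. A motif occurring *k*
times contributes *k(k−1)/2* candidate pairs, each assessed for maximality
on its own; a maximal pair is counted once, at its maximal length, and its
internal sub-repeats are not counted again. This makes per-size counts
well defined (the "longest repeat" of a genome is a single number) and
produces the smooth exponential decay of counts with repeat size seen in
real mtDNA. Pairs whose copies overlap (`pos2 − pos1 < L`) are included by
default and flagged; `include_overlapping=False` drops them.

The default minimum length is 5 bp: shorter duplexes mostly have positive
hybridization free energy and are not credible misalignment substrates.
The D-loop (control region) is excised before scanning — its tandem
repeats belong to a different mutational regime, and deletions removing
the replication origin cannot clonally expand — and the remaining arc of
the circular molecule is treated as strictly linear (no pairs straddle the
excision breakpoint).

The production scanner seeds on shared k-mers (k = minimum length),
keeps only left-maximal seed pairs (the bases before the two k-mer copies
differ or hit the sequence start, so each maximal pair has exactly one
seed) and extends each seed rightward to its maximal length. It is
validated bit-exactly against an independent brute-force enumeration
(runs of positional equality at every fixed offset) on hundreds of random
sequences; ambiguity codes can be masked, in which case a masked base
never matches anything.

## Mutagenicity score (TMS)

The total mutagenicity score of a spectrum is `Σ_L count(L) · w(L)` over
scored lengths (default L ≥ 10). Two weight tables ship as editable TSVs,
`tms_lambda_phage.tsv` and `tms_yeast.tsv`. Both are **reconstructed**
monotone log-linear calibrations (deletion propensity rising ~2× and
~1.5× per bp respectively) in the spirit of deletion-frequency assays on
engineered phage λ DNA and yeast mtDNA; the primary calibration data are
not distributed with this package. Weights are relative, so only ratios
across lengths matter; users with access to assay data can drop in their
own table. Lengths beyond a table's support are extrapolated with the
fitted log-linear trend recorded in the table header (a warning is
logged).

## Randomization null models

Eight schemes each destroy one class of structure in the non-D-loop arc
while preserving the rest (length is always preserved):

| scheme | randomizes | preserves |
|---|---|---|
| RGO | gene order (whole blocks, trailing spacers attached) | every per-gene sequence |
| RRNA/TRNA/PROTEIN_SHUFFLE | nucleotide order within each gene of one class | per-gene base composition; everything outside the class |
| FULL | nucleotide order genome-wide | global base composition |
| CODON_SHUFFLE | codon order within each CDS | per-gene codon multiset |
| USCU | synonymous codon choice (uniform within family) | the amino-acid sequence exactly |
| NU | everything (i.i.d. uniform bases) | length only |

USCU keeps each gene's initiation and (possibly incomplete) stop codon in
place, translates internal codons under the vertebrate mitochondrial code
(validating against the annotated protein when a `/translation` qualifier
is present and failing loudly on mismatch), and re-draws each codon
i.i.d. uniformly over its synonymous family. A `balanced` variant assigns
a maximally even multiset per family and permutes it, for sensitivity
analysis; i.i.d. is the default because it is the plainer reading of
"synonymous codons used with equal frequency".

Ensembles derive per-replicate generators from `(seed, scheme, replicate)`
counters, so results are reproducible and independent of evaluation
order. The ensemble Z-test compares a native count against the ensemble
mean and standard deviation (ddof = 1).

## Codon-usage bias

Wright's effective number of codons: per synonymous family with *n*
counted codons and frequencies *p_i*, homozygosity is
`F̂ = (nΣp_i² − 1)/(n − 1)`; N_c sums `N_k / mean(F̂)` over degeneracy
classes *k*, plus one per single-codon family. N_c = 20 at complete bias;
finite samples can push the raw sum past the code's sense-codon count
(61 standard, 60 vertebrate mitochondrial), so the result is capped
there. Families with n < 2, or with a non-positive finite-sample F̂, are
imputed at their class mean; an empty 3-fold class falls back to the
average of the 2- and 4-fold class means, any other empty class to 1/k
(both logged). `codonw_compat=True` splits six-fold families into their
2+4 halves by the first two codon positions, matching the degeneracy
classes of the CodonW program behind published mtDNA N_c values (42.6–42.64
for human); the default uses true code families. The implementation is
checked to 1e-9 against an independent straight-from-the-formula oracle.

The mutational-bias expectation is `N_c*(s) = 2 + s + 29/(s² + (1−s)²)`
for GC3 = s ∈ (0,1). Strand asymmetry uses GC-skew `(G−C)/(G+C)` and
AT-skew `(A−T)/(A+T)`; each skew raises an error only when its own
denominator is zero.

CDS concatenation drops each gene's first codon and its stop; a trailing
1–2 nt remainder is treated as an annotated incomplete stop (completed by
polyadenylation, routine in mammalian mtDNA) and dropped with it.
Nonstandard initiation codons (ATA, ATT, …) are accepted and read as Met
at position 1 only. Overlapping CDS annotations are concatenated
independently (overlapped bases duplicated) and flagged in the log.

## Phylogenetic longevity statistics

Felsenstein's independent contrasts are computed by the standard pruning
recursion: contrast `(x₁ − x₂)/√(v₁ + v₂)` at each internal node,
precision-weighted ancestral value, parent branch lengthened by
`v₁v₂/(v₁+v₂)`. Polytomies are resolved arbitrarily and zero/missing
branches set to 1e-8 × tree height. The implementation matches `ape::pic`
on random fixtures.

The headline chain — "is the repeat statistic associated with lifespan
after controlling body mass and shared ancestry?" — is
`pic_partial_correlation`: contrasts of the raw traits and of every
control are taken first; the x- and y-contrasts are residualized on the
control contrasts by through-origin least squares; the residual contrasts
are correlated through the origin with k − c − 1 degrees of freedom.
This ordering was chosen after measuring both candidates under a
128-leaf Brownian null: leaf-level OLS residualization before contrasts
(the ordering sometimes seen in the comparative literature, available as
`order="leaf"`) rejects a true null ≈13% of the time at the 5% level,
because leaf-level residuals are no longer tree-independent; the
contrast-level ordering rejects at 4.9%. The same chain recovers a true
cross-trait Brownian correlation of 0.8 with bias < 0.01 on that tree.

Known limitation: when a trait carries substantial non-heritable noise
(e.g. measurement error in lifespan records, or the sampling noise of
repeat counts in very small genomes), standardized contrasts at short
branches become heavy-tailed and the chain turns anticonservative. Under
the synthetic study conditions used in the tests (12-leaf clades,
Brownian codon-bias drift) the end-to-end false-positive rate measured
4–7%; with strong artificial leaf noise it rises. Interpret borderline
p-values accordingly on real data.

Supporting tests: lifespan-percentile subpopulation comparisons (two
sample t, Mann–Whitney U — exact when both groups ≤ 20 and tie-free,
asymptotic with tie correction otherwise — and two-sample
Kolmogorov–Smirnov), with ties at the threshold assigned to the
short-lived group; pairwise Mann–Whitney matrices across taxonomic
orders with raw p-values (no multiplicity correction, by design — the
analysis convention is a plain p ≤ 0.05); and the upper "constraint
line", an ordinary least-squares fit through a chosen handful of support
species with optional exclusions, flagging every point above the line.
Lifespan, body mass and TMS are log-transformed (natural log) before
residualization; DR counts are left untransformed.

## Synthetic data generator

`GenomeSpec` builds a circular annotated genome: one D-loop (default
1.1 kb of the 16.5 kb total), 2 rRNA, 22 tRNA and 13 protein-coding
genes separated by short spacers, one CDS (ND6-like) and every third
tRNA on the minus strand. Non-coding and RNA-gene bases are i.i.d. draws
from the heavy-strand base probabilities (default (A,C,G,T) =
(0.31, 0.31, 0.13, 0.25), the strongly C-skewed composition typical of
mammalian heavy strands); skew is therefore imposed on the heavy strand
only. CDS bodies draw amino acids from a bundled composition table
(Leu/Ile/Thr-heavy, as in mtDNA-encoded membrane proteins) and codons
from a per-family distribution controlled by one concentration parameter
c ∈ (0,1]: the preferred (A-ending) codon gets probability
`1/k + (1−c)(1−1/k)`. c = 1 gives uniform synonymous usage (N_c near the
60 cap); c → 0 gives single-codon usage (N_c → 20). The default c = 0.5
yields a moderate bias (N_c ≈ 38–40 on 16.5 kb genomes) comparable to
mammalian mtDNA. Genes start with ATG/ATA and end with TAA; generated
genomes always pass annotation validation and frame checks.

`CladeSpec` grows a pure-birth (Yule) tree — hand-simulated with
exponential waiting times plus one extra waiting time after the last
birth, so terminal branches are strictly positive — and evolves
log-lifespan and log-body-mass by correlated Brownian motion (default
correlation 0.68, the mammalian lifespan–mass value; root at 20 y and
5 kg). Codon-bias concentration can drift on the tree (`scu_drift_var`),
giving heritable repeat-count variation. A coupling coefficient adds
β × (standardized DR count) to leaf log-lifespan, planting a known
repeat→longevity effect; β = 0 is the null world. Optional i.i.d. leaf
noise on log-lifespan models noisy lifespan records (default 0). Ground
truth is returned alongside the data.

What passing tests on this bed do **not** show about real data: synthetic
rRNA/tRNA genes have no internal structure (so gene-class shuffles are
near-neutral here, unlike for real structured RNA genes); proteins are
i.i.d. amino-acid strings (no repeated domains or conserved motifs);
genomes at the leaves are generated independently rather than by descent,
so sequence-level phylogenetic signal in repeat counts comes only through
the drifting bias parameter; and the mutational process that creates real
composition bias is not simulated, only its stationary composition.

## Numerical and problem-size choices

Tests and the acceptance script run desk-scale: scanner exactness on 200
random sequences ≤ 2 kb at three minimum lengths; null-model ensembles of
20–50 replicates on 4–6 kb genomes; PIC calibration with 1000 Brownian
replicates on one 128-leaf tree; end-to-end clade nulls at 12 leaves and
3.5 kb genomes. These sizes keep the full suite around a minute while
leaving every statistical check adequately powered; all generators and
ensembles are seeded, and reports embed the seed and a configuration
hash so reruns are byte-identical.
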