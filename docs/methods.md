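# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinate and format conventions

All in-memory coordinates are 0-based half-open; files keep their own
conventions (GFF3 and cytosine reports are 1-based) and the conversion
lives exclusively in `formats_io`. Nucleotide input is upper-cased
with U mapped to T on read, because the shipped cis-element catalog
contains one RNA-alphabet consensus (`AMNAUGGC`). Tabular output is
TSV, UTF-8, with `.` for missing values.

## Family identification

Each family is a log-odds profile built from an ungapped seed
alignment: `score(col, aa) = log2((count + pc·bg(aa)) / (n + pc) /
bg(aa))` with pseudocount `pc = 1`, Swiss-Prot-style background
frequencies, and columns that are more than 50% gaps dropped. A full
profile HMM would add transition probabilities but not change the
scientific contract — threshold-gated family membership — so the PSSM
is the deliberate simplification.

Candidate membership is the best **local** profile-to-sequence
alignment score (Smith–Waterman over profile columns, affine gaps,
defaults −11 open / −1 extend in bit units). Significance: for every
(protein, profile) pair the protein is shuffled `n_decoys = 200` times
(composition- and length-preserving), the decoy scores are fitted to a
Gumbel (right-skewed extreme-value law, the standard null for optimal
local alignment scores), and `E = database_size × P(score ≥ s)`.
Membership requires E ≤ 0.01; a protein passing for several families
goes to the smallest E. Fewer than 50 decoys makes the Gumbel location
and scale estimates unstable, hence the hard floor.

Splice variants collapse to one primary transcript per locus (longest
CDS, ties to the lexicographically smallest transcript id). Names are
assigned per family in ascending order of (chromosome in natural sort
order, start): `Si<FAMILY>-NN`, with the small-HSP family written
`SisHSP-NN`.

## Protein properties

Molecular weight sums average residue masses plus one water (18.02 Da);
`X` is rejected unless the caller opts into a mean-residue-mass
substitution. The isoelectric point solves net charge(pH) = 0 by
bisection on [0, 14] to |charge| < 1e-4, with
Henderson–Hasselbalch terms for the termini and K/R/H (basic) and
D/E/C/Y (acidic). The EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8,
R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) is the default; the
Bjellqvist set is selectable. Note the |charge| < 1e-4 stopping band
can be ~0.01 pH wide for weakly ionizing peptides; two conforming
solvers may differ at that scale.

## Phylogenetics

Pairwise global alignment is Needleman–Wunsch with BLOSUM62 and affine
gaps (−10 open, −0.5 extend; a gap of length k costs open + (k−1)·
extend). Identity is matches over alignment columns. The multiple
aligner is progressive: 3-mer guide distances (1 − shared/min), an NJ
join order on those distances, and profile–profile global alignment of
the groups using expected-column BLOSUM scores over residue
frequencies. This is a deliberate, deterministic simplification of the
usual progressive aligners; it has no iterative refinement.

Distances from an MSA use pairwise deletion of gap columns; models are
p-distance (default) and Poisson (−ln(1−p), undefined at p = 1).
Neighbor-Joining is the Saitou–Nei algorithm: join the pair minimizing
`Q(i,j) = (r−2)d(i,j) − Σd(i,·) − Σd(j,·)`, standard limb-length and
distance-reduction formulas, ties broken on the smallest node-creation
index pair. NJ is consistent on additive matrices, which the tests
exploit: trees generated with random positive branch lengths are
recovered to 1e-9 in the induced patristic matrix. Negative limb
estimates are clamped to zero and counted on `tree.clamped_edges`.

Bootstrap: columns resampled with replacement; support of an internal
bipartition of the reference tree is the percentage of replicate trees
containing it (bipartitions encoded leaf-label-invariantly via
dendropy). 1000 replicates is the conventional setting and the default
of `bootstrap_support`; the end-to-end pipeline default is 100, a
desk-scale choice for its many family trees, configurable upward.

## Duplication, Ka/Ks and dating

Candidate paralogs are within-family pairs with global identity ≥ 0.8.
A pair is **tandem** iff same chromosome, at most 10 intervening
annotated genes, and inner gap ≤ 150 kb — thresholds chosen to cover
the 0.4–101.4 kb tandem separations this kind of survey observes, with
margin; both configurable. **Segmental** pairs must sit inside a
collinear block: all genome-wide high-identity pairs (family plus
background) are anchors; per chromosome pair, the longest strictly
monotone chain of anchor ranks (either orientation; rank gaps ≤ 25) is
found by DP, and a non-tandem pair inside a chain of ≥ 3 anchors is
segmental.

Ka/Ks is Nei–Gojobori (1986) with Jukes–Cantor correction. Site
counts: each codon position contributes (#synonymous one-step changes)
/(#possible changes), where changes creating stop codons are excluded
from both counts; S and N are averaged over the two sequences.
Observed differences: codons differing at k positions average over the
k! single-step pathways, excluding pathways through stop codons and
falling back to uniform weights if every pathway is blocked (NG86
variants differ exactly here, hence the explicit statement). Gapped
codon columns are excluded. pS or pN ≥ 0.75 is a saturation error.
Back-translation maps an aligned protein pair onto its CDS pair codon
by codon ('---' for gaps, terminal stops trimmed), refusing any
translation mismatch. Divergence time is T = Ks/(2λ)/10⁶ Mya with
λ = 6.5 × 10⁻⁹ synonymous substitutions per site per year.

## Orthology and synteny

Orthologs are reciprocal best hits on global-alignment identity with
an 80% floor ("80% homology" is not operationally defined in surveys
of this kind; identity is the chosen reading, configurable).
Best-hit ties break lexicographically. The synteny summary counts, per
comparison genome, focal family genes with an ortholog; per-genome
percentages are taken over the genes orthologous *anywhere* (that
denominator is the one that reproduces the usual printed arithmetic),
and the overall percentage over the whole family.

## Promoter cis-elements

Promoters are the 2 kb upstream of the gene span, strand-aware,
truncated (and flagged) at chromosome edges. The catalog ships as TSV
(name, IUPAC consensus, function note). Scanning tests every position
on both strands (minus-strand hits are windows whose reverse complement
satisfies the consensus, positions still promoter-forward); overlaps
are all reported; a subject N matches only a consensus N. Presence is
binarized per gene for the family-unique-element report.

## Expression and qPCR

RPKM = 10⁹·C/(N·L). 2^−ΔΔCt aggregation order: technical replicates →
biological replicate means → group mean Ct; ΔCt against the reference
gene (*Act2*) within the same (cultivar, tissue, condition, timepoint)
group; ΔΔCt against the control condition of the same cultivar, tissue
and timepoint. PCR efficiency is 10^(−1/slope) − 1 for a negative
dilution-series slope. Heat-map matrices are log2(x+1) for expression
and log10(Ct) for Ct mode (base-10 chosen and documented; the
convention is ambiguous in the literature).

## Methylation

Context is read strand-aware from the genome: CpG if the next base
(5'→3' on the cytosine's strand) is G; CHG for C-H-G (H ∈ {A,C,T});
else CHH; cytosines too close to a contig end for a full trinucleotide
are CHH with a flag. Gene-body is [start, end); the TSS region is the
same 2-kb upstream window as the promoter (the width is otherwise
unspecified in the surveys this mirrors). A cytosine is covered iff
total count ≥ 5 and methylated iff additionally the methylated
fraction is ≥ 0.5 — the published quantity is a raw count without a
stated rule, so the rule is explicit and configurable. Cytosines in
overlapping regions count in every region they fall in. The cultivar
comparison reports per-gene counts, S − T differences, and totals per
region × context.

## The synthetic-data generator

What it emulates, and with which defaults:

- **Families**: 20/9/27/20/37 members (113 total) across 9 chromosomes
  of 500 kb, plus 500 background genes. Each family has an 80-residue
  consensus domain; members and the 8-sequence seed alignments carry
  10% per-site substitutions of it. Flanks and background proteins are
  random with Swiss-Prot-like composition, so family signal is purely
  positional.
- **Gene models**: 1–4 exons (introns 80–300 bp), strand random,
  intergenic gaps 2.5–4.5 kb (promoters stay intergenic); designated
  loci carry 2 or 3 splice variants built as codon-prefix truncations.
- **Duplicates**: 4 tandem pairs (separations pinned to 0.4 kb and
  101.4 kb at the extremes, log-uniform between) and 4 segmental pairs
  embedded in duplicated blocks of 5 collinear background anchors on
  different chromosomes (every other block reversed in orientation).
  Partner CDS evolve by accept/reject single-nucleotide proposals:
  synonymous always accepted, nonsynonymous with probability ω (default
  0.1), stops never, until the synonymous difference proportion reaches
  the value whose JC correction equals the target Ks (cycled over
  0.1/0.2/0.3/0.4). Truth is defined by exhaustive recount of the
  realized pair, not by the target — a simple, auditable alternative to
  a codon-model CTMC.
- **Comparison genomes**: four proteomes holding orthologs of a
  staggered 86-gene union (84/76/65/47 genes), evolved at Ks 0.234/
  0.260/0.481/0.741 so that T = Ks/2λ lands at ~18/20/37/57 Mya, with ω
  0.19/0.17/0.09/0.06 keeping protein identity above the RBH cutoff.
  Recent duplicate partners are excluded from the union because RBH is
  inherently ambiguous between near-identical twins.
- **Expression**: negative-binomial counts (dispersion 0.1) with mean ∝
  gene length × library size × 2^effect × a lognormal per-gene
  baseline; default design: four tissue libraries plus a drought/
  control pair, with +2/+3/+5 log2 drought effects on the first three
  members of every family. qPCR Ct tables: 3 technical × 2 biological
  replicates, Gaussian technical noise (sd 0.15) and a per-RNA-prep
  shift (sd 0.3) shared by all genes of the sample — shared, because
  that is what reference-gene normalization removes; per-gene
  biological noise would put ~0.4 log2 units of irreducible error on
  every ΔΔCt estimate.
- **Methylation**: per-cultivar, per-region, per-context Bernoulli
  rates (tolerant gene-body CpG/CHG/CHH 0.55/0.35/0.10, susceptible
  0.75/0.50/0.16; TSS lower), coverage Poisson(10). The magnitudes are
  placeholders — there is no public dataset to calibrate against — but
  they encode the qualitative claims under test: CpG > CHG > CHH,
  gene body > TSS, tolerant < susceptible. Cytosine reports cover the
  family gene bodies and TSS windows (the genome-wide methylome is
  outside the profiler's scope, and full-genome reports would be ~50×
  larger with no additional testable signal).

What it does **not** emulate: read-level data (no FASTQ, alignment or
sequencing-error model), UTRs and non-coding transcripts, genome
repeat structure, correlated methylation along the chromosome, and
expression covariance between genes. Passing tests therefore show the
*operations* are correct on data with known truth — not that the
statistical power or error rates would transfer to a real genome.

Fixed seed ⇒ byte-identical outputs; every stage draws from its own
`SeedSequence([seed, stage])` stream.

## Runtime scale choices

The default test/acceptance problem sizes are the generator defaults
(113 + 500 genes, 200 decoys per protein, 1000 bootstrap replicates on
small alignments, 100 replicates in the pipeline, 50 evolution
replicates per Ks setting at 300 codons). These keep the full suite in
the low minutes on one CPU while leaving every statistical check
well-powered. The two alignment DP kernels are numba-compiled;
everything else is numpy/pandas.

## Known limitations

- The PSSM scan has no model of repeated or split domains; a protein
  with two domain copies reports the best-scoring span only.
- Progressive MSA quality degrades for families with long indels; the
  NG86 estimator saturates (by design, with an error) near pS = 0.75.
- RBH orthology cannot separate recent paralogs; the generator sidesteps
  this deliberately rather than resolving it.
- The segmental-duplication chainer works on gene ranks, not base-pair
  collinearity, and does not attempt whole-genome self-synteny
  discovery.
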