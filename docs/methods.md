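# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind each stage, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Synthetic gene family (module `simulate`)

The generator plants a multi-copy AMP gene family with complete ground
truth into random background sequence (i.i.d. uniform A/C/G/T — a neutral
decoy for the miner).

**Ancestral peptide.** A designed 42-residue mature peptide with the
family's canonical architecture: eight cysteines (the CSαβ disulfide
array), a C-terminal arginine marking the precursor cleavage point, and a
residue composition giving a weakly cationic peptide (pI ≈ 7.7, charge
≈ +1.6 at pH 7.4), matching the narrow pI 7–8 / charge −2…+4 window
characteristic of conventional members of this family. The CDS is a fixed
deterministic back-translation.

**Substitution process.** Mutations are proposed per nucleotide site at a
given rate and filtered by a per-codon selection coefficient ω:
synonymous candidates are accepted with probability min(1, 1/ω),
nonsynonymous with min(1, ω); candidates creating a STOP are rejected
(pseudogene STOPs are planted explicitly); ω = 0 codons (the 8 cysteines
and the terminal Arg) never change. The default ω vector additionally has
eight purifying sites (ω = 0.05) and three diversifying sites (ω = 5) —
the per-site selection structure the counting test is asked to recover.

**Family structure.** Defaults: 16 individuals; 16 ancestral genes built
from the base CDS at divergence-proposal rate 0.12; per-gene presence
probability 0.70; per-lineage substitution rate 0.0075/site. These values
were fixed once so the default family reproduces the observed repertoire
structure — a mean of ~11 distinct variants per individual of which ~6 are
private — and are not adjusted per run. Class labels are drawn per copy:
pseudogene 0.075 (an in-frame STOP planted in the middle half of the CDS),
Cys1/Cys5-loss 0.15 (both codons switched to serine by a single-nucleotide
change), conventional otherwise. Copies land on either strand with
probability 0.5, each on its own contig by default (a `tandem_fraction`
knob exists because the real tandem-vs-dispersed architecture is unknown).

**Promoters, expression, edits.** Each copy carries a 500-bp upstream
promoter with the configured ordered motifs planted at nearly fixed
offsets (jitter ±2 bp; defaults are two exact 10-mers). Expression flags
are drawn at probability 0.65 (mirroring the 7-of-11 expressed-copies
situation in the motivating data); transcripts are the sense exon-3
sequence with optional per-position substitution edits whose positions are
recorded in the truth table. Reads are error-free exact substrings at a
target mean depth.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and quality scores, diploidy
and phasing, recombination, indel variation inside the family, intron
evolution (exon 3 is planted intronless by default; a GT–AG scan utility
supports the optional intron mode), assembly fragmentation and collapsed
haplotypes, and transcript abundance (expression is binary).

## Mining (module `mine`)

Six-frame translated Smith–Waterman via `Bio.Align.PairwiseAligner` with
BLOSUM62; the matrix's `*` column (score −4 against everything) lets
pseudogenised copies with in-frame STOPs still be found. Gap costs are
open 11 / extend 1 in biopython's convention (a gap of length L costs
11 + (L−1)); this differs from BLAST's 11 + L by one unit per gap and has
no effect at the identity levels involved. A raw score threshold
(default 60) replaces E-values — Karlin–Altschul calibration is
deliberately omitted for these desk-scale assemblies, and the threshold
was validated on synthetic decoys (zero false loci in 50-seed trials,
where a random 2.5-kb contig never reaches score 60 against a 42-aa
query). An identity ≥ 40% filter to the query stands in for the manual
curation step of the original protocol. Same-frame overlapping hits merge
to their union; across frames the best score wins. Hits are extended to
the full query span on the codon lattice, so a copy whose terminal residue
mutated is still recovered at full planted length. Multiple copies per
frame are found by iterated best-hit extraction with `*` masking.

## Cataloguing (module `catalog`)

*Dereplication* merges exactly identical CDSs (carrier union, ids by
length-then-lexicographic order). *Classification* tests the STOP rule
first — a STOP-bearing cysteine-loss sequence is a pseudogene — then
aligns the translated peptide to the reference mature peptide (global,
end gaps free) and reads the occupancy of the 8 reference cysteine
columns: 8/8 conventional, exactly {Cys1, Cys5} missing → pseudomyticin,
anything else → atypical (a fourth class added because the three published
labels do not cover all cysteine patterns; it is counted separately).

*Family alignment* is progressive: UPGMA guide tree on pairwise NW
p-distances, profile–profile Gotoh merges with match 2 / mismatch −1 /
gap open −5 / extend −1. CDSs are aligned at the peptide level and
expanded back to codons, so gaps always come in multiples of three. Input
order is canonicalised, making the alignment deterministic.

*Clustering* is greedy-incremental at a pairwise-identity floor (default
0.95): variants visited by (length desc, lexicographic); each joins the
**best**-identity existing representative above the floor (best-assignment
rather than first-above-threshold: order-stable and reproducible), else
founds a cluster. Identity = identical columns / global-alignment length
with terminal gaps excluded — the closest deterministic reading of the
published CD-HIT settings, though not claimed identical to CD-HIT's
denominator. Under the conditions the equality is claimed for (inter-gene
divergence > 10%, within-gene variation < 3%; see
`simulate.clustering_scenario_params`) the cluster count equals the
planted family count; with the default generator's class planting the
within-gene radius can exceed 5% and clusters may split — a behaviour
real CD-HIT shares.

*Consensus* is per-codon-column strict plurality over the cluster members;
2–2 and 1–1–1–1 ties both yield the ambiguous codon `NNN` (residue `X`);
all-gap codon columns are dropped; STOP consensus codons translate to `*`.

*PAV*: boolean variant × individual and cluster × individual matrices
(cluster presence = union of member presence), rows sorted by descending
carrier frequency; statistics include per-individual means, private-variant
counts and universal-cluster counts.

## Biophysics (module `biophys`)

Charge model: Q(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic
1/(1+10^(pKa−pH)), basic = {N-terminus, K, R, H}, acidic = {C-terminus,
D, E, C, Y}. Cysteines are treated as free thiols — the convention of
generic pI calculators — although mature family members are
disulfide-bonded; this is exposed as a caveat rather than a switch because
every shipped pKa table includes C. Q is strictly decreasing in pH, so the
pI is found by sign bisection to a 1e−6 pH bracket, which also drives
|Q(pI)| below the 1e−3 tolerance even where the titration curve is flat (a
bare |Q| < tol stop can halt ~0.03 pH units off). Default pKa set is
IPC_protein, with IPC_peptide selectable; reproductions of published pI
ranges therefore carry a ±0.3 tolerance for pKa-set drift. Sliding-window
pI uses 15-residue windows with free termini (the simplest reading of a
windowed-pI profile; excluding termini is available as an option). `X`
residues contribute no charge and 110 Da. Mature boundaries come from a
global end-gap-free alignment of the precursor to the reference mature
peptide; the C-terminal boundary is taken from the reference's terminal
Arg column even when the aligned residue is not Arg.

## Trees and selection (module `evolve`)

Distances are Jukes–Cantor with pairwise deletion of gap columns;
p ≥ 0.75 is flagged saturated and capped at 5 substitutions/site for tree
building. The tree is Saitou–Nei neighbor joining with deterministic
tie-breaks (lowest taxon-name pair) and negative branch estimates clamped
to zero. A Bayesian MCMC tree was deliberately replaced by JC + NJ: the
tree is descriptive and feeds the counting test, which needs a
deterministic desk-scale topology; the substitution model stays JC because
that model was the selected best fit in the motivating analysis.

The per-site test is a counting (SLAC-style) test. Nei–Gojobori fractional
site counts N, S per codon exclude STOP-creating mutations from the
per-position denominator; path counts between two codons average the
synonymous/nonsynonymous steps over all minimal single-nucleotide paths,
excluding paths through STOPs (if every path is blocked, the raw
difference count is used, all nonsynonymous). Substitution events come
from two-pass Fitch parsimony per nucleotide site on an arbitrary rooting,
with up-pass ties resolved toward the parent state; branch events are the
codon differences between reconstructed states converted through the path
counts. Per column, q = N/(N+S) from the column's observed codons, and the
rounded observed nonsynonymous count out of the rounded total is tested
two-tailed against Binomial(k, q) with p = min(1, 2·min(tails)) — simple
and conservative. Calls at p < 0.1 (the published threshold): positive if
the observed fraction exceeds q, negative if below. Gapped or ambiguous
codons are ignored column-wise.

The recovery scenario (60 sequences down a balanced binary tree) uses a
per-branch rate of 0.1 substitution proposals per site, set by pilot power
analysis so purifying columns accumulate the ≥3 synonymous events the
binomial needs at p < 0.1; at that depth the test recovers ≥2/3 planted
diversifying and ≥6/8 planted purifying sites while keeping the
called-site fraction ≤ 0.15 under neutrality (ω = 1, 50 seeds, measured
mean ≈ 0.06). Parsimony undercounts on saturated columns, which mainly
costs power at ω > 1 sites — the known bias of counting methods.

## Promoter motifs (module `promoter`)

Discovery is expectation–maximisation under a ZOOPS model (zero or one
site per sequence) with a 0-order background estimated from the input,
pseudocount 0.01, convergence at ΔlogL < 1e−4 or 200 iterations, seeded
from the most frequent w-mers (three seeds per width, best final
likelihood wins; the procedure involves no random draws, so a fixed seed —
indeed any seed — gives identical PWMs). Width is chosen on the coarse
grid {6, 8, 10, 15, 20, 25, 30} by the criterion
(IC/col − 1.0) × width × expected sites: the subtraction removes the
≈1 bit/column EM extracts from pure background, which makes the criterion
peak at the true width instead of degenerating to the shortest (highest
IC/col) or widest (highest total IC) candidate. After each motif, maximum
a posteriori sites are masked with `N`.

Match significance uses the exact distribution of the integer-scaled
(×1000) log-odds score of a background window, built by dynamic-programming
convolution of column score distributions; the best-hit p-value over L−w+1
positions is 1−(1−p_pos)^(L−w+1), and m motifs combine by
P = x·Σ_{k<m}(−ln x)^k/k! with x the product of per-motif p-values.

Reported motifs must pass a three-part gate: combined match p-value across
the input promoter set < 1e−15 (the published gate value), information
content ≥ 1.2 bits/column, and expected sites in ≥ 50% of sequences. The
IC floor was calibrated on null runs of the generator (pure background
maxes out near 1.09 bits/column over 20 seeds, planted exact motifs sit
near 2) because an EM motif overfits its own training set and the combined
p-value alone cannot reject the null. No claim is made that exactly ten
motifs are recovered — the published count depends on MEME's E-value
machinery, which is out of scope.

Genome scans score both strands and report positions at
(score − min)/(max − min) ≥ 0.70 — the min–max-normalised reading of a
"70% accuracy" search, documented as an interpretation. Positional
conservation is the standard deviation of offsets relative to the TSS end
of the orientation-normalised promoters, flagged conserved at SD ≤ 10 bp.

## Expression and editing (module `expressedit`)

Expression evidence: best local-alignment identity (identical positions /
query length, both target strands) of each cluster sequence against each
transcriptome contig; expressed iff strictly > 0.95. Contigs below 0.95 to
every cluster are novel-cluster candidates. The published wording leaves a
boundary case (exactly 95%): it is assigned "absent, not novel" and
logged. Whether the threshold applies at nucleotide or peptide level is
ambiguous in the source protocol; it is applied to the searched sequence
as given, so callers choose by passing CDS or peptide.

Editing: reads contribute coverage only where they match the reference
exactly over their full length (both strands); maximal zero-coverage
intervals are candidate mismatch regions, corroborating the mismatch list
from a direct global alignment of the paired genomic and transcript
sequences. Zero corroborated candidates yields the "no discrepancies"
(genomic-origin) verdict. The explicit zero-coverage report replaces the
visual inspection step of the original protocol.

## Pipeline and CLI

`pipeline.run_pipeline` executes simulate → mine → catalog → {biophys,
select, promoter, express} with all randomness derived from one seed,
writing FASTA/TSV/BED/newick/JSON outputs per stage and a run report whose
numbers are recomputable from those files. Promoter discovery runs on one
full-length promoter per cluster (the representative's locus), mirroring a
per-cluster promoter panel and keeping the EM input compact. Thresholds
default to the canonical values (identity 0.95, expression 0.95,
divergence 0.05, selection p 0.1, promoter 500 bp, window 15, widths 6–30,
scan accuracy 0.70). The `ampfam` CLI exposes the stages as subcommands
with exit codes 0 (success), 2 (input error), 3 (stage failure).

## Problem sizes

Default runs use 16 individuals × ~11 gene copies on 2.5-kb contigs;
the recovery studies use 50 seeds of single-individual six-gene families
(0.8-kb contigs), 60-sequence selection alignments, and 20-sequence
500-bp promoter sets — sizes at which every stage completes in seconds to
a few minutes on one CPU while leaving the statistical structure intact.

## Known limitations

- No indel variation within the family alignment beyond what clustering
  tolerates; the progressive aligner is exercised mainly on
  substitution-only data.
- The counting selection test undercounts events on saturated columns
  (parsimony) and its binomial rounding discards fractional information.
- The identity denominator is an explicit choice, not a CD-HIT replica;
  absolute cluster counts on real data would differ at the margin.
- Allelic variants and paralogous copies cannot be discriminated — an
  intrinsic limitation of assembly-level data, inherited here.
- E-value statistics (search and motif significance) are replaced by
  calibrated raw-score/IC gates valid for desk-scale synthetic assemblies,
  not for genome-scale screens.
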