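# Methods

This note documents the models, rules and numerical choices behind
`decurate`, what the synthetic-data generator does and does not emulate,
and where the design was genuinely open.

## Differential expression

Counts for contig $c$ in sample $s$ are modelled negative-binomially
with mean $\mu_{cs}$ and common dispersion $\phi$,
$\mathrm{Var} = \mu + \phi\mu^2$, so $\phi = 0$ is Poisson.

**Library equalisation.** The conditional exact test requires equal
library sizes, so counts are scaled to the geometric-mean library size
and rounded to integers before testing. Library sizes are, in order of
preference: an explicit argument, a `library_size` column in the sample
sheet, or the column sums. The fallback is correct when the matrix
covers the whole transcriptome; when it covers a subset (as any
desk-scale simulation must), column sums are dominated by the planted DE
composition, which is why the generator records the true simulated
depths in the sample sheet and the DE caller uses them. This mirrors the
real situation, where library size comes from total mapped reads, not
from the DE subset.

**Exact test.** Within one comparison the replicate counts are summed
per condition after equalisation. The sum of $n$ i.i.d.
$\mathrm{NB}(\mu, \phi)$ variables is $\mathrm{NB}(n\mu, \phi/n)$.
Conditional on the total $s = a + b$, with the null per-replicate mean
estimated as $\hat\mu = s/(n_a + n_b)$, the two-sided p-value is the
total probability of all splits $(k, s-k)$ whose probability does not
exceed that of the observed split (float ties tolerated at relative
$10^{-12}$). At $\phi = 0$ with equal single-replicate libraries this
reduces exactly to the binomial conditional test; the suite cross-checks
it against full enumeration and against `edgeR::binomTest`.

**Dispersion.** $\phi$ is estimated as the median over contigs of
$\max\!\big(0, \sum_g (s_g^2 - \bar m_g) \big/ \sum_g \bar m_g^2\big)$,
pooling the per-group method-of-moments numerators and denominators over
replicate groups on equalised counts. Medians of $n{=}3$ sample
variances are biased slightly low (the sampling distribution of $s^2$ is
right-skewed), which is visible in the recovery tests (≈0.17 recovered at
truth 0.2) and acceptable for a common-dispersion plug-in: the
parameter-recovery suite bounds the estimate within [0.5×, 1.5×] of
truth at 2,000 contigs for φ ∈ {0.1, 0.4}.

**Calling.** All six unordered time-point pairs are tested;
Benjamini–Hochberg runs within each pair separately; log2 fold changes
come from CPM means with a 0.5 pseudo-count (treatment = later time
point). The overall DE flag is the union over pairs of FDR ≤ 0.01 and
|log2FC| ≥ 2, both bounds inclusive. BH is *not* idempotent on its own
output (e.g. p = (1.0, 0.25) adjusts to (1.0, 0.5), which re-adjusts to
(1, 1)); the tests assert the step-up definition and monotonicity
instead.

## Redundancy removal

Identity between two contigs is matched positions divided by the length
of the shorter sequence, from an end-gap-free placement of the shorter
within the longer (edlib), taking the better orientation — the
convention of identity-based dedup tools, so contained fragments count
as duplicates of their parent. Greedy clustering visits contigs longest
first (ties by id); each joins the first representative at ≥ 95%
identity or founds a cluster, making every representative the longest
member of its cluster. Isoform curation marks a member redundant when,
ignoring its terminal 30 bp, it is contained in a longer retained member
at the same identity threshold; the containment check is pairwise
(edlib infix) rather than via a multiple alignment, which the contract
does not need.

## ORF prediction

Six frames; each maximal stop-free codon run yields at most one record:
from its first ATG when it has one (`canonical` with a closing stop,
`no_stop` without), otherwise from the run start (`no_start` with a
stop, `internal` without). The minimum of 33 residues excludes the stop
codon. Coordinates are 0-based half-open on the forward strand so spans
slice the FASTA directly. Best-ORF selection takes the longest canonical
record unless a non-canonical one is ≥ 1.5× longer — the preference
ratio is a declared default, exposed as a parameter, since no published
rule quantifies "lower stringency" here. Equivalence with an independent
exhaustive start/stop-pairing enumerator is asserted on 1,000 random
sequences up to 2 kb.

## Homology search and classification

Alignment is exhaustive Smith–Waterman (biopython's PairwiseAligner,
BLOSUM62, gap open 11 / extend 1), verified against an independent
quadratic Gotoh DP. E-values use the Karlin–Altschul form
$E = Kmn\,e^{-\lambda S}$ with the standard gapped constants
λ = 0.267, K = 0.041; at desk-scale database sizes this is a calibration
convenience, not a claim of BLAST-equivalent statistics. A *confident*
match requires E ≤ 10⁻³ (inclusive) plus identity ≥ 0.35 and query
coverage ≥ 0.5 — both floors are declared defaults, configurable,
because no numeric cut-offs are published for this criterion. The
optional k-mer prefilter (k = 4, ≥ 2 shared words) is off by default in
`search` and enabled by the pipeline; at comparator divergence ≤ 0.3 a
true homolog shares dozens of 4-mers, so the filter only skips
hopeless subjects.

The no-ORF cross-check accepts a prior-assembly contig when the length
ratio is ≥ 0.9, identity ≥ 0.98 over the alignment excluding
terminal-window gaps, and no gap opens outside 30 bp windows at either
end — strict enough that only essentially identically assembled
transcripts count.

## Assembly refinement

Refinement detectors work from gap-free homology blocks obtained by
exact 4-mer seeding per (strand, frame, diagonal), merging seed runs
through droughts of up to 3k positions (isolated mismatches against a
diverged homolog do not change the diagonal). Smith–Waterman is
deliberately not used here: a local alignment bridges short inserts,
destroying the two-block structure the rules need.

* **Fragment pairs**: a suffix of one fragment matching a prefix of the
  other over ≥ 20 bp at ≥ 95% identity merges with the overlap collapsed
  once. The pipeline proposes candidate pairs among contigs sharing a
  best-hit subject.
* **Intron retention**: two collinear blocks with an unaligned insert
  ≥ 50 nt beginning GT and ending AG; the proposed correction excises
  the insert. When the codon spanning the 3′ junction coincidentally
  re-encodes the flanking residue (NAG → K/Q/E), the seeded block edge
  shifts by one codon, so boundaries may be snapped within ±12 nt — a
  snapped excision is accepted only if the corrected sequence
  demonstrably re-translates to the homolog across the junction, which
  keeps arbitrary GT/AG pairs inside unexplained inserts from being
  mistaken for splice sites.
* **Frameshift**: two collinear blocks in different reading frames with
  a contig junction of ≤ 10 nt. A single-base deletion shifts the frame
  by −1 ≡ +2 (mod 3), so any nonzero frame difference across a tight
  junction is treated as a ±1 indel.

## Categorisation against physiological baseline

For each DE contig and treatment time point t: if the 0-vs-t comparison
itself passes the DE thresholds, the direction of its log2FC categorises
t (*direct*). If the contig is significant only among treatment pairs,
the baseline is the mean control log2(FPKM+1) and t is categorised when
the mean replicate deviation is ≥ 1.0 (half the DE log2FC threshold — a
deliberately weaker bound for baseline inference) with all replicates
deviating in the same direction (*baseline-inferred*). A DE contig with
no categorisable time point is flagged *uncategorisable* and excluded
from the accounting; a separate column records whether the canonical
evidence — replicate coefficient of variation above 0.5 at every
implicated time point — held. CV is computed on log2(FPKM+1), a
scale-stabilised measure. Flagging every all-ns DE contig (rather than
only the high-CV ones) keeps the invariant that a categorisable DE
contig has at least one direction.

## Subclustering

Contig profiles (log2 median-centred FPKM; FPKM = 10⁹·count/(length ×
library size), full contig length, pseudo-count 1) are clustered with
complete linkage on 1 − Pearson distances and cut at 50% of the maximum
merge height (plus 10⁻⁹ absolute slack so numerically-zero trees
collapse). Rows are processed in id-sorted order and labels renumbered
by first appearance, making the partition invariant to input order.

A geometric constraint matters here: with four time points a centred
profile has three degrees of freedom, and at most 2d = 6 pairwise
non-positively-correlated shapes exist in d = 3 — exactly three
orthogonal contrasts and their negatives. The generator's six default
archetypes are therefore chosen as such an arrangement (sustained early
induction; transient early induction overshooting on return; induction
at 20 hps resolving by 96 hps; and the three mirror images, ±4 log2 at
the driving time point). Mutually positively correlated shapes are
provably not separable at a fixed dendrogram cut under this distance, so
archetype separability is a property of the planted design, stated here
rather than tuned.

## The synthetic-data generator

The generator emulates the *inputs* of a post-assembly curation study:

* a reference proteome (random 20-letter proteins, 60–300 aa, starting
  with M) standing in for the annotated protein universe, and a lineage
  proteome present **only** (diverged at rate 0.2) in the comparator
  species databases — the planted lineage-specific class;
* contigs built by uniform-codon reverse translation flanked by random
  UTRs (annotated / conserved classes), non-coding contigs certified at
  generation time to contain no stop-free run of ≥ 33 codons in any of
  the six frames (repairing runs by planting stops at random positions —
  a deterministic midpoint repair can oscillate when runs on opposite
  strands overlap), and contaminants copied from a decoy database;
* planted anomalies at configurable rates (defaults 4% redundant
  near-duplicates at 98% identity, 4% fragment pairs with 25–60 bp
  overlaps, 2% intron retentions of 54–120 nt, 2% single-base
  frameshifts), each recorded in the manifest with the parent sequence;
* NB counts over the 4 × 3 design: contig mean = baseline FPKM
  (log-uniform 20–200) × 2^archetype-offset × length/10³ ×
  library-size/10⁶, gamma-Poisson with φ = 0.2 by default, library
  depths uniform in [0.8, 1.2]·10⁶ and recorded in the sample sheet.
  Half of the contigs carry an archetype; anomaly copies inherit their
  parent's profile.

What it does **not** emulate: read-level sequencing error, codon usage
bias, homopolymer artefacts, shared domains between unrelated proteins,
expression-dependent assembly quality, or taxonomically meaningful
contamination. Consequently the recovery numbers (classification recall,
refinement recall, subcluster ARI) certify the pipeline logic under its
stated assumptions; they are upper bounds on, not predictions of,
performance on real assemblies, where homology is remote, ORFs are
interrupted by real biology, and profiles are noisier.

## Problem sizes and determinism

Default scales — 600 contigs for end-to-end runs, 5,000 for the null
false-positive simulation, 2,000 for dispersion recovery, 300 for
subcluster recovery — are chosen so each check completes in seconds to
tens of seconds while leaving binomial sampling error small relative to
the asserted margins. Every random draw flows from a single
`numpy.random.default_rng` seed carried in the design or derived from
the acceptance script's `--seed`; identical configuration and seed give
byte-identical FASTA, counts, reports and summaries.

## Known limitations

* The exact test recomputes the conditional distribution per contig;
  fine at desk scale, quadratic in the conditioned total.
* The common dispersion is a single global value; no tagwise shrinkage.
* Refinement detectors need a reasonably close homolog; with a diverged
  one, seeded block edges blur and sensitivity drops (by design they
  then stay silent rather than guess).
* The E-value calibration is nominal for small databases; the inclusive
  1e-3 threshold is meaningful relative to that calibration only.
* `curate_isoforms` and `noorf_crosscheck` are pairwise and quadratic in
  the candidate set.
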