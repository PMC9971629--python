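# Methods

This note documents the models, the tunable parameters and the design
choices behind each stage, what the synthetic data does and does not
emulate, and the known limitations.

## Conventions

GTF files are 1-based inclusive on disk and converted to 0-based half-open
intervals in memory (tested by write∘read round trips). Sequences are held
in DNA letters; `U` is normalised to `T` on input and a per-record flag
remembers the original alphabet, so RNA miRNA catalogs and DNA transcript
FASTA mix freely. Strand is mandatory — the pipeline assumes a
strand-specific library — and strandless records are rejected. All
thresholds live in one flat `RunConfig` (YAML-serialisable; CLI flags
override it), and a single integer seed determines every stochastic
output: two runs with the same config produce byte-identical tables.

## lncRNA discovery

The basic screen keeps a transcript iff its class code is in
`{i, x, u, o, e}`, spliced length ≥ `min_length_nt` (200), exon count ≥
`min_exons` (2), and max-over-samples FPKM ≥ `min_fpkm` (0.1). Two points
were genuinely open and are resolved as config switches:

* *Which FPKM aggregate?* Detection thresholds in this field are usually
  quoted without saying whether 0.1 applies per sample, to the mean, or to
  the max. We apply it to the **max over samples** — the most permissive
  reading, chosen so condition-specific lncRNAs (expressed only under
  stress) are not discarded.
* *The exon filter.* Requiring ≥ 2 exons contradicts the empirical fact
  that most plant lncRNAs are single-exon; published pipelines do both.
  The filter is therefore a switch (`exon_filter_enabled`, default on),
  and the contradiction is documented rather than resolved.

Coding potential is scored by a deliberately simple ORF rule: coding ⇔
longest complete forward-strand ATG→stop ORF ≥ `orf_max_codons` (100, the
classical lncRNA convention; the stricter 50-aa rule used for novel-gene
discovery is a separate config key and not applied to the lncRNA screen).
The score counts codons from ATG up to but excluding the stop; an ORF
still open at the 3' end does not count. The consensus step is the
three-tool intersection design: a transcript is non-coding only if every
required tool says so, and the per-tool-subset Venn counts are reported.
By default the pipeline feeds the consensus with the ORF scorer run at
three stringencies (100/110/120 codons) so the Venn machinery is
exercised; tables of calls from real external classifiers can be supplied
instead and flow through unchanged. Positional categories follow the class
codes (u → lincRNA, x → antisense, o/e → sense-overlap, i → intronic,
reported separately). Length summaries use bins < 1000 / 1000–2000 /
> 2000 nt, the lower bin closed at 999 so a 1000-nt transcript is
medium-length. Group presence for the CK/DR Venn reuses `min_fpkm` in at
least one replicate of the group.

## Differential expression

Counts are normalised by median-of-ratios size factors: s_j = median over
reference features of k_fj / geomean_f, where the reference set is
features with nonzero counts in every sample. The test is a
negative-binomial Wald test with the mean/dispersion parameterisation
Var = μ + αμ²:

* per-feature α by method of moments from the pooled within-group variance
  of normalised counts, floored at 1e-8;
* a parametric mean-dispersion trend α(μ) = a₀ + a₁/μ fitted by least
  squares, with the final dispersion the **maximum** of the per-feature and
  trend values. At three replicates per group the moment estimator is very
  noisy; taking the maximum is deliberately conservative and keeps the
  test's type-I error near (slightly below) nominal, which the null
  calibration test verifies on a 5000-feature NB null (empirical rate at
  p < 0.05 required to stay within [0.025, 0.10]);
* z = Δlog(mean) / SE via the delta method, two-sided normal p-value.

Fold changes use a pseudocount of ε = 1 normalised count per group mean,
log2FC = log2((m_DR + 1)/(m_CK + 1)), so features absent in one condition
get large finite fold changes (a group mean of ~8000 reads against zero
reports ≈ 2¹³) instead of infinities. BH adjustment is the standard
step-up, delegated to statsmodels behind `bh_adjust` and cross-checked in
the tests against a literal implementation of the definition.

Calling rules differ by feature kind, matching common practice for this
design: lncRNAs at raw `p < alpha`, mRNAs at `FDR < mrna_fdr`, both with
`|log2FC| ≥ lfc_threshold`. The literature quotes both ≥ 1 and ≥ 2 for the
fold-change cut; the default is 1 and it is a config key — neither value
is asserted as canonical.

## Target prediction

*cis*: a gene is a cis target when its genomic span (first exon start to
last exon end) lies within `cis_window_bp` (100 kb) of the lncRNA span on
the same chromosome, strand-agnostic; overlap counts as distance 0 and the
boundary is inclusive. Spans rather than TSSs are used because the
windowing convention of the usual Perl-script implementations is unstated;
the window is symmetric, so the choice only shifts distances by gene
length.

*trans*: a simplified additive duplex energy replaces full
nearest-neighbour thermodynamics while preserving the decision structure
of ndG-threshold tools. Per aligned position: G:C −3, A:T/U −2, G:U −1,
anything else +2. The two molecules are paired antiparallel at every
ungapped offset; the reported score is the minimum window sum over
contiguous windows of w = min(len_a, len_b, 100) nt, divided by w. The
score is symmetric in its arguments. The cutoff −1.0 (on this model's
scale) was calibrated so that perfect complements of ≥ 20 nt always pass
(worst case, all-A:T, scores −2.0/nt) while random kilobase pairs
essentially never do: random per-position energy has mean +0.5 and
SD 2.0, so a 100-nt window needs a ≈ 7.5 SD excursion to reach −1.0/nt.
The rolling scan is a numba-jitted kernel with a pure-Python fallback.

## miRNA response elements and target mimics

Sites are scored by a plant-style penalty model. The target window is
aligned antiparallel to the miRNA (positions numbered 1..n from the miRNA
5' end, so position 1 faces the 3'-most target base) by anchored dynamic
programming allowing only target-side insertions (≤ 5): mismatch 1.0, G:U
wobble 0.5, insertion 1.0 per nt, each doubled opposite positions 2–13.
These weights follow the established plant target-prediction convention
(seed-proximal defects are penalised double); all of them are config keys.

An endogenous target mimic is defined structurally: near-perfect pairing
interrupted by a 3-nt target-side bulge opposite miRNA positions 9–11,
which blocks slicing while preserving binding. Classification runs a
**constrained** alignment that forces exactly three insertions into the
9–11 zone and asks whether the rest of the duplex is good: the site is a
`mimic` iff that alignment has no mismatch opposite positions 2–8 and a
non-bulge penalty ≤ `mimic_non_bulge_max` (2.0); otherwise it is a
`cleavage_target`. Asking the question this way makes the call robust to
alignment ambiguity — when the inserted bases happen to pair elsewhere,
the unconstrained optimum can describe the same sequence with the bulge
shifted, but the constrained test still recognises the canonical
geometry. For reporting, a mimic's effective score excludes the bulge's
own 6.0 insertion penalty (the bulge is the defining feature, not a
defect); sites pass when the effective score ≤ `mimic_score_cutoff` (4.0).
The genome-wide scan prefilters candidate positions with vectorised
ungapped and 3-nt-bulged complementarity templates (≤ 8 non-complementary
positions) before running the DP, and overlapping same-miRNA hits keep
only the best-scoring site.

## ceRNA network

MRE sets use distinct miRNA identities — a miRNA with several sites on
one molecule counts once — so the ceRNA score
|shared| / |lncRNA set| is a set ratio bounded by 1. The shared-count
p-value is a hypergeometric upper tail P(X ≥ k) with population = all
miRNAs holding ≥ 1 site in the catalog, successes = the mRNA's set, draws
= the lncRNA's set; the test form and universe are this package's choice,
since score-based ceRNA screens rarely name theirs. BH FDR is computed
across all tested DE×DE pairs. Retention requires shared count **strictly
greater than** `cerna_min_shared` (3), p < 0.05, FDR < 0.1 and Pearson
r(lncRNA, mRNA) > 0 across samples; when a miRNA expression matrix is
supplied, r(miRNA, lncRNA) < 0 and r(miRNA, mRNA) < 0 are additionally
required — rRNA-depleted libraries usually lack miRNA quantification, so
these filters engage only when data exist. Zero-variance expression
vectors make r undefined; such triplets are dropped with a logged warning.
Empty DE sets yield an empty network, not an error.

## Enrichment

Classic per-term hypergeometric over-representation (P(X ≥ k) for k study
hits of K annotated genes, study n of background N), BH across terms,
ranked by p with ties broken by term id, top-20 reported by default. No
ontology-graph decorrelation (elim/weight-style algorithms) — enriched
term lists are the deliverable, and the background defaults to all genes
with ≥ 1 annotation.

## Synthetic data: what it emulates, and what it does not

The generator builds a 2-chromosome × 1 Mb genome (large enough that
100-kb cis windows see both hits and misses) carrying 80 coding genes and
124 lncRNAs with the field-typical structure: category counts echo the
~75% lincRNA / ~22% antisense split, lengths draw from bins
(0.885, 0.079, 0.036) over < 1 kb / 1–2 kb / > 2 kb, and exon counts from
{1: 0.20, 2: 0.55, 3: 0.20, 4: 0.05} so the exon filter has work to do.
Coding genes embed a ≥ 110-codon ORF; lncRNA sequences are random at
GC 0.45 with any chance ≥ 100-codon ORF repaired by an in-frame stop
mutation that never touches a planted site. Placement is by class code:
"u" transcripts overlap no gene, "x" overlap a gene antisense, "o"/"e"
overlap sense, "i" sit inside an intron.

Counts follow NB(μ·s_j, α) with Var = μ + αμ², α = 0.05 (typical bulk
RNA-seq at 3 replicates), size factors lognormal around 1 (σ = 0.05) and
baseline means lognormal around ~80. Planted effects span
|log2FC| ∈ {2, 4, 13} — threshold-adjacent through the several-thousand-
fold extremes real drought studies report — with DE baselines drawn from
[100, 400] so the |log2FC| = 4 recovery criterion is measured at adequate
depth. A few "silent" lncRNAs (μ ≈ 0) exercise the FPKM filter.

Planted sites are constructed to satisfy the module rules by construction:
cleavage sites are perfect reverse complements, mimic sites carry the
canonical 9–11 bulge with inserted bases chosen (where the miRNA sequence
permits) unable to pair with the surrounding positions. Each of 6 ceRNA
triplets gets 5 distinct shared miRNAs planted on a co-upregulated
(+4/+4) DE lncRNA–mRNA pair; 6 decoy pairs share only 2 miRNAs. Free
mimic/cleavage sites are planted on structurally detectable non-DE hosts
(a site on a molecule the screen removes would be unevaluable truth).
Four DE lncRNAs additionally receive a 120-nt reverse-complement segment
of an mRNA as planted trans-target truth. A term map annotates genes with
12 random terms plus one "drought" term enriched near planted DE lncRNAs.
An audit operation re-derives every truth record from the emitted files
(`audit_ground_truth`), and it runs in the test suite.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (no FASTQ, alignment or
assembly noise), misassembled or fragmented transcript models, batch
effects and GC/length biases in counts, paralogous sequence families that
confound MRE scanning, miRNA expression dynamics, and realistic ontology
structure. Recovery rates on this benchmark are upper bounds, not
forecasts for field data.

## Problem sizes and numerical choices

Default sizes (204 transcripts, 30 miRNAs, 6 samples) were chosen so the
full pipeline runs in seconds and the complete validation — including a
5000-feature null calibration and the four brute-force oracle comparisons
at ≥ 1000 random instances each — stays comfortably within a single CPU's
patience. Determinism is enforced by sorting every iteration order and
fixing float formatting in the writers; the determinism test compares two
full runs byte for byte. Degenerate inputs are errors, not warnings:
empty FASTA records, negative counts, zero-total samples, zero-length
features, strandless transcripts, inconsistent hypergeometric counts.

## Known limitations

* The ORF-length coding-potential scorer is a stand-in with the same
  decision shape as CPC/CNCI/PFAM-based screens, not a reimplementation;
  on real data one should feed external call tables into the consensus.
* The NB test is a dependency-light Wald test, not DESeq(2); its p-values
  agree in structure (normalisation, dispersion shrinkage, NB likelihood)
  but not numerically with those tools.
* The trans energy model has no stacking, loops or accessibility terms;
  its cutoff is meaningful only on its own scale.
* The eTM rule is the canonical 3-nt/9–11 geometry; non-canonical mimics
  (larger loops, shifted bulges) are deliberately out of scope.
* cis distances use transcript spans, not TSSs.
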