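# Methods

`seedlnc` implements a desk-scale analysis of long non-coding RNA (lncRNA)
behaviour during rice seed aging: identification of lncRNAs from assembled
transcript models, differential expression between artificially aged (S50)
and fresh (S96) seed libraries, cis/trans target prediction, competing
endogenous RNA (ceRNA) network assembly, and pathway enrichment. Because the
pipeline is exercised on synthetic data with planted ground truth, every
stage's output can be scored as a recovery problem.

## Identification cascade

Candidate transcripts pass five rounds, applied in a fixed order with
inclusive thresholds:

0. strand certainty — strand must be `+` or `-`; transcripts assembled with
   undetermined strand (`.`) are removed;
1. exon count >= 2 (single-exon fragments are typically assembly noise);
2. mature length >= 200 nt (sum of exon lengths, 1-based inclusive
   coordinates, so `length = end - start + 1` per exon);
3. annotation overlap — any >= 1 bp exonic overlap with an annotated
   protein-coding exon *on the same strand* removes the candidate; a
   candidate whose exon chain exactly matches an annotated lncRNA is kept
   and flagged `annotated`, all other survivors are `novel`;
4. expression — maximum FPKM across all samples >= 0.5. The aggregation is
   configurable (`max`, `mean`, `all`); `max` is the default because a
   transcript reliably quantified in any library is real, and the
   alternative readings are not distinguishable from the printed criterion;
5. coding potential — survivors must be non-coding (below).

The per-step accounting telescopes (input − removed = next input) and is
asserted on every run.

### Coding potential

Full coding-potential classifiers and protein-domain searches are external
tools; the cascade instead scores each transcript from its longest forward
ATG→stop open reading frame (three forward frames, length including the
stop codon):

```
score     = orf_nt / 300 + orf_coverage
is_coding = orf_nt >= 300  or  (orf_nt >= 200 and orf_coverage >= 0.5)
```

where `orf_coverage = orf_nt / transcript_length`. The 300 nt (100 codon)
cutoff is the conventional minimum for a protein-coding ORF; the secondary
rule catches shorter ORFs that dominate a short transcript. The cascade
also accepts precomputed `is_coding` labels, so output of an external
classifier can be substituted without touching the other rounds.

### Positional classification

Survivors are classified against the protein-coding annotation with
explicit precedence:

1. **lncNAT** — >= 1 bp exonic overlap with a coding exon on the opposite
   strand;
2. **intronic** — entirely contained in an intron of a coding gene (either
   strand) with no exonic overlap;
3. **sense_overlapping** — span overlap with a coding gene without exonic
   overlap;
4. **lincRNA** — no span overlap with any coding gene.

Intronic outranks sense_overlapping because a transcript nested in an
intron is better described by its containment than by the incidental span
overlap.

## Differential expression

Counts are modelled as negative binomial, `Var = mu + alpha * mu^2`.

**Normalization.** Median-of-ratios size factors (the ratio of each
sample's counts to the per-transcript geometric mean, median over
transcripts nonzero in all samples; total-count scaling as a warned
fallback). Median-of-ratios assumes most features are unchanged between
conditions. In this system that assumption is violated by design: the
biological signature being studied is genome-wide lncRNA downregulation, so
a large block of features shifts in one direction and drags the median with
it. `nb_test` therefore refines the factors iteratively: after a first
pass, factors are re-estimated on the transcripts *not* currently called
DE, and the test repeats until the call set stabilizes (at most 8 rounds,
usually 3–4). With fewer than 10 non-DE transcripts the refinement stops.
Calls are invariant to a common rescaling of all counts.

**Dispersion.** Method-of-moments within each condition. The default
`dispersion_mode="shared"` aggregates across transcripts,
`alpha = sum_g (s2_g - m_g) / sum_g m_g^2`, pooled over the two conditions.
With 3 replicates a per-transcript moment estimate has so few degrees of
freedom that a normal-reference Wald test becomes strongly anti-conservative
(simulated type-I error ≈ 0.13 at the 0.05 level); the shared estimate is
nearly unbiased when dispersion is approximately common across transcripts,
which is also the generator's noise model. `dispersion_mode="per-gene"`
keeps the per-transcript estimates (floored at 1e-8) for data where
dispersion heterogeneity matters more than calibration at tiny n.

**Test.** Wald statistic on the difference of log normalized condition
means with variance `(1/mu + alpha)/n` per condition, two-sided p from the
normal reference; `log2FC = log2((mu_aged + 0.5)/(mu_new + 0.5))` with a
0.5 pseudocount so zeros stay finite. Benjamini–Hochberg q-values are
reported; calls use the raw p by default (`|log2FC| > 1` and `p < 0.05`,
both strict), since that is the stated selection criterion in this type of
analysis; `use_adjusted=True` switches the calls to q. This is a deliberate
simplification of shrinkage-based NB frameworks (no Cox–Reid adjustment, no
fold-change shrinkage); a cross-check test confirms log2FC estimates track
a reference NB implementation closely on planted data.

FPKM is computed as `count * 1e9 / (length * library_total)`, which makes
`sum_i FPKM_i * length_i = 1e9` an exact per-sample identity used as a
test invariant. The qPCR utility returns `2^-ddCt`.

## Target prediction

**Cis** — a protein-coding gene is a candidate cis target when its span
lies within 100 kb of the lncRNA span on the same chromosome, either
strand. Distance is the coordinate gap between the facing span ends (0 when
overlapping), and the boundary is inclusive: a gene exactly 100,000 bp away
qualifies, 100,001 does not. Measuring from span ends (not TSS) is a
documented choice; the window is configurable.

**Trans** — Pearson correlation of FPKM profiles over all six samples; a
pair qualifies at `r > 0.95` and `p < 0.01`, both strict, with p from the
t-transform `t = r*sqrt((n-2)/(1-r^2))` on n−2 degrees of freedom. At
n = 6 the r threshold dominates (r = 0.95 corresponds to p ≈ 0.004).
Constant profiles have undefined correlation and are excluded. Correlations
are computed on FPKM rather than raw counts so that library depth cancels;
with six samples spanning both conditions, strongly co-regulated DE pairs
dominate the trans calls, which is the intended reading of co-expression.

## miRNA sites and the ceRNA network

Both scanners slide a miRNA-length window along the transcript (converted
to RNA), scoring the window read 3'→5' against the miRNA 5'→3'; gaps and
bulges are not modelled (v1 limitation — the generator plants gapless
sites).

* **lncRNA mode** (hybridization-style pseudo-energy): G:C −3, A:U −2,
  G:U wobble −1, otherwise +1; hits kept at <= −20 (default). A perfect
  21-mer duplex scores between −42 (all A:U) and −63 (all G:C).
* **mRNA mode** (plant expectation penalty): perfect pair 0, G:U 0.5,
  mismatch 1, doubled at miRNA positions 2–13 (the seed-critical region;
  position 1 never doubled); hits kept at <= 5.0 (default).

Overlapping windows are resolved best-score-first, leftmost on ties, so
hit lists are deterministic.

Chance-hit behaviour differs sharply between the modes. The exact null
law of the pseudo-energy (convolution of per-position distributions, which
depend on the miRNA's base composition) puts roughly 1% of random windows
below −20 — order 10 candidate windows per kb — so at the default cutoff
the lncRNA-side relation is permissive, and a fidelity analysis should
tighten `energy_cutoff` (at −35 the chance rate falls below 0.05/kb).
The expectation penalty at cutoff 5.0 is extremely selective (mean random
penalty ≈ 23), so mRNA-side hits are essentially only planted or true
sites. Both cutoffs are configuration, and hit lists can be ingested from
external prediction tools instead of the built-in scanners.

The ceRNA network is the relational join of the miRNA→lncRNA and
miRNA→mRNA hit sets on the shared miRNA, optionally restricted to
differentially expressed lncRNAs and mRNAs (the default in the pipeline,
mirroring the practice of building the network over significant DELs and
DEGs). Triplets are emitted with a node/edge summary and a three-column
edge list importable by network viewers.

## Enrichment

Plain hypergeometric upper tail per term: with N population genes, K in the
term, n in the study set and k in both, `p = P(X >= k)`; rich factor
`k / K`; BH q-values across tested terms; significance at raw p < 0.05.
Terms are opaque identifiers from a gene→term table; no ontology topology
or transcript-length bias correction is applied (a documented
simplification relative to length-aware GO methods). The population
defaults to all annotated genes.

In the pipeline, the study set is the cis/trans target genes of
down-regulated lncRNAs intersected with down-regulated mRNAs. At the toy
genome density a 100 kb window reaches most genes, so restricting the study
set to targets that are themselves differentially expressed keeps the
background informative; the `enrich` operation itself takes any study set.

## Synthetic data generator

The generator emulates the statistical structure of the study, not its
sequences:

* **Design** — two conditions (aged S50, new S96) × 3 replicates.
* **Populations** — 200 mRNAs (800–3000 nt, 1–12 exons, explicit planted
  ORF with >= 60 nt 3' UTR) and 100 lncRNAs (200–1000 nt, 2–3 exons), the
  lncRNAs split 2:1 into intergenic lincRNAs (>= 2 kb from any gene) and
  antisense lncNATs (>= 1 bp exonic overlap with a host mRNA's 3' exon on
  the opposite strand). 93% of lncRNAs are rejection-sampled to a longest
  ORF <= 200 nt; the remainder carry a 201–280 nt ORF in transcripts long
  enough that the coding rule still rejects them, reproducing the ">90%
  short-ORF" population profile.
* **Contaminants** — one class per cascade round (12 strand-uncertain, 15
  single-exon, 12 short, 10 same-strand overlapping, 10 unexpressed, 8
  coding), so every filter demonstrably removes something.
* **Counts** — NB with shared dispersion α = 0.1 (a typical replicate-level
  value for bulk RNA-seq; no dispersion is printed for the original
  libraries, so this is an assumption), per-sample library factors uniform
  in [0.75, 1.35] (< 2× spread), means log-uniform (lncRNA 100–1000, mRNA
  200–5000).
* **Differential expression** — 90 down / 4 up lncRNAs (the heavily
  down-skewed aged-seed lncRNA signature at toy scale) and 60 down / 5 up
  mRNAs; planted
  |log2FC| uniform in [2, 4]. The magnitude floor of 2 is chosen from a
  power analysis: at n = 3 + 3 and α = 0.1 the sampling SD of an estimated
  log2FC is ≈ 0.4, so effects >= 2 are detected with probability > 99%,
  making direction-recovery a sharp test of the pipeline rather than of
  sampling luck. The four published upregulated lncRNAs show fold changes
  of similar magnitude (log2FC ≈ 1.5–2.1).
* **miRNA sites** — 12 random 21-nt miRNAs; 10 planted triplets, each
  writing the exact reverse complement of a miRNA into one down-regulated
  lincRNA and the 3' UTR of one down-regulated mRNA (re-checked not to
  create a coding ORF). Sites are never planted in transcripts that share
  genomic sequence with another transcript.
* **Terms** — 20 pathways over the mRNA genes; pathway `T001` is the
  positive control: 20 of its 30 genes are down-regulated mRNAs
  co-localized with down-regulated lncRNAs, so it must rank first in the
  pipeline's enrichment stage.
* **Consistency** — transcript sequences are embedded into the genome
  FASTA (strand-aware, spliced), so extracting exon sequence from
  `genome.fa` reproduces `transcripts.fa` exactly; lncNATs own only the
  bases not claimed by their host and are rejection-sampled around the
  fixed overlap.

Everything derives from a single root seed through independent
`SeedSequence` streams (placement, sequence, DE assignment, sites, terms,
counts), so a dataset is byte-reproducible and `simulate_counts` can be
re-run independently of generation.

The generator's ground truth records each candidate's expected cascade
fate by a separate straight-line application of the five rules, which the
cascade must reproduce exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level errors and mapping ambiguity,
isoform/assembly artefacts beyond the planted contaminant classes,
GC/length biases in counting, batch effects, dispersion heterogeneity
across transcripts, miRNA target sites with bulges or imperfect seeds, and
real GO/KEGG term structure.

## Numerical and reproducibility choices

* Dispersion floor 1e-8; correlation clamped to [−1, 1]; hypergeometric
  tail via a log-space survival function.
* Problem sizes: the default study is ~370 transcripts × 6 samples and
  runs end-to-end in a few seconds; statistical suites use 5,000 null
  transcripts for calibration, 200 replicate simulations for power, and a
  ~935-candidate dataset for the cascade/oracle equivalence check.
* Tie-breaks: overlapping miRNA hits best-score-then-leftmost; enrichment
  sorted by (p, term id); edge lists sorted by (source, target);
  identical inputs give byte-identical outputs for a fixed seed.
* Degenerate inputs: empty candidate sets, empty study sets and empty
  datasets produce well-formed empty outputs (with warnings where
  informative); constant vectors, zero-total samples and inconsistent
  designs raise errors naming the offender.

## Known limitations

* The coding-potential rule is ORF-based only; transcripts coding short
  peptides or with non-ATG starts are mis-scored (external labels can be
  supplied).
* The NB test has no shrinkage across transcripts beyond the shared
  dispersion; at very low means the normal Wald reference is approximate.
* The miRNA scanners are gapless; bulged sites (such as classic target
  mimics) are outside v1's model.
* Cis prediction uses span distance only; no orientation, TSS or
  chromatin information.
* Enrichment ignores transcript-length bias and ontology structure.
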