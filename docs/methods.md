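# Methods

## Study design and data model

The pipeline targets a four-group bulk RNA-seq design — larvae, nymphs,
adult females, adult males, three replicates each — plus a protein-level
annotation layer (domains, GO/KO flags, in-house categories, signal-peptide
and subcellular-localization calls) and tabular BLAST results of the
proteome against per-taxon-group databases (non-Acari invertebrates, fungi,
bacteria, archaea, protozoa, viruses). Everything upstream of these three
inputs — read processing, alignment, quantification, domain/predictor
runs, database construction — is out of scope; the pipeline consumes their
outputs as plain columns and trusts them.

## Expression profiles

**TPM.** Counts are normalized per sample to transcripts per million:
`rate_g = count_g / (length_g/1000)`, `TPM_g = rate_g / Σ rate · 10⁶`.
Every non-degenerate sample column sums to 10⁶; an all-zero sample stays
all-zero.

**Differential expression.** Fold changes are
`log2((mean TPM_X + 1) / (mean TPM_Y + 1))` (pseudocount 1, positive =
higher in the first-named group). Comparisons are canonically ordered
(L,N), (L,F), (L,M), (N,F), (N,M), (F,M).

The default test is a *moderated t-test of a fold-change threshold null*
on log2 of median-of-ratios-normalized counts:

* Per-gene pooled within-group variances (4 df at 3+3 replicates) are
  shrunk toward a scaled inverse-chi-square prior fitted across genes by
  moment matching on log variances (the empirical-Bayes squeeze used by
  limma-style engines). This is what makes a 3-replicate design usable:
  an unmoderated t-test at 4 df has too little power for any realistic
  per-comparison FDR threshold.
* The null hypothesis is the composite |effect| ≤ log2(fold cutoff)
  (default log2 2), the analogue of DESeq2's `lfcThreshold` mode. Testing
  the point null and filtering on observed fold change afterwards lets
  sampling noise around ±2-fold through at exactly the genes the filter is
  meant to exclude; testing the threshold null makes "significant" mean
  "confidently beyond the biological cutoff".
* The test input is log2(count / size factor + 1) with median-of-ratios
  size factors, not TPM. When a sizeable fraction of the transcriptome is
  stage-biased, TPM's fixed column sum pushes every other gene in the
  opposite direction (compositional bias); median-of-ratios normalization
  is robust to it as long as most genes are unchanged. The reported fold
  changes remain TPM-based (they are the quantity biologists read), so on
  strongly compositionally-shifted data the fold-change column carries a
  bias of up to ~log2 of the library-composition ratio — a documented
  property of the TPM scale, not of the test.

A plain Welch t-test of the point null on log2(TPM+1) is available as
`method="welch"` for transparency; it is underpowered at this design
scale and not used by default. Neither method reproduces a count-model
engine's p-values numerically; the contract is the (log2fc, p, q) tuple.

**Multiple testing.** Benjamini–Hochberg within each comparison, across
all tested genes (genes with all-zero counts included, keeping m = all
genes — conservative). The implementation delegates to statsmodels; tests
verify it against a direct step-up evaluation.

**Profile classes and stage flags.** A gene's call per comparison is +1 /
−1 / 0 (significant up in the first group / the second / neither) at
q ≤ 0.05 and |log2fc| ≥ log2 2. The profile (Venn) class is the subset of
the six comparisons with a nonzero call — 63 possible non-empty classes;
a gene is a DEG iff its class is non-empty. A stage flag (e.g. "female
gene") requires all three comparisons against the other groups to be
significant with the gene on the same side — the strictest and most
interpretable call.

**PCA and heatmaps.** PCA operates on gene rows centered and scaled to
unit variance (equal weight per gene; zero-variance genes dropped), via
SVD over samples. Heatmap ordering uses agglomerative clustering with
Euclidean distance and complete linkage; cluster labels are renumbered by
first appearance in input order so output is deterministic.

## Co-expression network

The graph connects genes whose per-stage mean TPM vectors have Pearson
r ≥ 0.9. With only four stage values the correlation is coarse — this is
a property of the stage-mean design, preserved deliberately. Genes
constant across stages are excluded (undefined correlation).

Markov clustering is implemented from scratch on the dense weighted
adjacency matrix: self-loops set to each node's maximum incident weight,
columns normalized to a stochastic matrix, then alternating expansion
(matrix squaring) and inflation (elementwise power 3.0 by default, the
"granularity" knob — higher is finer), with entries below 1e-5 pruned,
until the matrix change falls below 1e-8 or 200 iterations (non-convergence
returns the current state with a warning flag). Clusters are read from
attractor rows; nodes attracted by several attractors resolve to the
lowest cluster id. Edge weights are used as-is (weighted MCL) rather than
binarized, preserving correlation strength.

Curation merges the pair of clusters with the highest centroid (mean
stage profile) Pearson correlation, repeatedly, while it exceeds 0.95;
ties break toward the lowest id pair. The threshold is a config knob: the
original curation it emulates was qualitative.

## Cuticular-protein screens

**Known families.** CPR requires the insect-cuticle-protein domain
IPR000618. CPAP requires ≥ 1 chitin-binding peritrophin-A accession
(PF01607 / IPR036508 / IPR002557) and no chitinase or chitin-deacetylase
evidence (domain or in-house flag); the CBD count is the number of CBD
accession instances in the annotation (no HMM rescanning). CPLCP uses an
operational rule — PV/PY-pair density ≥ 0.03 per residue plus proline
fraction ≥ 0.15 — flagged as heuristic. Precedence is CPR > CPAP > CPLCP:
a protein carrying both IPR000618 and CBDs is classified CPR (a
convention; the evidence hierarchy is not otherwise specified). True
peritrophins are not distinguished from cuticular CPAPs — they are not
separable on sequence evidence alone.

**CPH candidates.** Four filters in order, each recording the dropout
stage: (1) *unannotated* — no InterPro/Panther accession, GO, KO or
in-house category; (2) *highly expressed* — mean TPM at or above the 90th
percentile of the whole-transcriptome mean TPM ("top decile"; the
quantile is recomputed per dataset, never hard-coded); (3) *secreted* —
signal peptide and extracellular localization flags both set; (4) *CP
traits* — at least one of:

| trait | rule (defaults) |
|---|---|
| aap_motifs | ≥ 3 occurrences of A-A-P-(A\|V\|L), overlaps allowed |
| hydrophobic_rich | fraction of G,A,V,L,I,P,F,M,W > 0.5 |
| cys_free | no cysteine in the mature peptide (after signal-peptide cleavage) |
| gly_dense | some 20-residue window ≥ 50% glycine |
| pvpy_rich | (PV + PY 2-mers) / length ≥ 0.03 |
| tandem_repeat | a k-mer (k 2–10) ≥ 3 consecutive copies covering ≥ 20% of the sequence |

The numeric thresholds operationalize criteria that were stated verbally;
all are exposed in `TraitParams`. Sequences shorter than the 20-residue
glycine window are scored on the whole sequence as one window. Raising
the expression decile or any trait threshold can only shrink the
candidate set (monotonicity, covered by tests).

## HGT screen

Per gene and taxon group the best (maximum) BLAST bitscore is collected;
groups without a hit contribute 0. For each non-metazoan group,
h = best(group) − best(non-Acari invertebrates). The donor is the group
with the highest h (ties: higher bitscore, then fixed group order); a
candidate passes iff h > 30 and donor bitscore > 100, both strict. The
zero convention for missing invertebrate hits means a gene hit only by a
strong non-metazoan donor passes — the intended behaviour for genes of
non-metazoan origin. Only query, subject and bitscore are used; the other
outfmt-6 columns are parsed and ignored. Taxonomy is a property of the
input databases and is not re-verified.

## Enrichment

One upper-tail hypergeometric engine: p = P(X ≥ k | N, K, n) for a term
with K genes, a query of n genes sharing k, in a universe of N; BH across
tested terms. Term maps are flat (no ontology-DAG propagation — supply
pre-propagated maps if needed); terms below 3 genes are skipped by
default; query genes outside the universe are dropped with a warning.

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, plus exact truth tables.

* **Counts** — negative binomial with variance μ + μ²·φ (φ = dispersion,
  default 0.1, a conventional bulk RNA-seq value; the emulated study did
  not report per-gene dispersions). Per-gene baselines vary log-normally
  (σ = 0.5) around `baseline_mean` (default 100). Planted profiles
  multiply the up-group means by 2^effect (default effect_log2fc = 3).
  Default fractions: 10% female-biased, 5% male-biased, 5% juvenile-biased
  (females dominating the DE landscape, as in the emulated system).
  Gene lengths are uniform on 300–3000 nt. Identical config ⇒ identical
  output.
* **Proteomes** — background proteins are uniform random sequences with a
  GO flag and a non-cuticular domain (so the unannotated filter excludes
  them by construction); CPR/CPAP proteins carry the corresponding domain
  accessions; CPH-like proteins carry no annotation, a signal peptide,
  an extracellular flag, a top-decile mean TPM and one planted trait
  (literal motif insertion — AAP(A/V/L) runs, glycine-rich cysteine-free
  bodies, or PV/PY repeats — which is simpler than a trait-conditioned
  sequence model and sufficient for rule testing).
* **BLAST tables** — planted HGT genes get a donor-group hit at the
  requested bitscore above their invertebrate best; all other genes get
  an invertebrate hit dominating every non-metazoan hit, so their h-index
  is ≤ 0. Only the three meaningful columns vary; the other nine outfmt-6
  columns hold plausible constants.

What the simulations do **not** emulate: read-level noise and mapping
artifacts, correlated gene–gene expression beyond the planted profiles,
batch effects, partial annotation (every simulated protein is cleanly
annotated or cleanly unannotated), and realistic BLAST score
distributions. Passing recovery tests therefore demonstrates that the
screens implement their rules correctly and are calibrated under the
assumed noise model — not that the rules themselves are complete for real
proteomes.

## Problem sizes and numerical choices

The reference recovery experiment is 2000 genes × 12 samples (planted
effect 3 log2 units, dispersion 0.1), where stage-flag recovery is
97–99% and the flat-gene false-call rate 0% across seeds; the CPH screen
is scored on 5 planted candidates among 500 background proteins and the
HGT screen on 20 planted donors among 500 queries (both recover exactly).
MCL sanity uses disjoint cliques and a two-clique barbell checked against
a naive reference iteration. These sizes make the whole suite and the
acceptance script run in seconds while leaving every statistical margin
wide.

Tolerances and tie-breaks worth knowing: BH and hypergeometric values are
checked against brute-force oracles to 1e-12; MCL pruning at 1e-5 and
convergence at 1e-8; hierarchical-cluster and curation ties break by
input order / lowest id; degenerate two-group tests (no within-group
variance anywhere) return p = 1 when the means are equal and p = 0
otherwise.

## Known limitations

* The DE stand-in shares the moderation *idea* with count-model engines
  but not their likelihoods; p-values are not comparable to DESeq2's.
* TPM-scale fold changes carry compositional bias when a large fraction
  of the transcriptome shifts; the test is protected (median-of-ratios),
  the reported fold changes are not.
* Correlation on four stage means saturates quickly; r ≥ 0.9 edges are
  dense among co-trending genes, and MCL cluster counts on such graphs
  are sensitive to inflation.
* The CPLCP rule and all trait thresholds are operational conventions;
  they recover planted signals exactly but have not been tuned against
  curated real-proteome labels.
* The HGT screen inherits every bias of its input databases (taxon
  coverage, contamination); h-index passing is a screen, not a
  phylogenetic demonstration of transfer.
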