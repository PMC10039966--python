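# Methods

## Analysis model

The unit of analysis is one contrast: an aneuploid strain against a diploid
control measured by bulk RNA-seq, summarized as FPKM per gene per sample.
Replicate structure lives in a sample sheet; a strain's expression level is
the arithmetic mean FPKM over its replicates. All downstream quantities are
functions of these strain means plus a per-gene p-value.

**Cis/trans partition.** A karyotype config names each strain's extra
chromosome(s). Genes annotated to an extra chromosome are *cis*, all other
annotated genes *trans*. For euploid strains descended from an aneuploid
(e.g. offspring that regained the normal karyotype), a `reference_extra`
argument designates the formerly extra chromosome so its genes can still be
analysed as the cis panel; supplying it for a strain that actually carries
extra chromosomes is rejected as ambiguous. Genes present in the matrix but
absent from the annotation are retained for differential analysis and
excluded from the partition, with a logged count — the partition requires a
chromosome assignment, the DEG call does not.

**Ratio distributions.** For a gene subset, ratios `case_mean / ctrl_mean`
are formed over genes with mean FPKM > 0 in *both* strains (the symmetric
rule is the only one under which every ratio is defined; it also avoids an
artifactual spike at zero). Ratios are binned half-open `[a, a + w)` with
`w = 0.05`, anchored at 0, capped at 3.0 with an overflow pool so no gene is
lost; `sum(counts) + overflow = n_genes` always holds. Both raw counts and
normalized frequencies are emitted, since "frequency per bin" is ambiguous
between the two. The raw per-gene ratios are kept on the distribution
object so medians and demarcation fractions are binning-independent.

**Peak calls.** The default peak is the midpoint of the highest-count bin,
ties broken toward the lower ratio. Classification compares the peak
against the canonical demarcations with a tolerance of one bin width
(0.05): dosage effect at 1.50, compensation at 1.00, inverse at 2/3,
intermediate strictly between compensation and dosage, otherwise other.
A kernel-density peak (`method="kde"`, Gaussian kernel, bandwidth equal to
the bin width) is provided for flat or jittery histograms: the raw bin
mode carries ±1-bin discretization noise, so recovery statements about
noisy simulations use the KDE peak, which in our recovery experiments
classifies all three pure response classes correctly in 100/100 seeded
runs at 2,000 subset genes and replicate noise 0.1, where the raw mode
manages 92/100 for the 1.5× class.

**Extreme fractions.** Fractions below / within / above the printed
cutoffs 0.67 and 1.50 are computed from the raw ratios. The cutoffs are
used literally, so a ratio of exactly 2/3 (= 0.6667) counts as "below
0.67"; for the stress-like gene sets these fractions were designed for
(multipliers < 0.5 or > 2) the distinction is immaterial.

**DEG calling.** A gene is *up* when `ratio ≥ fold` and `p ≤ α`, *down*
when `ratio ≤ 1/fold` and `p ≤ α` (defaults fold = 1.5, α = 0.05, both
boundaries inclusive), *unexpressed* when either strain mean is 0,
otherwise *ns*. The default p-value is a two-sided Welch t-test on
`log2(FPKM + 1)` across replicates; pseudocount 1 keeps zeros finite and
the log scale matches the multiplicative noise model. The original
count-model machinery of upstream DE tools is intentionally out of scope:
an `external` mode ingests any per-gene p-value table, and every
downstream analysis consumes only `(ratio, p)`. Raw p-values gate DEG
status — no multiple-testing correction, matching the thresholding
convention this design follows — while BH q-values are computed and
reported for transparency. When both groups have zero within-group
variance (e.g. noise-free simulations) the t statistic is undefined and p
is reported as 1.0: without variance there is no evidence scale, and a
clean fold change alone never reaches significance.

**Strata.** Expressed genes are stratified on the diploid mean with
half-open boundaries: low `0 < FPKM ≤ 10`, medium `10 < FPKM ≤ 100`, high
`FPKM > 100` (boundaries configurable). Per-stratum percentages are rounded
half-up to two decimals, the convention used for printed percentages.
Stratum-vs-stratum log2 fold-change comparisons use the two-sided Wilcoxon
rank-sum test: exact null when the combined n ≤ 20, normal approximation
with continuity correction above.

**Set operations.** Venn decompositions of 2–4 labeled DEG sets are exact
set algebra (verified against inclusion–exclusion by property test).
Compensated genes are cis genes expressed in both strains with `p ≥ 0.05`;
a `scope="all"` flag widens to every expressed gene because the published
compensated-gene counts do not state their universe. Over-representation is
the upper-tail hypergeometric with BH FDR across terms; the universe
defaults to the contrast's expressed genes, standard practice for
over-representation. Term semantics are whatever GMT the user supplies; no
ontology structure is modelled.

**Clustering.** Strains are embedded as vectors of `log2(mean FPKM + 1)`
over the union of genes dysregulated in at least one contrast, rows
z-scored (constant rows set to 0), then clustered agglomeratively with
euclidean distance and complete linkage — the defaults of the common
clustered-heatmap tools, since the upstream description names the tool but
not its parameters. Distance, linkage, row scaling and a replicate-level
mode are all flags; strain means are the default because the reference
layout shows one column per strain.

## Synthetic data

The generator emulates the study design directly rather than the
sequencing process:

- **Baseline.** Per-gene diploid mean `exp(N(μ, σ²))` with natural-log
  defaults μ = 1.5, σ = 1.5 — chosen so all three FPKM strata are populated
  (≈70% low, ≈28% medium, ≈2% high).
- **Chromosomes.** 12 chromosomes, genes assigned by configurable weights
  (uniform by default). Recovery experiments that need ≥ 2,000 cis genes
  weight half the genes onto the extra chromosome.
- **Responses.** Per strain, cis genes draw from a mixture over
  {dosage effect ×1.5 exactly, compensated ×1.0, intermediate
  ~ U(1.0, 1.5)} and trans genes from {inverse ×2/3, unchanged ×1.0,
  direct ×1.5, extreme: half U(0.2, 0.5), half U(2, 4)}. The default
  seven-strain panel mirrors a parental/filial trisomy-11/-12 study:
  parental trisomics lean intermediate in cis with a broad inverse trans
  component; filial trisomics shift toward compensation with a stronger
  inverse component; karyotypically normal offspring keep a mild trans
  dysregulation; the wild type is all-unchanged.
- **Condition effect.** `de_signal_fraction` (default 0) marks a random
  gene fraction with an independent ×2 or ×0.5 effect; these genes are
  labelled class `extreme` so every truth class keeps its exact multiplier
  contract.
- **Replicates and noise.** Two replicates per strain, each multiplied by
  unit-mean log-normal noise `exp(N(−s²/2, s²))`, so expected values are
  exactly `baseline × multiplier` at any noise level and *exact* at
  `s = 0`. The default `s = 0.15` was chosen a priori to land replicate
  Pearson correlations in the 0.90–0.99 band typical of bulk RNA-seq
  biological replicates.
- **Determinism.** One `numpy` Generator stream per run, seeded once.

What the simulator does **not** model: library-size or length biases,
count overdispersion, gene–gene correlation, chromosomal position effects,
and any read-level artifacts. Passing recovery tests therefore demonstrate
that the analysis correctly inverts the generative model it targets — not
that it is robust to normalization failures or correlated noise in real
data.

## Problem sizes and numerical conventions

- Zero-noise recovery runs use 5,000 genes; noisy peak-recovery uses
  ≥ 2,000 subset genes × 100 seeds; co-clustering uses 1,200 genes × 50
  seeds — sizes at which the asserted statistical properties are stable.
- Bin assignment uses `floor(round(r/w, 9))` so a ratio exactly equal to a
  representable bin edge (e.g. 1.5/0.05) opens its bin instead of falling
  one below through floating-point error; boundaries within 1e-9 of an
  edge snap to it.
- Ties in the histogram mode break toward the lower ratio; KDE mode is
  evaluated on a grid one-tenth of a bin wide.
- Percentages round half-up via decimal arithmetic, not banker's rounding.
- Chromosome names are canonicalized case-insensitively (`Chr11` → `11`,
  leading zeros stripped from numerals); normalization is idempotent.

## Known limitations

- FPKM is taken as given; no between-sample normalization is applied, so
  systematic library-size distortions propagate directly into ratios.
- With two replicates per group the Welch test is underpowered and its
  degrees of freedom minimal; the external p-value mode is preferable
  whenever a count-based DE tool's output is available.
- Peak classification with one-bin tolerance cannot distinguish
  compensation from an unchanged trans response (both sit at 1.0), and an
  intermediate peak within 0.05 of either demarcation is absorbed by it.
- The compensated-gene definition (p ≥ 0.05) deliberately accepts the
  null; it flags absence of evidence for change, not evidence of active
  buffering.
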