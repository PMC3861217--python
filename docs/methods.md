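# Methods

This note records the models and procedures implemented in `symbiovar`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions that were genuinely open.

## Consensus calling and alignment masking

Per-strain genomes are reference-based: a consensus sequence has exactly the
reference length, substitutions and ambiguities replace single bases, and
deletions surface as `N`. The consensus rule for a pileup column is:

- `N` if total depth < `min_depth` (default 10) or > `max_depth` (default
  100). The lower bound guards against undersampled columns, the upper
  against collapsed repeats and mapping artefacts.
- otherwise the plurality base if its fraction of the column depth is at
  least `plurality_fraction` (default 0.8);
- otherwise the two-base IUPAC code of the two most frequent bases. Ties are
  broken alphabetically, which makes the caller deterministic.

The published analyses this mirrors used a quality-aware pileup consensus
tool of which only the depth bounds are documented; the depth-bounded
plurality rule is this package's documented stand-in. It reproduces both hard
calls and the shared "ambiguous nucleotide" calls that appear in such
datasets without modelling base qualities. `plurality_fraction = 0.8` makes a
0.5/0.5 mixed column ambiguous and a 5-in-30 minor count invisible, which
matches the intuition that a clonal symbiont sample is either fixed or
genuinely mixed.

Merging consensus genomes into an alignment is positional (no realignment is
needed because all sequences share reference coordinates). Columns containing
`N` in **any** strain — fully ambiguous calls or deletions relative to the
reference — are removed; non-`N` IUPAC codes are retained so that shared
ambiguous alleles remain visible to the variant stage. The surviving columns
carry a strictly increasing `column_map` back to 1-based reference
coordinates (GenBank convention, used throughout the package).

Consequences worth noting: variation inside deleted or low/high-depth regions
of *any* strain is invisible to all strains, and insertions relative to the
reference cannot be represented at all. This is the standard trade-off of
reference-based assembly of near-clonal genomes.

## Clade variants and coding effects

A **fixed difference** between clades A and B is a variant column where all
A-strains share one allele, all B-strains share another, and the two differ.
Under the default `shared-ambiguous-allowed` policy a clade whose members all
carry the *same* IUPAC code counts as carrying that code as its allele, and
the site is flagged; `strict` mode drops such sites. The default matches how
shared ambiguous calls are footnoted, rather than discarded, in published
variant tables.

Coding effects substitute the alternative allele into its codon
(reverse-complementing on minus-strand genes), translate ref and alt codons
with the bacterial genetic code (NCBI translation table 11 — appropriate for
an α-proteobacterium), and classify as synonymous, non-synonymous, nonsense
(gain of stop) or stop-loss. The amino-acid position is codon index + 1. A
site in overlapping genes produces one call per gene. Pseudogenes count as
genic for mapping but are excluded from effect classification by default
(their reading frame is not trustworthy); both are reported. Summary counts
treat nonsense and stop-loss as non-synonymous, consistent with published
tallies that list them in the non-synonymous table.

The classifier is verified against an independent oracle that translates the
entire mutated CDS and diffs the protein, over 1,000 random substitutions.

## Copy-number segmentation

Read depth is summed into non-overlapping bins (default 200 bp; a trailing
partial bin is dropped). Segmentation is a mean-shift procedure: each bin's
value is iteratively replaced by a depth-weighted local mean with a kernel
that is Gaussian in bin index (sd = `bandwidth`, default 8 bins, truncated at
3 sd) and Gaussian in current value (sd = `depth_bandwidth`, default
√(mean depth), the Poisson scale). Iteration stops when the largest update
falls below 10⁻³ of the mean depth or after 200 iterations (with a warning).
Bins converge to local modes; mode changes larger than half the Poisson scale
define candidate breakpoints. Two clean-up passes follow:

1. runs shorter than `min_segment_bins` (default 3) — isolated Poisson
   outliers that survive as their own mode — are absorbed into the
   neighbouring segment with the closer mean;
2. adjacent segments whose raw means differ by less than `merge_threshold`
   (default 0.25, relative) are merged, most-similar pair first.

Defaults were chosen so that a flat Poisson profile yields a single segment
while a ≥2-fold amplification of ≥5 bins is kept; the test suite checks the
breakpoints against an exhaustive two-changepoint Poisson likelihood scan on
small profiles, and recovery of planted copy numbers 2–7 at per-bin mean ≥ 30
to within 10% with breakpoints within one bin.

Copy number is the segment mean over the **median** of background bins
(median for robustness against residual CNVs); background bins are those in
segments whose mean is within 25% of the genome-wide median. Significance is
a two-sided Welch *t* test of segment bins vs background bins, Bonferroni
corrected across candidate segments; identical groups short-circuit to p = 1,
and single-bin candidates report NaN (no within-segment variance exists).
Breakpoints are reported at bin boundaries — the precision the binning
supports.

Split-read SV candidates enter as a per-strain support matrix (the detection
step itself is out of scope); the filter keeps candidates with maximum
support ≥ 10 reads and, by default, at least one zero-support strain. The
monophyly check asks whether the carrier set equals the leaf set of one clade
of a given rooted strain tree (single carriers are trivially monophyletic;
an empty carrier set is defined false) — true variants should have arisen
once. The flank-repeat search finds maximal exact matches ≥ `min_length`
between windows immediately up- and downstream of an amplified interval
(window = interval length by default), direct orientation by default,
seed-and-extend with 24-mer anchors.

## qPCR relative quantification

Technical replicates are averaged on the Ct scale (Ct is already
logarithmic); a well group is flagged when the replicate SD exceeds 0.5
cycles or any replicate is below detection. Relative quantity of sample *s*
vs calibrator *c* for target gene *t* with reference gene *r*:

ratio = E_t^(Ct_t,c − Ct_t,s) / E_r^(Ct_r,c − Ct_r,s)

Efficiencies default to 2.0 (perfect doubling), making the formula reduce to
2^−ΔΔCt; per-gene efficiencies in (1, 2] may be supplied. Below-detection
wells propagate a censored marker and are never imputed into statistics.
Copy-number panels report per-replicate ratios and per-(sample, gene)
medians. The round trip through the generator is exact at zero noise and
recovers a 7-fold copy number with < 10% median error at 0.2-cycle noise.

## Survival analysis

Hazard ratios come from a Cox proportional-hazards partial-likelihood fit
(lifelines; Efron tie handling — relevant because survival is recorded at
daily resolution) with the line and the experiment replicate as fixed
effects, treatment-coded against a designated baseline line. Replicate vials
are handled with a cluster-robust sandwich variance on vial (the default
policy). A shared-frailty formulation is the classical alternative; the
installed survival stack does not provide frailty terms, and the
cluster-robust estimator targets the same inferential problem (within-vial
correlation), so it is the package's default rather than a fallback. The
policy is recorded in the output. Lines with zero events are flagged
inestimable and excluded.

All-pairs comparisons of the log hazard ratios use single-step
maximum-statistic adjustment: p_adj(z) = P(max_m |Z_m| ≥ |z|) over the family
of pairwise contrasts. The default evaluates this under a one-factor
equicorrelation approximation (mean off-diagonal correlation of the contrast
statistics, one-dimensional Gaussian quadrature); an exact-correlation
Monte-Carlo evaluation with a fixed internal seed is available
(`method="mc"`). Letters are assigned by insert-and-absorb so that two lines
share a letter **iff** their adjusted comparison is non-significant (α = 0.05,
two-sided); letters are ordered by increasing hazard ratio.

## Clustering, correlations, growth

Phenotype matrices (variants × metrics) are z-scaled per column (mean 0,
sample SD 1; a zero-variance column is an error naming the column), clustered
by complete linkage on Euclidean distances, and cut into *k* groups; scipy's
deterministic condensed-distance ordering breaks ties by row order. Pearson
correlations report raw and Bonferroni-adjusted p (min(1, m·p) for a family
of m tests).

Growth comparison fits titre ~ age and log(titre) ~ age by OLS with
group × age interactions against a reference group. Model preference uses AIC
on the common raw-titre scale: the log model's likelihood is corrected by the
Jacobian of the log transform (AIC_log + 2·Σ log y). AIC was chosen because
the model pairs are non-nested on a common scale; no particular criterion is
canonical here. Doubling time is ln 2 / (natural-log-scale slope), defined
only for positive slopes (∞ otherwise). Group contrasts of log titres with
replicate structure use a REML linear mixed model (random line intercept),
falling back to OLS with a warning when only one replicate per line exists.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions the acceptance checks run under.

- **Scale**: 100 kb linear genome, 40 non-overlapping CDS features (300–900
  bp, both strands, ~5% marked pseudogenes), a 21 kb cassette of 8 genes
  flanked by two identical 1912 bp direct repeats, carried at 7 tandem copies
  by the last clade-B strain. This is large enough to exercise every stage in
  seconds; the real genome is ~1.27 Mb, so per-gene collision statistics (how
  many distinct genes 59 non-synonymous SNPs hit) do not transfer.
- **Clades**: sizes (4, 5) matching the nine-strain study design. Clade A
  carries the reference allele at every fixed-difference site (the reference
  genome derives from an A-clade strain); clade B the alternative. The
  planted composition can be controlled exactly, e.g. (59 non-synonymous, 24
  synonymous, 25 intergenic) = 108 — planting coding categories searches
  codons so the category is true by construction. Private SNPs and ambiguous
  (IUPAC) sites are planted per-bp per strain; deletions (1–30 bp) are planted
  clade-fixed; exact counts of carrier-unique SNPs (2) and ambiguous sites
  (6) reproduce the wMelPop-like contrast. No events are planted inside the
  flank repeats, keeping them identical.
- **Depth**: per-position depth ~ Poisson(λ), default λ = 30 (well inside the
  [10, 100] consensus bounds); binned counts ~ Poisson(CN · λ · width).
  Sequencing errors are off by default; an optional uniform substitution rate
  exercises ambiguity handling.
- **Ct values**: Ct = c₀ − log_E(quantity) + N(0, sd), default E = 2,
  sd = 0.2 cycles, 3 technical replicates — the replicate structure of a
  384-well design.
- **Survival**: exponential event times with hazard
  baseline · exp(lnHR + frailty), observed as whole days (daily checks),
  censored at a 60-day horizon; 10 vials × 10 flies per line. Vial frailty
  defaults to 0 (pure fixed-effects truth) so estimator calibration can be
  tested cleanly; log-normal frailty is available.
- **Growth**: titre = a + b·t + ε or exp(a + b·t + ε).

Not emulated: read-level artefacts (mapping bias, GC-dependent coverage,
duplicates, base-quality structure), within-sample heterogeneity of symbiont
populations, non-exponential survival shapes, and plate/batch effects in
qPCR. Passing tests therefore demonstrate correctness of the algorithms under
the stated statistical model, not robustness to those real-data artefacts.

Determinism: a fixed `SimConfig` (including seed) yields byte-identical
output files; all stages draw from seeded generators in a fixed order.

## Known limitations

- Insertions relative to the reference are out of scope end to end.
- The copy-number baseline (background median) and the mean-shift bandwidth
  are exposed parameters because no canonical values exist; results at
  2-fold amplifications with < 30 expected reads per bin become sensitive to
  them.
- The published flank-repeat length (1912 bp) is inconsistent with its
  printed coordinates (which span 1,918 bp); the repeat finder reports
  computed lengths and does not arbitrate. The generator plants 1912 bp.
- The equicorrelation adjustment is an approximation; with very unbalanced
  designs, use `method="mc"`.
- Cox estimates at daily resolution rely on Efron's tie correction; with
  very coarse grids (most deaths sharing a handful of days) a discrete-time
  model would be more appropriate.
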