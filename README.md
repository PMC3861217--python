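# symbiovar

Comparative genomics and phenotype integration for closely related clades of a
bacterial endosymbiont, built around the *Wolbachia* wMel system in
*Drosophila melanogaster*: the wMel strain comprises two monophyletic groups
of near-identical variants ("wMel-like" and "wMelCS-like") that differ in
antiviral protection, within-host titre and effect on host lifespan, and a
laboratory variant (wMelPop) that over-replicates because a ~21 kb
repeat-flanked region ("Octomom") is tandemly amplified.

`symbiovar` is for researchers who need to turn reference-based resequencing
of such near-clonal symbionts, plus qPCR and phenotype assays, into the
quantities that discriminate the clades:

- **consensus & alignment** — per-strain consensus genomes from pileup tables
  under read-depth bounds (positions with depth outside [10, 100] become `N`;
  a plurality base is called at fraction ≥ 0.8, otherwise a two-base IUPAC
  code), and positional multiple alignments with every `N`-containing column
  removed and mapped back to reference coordinates.
- **clade variants** — polymorphic sites, *fixed differences* (sites where
  every member of clade A shares one allele and every member of clade B a
  different one), strain-unique SNPs, gene/intergenic mapping, and coding
  effects under the bacterial genetic code (translation table 11).
- **copy-number variation** — mean-shift segmentation of 200 bp binned read
  depth into piecewise-constant copy-number segments, fold estimates relative
  to the background median, Welch *t* significance with Bonferroni
  correction, exact direct-repeat search around amplified intervals, and
  split-read SV candidate filtering (max support ≥ 10 and one zero-support
  strain) with a tree-based monophyly check.
- **qPCR quantification** — efficiency-corrected relative quantities,
  ratio = E_target^ΔCt(target) / E_ref^ΔCt(ref) with ΔCt measured calibrator
  minus sample (the 2^−ΔΔCt rule when both efficiencies are 2).
- **phenotype statistics** — Cox proportional-hazard log hazard ratios with
  experiment fixed effects and vial-cluster-robust variance, all-pairs
  single-step (Tukey-style) comparisons summarized as a compact letter
  display, Kruskal–Wallis/Wilcoxon–Holm rank tests, z-scaled Euclidean
  complete-linkage clustering of variant phenotype matrices,
  Bonferroni-corrected Pearson correlations, linear vs log-linear growth
  model comparison with doubling times (ln 2 / slope), and REML mixed-model
  group contrasts on log titres.
- **synthetic data** — a generator that emulates every input with known
  planted truth (two clades with planted fixed SNPs/indels/ambiguities, a
  repeat-flanked amplified cassette, Poisson depth proportional to copy
  number, Ct values under an efficiency model, clustered survival under
  proportional hazards, titre time courses), so the whole pipeline is
  testable without any external data.

## Worked example

Generate a nine-strain synthetic study (two clades, 108 planted fixed
differences of which 59 non-synonymous and 24 synonymous in genes and 25
intergenic, 7 clade-fixed deletions, and a 7-copy cassette in one strain),
then run the genomic pipeline end to end:

```python
from symbiovar.synthgen import SimConfig, generate_dataset
from symbiovar.consensus_align import build_consensus, mask_ambiguous_columns
from symbiovar.clade_variants import (extract_variants, fixed_differences,
    classify_fixed_differences, summarize_differences)
from symbiovar.cnv_detect import call_cnv, flanking_repeats

cfg = SimConfig(seed=1,
                clade_a_names=("wMel", "wMel2_a", "wMel2_b", "wMel3"),
                clade_b_names=("wMelCS_a", "wMelCS_b", "wMelCS2_a", "wMelCS2_b", "wMelPop"),
                n_fixed_diffs=108, fixed_diff_composition=(59, 24, 25), n_indels=7,
                carrier_unique_snps=2, carrier_ambiguous_sites=6)
ds = generate_dataset(cfg)

consensus = [build_consensus(ds.pileups[s], cfg.genome_length, s)
             for s in cfg.strain_names]
aligned = mask_ambiguous_columns(consensus)
table = extract_variants(aligned, ds.reference)
diffs = fixed_differences(table, list(cfg.clade_a), list(cfg.clade_b))
effects = classify_fixed_differences(diffs, ds.features, ds.reference)
print(summarize_differences(effects, n_indels=cfg.n_indels))

for s in call_cnv(ds.depth_profiles["wMelPop"]):
    print(f"{s.start_bp:>6}-{s.end_bp:<6} CN={s.copy_number:.2f} p={s.p_value}")
print(flanking_repeats(ds.reference, cfg.cassette_interval, min_length=500))
```

Output:

```
{'total_snps': 108, 'genic_snps': 83, 'intergenic_snps': 25, 'non_synonymous': 59,
 'genes_with_nonsyn': 30, 'indels': 7}
     1-60000  CN=1.00 p=None
 60001-81000  CN=7.00 p=1.0931262898697994e-250
 81001-100000 CN=1.00 p=None
[RepeatPair(left=(58088, 59999), right=(81000, 82911), length=1912,
            orientation='direct', identity=1.0)]
```

The summary counts are exactly the planted truth: all 108 clade-fixed SNPs
survive consensus calling and masking, 83 fall in genes and 59 change an
amino acid. The depth segmentation recovers the amplified cassette at its bin
boundaries with a 7.00-fold copy-number estimate (Welch *t* against the
background bins, p ≈ 10⁻²⁵⁰), and the repeat search finds the planted pair of
identical 1912 bp direct repeats flanking it — the configuration that enables
tandem amplification by unequal recombination.

A `symbiovar` command-line interface wraps each stage
(`simulate`, `consensus`, `mask`, `variants`, `cnv`, `svfilter`, `qpcr`,
`survival`, `cluster`, `growth`); run `symbiovar --help` for details.

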