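# evoenrich

Enrichment of evolutionary signatures in trait-associated genomic
regions, scored against empirical null distributions matched on minor
allele frequency (MAF) and linkage-disequilibrium (LD) structure.

## Who this is for

You have a set of genomic regions from a genome-wide assay — GWAS
summary statistics are the canonical input — and one or more per-SNP
evolutionary scores (F_ST, XP-EHH, iES, Beta Score, allele-age/TMRCA,
PhyloP, PhastCons, GERP, LINSIGHT, or any genome-wide track of your
own). You want to know whether your regions carry more (or less) of a
signature than comparable regions of the genome. "Comparable" is the
crux: trait-associated regions are ascertained toward common variants in
strong LD, and both MAF and LD shape the power of evolutionary measures.
`evoenrich` builds the null from control SNPs matched to each region's
index SNP on MAF (±5 percentage points) and LD-buddy count (SNPs with
r² ≥ 0.9, ±50%), LD-expands each control into a control region, and
compares observed extremes to that matched background.

## The statistic

Input regions are LD-clumped from summary statistics (greedy, index SNP
= lowest p-value; defaults p1 = 5×10⁻⁸, p2 = 0.01, r² ≥ 0.5, 250 kb).
For a measure with extremity direction `max`/`min`/`absmax`, each
region's observed value is its most extreme SNP score. Per region, 5000
matched control regions give a background distribution of extremes, and
the region is scored as

- z = (observed − bg mean) / bg SD,
- empirical p = (1 + #{bg at least as extreme}) / (1 + 5000),
- Benjamini–Hochberg q across regions.

At the trait level, the mean (or max) of the observed extremes is
compared to 5000 matched sets (one control region drawn per input
region); enrichment is (observed − background mean) / genome-wide SD of
the measure, with the same empirical-p rule. Positive enrichment means
the trait regions are more extreme than their matched background, in
genome-SD units.

## Worked example

Everything runs on synthetic fixtures, so no downloads are needed.
Simulate a dataset with a +2.5 genome-SD signal injected into an
"xpehh"-like track at 6 trait regions, with two untouched tracks:

```sh
cat > sim.yaml <<EOF
n_haplotypes: 200
n_snps: 4000
n_blocks: 800
n_trait_regions: 6
signal_measures: [[xpehh, 2.5]]
measure_names: [xpehh, phastcons, fst]
EOF
evoenrich simulate --config sim.yaml --out fix --seed 11
evoenrich run --gwas fix/gwas.tsv --panel fix/panel.tsv \
    --measures fix/measures.yaml --out out \
    --n-controls 500 --n-sets 1000 --seed 4
```

`out/set_results.tsv`:

```
measure	summary_stat	observed_summary	bg_mean	bg_sd	enrichment	emp_p	n_sets
xpehh	mean	3.64223	1.14502	0.253955	2.46066	0.000999001	1000
phastcons	mean	0.819123	1.15126	0.260825	-0.332853	0.903097	1000
fst	mean	1.40749	1.16339	0.271675	0.247835	0.188811	1000
```

The injected measure is recovered: the trait regions' mean extreme
(3.64) sits 2.46 genome-SD units above its matched background, with the
empirical p at the attainable floor 1/(1000+1); the untouched measures
stay near zero with unremarkable p. The first rows of
`out/region_results.tsv` localize the signal per region:

```
region_id	measure	observed_extreme	bg_mean	bg_sd	zscore	emp_p	q_value	n_background
blk00453_0	xpehh	3.9911	1.09524	0.633714	4.56968	0.00199601	0.00239521	500
blk00441_0	xpehh	3.703	1.14229	0.589097	4.34684	0.00199601	0.00239521	500
```

Each row: the region's extreme score, its matched background moments,
the z-score, the empirical p (floor 1/501 at 500 controls), and the BH
q-value across regions. `out/` also contains `matching_report.tsv`
(per-region matching profile, counts, and any tolerance relaxation),
a region × measure z-score heatmap, a set-level radar plot, the verbatim
`run_config.yaml`, and a log.

Real inputs drop in the same way: `--panel` takes a phased VCF
(biallelic SNPs) or a haplotype-matrix TSV, `--gwas` any TSV with
CHR/POS/SNP/P columns (remappable via `--col-*`), and `--measures` a
YAML listing per-SNP score TSVs with their extremity directions. Large
inputs can be partitioned (e.g. per chromosome), run separately, and
combined with `evoenrich merge`.

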