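# Methods

## The problem

Genome-wide assays (GWAS, eQTL mapping, \*-seq peak calling) produce sets
of trait-associated genomic regions. Asking whether those regions carry
unusual signatures of evolutionary forces — allelic differentiation,
balancing selection, substitution-rate conservation — requires a null
expectation, and a naive genome-wide null is wrong: minor allele
frequency (MAF) and linkage disequilibrium (LD) influence both the power
to detect associations and the power to detect evolutionary signatures.
A region discovered by GWAS is, by construction, a common-variant,
high-LD region; comparing its conservation scores to random SNPs
confounds ascertainment with biology.

`evoenrich` builds empirical null distributions *matched* to each
region's allele-frequency and LD profile, and reports region- and
trait-level enrichment of any per-SNP evolutionary score against them.

## Procedure

1. **Clumping.** Input summary statistics are reduced to independent
   regions by greedy LD clumping: repeatedly take the unassigned SNP with
   the smallest p ≤ `p1` (default 5×10⁻⁸) as an index SNP, and assign to
   it all unassigned SNPs with p ≤ `p2` (0.01), within `kb_window`
   (250 kb), and r² ≥ `r2_clump` (0.5) with the index. r² is haplotype
   (phased) r² = D²/(p_A(1−p_A)p_B(1−p_B)) computed from the reference
   panel. Ties in p are broken by (chrom, pos), so output is independent
   of input row order.

2. **Matching.** Each index SNP's profile is its MAF and LD-buddy count
   (number of panel SNPs with r² ≥ `r2_buddy` = 0.9 within
   `ld_window_kb` = 1000 kb). For each region, `n_controls` = 5000
   control SNPs are sampled uniformly without replacement from panel SNPs
   with MAF within ±5 percentage points (absolute) and buddy count within
   ±50% (relative) of the profile. If fewer eligibles exist, tolerances
   relax stepwise (+1 MAF point, +10 buddy points per step, 5 steps max),
   each event logged and reported. Candidates exclude all trait-region
   members *and* their LD buddies at the expansion threshold, so no
   control region can overlap a trait region's LD neighbourhood.

3. **LD expansion.** Each control SNP becomes a matched region: the
   control plus all its buddies at `r2_expand` (default 0.9, kept equal
   to the buddy threshold so "in LD" has one meaning; configurable
   separately).

4. **Region-level enrichment.** For each measure, a region's observed
   statistic is the most extreme score among its SNPs (`max`, `min`, or
   `absmax` per measure; `absmax` preserves sign and suits signed scores
   like PhyloP). The same extreme over each matched region forms the
   background. Reported per (region, measure):
   - z = (observed − background mean) / background sample SD;
   - empirical p = (1 + #{background ≥ observed}) / (1 + B), one-sided in
     the extremity direction, ties counting as extreme. The +1
     pseudo-count is standard permutation-test practice and makes the
     attainable floor 1/(B+1) explicit;
   - Benjamini–Hochberg q across regions, per measure by default
     (`--fdr-scope pooled` corrects across measures too). Regions whose
     background has zero SD get an undefined z and are excluded from FDR.

5. **Set-level enrichment.** The observed set statistic is a summary
   (mean by default, max optional) of the per-region observed extremes.
   `n_sets` = 5000 matched sets are drawn — one matched region per input
   region, uniform, independent across regions and sets (with
   replacement, so `n_sets` is not capped by `n_controls`) — and
   summarized the same way. Enrichment = (observed − mean background
   summary) / genome-wide SD of the measure (sample SD over all scored
   SNPs), so positive values mean the trait set is more extreme than its
   matched background in genome-SD units. The empirical p uses the same
   +1/(B+1) rule.

The region-level z uses the background SD (it asks "how unusual is this
region among its matched controls"); the set-level enrichment uses the
genome-wide SD (it puts all measures on one comparable scale for the
radar view). Both background samples share the per-(region, control)
extremes, so every matched region is scored exactly once.

## Parameters that matter

| knob | default | unit | why |
| --- | --- | --- | --- |
| `n_controls` | 5000 | SNPs/region | background resolution; p floor 1/5001 |
| `n_sets` | 5000 | sets | set-level p floor 1/5001 |
| `maf_tol` | 0.05 | frequency (abs.) | ±5 MAF points; relative tolerance collapses for rare variants |
| `buddy_tol_rel` | 0.50 | fraction | count properties tolerate relative bands |
| `r2_buddy`, `r2_expand` | 0.9 | r² | definition of "LD buddy" / expansion |
| `ld_window_kb` | 1000 | kb each side | LD is local; bounds the pair scan. No canonical value exists; configurable |
| `clump_p1`/`p2`/`r2`/`kb` | 5e-8 / 0.01 / 0.5 / 250 | — | standard clump defaults with genome-wide significance for index SNPs |
| `summary_stat` | mean | — | mean suits polygenic sets; max flags single extreme loci |

## Synthetic data

`synthetic_fixtures` emulates the three inputs with exact control over
the features the method conditions on:

- **Panel**: blocks of SNPs; each block has a seed column drawn
  Bernoulli with frequency ~ Uniform(0.05, 0.5), other columns copy the
  seed with per-haplotype flip probability 1 − `within_block_copy_prob`.
  Blocks sit 2.5 Mb apart (≫ the LD window), so between-block r² is at
  the sampling floor and each block is one LD unit. Default 200
  haplotypes (100 phased diploids).
- **Tracks**: i.i.d. standard-normal baseline per SNP; signal measures
  add `effect × genome-SD` at every SNP of the designated trait blocks.
- **GWAS**: each designated trait block's seed SNP is a lead with
  p ∈ (10⁻¹², 10⁻⁹) log-uniform; its partners get p ∈ (6×10⁻⁸, 9×10⁻³);
  all other SNPs p ∈ (0.05, 1). Clumping at defaults therefore recovers
  exactly the designated regions, each led by its seed.

`within_block_copy_prob` defaults to 0.998, which makes within-block r²
≈ 0.99: the block is then a coherent LD unit, and a clumped trait region
(members at r² ≥ 0.5) and an LD-expanded control region (members at
r² ≥ 0.9) have the same expected size, which is what the calibration
properties of the method presume. At lower copy fidelity the two
definitions diverge — trait regions keep their full block while control
expansions shrink — and region/set empirical p-values drift
anti-conservative. That drift is a real property of applying the method
to panels whose blocks are weak proxies, not a code artifact; it is
visible in this generator by lowering `within_block_copy_prob`, and it
also appears at small haplotype counts, where sampled r² of a true-0.99
pair falls below the 0.9 threshold often enough to shrink expansions
(with 100 haplotypes, matched regions average ≈4.85 SNPs vs 5.0 for
trait regions).

What the generator does **not** emulate: realistic recombination maps or
coalescent genealogies (LD is block-diagonal by construction), allele
frequency–score correlations (real conservation scores correlate with
MAF), overlapping or nested LD blocks, and association p-values driven by
phenotype models. Passing tests therefore demonstrate the statistical
machinery — matching, null construction, calibration, signal recovery —
under controlled conditions, not performance on real human data.

## Numerical choices

- Haplotype r² is the squared Pearson correlation of 0/1 columns; the
  banded LD scan compares against the threshold with a 10⁻¹² slack so
  exact-threshold pairs are included deterministically.
- MAF/buddy eligibility predicates carry a 10⁻⁹ slack so boundary
  candidates (deviation exactly 0.05) qualify regardless of float
  representation.
- Sample (n−1) standard deviations throughout.
- Matching uses one independent, deterministically derived random
  substream per region (keyed by sorted region id), so results do not
  depend on region iteration order; the same applies to set draws.
- Monomorphic and non-biallelic panel records are dropped at load with a
  logged count; zero-variance tracks are rejected outright.
- Matched regions with no scored SNP have an undefined extreme and are
  dropped from backgrounds; `n_background` reports the effective count.
- Output floats are written at six significant digits; re-parsing
  reproduces exactly the written values, and identical config + seed
  gives byte-identical outputs.

## Problem sizes used in the test and acceptance runs

Simulation-based checks use reduced but representative sizes chosen for
desk-scale reproducibility: the default-parameter conformance run uses a
20k-SNP × 200-haplotype panel (50k SNPs in the acceptance script, which
guarantees ≥5000 base-tolerance eligibles even for leads whose realized
MAF drifts ~2σ from its target); null calibration uses 200 regions × 500
backgrounds and 100 replicate datasets at 2k SNPs each; signal recovery
uses 20 regions × 500 controls × 500 sets across 20 replicates.

## Known limitations

- The pair scan is windowed; true long-range LD (> `ld_window_kb`) is
  invisible to buddy counts, as in any windowed LD index.
- Matching uses MAF and buddy count only; gene density or distance to
  nearest gene are not matching properties here.
- Controls are drawn without replacement within a region but may recur
  across regions; for very rare profiles the relaxation ladder can
  exhaust at < `n_controls`, reported as an insufficient-matches
  fraction.
- Set draws are with replacement across sets, so distinct matched sets
  are not guaranteed (nor needed for the empirical null).
- Per-chromosome partitioning is supported by `merge`, which recomputes
  set-level enrichment from stored per-region background extremes; the
  merged run must come from chunks with identical tracks and panel.
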