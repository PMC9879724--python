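"""Synthetic panels, score tracks and summary statistics.

Emulates the three real inputs of the pipeline — a phased reference
panel, genome-wide evolutionary-measure tracks, and GWAS summary
statistics — with full control over the features that drive the method:

* **Block LD.**  Variants come in physical blocks.  Each block has a seed
  column drawn Bernoulli from a MAF distribution; the other columns copy
  the seed with independent per-haplotype flip noise (probability
  1 - ``within_block_copy_prob``), so within-block r² is tunable and
  between-block r² is at the sampling-noise floor.  Blocks are spaced
  far beyond the LD window, so LD never crosses blocks.
* **Score tracks.**  Baseline scores are i.i.d. standard normal per SNP.
  For each (measure, effect) pair in ``signal_measures``, ``effect``
  genome-SD units are added to every SNP inside the designated trait
  regions.
* **GWAS.**  The seed SNP of each trait block is a lead with p-value
  below genome-wide significance; its block partners get p in
  (5e-8, 0.01); every other SNP gets p uniform on (0.05, 1).  Clumping
  the output at default thresholds therefore recovers exactly the
  designated regions, each led by its seed.

All randomness flows from ``rng_seed`` through fixed named substreams, so
panels, tracks and GWAS are individually reproducible and mutually
consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clumping import GwasRecord
from .measures import MeasureCatalog, MeasureTrack, build_catalog
from .reference_panel import GenotypePanel

logger = logging.getLogger("evoenrich")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``signal_measures`` lists (measure name, effect size in genome-SD
    units); names must appear in ``measure_names``.  The MAF distribution
    is Uniform(``maf_min``, ``maf_max``); the default range (0.05, 0.5)
    spans common variation and guarantees matchable candidates.
    """

    n_haplotypes: int = 200
    n_snps: int = 10_000
    n_blocks: int = 2_000
    within_block_copy_prob: float = 0.998
    maf_min: float = 0.05
    maf_max: float = 0.5
    n_trait_regions: int = 20
    signal_measures: tuple[tuple[str, float], ...] = (("signal", 3.0),)
    measure_names: tuple[str, ...] = ("signal", "noise")
    rng_seed: int = 0
    # physical layout: blocks far apart so LD never crosses them
    blocks_per_chrom: int = 100
    block_spacing_bp: int = 2_500_000
    snp_spacing_bp: int = 1_000

    def __post_init__(self):
        if self.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (phased diploids)")
        if min(self.n_snps, self.n_blocks) < 1 or self.n_trait_regions < 0:
            raise ValueError("counts must be positive")
        if self.n_blocks > self.n_snps:
            raise ValueError("more blocks than SNPs")
        if self.n_trait_regions > self.n_blocks:
            raise ValueError("more trait regions than blocks")
        if not 0.0 <= self.within_block_copy_prob <= 1.0:
            raise ValueError("within_block_copy_prob must be in [0, 1]")
        if not 0.0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")
        known = set(self.measure_names)
        for name, _ in self.signal_measures:
            if name not in known:
                raise ValueError(f"signal measure {name!r} not in measure_names")

    def _seed(self, stream: int) -> list[int]:
        return [self.rng_seed & 0x7FFFFFFF, stream]


def _block_sizes(config: SimConfig) -> np.ndarray:
    base, extra = divmod(config.n_snps, config.n_blocks)
    sizes = np.full(config.n_blocks, base, dtype=np.int64)
    sizes[:extra] += 1
    return sizes


def _block_ids(config: SimConfig) -> list[list[str]]:
    return [
        [f"blk{b:05d}_{k}" for k in range(size)]
        for b, size in enumerate(_block_sizes(config))
    ]


def _block_layout(config: SimConfig, b: int, k: int) -> tuple[str, int]:
    chrom = str(b // config.blocks_per_chrom + 1)
    start = 1 + (b % config.blocks_per_chrom) * config.block_spacing_bp
    return chrom, start + k * config.snp_spacing_bp


def trait_blocks(config: SimConfig) -> list[int]:
    """Indices of the blocks designated as trait-associated regions,
    drawn once and reproducibly from the config seed."""
    rng = np.random.default_rng(config._seed(4))
    return sorted(
        rng.choice(config.n_blocks, size=config.n_trait_regions, replace=False).tolist()
    )


def trait_snp_ids(config: SimConfig) -> list[str]:
    """All SNP ids inside the designated trait regions."""
    ids = _block_ids(config)
    return [vid for b in trait_blocks(config) for vid in ids[b]]


def simulate_panel(config: SimConfig) -> GenotypePanel:
    """Generate the block-structured phased haplotype panel."""
    rng = np.random.default_rng(config._seed(1))
    H = config.n_haplotypes
    flip_p = 1.0 - config.within_block_copy_prob

    cols, ids, chroms, poss = [], [], [], []
    for b, size in enumerate(_block_sizes(config)):
        freq = rng.uniform(config.maf_min, config.maf_max)
        seed_col = (rng.random(H) < freq).astype(np.uint8)
        # a fixed column would be dropped at load, shifting ids: keep it polymorphic
        if seed_col.min() == seed_col.max():
            seed_col[rng.integers(H)] ^= 1
        for k in range(size):
            if k == 0:
                col = seed_col
            else:
                flips = (rng.random(H) < flip_p).astype(np.uint8)
                col = seed_col ^ flips
                if col.min() == col.max():
                    col = col.copy()
                    col[rng.integers(H)] ^= 1
            chrom, pos = _block_layout(config, b, k)
            cols.append(col)
            ids.append(f"blk{b:05d}_{k}")
            chroms.append(chrom)
            poss.append(pos)

    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return GenotypePanel(variants, np.stack(cols, axis=1))


def simulate_tracks(panel: GenotypePanel, config: SimConfig) -> MeasureCatalog:
    """Generate one track per configured measure name.

    Baseline scores are i.i.d. N(0, 1).  Signal measures get
    ``effect x genome_sd`` added at every SNP of every trait region,
    where genome_sd is the baseline track's sample SD.
    """
    rng = np.random.default_rng(config._seed(2))
    all_ids = [vid for block in _block_ids(config) for vid in block]
    trait = set(trait_snp_ids(config))
    effects = dict(config.signal_measures)

    tracks = []
    for name in config.measure_names:
        base = rng.standard_normal(len(all_ids))
        eff = effects.get(name, 0.0)
        if eff:
            sd = float(np.std(base, ddof=1))
            shift = np.array([eff * sd if vid in trait else 0.0 for vid in all_ids])
            base = base + shift
        tracks.append(
            MeasureTrack(name=name, scores=dict(zip(all_ids, base)), direction="max")
        )
    return build_catalog(tracks)


def simulate_gwas(panel: GenotypePanel, config: SimConfig) -> list[GwasRecord]:
    """Generate summary statistics with designated lead SNPs.

    Lead p-values are log-uniform on (1e-12, 1e-9); trait-block partners
    log-uniform on (6e-8, 9e-3); all other SNPs uniform on (0.05, 1).
    """
    rng = np.random.default_rng(config._seed(3))
    block_ids = _block_ids(config)
    trait = set(trait_blocks(config))

    records = []
    for b, ids in enumerate(block_ids):
        for k, vid in enumerate(ids):
            if vid not in panel:
                continue
            if b in trait and k == 0:
                p = 10.0 ** rng.uniform(-12, -9)
            elif b in trait:
                p = 10.0 ** rng.uniform(np.log10(6e-8), np.log10(9e-3))
            else:
                p = rng.uniform(0.05, 1.0)
            v = panel.variant(vid)
            records.append(GwasRecord(id=vid, chrom=v.chrom, pos=v.pos, pvalue=p))
    return records


@dataclass
class SimData:
    """One complete synthetic dataset plus its ground truth."""

    config: SimConfig
    panel: GenotypePanel
    catalog: MeasureCatalog
    gwas: list[GwasRecord]
    trait_blocks: list[int] = field(default_factory=list)
    lead_ids: list[str] = field(default_factory=list)


def simulate_dataset(config: SimConfig) -> SimData:
    """Convenience: panel + tracks + GWAS + truth in one call."""
    panel = simulate_panel(config)
    blocks = trait_blocks(config)
    ids = _block_ids(config)
    return SimData(
        config=config,
        panel=panel,
        catalog=simulate_tracks(panel, config),
        gwas=simulate_gwas(panel, config),
        trait_blocks=blocks,
        lead_ids=[ids[b][0] for b in blocks],
    )


# -- fixture directory writer ---------------------------------------------


def write_panel_tsv(panel: GenotypePanel, path: str | Path) -> None:
    hap_cols = {f"H{h}": panel.haplotypes[h, :] for h in range(panel.n_haplotypes)}
    df = pd.concat(
        [panel.variants[["id", "chrom", "pos"]].rename(
            columns={"id": "ID", "chrom": "CHROM", "pos": "POS"}
        ), pd.DataFrame(hap_cols, index=panel.variants.index)],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False)


def write_panel_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF (synthetic data)."""
    n_samples = panel.n_haplotypes // 2
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"S{i}" for i in range(n_samples))
            + "\n"
        )
        for i, row in panel.variants.iterrows():
            col = panel.haplotypes[:, i]
            gts = "\t".join(
                f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_fixture_dir(
    config: SimConfig, outdir: str | Path, write_vcf: bool = False
) -> Path:
    """Write a complete, self-contained fixture directory.

    Contains ``panel.tsv`` (and optionally ``panel.vcf``), one track TSV
    per measure, ``measures.yaml``, ``gwas.tsv`` and ``truth.yaml`` with
    the injected effects and designated lead SNPs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(config)

    write_panel_tsv(data.panel, out / "panel.tsv")
    if write_vcf:
        write_panel_vcf(data.panel, out / "panel.vcf")

    measures_cfg = []
    for track in data.catalog:
        tdf = pd.DataFrame(
            {
                "SNP": list(track.scores.keys()),
                "SCORE": list(track.scores.values()),
            }
        )
        tpath = out / f"track_{track.name}.tsv"
        tdf.to_csv(tpath, sep="\t", index=False)
        measures_cfg.append(
            {"name": track.name, "path": tpath.name, "direction": track.direction}
        )
    with open(out / "measures.yaml", "w") as fh:
        yaml.safe_dump(measures_cfg, fh)

    gdf = pd.DataFrame(
        {
            "SNP": [r.id for r in data.gwas],
            "CHR": [r.chrom for r in data.gwas],
            "POS": [r.pos for r in data.gwas],
            "P": [r.pvalue for r in data.gwas],
        }
    )
    gdf.to_csv(out / "gwas.tsv", sep="\t", index=False)

    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "trait_blocks": data.trait_blocks,
                "lead_ids": data.lead_ids,
                "signal_measures": [list(x) for x in config.signal_measures],
                "rng_seed": config.rng_seed,
            },
            fh,
        )
    logger.info("fixture directory written to %s", out)
    return out
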