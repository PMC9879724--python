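"""Pipeline orchestration: clump, match, score, write, plot, merge.

:func:`run_analysis` is the in-memory core — panel + summary statistics +
measure catalog in, region- and set-level results out.
:func:`run_pipeline` wraps it with file IO: it reads the three inputs,
writes ``region_results.tsv``, ``set_results.tsv``,
``matching_report.tsv``, ``region_backgrounds.tsv``,
``measure_stats.tsv``, ``run_config.yaml`` and a log, and renders the
heatmap / radar plots.  :func:`merge_runs` combines per-chunk runs (e.g.
per-chromosome) and recomputes the set-level enrichment over the union of
regions.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .clumping import (
    DEFAULT_KB_WINDOW,
    DEFAULT_P1,
    DEFAULT_P2,
    DEFAULT_R2_CLUMP,
    GwasRecord,
    Region,
    clump,
)
from .matching import (
    DEFAULT_BUDDY_TOL_REL,
    DEFAULT_MAF_TOL,
    DEFAULT_N_CONTROLS,
    MatchedRegion,
    MatchProfile,
    MatchResult,
    candidate_pool,
    match_regions,
)
from .measures import MeasureCatalog, read_measure_config, build_catalog, validate_track
from .reference_panel import (
    DEFAULT_LD_WINDOW_KB,
    DEFAULT_R2_BUDDY,
    GenotypePanel,
    build_ld_index,
    load_panel,
)
from .region_enrichment import RegionResult, background_extremes, region_extreme, score_regions
from .set_enrichment import DEFAULT_N_SETS, SetResult, score_set

logger = logging.getLogger("evoenrich")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; serialized verbatim into the output
    directory for provenance."""

    gwas: str = ""
    panel: str = ""
    measure_config: str = ""
    outdir: str = ""
    n_controls: int = DEFAULT_N_CONTROLS
    n_sets: int = DEFAULT_N_SETS
    maf_tol: float = DEFAULT_MAF_TOL
    buddy_tol_rel: float = DEFAULT_BUDDY_TOL_REL
    r2_buddy: float = DEFAULT_R2_BUDDY
    r2_expand: float = DEFAULT_R2_BUDDY
    ld_window_kb: float = DEFAULT_LD_WINDOW_KB
    clump_p1: float = DEFAULT_P1
    clump_p2: float = DEFAULT_P2
    clump_r2: float = DEFAULT_R2_CLUMP
    clump_kb: float = DEFAULT_KB_WINDOW
    summary_stat: str = "mean"
    fdr_scope: str = "per-measure"
    rng_seed: int = 0
    make_plots: bool = True
    gwas_columns: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.summary_stat not in ("mean", "max"):
            raise ValueError("summary_stat must be 'mean' or 'max'")
        if self.fdr_scope not in ("per-measure", "pooled"):
            raise ValueError("fdr_scope must be 'per-measure' or 'pooled'")
        for name in ("maf_tol", "r2_buddy", "r2_expand", "clump_r2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} = {v} outside (0, 1]")
        for name in ("n_controls", "n_sets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class AnalysisResult:
    """Everything one in-memory run produces."""

    regions: list[Region]
    matched: dict[str, list[MatchedRegion]]
    profiles: dict[str, MatchProfile]
    match_report: dict[str, MatchResult]
    region_results: list[RegionResult]
    set_results: list[SetResult]
    bg_extremes: dict[str, dict[str, np.ndarray]]
    observed_extremes: dict[tuple[str, str], float]


def run_analysis(
    panel: GenotypePanel,
    records: list[GwasRecord],
    catalog: MeasureCatalog,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Clump -> match -> LD-expand -> region scores -> set scores.

    The candidate pool excludes every member of every trait region plus
    those members' LD buddies at the expansion threshold, so no control
    region can overlap a trait region's LD expansion.
    """
    cfg = config or RunConfig()

    regions = clump(
        records, panel,
        p1=cfg.clump_p1, p2=cfg.clump_p2, r2_clump=cfg.clump_r2, kb_window=cfg.clump_kb,
    )
    if not regions:
        return AnalysisResult(
            regions=[], matched={}, profiles={}, match_report={},
            region_results=[], set_results=[], bg_extremes={}, observed_extremes={},
        )

    buddy_index = build_ld_index(panel, cfg.r2_buddy, cfg.ld_window_kb)
    expand_index = (
        buddy_index
        if cfg.r2_expand == cfg.r2_buddy
        else build_ld_index(panel, cfg.r2_expand, cfg.ld_window_kb)
    )

    excluded: set[str] = set()
    for region in regions:
        for vid in region.member_ids:
            excluded.add(vid)
            excluded.update(expand_index.buddies(vid))

    pool = candidate_pool(panel, buddy_index, excluded)
    profiles = {
        r.index.id: MatchProfile.of(r.index, buddy_index) for r in regions
    }
    matched, report = match_regions(
        profiles, pool, expand_index, panel,
        n_controls=cfg.n_controls, maf_tol=cfg.maf_tol,
        buddy_tol_rel=cfg.buddy_tol_rel, rng_seed=cfg.rng_seed,
    )
    n_unmatched = sum(res.unmatched for res in report.values())
    if n_unmatched:
        logger.warning("%d region(s) unmatched and excluded downstream", n_unmatched)

    bg_extremes = {
        t.name: background_extremes(matched, t) for t in catalog
    }
    observed: dict[tuple[str, str], float] = {}
    for track in catalog:
        for region in regions:
            if region.index.id not in matched:
                continue
            e = region_extreme(region.members, track)
            if e is not None:
                observed[(region.index.id, track.name)] = float(e)

    region_results = score_regions(
        regions, matched, catalog, fdr_scope=cfg.fdr_scope, bg_extremes=bg_extremes
    )
    set_results = (
        score_set(
            regions, matched, catalog,
            n_sets=cfg.n_sets, summary_stat=cfg.summary_stat,
            rng_seed=cfg.rng_seed, bg_extremes=bg_extremes,
        )
        if matched
        else []
    )
    return AnalysisResult(
        regions=regions, matched=matched, profiles=profiles, match_report=report,
        region_results=region_results, set_results=set_results,
        bg_extremes=bg_extremes, observed_extremes=observed,
    )


def _write_outputs(result: AnalysisResult, catalog: MeasureCatalog, out: Path) -> None:
    eio.write_region_results(result.region_results, out / "region_results.tsv")
    eio.write_set_results(result.set_results, out / "set_results.tsv")
    eio.write_matching_report(
        result.profiles, result.match_report, out / "matching_report.tsv"
    )
    eio.write_region_backgrounds(
        result.observed_extremes, result.bg_extremes, out / "region_backgrounds.tsv"
    )
    eio.write_measure_stats(
        {t.name: t.direction for t in catalog}, catalog.genome_sd,
        out / "measure_stats.tsv",
    )


def run_pipeline(config: RunConfig) -> Path:
    """File-to-file run.  Returns the output directory; raises with an
    actionable message naming the offending file on malformed input."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)
    try:
        panel = load_panel(config.panel)
        logger.info(
            "panel: %d variants x %d haplotypes", panel.n_variants, panel.n_haplotypes
        )
        records = eio.read_gwas_tsv(config.gwas, config.gwas_columns or None)
        logger.info("gwas: %d records", len(records))
        tracks = read_measure_config(config.measure_config)
        for t in tracks:
            validate_track(t, panel)
        catalog = build_catalog(tracks)

        result = run_analysis(panel, records, catalog, config)
        _write_outputs(result, catalog, out)
        config.to_yaml(out / "run_config.yaml")

        if config.make_plots:
            render_plots(result.region_results, result.set_results, out)
        logger.info(
            "run complete: %d regions, %d region results, %d set results",
            len(result.regions), len(result.region_results), len(result.set_results),
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


# -- plots -----------------------------------------------------------------


def render_plots(
    region_results: list[RegionResult],
    set_results: list[SetResult],
    outdir: str | Path,
) -> list[Path]:
    """Minimal renderings: a region x measure z-score heatmap (index SNPs
    as columns, measures as rows) and a set-level radar plot (one spoke
    per measure, radius = enrichment).  Empty results are skipped with a
    log note."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    written: list[Path] = []

    if region_results:
        measures = sorted({r.measure for r in region_results})
        regions = sorted({r.region_id for r in region_results})
        grid = np.full((len(measures), len(regions)), np.nan)
        for r in region_results:
            grid[measures.index(r.measure), regions.index(r.region_id)] = r.zscore
        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.35 * len(regions) + 2), max(3.0, 0.4 * len(measures) + 1.5))
        )
        im = ax.imshow(grid, aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(regions)), regions, rotation=90, fontsize=6)
        ax.set_yticks(range(len(measures)), measures, fontsize=8)
        ax.set_xlabel("index SNP")
        fig.colorbar(im, ax=ax, label="region z-score")
        fig.tight_layout()
        path = out / "region_heatmap.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    else:
        logger.info("no region results; heatmap skipped")

    if set_results:
        names = [r.measure for r in set_results]
        vals = [r.enrichment for r in set_results]
        angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(polar=True)
        theta = np.append(angles, angles[0])
        rho = np.append(vals, vals[0])
        ax.plot(theta, rho, "o-")
        ax.fill(theta, rho, alpha=0.25)
        ax.set_xticks(angles)
        ax.set_xticklabels(names, fontsize=8)
        ax.set_title("set-level enrichment (genome-SD units)", fontsize=9)
        fig.tight_layout()
        path = out / "set_radar.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    else:
        logger.info("no set results; radar plot skipped")
    return written


# -- merge -----------------------------------------------------------------


def merge_runs(
    input_dirs: list[str | Path],
    outdir: str | Path,
    n_sets: int | None = None,
    summary_stat: str | None = None,
    rng_seed: int | None = None,
    fdr_scope: str = "per-measure",
) -> Path:
    """Combine per-chunk runs (e.g. one per chromosome).

    Region results are concatenated and BH-corrected over the union of
    regions; set-level enrichment is recomputed from the stored
    per-region background extremes, drawing fresh matched sets across all
    regions.  Measure directions and genome-wide SDs must agree across
    inputs.
    """
    from .region_enrichment import bh_fdr
    from .set_enrichment import MatchedSets, set_empirical_p, set_enrichment_score, set_summaries, set_summary

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dirs = [Path(d) for d in input_dirs]
    if not dirs:
        raise ValueError("merge requires at least one input directory")

    directions: dict[str, str] = {}
    genome_sd: dict[str, float] = {}
    all_region_results: list[RegionResult] = []
    observed: dict[tuple[str, str], float] = {}
    bg: dict[str, dict[str, np.ndarray]] = {}
    base_cfg = eio_read_config(dirs[0] / "run_config.yaml")

    for d in dirs:
        dd, gs = eio.read_measure_stats(d / "measure_stats.tsv")
        for m in dd:
            if m in directions and (
                directions[m] != dd[m] or not math.isclose(genome_sd[m], gs[m], rel_tol=1e-9)
            ):
                raise ValueError(
                    f"merge: measure {m!r} inconsistent between inputs "
                    "(direction or genome SD differs)"
                )
            directions[m], genome_sd[m] = dd[m], gs[m]
        all_region_results.extend(eio.read_region_results(d / "region_results.tsv"))
        obs_d, bg_d = eio.read_region_backgrounds(d / "region_backgrounds.tsv")
        observed.update(obs_d)
        for m, per_region in bg_d.items():
            dup = set(bg.get(m, {})) & set(per_region)
            if dup:
                raise ValueError(f"merge: region(s) {sorted(dup)[:3]} appear in multiple inputs")
            bg.setdefault(m, {}).update(per_region)

    n_sets = n_sets if n_sets is not None else int(base_cfg.get("n_sets", DEFAULT_N_SETS))
    summary_stat = summary_stat or str(base_cfg.get("summary_stat", "mean"))
    rng_seed = rng_seed if rng_seed is not None else int(base_cfg.get("rng_seed", 0))

    # re-apply BH over the merged region table
    if fdr_scope == "pooled":
        groups = {None: [r for r in all_region_results if not math.isnan(r.zscore)]}
    else:
        groups = {}
        for r in all_region_results:
            if not math.isnan(r.zscore):
                groups.setdefault(r.measure, []).append(r)
    for rs in groups.values():
        if rs:
            for r, q in zip(rs, bh_fdr([r.emp_p for r in rs])):
                r.q_value = float(q)
    eio.write_region_results(all_region_results, out / "region_results.tsv")

    # recompute set level over the union of regions
    set_results: list[SetResult] = []
    rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, 202])
    region_ids = sorted({rid for m in bg for rid in bg[m]})
    lengths = {rid: len(next(iter(bg.values()))[rid]) for rid in region_ids}
    indices = np.empty((n_sets, len(region_ids)), dtype=np.int64)
    for r, rid in enumerate(region_ids):
        indices[:, r] = rng.integers(0, lengths[rid], size=n_sets)
    dummy_matched = {rid: [] for rid in region_ids}
    sets = MatchedSets(region_ids, indices, dummy_matched)
    for m in sorted(bg):
        obs_vals = [observed[(rid, m)] for rid in region_ids if (rid, m) in observed]
        if not obs_vals:
            continue
        obs_summary = set_summary(obs_vals, summary_stat)
        bgs = set_summaries(sets, bg[m], summary_stat)
        bgs = bgs[~np.isnan(bgs)]
        if bgs.size == 0:
            continue
        set_results.append(
            SetResult(
                measure=m, summary_stat=summary_stat, observed_summary=obs_summary,
                bg_mean=float(bgs.mean()),
                bg_sd=float(np.std(bgs, ddof=1)) if bgs.size > 1 else float("nan"),
                enrichment=set_enrichment_score(obs_summary, bgs, genome_sd[m]),
                emp_p=set_empirical_p(obs_summary, bgs, directions[m]),
                n_sets=int(bgs.size),
            )
        )
    eio.write_set_results(set_results, out / "set_results.tsv")
    eio.write_measure_stats(directions, genome_sd, out / "measure_stats.tsv")
    render_plots(all_region_results, set_results, out)
    return out


def eio_read_config(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
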