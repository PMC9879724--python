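"""Trait-level (set) enrichment against matched-set nulls.

The observed set statistic is a summary (mean by default, max optional)
of the per-region observed extremes.  The null is built from matched
sets: each set draws one matched control region per input region
(uniformly, with replacement across sets, independently across regions),
and the same summary is taken over the drawn regions' extremes.

Set enrichment = (observed summary - mean of background summaries)
divided by the measure's genome-wide standard deviation, so positive
values mean the trait regions are more extreme than their matched
background, in genome-SD units.  An empirical p-value uses the same
+1/(B+1) counting rule as the region level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matching import MatchedRegion
from .measures import MeasureCatalog
from .region_enrichment import (
    background_extremes,
    region_empirical_p,
    region_extreme,
)

logger = logging.getLogger("evoenrich")

DEFAULT_N_SETS = 5000
SUMMARY_STATS = ("mean", "max")


@dataclass
class SetResult:
    """Trait-level enrichment of one measure."""

    measure: str
    summary_stat: str
    observed_summary: float
    bg_mean: float
    bg_sd: float
    enrichment: float
    emp_p: float
    n_sets: int


class MatchedSets:
    """Matched sets encoded as an index matrix.

    Row s, column r holds which of region r's matched control regions
    belongs to set s.  ``region_ids`` fixes the column order.  Iterating
    (or indexing) yields one set as a mapping region id ->
    :class:`MatchedRegion`.
    """

    def __init__(
        self,
        region_ids: list[str],
        indices: np.ndarray,
        matched: dict[str, list[MatchedRegion]],
    ):
        self.region_ids = list(region_ids)
        self.indices = indices
        self._matched = matched

    def __len__(self) -> int:
        return self.indices.shape[0]

    def __getitem__(self, s: int) -> dict[str, MatchedRegion]:
        return {
            rid: self._matched[rid][self.indices[s, r]]
            for r, rid in enumerate(self.region_ids)
        }


def set_summary(extremes: list[float] | np.ndarray, stat: str = "mean") -> float:
    """Mean or max over the defined (non-NaN) region extremes."""
    if stat not in SUMMARY_STATS:
        raise ValueError(f"summary stat must be one of {SUMMARY_STATS}")
    vals = np.asarray(extremes, dtype=np.float64)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("set summary requires at least one defined extreme")
    return float(vals.mean() if stat == "mean" else vals.max())


def build_matched_sets(
    matched: dict[str, list[MatchedRegion]],
    n_sets: int = DEFAULT_N_SETS,
    rng_seed: int | np.random.Generator | None = None,
) -> MatchedSets:
    """Draw ``n_sets`` matched sets, one control region per input region.

    Draws are uniform over each region's matched list, independent across
    regions and across sets (with replacement), and reproducible from
    ``rng_seed``.  Every input region must have at least one matched
    region (unmatched regions are excluded upstream).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not matched:
        raise ValueError("no matched regions to draw sets from")
    if any(len(v) == 0 for v in matched.values()):
        raise ValueError("every region must have >= 1 matched region")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    region_ids = sorted(matched.keys())
    indices = np.empty((n_sets, len(region_ids)), dtype=np.int64)
    for r, rid in enumerate(region_ids):
        indices[:, r] = rng.integers(0, len(matched[rid]), size=n_sets)
    return MatchedSets(region_ids, indices, matched)


def set_summaries(
    sets: MatchedSets, bg_extremes: dict[str, np.ndarray], stat: str = "mean"
) -> np.ndarray:
    """Background summary per matched set for one measure.

    ``bg_extremes`` is the per-region extreme array from
    :func:`region_enrichment.background_extremes` (NaN where a matched
    region had no scored member; such draws are ignored by the summary).
    """
    mat = np.column_stack(
        [bg_extremes[rid][sets.indices[:, r]] for r, rid in enumerate(sets.region_ids)]
    )
    with np.errstate(invalid="ignore"):
        out = np.nanmean(mat, axis=1) if stat == "mean" else np.nanmax(mat, axis=1)
    return out


def set_enrichment_score(
    observed_summary: float, bg_summaries: list[float] | np.ndarray, genome_sd: float
) -> float:
    """(observed - mean background) / genome-wide SD; positive = trait
    regions above their matched background."""
    if genome_sd <= 0:
        raise ValueError("genome_sd must be positive")
    bg = np.asarray(bg_summaries, dtype=np.float64)
    if bg.size == 0:
        raise ValueError("background summaries must be non-empty")
    return float((observed_summary - bg.mean()) / genome_sd)


def set_empirical_p(
    observed_summary: float,
    bg_summaries: list[float] | np.ndarray,
    direction: str = "max",
) -> float:
    """Same +1/(B+1) counting rule as the region level, applied to set
    summaries."""
    return region_empirical_p(observed_summary, bg_summaries, direction)


def score_set(
    regions,
    matched: dict[str, list[MatchedRegion]],
    catalog: MeasureCatalog,
    n_sets: int = DEFAULT_N_SETS,
    summary_stat: str = "mean",
    rng_seed: int = 0,
    bg_extremes: dict[str, dict[str, np.ndarray]] | None = None,
) -> list[SetResult]:
    """Full set-level scoring across all measures.

    The matched sets (index draws) are shared across measures: a set is a
    collection of control regions, scored under each measure in turn.
    ``bg_extremes`` may supply precomputed per-measure extreme arrays.
    """
    rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, 202])
    sets = build_matched_sets(matched, n_sets=n_sets, rng_seed=rng)
    results = []
    for track in catalog:
        ext_map = (
            bg_extremes[track.name]
            if bg_extremes is not None
            else background_extremes(matched, track)
        )
        observed = [
            region_extreme(r.members, track)
            for r in regions
            if r.index.id in matched
        ]
        observed = [o for o in observed if o is not None]
        if not observed:
            logger.warning("measure %s: no region has a defined extreme; skipped",
                           track.name)
            continue
        obs_summary = set_summary(observed, summary_stat)
        bg = set_summaries(sets, ext_map, summary_stat)
        bg = bg[~np.isnan(bg)]
        if bg.size == 0:
            logger.warning("measure %s: no defined background summary; skipped",
                           track.name)
            continue
        results.append(
            SetResult(
                measure=track.name,
                summary_stat=summary_stat,
                observed_summary=obs_summary,
                bg_mean=float(bg.mean()),
                bg_sd=float(np.std(bg, ddof=1)) if bg.size > 1 else float("nan"),
                enrichment=set_enrichment_score(
                    obs_summary, bg, catalog.genome_sd[track.name]
                ),
                emp_p=set_empirical_p(obs_summary, bg, track.direction),
                n_sets=int(bg.size),
            )
        )
    return results
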