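"""Region-level enrichment against the matched-control null.

For each trait region and measure, the observed statistic is the most
extreme score among the region's SNPs (extremity per the measure's
direction).  The null is the distribution of the same extreme over the
region's matched control regions.  Enrichment is reported as

* a z-score, (observed - background mean) / background sample SD;
* a one-sided empirical p-value in the measure's extremity direction,
  with the +1/(B+1) pseudo-count so finite permutations never yield
  p = 0;
* a Benjamini-Hochberg q-value across regions (per measure by default;
  pooling across measures is available as an option).

Matched regions with no scored member have an undefined extreme and are
dropped from the background; ``n_background`` records how many remained,
making the attainable p-value floor 1/(n_background + 1) explicit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .matching import MatchedRegion
from .measures import MeasureCatalog, MeasureTrack
from .reference_panel import Variant

logger = logging.getLogger("evoenrich")


@dataclass
class RegionResult:
    """Enrichment of one measure in one trait region."""

    region_id: str
    measure: str
    observed_extreme: float
    bg_mean: float
    bg_sd: float
    zscore: float  # NaN when the background SD is zero (excluded from FDR)
    emp_p: float
    q_value: float  # NaN until FDR is applied, or if excluded
    n_background: int


def region_extreme(
    members: frozenset[Variant] | set[Variant], track: MeasureTrack
) -> float | None:
    """Most extreme score among a region's scored members.

    ``max``/``min`` take the corresponding end; ``absmax`` takes the score
    of largest magnitude with its sign preserved.  Returns None when no
    member is scored (a first-class outcome, not an error).
    """
    vals = [track.scores[v.id] for v in members if v.id in track.scores]
    if not vals:
        return None
    if track.direction == "max":
        return max(vals)
    if track.direction == "min":
        return min(vals)
    return max(vals, key=abs)


def region_zscore(observed: float, background: list[float] | np.ndarray) -> float:
    """(observed - mean) / sample SD of the background extremes.

    Returns NaN (flagged, excluded from FDR) when the background has fewer
    than two values or zero SD.
    """
    bg = np.asarray(background, dtype=np.float64)
    if bg.size < 2:
        return math.nan
    sd = float(np.std(bg, ddof=1))
    if sd == 0.0:
        return math.nan
    return float((observed - bg.mean()) / sd)


def _at_least_as_extreme(
    background: np.ndarray, observed: float, direction: str
) -> np.ndarray:
    if direction == "max":
        return background >= observed
    if direction == "min":
        return background <= observed
    return np.abs(background) >= abs(observed)


def region_empirical_p(
    observed: float, background: list[float] | np.ndarray, direction: str = "max"
) -> float:
    """One-sided empirical p with the +1/(B+1) pseudo-count:
    (1 + #{b at least as extreme as observed}) / (1 + B).  Ties count as
    extreme."""
    bg = np.asarray(background, dtype=np.float64)
    if bg.size == 0:
        raise ValueError("empirical p requires a non-empty background")
    k = int(_at_least_as_extreme(bg, observed, direction).sum())
    return (1 + k) / (1 + bg.size)


def bh_fdr(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def background_extremes(
    matched: dict[str, list[MatchedRegion]], track: MeasureTrack
) -> dict[str, np.ndarray]:
    """Per-region array of matched-region extremes for one track, NaN for
    matched regions with no scored member.  Shared by the region- and
    set-level stages so each matched region is scored exactly once."""
    out = {}
    for region_id, mrs in matched.items():
        vals = np.full(len(mrs), np.nan)
        for i, mr in enumerate(mrs):
            e = region_extreme(mr.members, track)
            if e is not None:
                vals[i] = e
        out[region_id] = vals
    return out


def score_regions(
    regions,
    matched: dict[str, list[MatchedRegion]],
    catalog: MeasureCatalog,
    fdr_scope: str = "per-measure",
    bg_extremes: dict[str, dict[str, np.ndarray]] | None = None,
) -> list[RegionResult]:
    """Full region-level scoring: extremes, z, empirical p, BH q.

    ``regions`` is the list of clumped trait regions; only those with
    matched controls are scored.  ``fdr_scope`` is ``per-measure``
    (default: BH across regions within each measure) or ``pooled`` (one
    BH pass over all region x measure p-values).  ``bg_extremes`` may
    supply precomputed ``background_extremes`` per measure name.
    """
    if fdr_scope not in ("per-measure", "pooled"):
        raise ValueError("fdr_scope must be 'per-measure' or 'pooled'")
    results: list[RegionResult] = []
    for track in catalog:
        bg_map = (
            bg_extremes[track.name]
            if bg_extremes is not None
            else background_extremes(matched, track)
        )
        for region in regions:
            if region.index.id not in matched:
                continue
            obs = region_extreme(region.members, track)
            bg = bg_map[region.index.id]
            bg = bg[~np.isnan(bg)]
            if obs is None or bg.size == 0:
                logger.warning(
                    "region %s / measure %s: no defined extreme; skipped",
                    region.index.id, track.name,
                )
                continue
            results.append(
                RegionResult(
                    region_id=region.index.id,
                    measure=track.name,
                    observed_extreme=float(obs),
                    bg_mean=float(bg.mean()),
                    bg_sd=float(np.std(bg, ddof=1)) if bg.size > 1 else math.nan,
                    zscore=region_zscore(obs, bg),
                    emp_p=region_empirical_p(obs, bg, track.direction),
                    q_value=math.nan,
                    n_background=int(bg.size),
                )
            )

    # BH over results with a defined z-score (zero-SD backgrounds excluded)
    if fdr_scope == "pooled":
        groups = {None: [r for r in results if not math.isnan(r.zscore)]}
    else:
        groups = {}
        for r in results:
            if not math.isnan(r.zscore):
                groups.setdefault(r.measure, []).append(r)
    for rs in groups.values():
        if not rs:
            continue
        qs = bh_fdr([r.emp_p for r in rs])
        for r, q in zip(rs, qs):
            r.q_value = float(q)
    return results
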