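"""Evolutionary-measure score tracks.

A track holds one precomputed per-SNP score for a signature of an
evolutionary force — e.g. allelic differentiation between populations
(F_ST, XP-EHH, iES), balancing selection (Beta Score), allele age
(TMRCA), or cross-species substitution-rate conservation (PhyloP,
PhastCons, GERP, LINSIGHT).  Tracks are consumed, never derived from raw
data here.

Each track carries an extremity ``direction`` defining which member of a
region is "most extreme": ``max`` (default), ``min``, or ``absmax``
(largest absolute value, sign preserved — suits signed scores such as
PhyloP).  The genome-wide dispersion of a track (sample standard
deviation over all scored SNPs) is the scale unit of set-level
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("evoenrich")

DIRECTIONS = ("max", "min", "absmax")
DEFAULT_DIRECTION = "max"


class ZeroVarianceError(ValueError):
    """A constant track has no usable dispersion."""


class TrackMismatchError(ValueError):
    """A track's (chrom, pos) disagrees with the panel's for a shared id."""


@dataclass
class MeasureTrack:
    """Per-SNP scores for one evolutionary measure.

    ``positions`` optionally maps variant id -> (chrom, pos) for
    cross-checking against a panel; mismatches are errors, not silent
    drops.
    """

    name: str
    scores: dict[str, float]
    direction: str = DEFAULT_DIRECTION
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"track {self.name!r}: direction must be one of {DIRECTIONS}"
            )
        if not self.scores:
            raise ValueError(f"track {self.name!r}: empty score map")


@dataclass
class MeasureCatalog:
    """An ordered collection of tracks plus each track's genome-wide SD."""

    tracks: list[MeasureTrack]
    genome_sd: dict[str, float]

    def __iter__(self):
        return iter(self.tracks)

    def track(self, name: str) -> MeasureTrack:
        for t in self.tracks:
            if t.name == name:
                return t
        raise KeyError(f"no measure named {name!r}")


def annotate(variant_ids: Iterable[str], track: MeasureTrack) -> dict[str, float]:
    """Scores for the given ids; ids missing from the track are omitted
    (the missing fraction is logged)."""
    ids = list(variant_ids)
    out = {vid: track.scores[vid] for vid in ids if vid in track.scores}
    if ids and len(out) < len(ids):
        logger.debug(
            "track %s: %.1f%% of %d ids unscored",
            track.name, 100.0 * (1 - len(out) / len(ids)), len(ids),
        )
    return out


def genome_sd(track: MeasureTrack) -> float:
    """Sample standard deviation (n-1 denominator) over all scored SNPs."""
    vals = np.fromiter(track.scores.values(), dtype=np.float64)
    if vals.size < 2:
        raise ValueError(f"track {track.name!r}: need >= 2 scored SNPs")
    sd = float(np.std(vals, ddof=1))
    if sd <= 0.0:
        raise ZeroVarianceError(f"track {track.name!r} has zero variance")
    return sd


def build_catalog(tracks: Iterable[MeasureTrack]) -> MeasureCatalog:
    """Assemble a catalog, rejecting zero-variance tracks."""
    tracks = list(tracks)
    return MeasureCatalog(tracks=tracks, genome_sd={t.name: genome_sd(t) for t in tracks})


def validate_track(track: MeasureTrack, panel) -> None:
    """Cross-check the track's (chrom, pos) against the panel where both
    are present; any disagreement for a shared id raises."""
    if not track.positions:
        return
    meta = panel.variants.set_index("id")
    shared = meta.index.intersection(track.positions.keys())
    for vid in shared:
        chrom, pos = track.positions[vid]
        row = meta.loc[vid]
        if str(chrom) != str(row["chrom"]) or int(pos) != int(row["pos"]):
            raise TrackMismatchError(
                f"track {track.name!r}: {vid} at {chrom}:{pos} but panel has "
                f"{row['chrom']}:{row['pos']}"
            )


# -- readers ---------------------------------------------------------------


def read_track_tsv(
    path: str | Path, name: str, direction: str = DEFAULT_DIRECTION
) -> MeasureTrack:
    """Read a score track TSV with header ``SNP CHROM POS SCORE``."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHROM": str})
    df.columns = [c.upper() for c in df.columns]
    missing = {"SNP", "SCORE"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: track lacks column(s) {sorted(missing)}")
    scores = dict(zip(df["SNP"], df["SCORE"].astype(float)))
    positions = {}
    if {"CHROM", "POS"} <= set(df.columns):
        positions = {
            vid: (str(c), int(p)) for vid, c, p in zip(df["SNP"], df["CHROM"], df["POS"])
        }
    return MeasureTrack(name=name, scores=scores, direction=direction, positions=positions)


def read_measure_config(path: str | Path) -> list[MeasureTrack]:
    """Read a YAML measure config: a list of ``{name, path, direction}``
    entries; ``path`` is resolved relative to the config file."""
    cfg_path = Path(path)
    with open(cfg_path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"{path}: measure config must be a non-empty list")
    tracks = []
    for e in entries:
        if "name" not in e or "path" not in e:
            raise ValueError(f"{path}: each measure needs 'name' and 'path'")
        track_path = Path(e["path"])
        if not track_path.is_absolute():
            track_path = cfg_path.parent / track_path
        if not track_path.exists():
            raise FileNotFoundError(
                f"measure {e['name']!r}: track file {track_path} not found"
            )
        tracks.append(
            read_track_tsv(track_path, e["name"], e.get("direction", DEFAULT_DIRECTION))
        )
    return tracks
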