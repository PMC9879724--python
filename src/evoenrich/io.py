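"""Readers and writers for the pipeline's tab-delimited formats.

All outputs are TSV with stable headers; floats are written at six
significant digits.  Every output re-parses into exactly the values
written, which is what the round-trip tests assert.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .clumping import GwasRecord
from .matching import MatchProfile, MatchResult
from .region_enrichment import RegionResult
from .set_enrichment import SetResult

logger = logging.getLogger("evoenrich")

FLOAT_FMT = "%.6g"

GWAS_COLUMNS = {"snp": "SNP", "chr": "CHR", "pos": "POS", "p": "P"}


def read_gwas_tsv(
    path: str | Path, columns: dict[str, str] | None = None
) -> list[GwasRecord]:
    """Read summary statistics from a TSV with (at least) columns named
    CHR, POS, SNP, P — case-insensitive, remappable via ``columns``
    (keys ``snp``/``chr``/``pos``/``p``)."""
    colmap = dict(GWAS_COLUMNS)
    if columns:
        colmap.update({k.lower(): v for k, v in columns.items()})
    df = pd.read_csv(path, sep="\t")
    upper = {c.upper(): c for c in df.columns}
    resolved = {}
    for key, want in colmap.items():
        if want.upper() not in upper:
            raise ValueError(
                f"{path}: missing column {want!r} (have {list(df.columns)})"
            )
        resolved[key] = upper[want.upper()]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            records.append(
                GwasRecord(
                    id=str(row[resolved["snp"]]),
                    chrom=str(row[resolved["chr"]]),
                    pos=int(row[resolved["pos"]]),
                    pvalue=float(row[resolved["p"]]),
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: line {i}: {err}") from err
    return records


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return FLOAT_FMT % x


REGION_RESULT_COLUMNS = [
    "region_id", "measure", "observed_extreme", "bg_mean", "bg_sd",
    "zscore", "emp_p", "q_value", "n_background",
]

SET_RESULT_COLUMNS = [
    "measure", "summary_stat", "observed_summary", "bg_mean", "bg_sd",
    "enrichment", "emp_p", "n_sets",
]


def write_region_results(results: list[RegionResult], path: str | Path) -> None:
    rows = [
        [
            r.region_id, r.measure, _fmt(r.observed_extreme), _fmt(r.bg_mean),
            _fmt(r.bg_sd), _fmt(r.zscore), _fmt(r.emp_p), _fmt(r.q_value),
            str(r.n_background),
        ]
        for r in results
    ]
    pd.DataFrame(rows, columns=REGION_RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_region_results(path: str | Path) -> list[RegionResult]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"region_id": str})
    return [
        RegionResult(
            region_id=row.region_id,
            measure=row.measure,
            observed_extreme=float(row.observed_extreme),
            bg_mean=float(row.bg_mean),
            bg_sd=float(row.bg_sd),
            zscore=float(row.zscore),
            emp_p=float(row.emp_p),
            q_value=float(row.q_value),
            n_background=int(row.n_background),
        )
        for row in df.itertuples(index=False)
    ]


def write_set_results(results: list[SetResult], path: str | Path) -> None:
    rows = [
        [
            r.measure, r.summary_stat, _fmt(r.observed_summary), _fmt(r.bg_mean),
            _fmt(r.bg_sd), _fmt(r.enrichment), _fmt(r.emp_p), str(r.n_sets),
        ]
        for r in results
    ]
    pd.DataFrame(rows, columns=SET_RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_set_results(path: str | Path) -> list[SetResult]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return [
        SetResult(
            measure=row.measure,
            summary_stat=row.summary_stat,
            observed_summary=float(row.observed_summary),
            bg_mean=float(row.bg_mean),
            bg_sd=float(row.bg_sd),
            enrichment=float(row.enrichment),
            emp_p=float(row.emp_p),
            n_sets=int(row.n_sets),
        )
        for row in df.itertuples(index=False)
    ]


def write_matching_report(
    profiles: dict[str, MatchProfile], report: dict[str, MatchResult], path: str | Path
) -> None:
    rows = []
    for region_id in sorted(report):
        res = report[region_id]
        prof = profiles[region_id]
        rows.append(
            [
                region_id, _fmt(prof.maf), str(prof.n_buddies),
                str(res.n_requested), str(res.n_found), _fmt(res.final_maf_tol),
                _fmt(res.final_buddy_tol_rel), str(res.relax_steps),
                str(int(res.unmatched)),
            ]
        )
    pd.DataFrame(
        rows,
        columns=[
            "region_id", "profile_maf", "profile_buddies", "n_requested",
            "n_found", "final_maf_tol", "final_buddy_tol_rel", "relax_steps",
            "unmatched",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_region_backgrounds(
    observed: dict[tuple[str, str], float],
    bg_extremes: dict[str, dict[str, np.ndarray]],
    path: str | Path,
) -> None:
    """Per-(region, measure) background extreme samples, space-separated.

    This file is what lets ``merge`` recompute set-level enrichment from
    per-chunk runs without re-running matching.
    """
    rows = []
    for measure in sorted(bg_extremes):
        for region_id in sorted(bg_extremes[measure]):
            vals = bg_extremes[measure][region_id]
            key = (region_id, measure)
            rows.append(
                [
                    region_id, measure,
                    _fmt(observed[key]) if key in observed else "NA",
                    " ".join(_fmt(v) for v in vals),
                ]
            )
    pd.DataFrame(
        rows, columns=["region_id", "measure", "observed_extreme", "bg_extremes"]
    ).to_csv(path, sep="\t", index=False)


def read_region_backgrounds(
    path: str | Path,
) -> tuple[dict[tuple[str, str], float], dict[str, dict[str, np.ndarray]]]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"region_id": str})
    observed: dict[tuple[str, str], float] = {}
    bg: dict[str, dict[str, np.ndarray]] = {}
    for row in df.itertuples(index=False):
        vals = np.array(
            [float(x) if x != "NA" else np.nan for x in str(row.bg_extremes).split()]
        )
        bg.setdefault(row.measure, {})[row.region_id] = vals
        if not (isinstance(row.observed_extreme, float) and math.isnan(row.observed_extreme)):
            observed[(row.region_id, row.measure)] = float(row.observed_extreme)
    return observed, bg


def write_measure_stats(
    directions: dict[str, str], genome_sd: dict[str, float], path: str | Path
) -> None:
    rows = [
        [name, directions[name], _fmt(genome_sd[name])] for name in sorted(directions)
    ]
    pd.DataFrame(rows, columns=["measure", "direction", "genome_sd"]).to_csv(
        path, sep="\t", index=False
    )


def read_measure_stats(path: str | Path) -> tuple[dict[str, str], dict[str, float]]:
    df = pd.read_csv(path, sep="\t")
    return (
        dict(zip(df["measure"], df["direction"])),
        dict(zip(df["measure"], df["genome_sd"].astype(float))),
    )
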