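"""Greedy LD clumping of GWAS summary statistics.

Reduces a table of per-SNP association p-values to approximately
independent regions, PLINK ``--clump`` style: repeatedly take the
unassigned record with the smallest p-value at or below ``p1`` as a new
index SNP, then assign to it every unassigned record with p-value at or
below ``p2``, within ``kb_window`` kilobases on the same chromosome, and
with r² >= ``r2_clump`` against the index.  Each region is labeled by its
index SNP (the lowest p-value member).

Defaults mirror PLINK's documented clump defaults except ``p1`` = 5e-8
(genome-wide significance), since the intended input is GWAS hits.
p-value ties are broken by (chrom, pos) ascending for determinism, so the
output is invariant to input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .reference_panel import GenotypePanel, Variant, compute_r2

logger = logging.getLogger("evoenrich")

DEFAULT_P1 = 5e-8
DEFAULT_P2 = 0.01
DEFAULT_R2_CLUMP = 0.5
DEFAULT_KB_WINDOW = 250.0


@dataclass(frozen=True)
class GwasRecord:
    """One row of summary statistics: variant id, location, p-value in (0, 1]."""

    id: str
    chrom: str
    pos: int
    pvalue: float

    def __post_init__(self):
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.id}: p-value {self.pvalue} outside (0, 1]")


@dataclass(frozen=True)
class Region:
    """An LD-clumped trait-associated locus.

    ``index`` is the member with the lowest p-value among input records;
    ``members`` always contains the index.
    """

    index: Variant
    members: frozenset[Variant]
    index_pvalue: float

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(v.id for v in self.members)


def clump(
    records: list[GwasRecord],
    panel: GenotypePanel,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    r2_clump: float = DEFAULT_R2_CLUMP,
    kb_window: float = DEFAULT_KB_WINDOW,
) -> list[Region]:
    """Greedy clump of ``records`` into independent regions.

    Records whose id is absent from the panel cannot contribute LD and are
    dropped with a logged count.  Returns regions in the order their index
    SNPs were selected (ascending index p-value).  An empty result (no
    record passes ``p1``) is returned with a warning.
    """
    resolved = [r for r in records if r.id in panel]
    n_dropped = len(records) - len(resolved)
    if n_dropped:
        logger.info("clump: dropped %d record(s) absent from the panel", n_dropped)
    # deduplicate by id, keeping the smallest p-value
    by_id: dict[str, GwasRecord] = {}
    for r in resolved:
        if r.id not in by_id or r.pvalue < by_id[r.id].pvalue:
            by_id[r.id] = r
    recs = sorted(by_id.values(), key=lambda r: (r.pvalue, r.chrom, r.pos))

    window_bp = int(round(kb_window * 1000))
    assigned: set[str] = set()
    regions: list[Region] = []

    # per-chromosome position-sorted views for window lookups
    by_chrom: dict[str, list[GwasRecord]] = {}
    for r in recs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: r.pos)
    pos_arrays = {c: np.array([r.pos for r in v]) for c, v in by_chrom.items()}

    for rec in recs:
        if rec.id in assigned:
            continue
        if rec.pvalue > p1:
            break  # sorted ascending: no further index candidates
        assigned.add(rec.id)
        members = {panel.variant(rec.id)}
        pos = pos_arrays[rec.chrom]
        lo = int(np.searchsorted(pos, rec.pos - window_bp, side="left"))
        hi = int(np.searchsorted(pos, rec.pos + window_bp, side="right"))
        for cand in by_chrom[rec.chrom][lo:hi]:
            if cand.id in assigned or cand.pvalue > p2:
                continue
            if compute_r2(panel, rec.id, cand.id) >= r2_clump:
                assigned.add(cand.id)
                members.add(panel.variant(cand.id))
        regions.append(
            Region(
                index=panel.variant(rec.id),
                members=frozenset(members),
                index_pvalue=rec.pvalue,
            )
        )

    if not regions:
        logger.warning("clump: no record passed p1 = %g; empty result", p1)
    return regions
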