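"""Phased reference genotype panel.

The panel is the source of every population-genetic quantity the pipeline
needs: minor allele frequencies, pairwise haplotype r², and per-variant
LD-buddy counts (number of same-chromosome variants with r² at or above a
threshold, within a physical window).  Haplotypes are stored as a dense
0/1 matrix of shape (n_haplotypes, n_variants); variant metadata lives in
a pandas DataFrame ordered by (chrom, pos).

r² is haplotype-based (phased): r² = D² / (pA(1-pA) pB(1-pB)) with
D = pAB - pA*pB, which for 0/1 columns equals the squared Pearson
correlation.  Monomorphic and non-biallelic records are dropped at load
time (MAF matching and r² are undefined for them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("evoenrich")

#: default r^2 threshold defining an "LD buddy"
DEFAULT_R2_BUDDY = 0.9
#: physical window (each side, kb) within which buddy pairs are sought;
#: bounded for tractability, configurable everywhere it is used
DEFAULT_LD_WINDOW_KB = 1000.0

# small slack for floating-point threshold comparisons on derived ratios
_EPS = 1e-12


class PanelError(ValueError):
    """Malformed or unusable panel input."""


class UnknownVariantError(KeyError):
    """Variant id not present in the panel."""


class MonomorphicError(ValueError):
    """LD is undefined for a monomorphic variant."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP retained in the panel.

    ``pos`` is 1-based (VCF convention).  ``maf`` is the minor allele
    frequency over panel haplotypes, in (0, 0.5].
    """

    id: str
    chrom: str
    pos: int
    maf: float


class GenotypePanel:
    """Phased haplotype matrix plus variant metadata.

    Parameters
    ----------
    variants
        DataFrame with columns ``id``, ``chrom``, ``pos``.  Rows are
        reordered to (chrom, pos); ids must be unique, as must
        (chrom, pos) pairs.
    haplotypes
        Array of shape (n_haplotypes, n_variants) with 0/1 entries,
        columns aligned to ``variants`` rows (before reordering).

    Monomorphic columns are dropped with a logged count.  The number of
    haplotypes must be even (phased diploids).
    """

    def __init__(self, variants: pd.DataFrame, haplotypes: np.ndarray):
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2:
            raise PanelError("haplotypes must be a 2-D matrix")
        if haplotypes.shape[1] != len(variants):
            raise PanelError(
                f"{haplotypes.shape[1]} haplotype columns vs {len(variants)} variants"
            )
        if haplotypes.shape[0] % 2 != 0:
            raise PanelError("odd number of haplotypes; panel must be phased diploids")
        if not np.isin(haplotypes, (0, 1)).all():
            raise PanelError("haplotype entries must be 0/1")

        variants = variants.reset_index(drop=True).copy()
        for col in ("id", "chrom", "pos"):
            if col not in variants.columns:
                raise PanelError(f"variants table lacks required column {col!r}")
        variants["id"] = variants["id"].astype(str)
        variants["chrom"] = variants["chrom"].astype(str)
        variants["pos"] = variants["pos"].astype(np.int64)

        freq = haplotypes.mean(axis=0)
        poly = (freq > 0.0) & (freq < 1.0)
        n_dropped = int((~poly).sum())
        if n_dropped:
            logger.info("dropping %d monomorphic variant(s) at load", n_dropped)
            variants = variants.loc[poly].reset_index(drop=True)
            haplotypes = haplotypes[:, poly]
            freq = freq[poly]

        if variants["id"].duplicated().any():
            dup = variants.loc[variants["id"].duplicated(), "id"].iloc[0]
            raise PanelError(f"duplicate variant id {dup!r}")
        if variants.duplicated(subset=["chrom", "pos"]).any():
            raise PanelError("duplicate (chrom, pos) in panel")

        variants["maf"] = np.minimum(freq, 1.0 - freq)

        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
        variants = variants.iloc[order].reset_index(drop=True)
        haplotypes = np.ascontiguousarray(haplotypes[:, order])

        self.variants: pd.DataFrame = variants
        self.haplotypes: np.ndarray = haplotypes
        self._col: dict[str, int] = {
            vid: i for i, vid in enumerate(variants["id"].tolist())
        }

    # -- basic accessors ---------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._col

    def column(self, variant_id: str) -> int:
        try:
            return self._col[variant_id]
        except KeyError:
            raise UnknownVariantError(f"variant {variant_id!r} not in panel") from None

    def variant(self, variant_id: str) -> Variant:
        row = self.variants.iloc[self.column(variant_id)]
        return Variant(
            id=row["id"], chrom=row["chrom"], pos=int(row["pos"]), maf=float(row["maf"])
        )


@dataclass
class LDIndex:
    """Per-variant LD-buddy relations at a fixed r² threshold.

    ``buddy_members[v]`` is the set of variant ids on the same chromosome,
    within the build window, with pairwise r² >= ``r2_threshold``; the
    relation is symmetric and irreflexive.  ``buddy_count[v]`` equals
    ``len(buddy_members[v])``.
    """

    r2_threshold: float
    buddy_count: dict[str, int] = field(default_factory=dict)
    buddy_members: dict[str, set[str]] = field(default_factory=dict)

    def buddies(self, variant_id: str) -> set[str]:
        return self.buddy_members.get(variant_id, set())

    def count(self, variant_id: str) -> int:
        return self.buddy_count.get(variant_id, 0)


def compute_maf(panel: GenotypePanel, variant_id: str) -> float:
    """Minor allele frequency min(f, 1-f) of ``variant_id`` over haplotypes."""
    col = panel.haplotypes[:, panel.column(variant_id)]
    f = float(col.mean())
    return min(f, 1.0 - f)


def compute_r2(panel: GenotypePanel, variant_a: str, variant_b: str) -> float:
    """Haplotype r² = D²/(pA(1-pA) pB(1-pB)) between two panel variants.

    Symmetric in its arguments and invariant to swapping the allele
    labels of either variant.  Raises :class:`MonomorphicError` if either
    column is fixed (cannot happen for variants retained at load).
    """
    x = panel.haplotypes[:, panel.column(variant_a)].astype(np.float64)
    y = panel.haplotypes[:, panel.column(variant_b)].astype(np.float64)
    pa, pb = x.mean(), y.mean()
    va, vb = pa * (1.0 - pa), pb * (1.0 - pb)
    if va <= 0.0 or vb <= 0.0:
        raise MonomorphicError(
            f"r2 undefined: monomorphic input ({variant_a!r}, {variant_b!r})"
        )
    d = float(np.mean(x * y)) - pa * pb
    r2 = (d * d) / (va * vb)
    # clip tiny numerical overshoot above 1 for perfectly correlated columns
    return min(float(r2), 1.0)


def build_ld_index(
    panel: GenotypePanel,
    r2_threshold: float = DEFAULT_R2_BUDDY,
    window_kb: float = DEFAULT_LD_WINDOW_KB,
) -> LDIndex:
    """Compute LD-buddy sets for every panel variant.

    Pairs are considered only on the same chromosome within ``window_kb``
    kilobases (each side).  The scan is banded: for each variant the dot
    product with all downstream in-window columns is taken at once, so the
    cost is O(n_variants x band_width x n_haplotypes).
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    window_bp = int(round(window_kb * 1000))

    ids = panel.variants["id"].to_numpy()
    members: dict[str, set[str]] = {vid: set() for vid in ids}

    X = panel.haplotypes.astype(np.float64)
    p = X.mean(axis=0)
    var = p * (1.0 - p)
    H = panel.n_haplotypes

    for chrom, grp in panel.variants.groupby("chrom", sort=False):
        lo_all = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for k in range(len(lo_all)):
            i = lo_all[k]
            hi = int(np.searchsorted(pos, pos[k] + window_bp, side="right"))
            if hi <= k + 1:
                continue
            js = lo_all[k + 1 : hi]
            pab = (X[:, i] @ X[:, js]) / H
            d = pab - p[i] * p[js]
            r2 = (d * d) / (var[i] * var[js])
            for j in js[r2 >= r2_threshold - _EPS]:
                a, b = ids[i], ids[j]
                members[a].add(b)
                members[b].add(a)

    counts = {vid: len(s) for vid, s in members.items()}
    return LDIndex(r2_threshold=r2_threshold, buddy_count=counts, buddy_members=members)


# -- loaders ---------------------------------------------------------------


def read_panel_tsv(path: str | Path) -> GenotypePanel:
    """Read a haplotype-matrix TSV: header ``ID CHROM POS`` then one 0/1
    column per haplotype."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = [c.upper() for c in df.columns[:3]]
    if cols != ["ID", "CHROM", "POS"]:
        raise PanelError(
            f"{path}: expected header starting 'ID\\tCHROM\\tPOS', got {list(df.columns[:3])}"
        )
    hap_cols = df.columns[3:]
    if len(hap_cols) == 0:
        raise PanelError(f"{path}: no haplotype columns")
    variants = df.iloc[:, :3].copy()
    variants.columns = ["id", "chrom", "pos"]
    haps = df[hap_cols].to_numpy()
    if not np.isin(haps, (0, 1)).all():
        raise PanelError(f"{path}: haplotype entries must be 0/1")
    # TSV rows are variants; the panel wants haplotypes as rows
    return GenotypePanel(variants, haps.astype(np.uint8).T)


def read_panel_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF of phased biallelic SNPs with cyvcf2.

    Non-biallelic or non-SNP records are skipped with a logged count;
    any unphased genotype is an error (the r² model requires phase).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, chroms, poss, columns = [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        col = np.empty(2 * len(gts), dtype=np.uint8)
        for s, g in enumerate(gts):
            if not g[2]:
                raise PanelError(
                    f"{path}: unphased genotype at {rec.CHROM}:{rec.POS} "
                    f"(sample index {s}); a phased panel is required"
                )
            if g[0] < 0 or g[1] < 0:
                raise PanelError(
                    f"{path}: missing genotype at {rec.CHROM}:{rec.POS}; "
                    "the panel must be complete"
                )
            col[2 * s] = g[0]
            col[2 * s + 1] = g[1]
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        ids.append(vid)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        columns.append(col)
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP record(s) in %s", n_skipped, path)
    if not columns:
        raise PanelError(f"{path}: no usable biallelic SNP records")
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return GenotypePanel(variants, np.stack(columns, axis=1))


def load_panel(path: str | Path) -> GenotypePanel:
    """Dispatch on file extension: ``.vcf``/``.vcf.gz`` or haplotype TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_panel_vcf(path)
    return read_panel_tsv(path)
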