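"""SNPsnap-style selection of matched control SNPs.

For each trait region's index SNP, draw control SNPs (default 5000)
matched on minor allele frequency (within ±5 percentage points, absolute)
and LD-buddy count (within ±50% relative), then LD-expand each control
into a matched region: the control plus all of its LD buddies at the
expansion threshold.

If fewer eligible candidates than requested exist at base tolerances, the
tolerances relax stepwise (MAF +1 percentage point and buddy tolerance
+10 percentage points per step, up to 5 steps); every relaxation is
logged and reported.  A region with zero eligible candidates even after
maximal relaxation is flagged unmatched and excluded downstream.

The "±5%" MAF tolerance is absolute (percentage points of frequency),
matching SNPsnap's convention; a relative reading collapses for rare
variants.  Controls are sampled uniformly without replacement within a
region; the same control SNP may serve different input regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reference_panel import GenotypePanel, LDIndex, Variant

logger = logging.getLogger("evoenrich")

DEFAULT_N_CONTROLS = 5000
DEFAULT_MAF_TOL = 0.05
DEFAULT_BUDDY_TOL_REL = 0.50
RELAX_MAF_STEP = 0.01
RELAX_BUDDY_STEP = 0.10
MAX_RELAX_STEPS = 5

_EPS = 1e-9  # float slack so boundary candidates (exactly at tolerance) qualify


@dataclass(frozen=True)
class MatchProfile:
    """Matching target: the index SNP's MAF and LD-buddy count."""

    maf: float
    n_buddies: int

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"profile maf {self.maf} outside (0, 0.5]")
        if self.n_buddies < 0:
            raise ValueError("n_buddies must be non-negative")

    @classmethod
    def of(cls, variant: Variant, ld_index: LDIndex) -> "MatchProfile":
        return cls(maf=variant.maf, n_buddies=ld_index.count(variant.id))


@dataclass(frozen=True)
class MatchedRegion:
    """A control index SNP plus its LD-expansion partners."""

    control_index: Variant
    members: frozenset[Variant]

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(v.id for v in self.members)


class CandidatePool:
    """Control-SNP candidates binned by MAF percentage point.

    All members of all input trait regions are excluded up front so no
    control can leak trait signal into the null.  Eligibility lookups
    touch only the MAF bins overlapping the tolerance window, then filter
    on the buddy-count predicate.
    """

    def __init__(self, panel: GenotypePanel, ld_index: LDIndex, excluded: set[str]):
        keep = ~panel.variants["id"].isin(excluded).to_numpy()
        sub = panel.variants.loc[keep]
        self.ids: np.ndarray = sub["id"].to_numpy()
        self.maf: np.ndarray = sub["maf"].to_numpy(dtype=np.float64)
        self.buddies: np.ndarray = np.array(
            [ld_index.count(v) for v in self.ids], dtype=np.int64
        )
        self._bins: dict[int, np.ndarray] = {}
        binned = np.floor(self.maf * 100.0 + 1e-9).astype(np.int64)
        order = np.argsort(binned, kind="stable")
        uniq, starts = np.unique(binned[order], return_index=True)
        bounds = np.append(starts, len(order))
        for b, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
            self._bins[int(b)] = order[lo:hi]

    def __len__(self) -> int:
        return len(self.ids)

    def eligible(
        self, profile: MatchProfile, maf_tol: float, buddy_tol_rel: float
    ) -> np.ndarray:
        """Positions (into the pool arrays) of candidates satisfying both
        the MAF and buddy-count tolerance predicates."""
        lo_bin = int(np.floor((profile.maf - maf_tol) * 100.0 - 1e-9))
        hi_bin = int(np.floor((profile.maf + maf_tol) * 100.0 + 1e-9))
        chunks = [self._bins[b] for b in range(lo_bin, hi_bin + 1) if b in self._bins]
        if not chunks:
            return np.empty(0, dtype=np.int64)
        cand = np.concatenate(chunks)
        ok_maf = np.abs(self.maf[cand] - profile.maf) <= maf_tol + _EPS
        slack = buddy_tol_rel * max(profile.n_buddies, 1)
        ok_bud = np.abs(self.buddies[cand] - profile.n_buddies) <= slack + _EPS
        return np.sort(cand[ok_maf & ok_bud])


def candidate_pool(
    panel: GenotypePanel, ld_index: LDIndex, excluded: set[str]
) -> CandidatePool:
    """Build the indexed candidate store, excluding ``excluded`` variant ids
    (all members of all input trait regions)."""
    return CandidatePool(panel, ld_index, excluded)


@dataclass
class MatchResult:
    """Outcome of matching one region's profile against the pool."""

    controls: list[str] = field(default_factory=list)
    n_requested: int = 0
    n_found: int = 0
    final_maf_tol: float = DEFAULT_MAF_TOL
    final_buddy_tol_rel: float = DEFAULT_BUDDY_TOL_REL
    relax_steps: int = 0
    unmatched: bool = False

    @property
    def insufficient_fraction(self) -> float:
        """Fraction of the request left unfilled after maximal relaxation."""
        if self.n_requested == 0:
            return 0.0
        return 1.0 - self.n_found / self.n_requested


def match_controls(
    profile: MatchProfile,
    pool: CandidatePool,
    n_controls: int = DEFAULT_N_CONTROLS,
    maf_tol: float = DEFAULT_MAF_TOL,
    buddy_tol_rel: float = DEFAULT_BUDDY_TOL_REL,
    rng_seed: int | np.random.Generator | None = None,
) -> MatchResult:
    """Sample matched controls for one profile.

    Returns a :class:`MatchResult`; ``controls`` holds variant ids sampled
    uniformly without replacement from the eligible candidates, fully
    reproducible from ``rng_seed``.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    step = 0
    while True:
        tol_m = maf_tol + step * RELAX_MAF_STEP
        tol_b = buddy_tol_rel + step * RELAX_BUDDY_STEP
        elig = pool.eligible(profile, tol_m, tol_b)
        if len(elig) >= n_controls or step >= MAX_RELAX_STEPS:
            break
        step += 1

    if step:
        logger.info(
            "matching relaxed %d step(s) for profile maf=%.3f buddies=%d "
            "(final tolerances maf ±%.2f, buddies ±%.0f%%): %d eligible",
            step, profile.maf, profile.n_buddies, tol_m, 100 * tol_b, len(elig),
        )
    if len(elig) == 0:
        logger.warning(
            "no eligible control for profile maf=%.3f buddies=%d after maximal "
            "relaxation; region flagged unmatched", profile.maf, profile.n_buddies,
        )
        return MatchResult(
            n_requested=n_controls,
            final_maf_tol=tol_m,
            final_buddy_tol_rel=tol_b,
            relax_steps=step,
            unmatched=True,
        )

    take = min(n_controls, len(elig))
    chosen = rng.choice(elig, size=take, replace=False)
    controls = [str(pool.ids[i]) for i in chosen]
    return MatchResult(
        controls=controls,
        n_requested=n_controls,
        n_found=take,
        final_maf_tol=tol_m,
        final_buddy_tol_rel=tol_b,
        relax_steps=step,
    )


def ld_expand(
    control: Variant, ld_index: LDIndex, panel: GenotypePanel
) -> MatchedRegion:
    """Expand a control SNP into its matched region: the control plus all
    LD buddies at the index's threshold."""
    members = {control}
    for vid in ld_index.buddies(control.id):
        members.add(panel.variant(vid))
    return MatchedRegion(control_index=control, members=frozenset(members))


def match_regions(
    profiles: dict[str, MatchProfile],
    pool: CandidatePool,
    ld_index: LDIndex,
    panel: GenotypePanel,
    n_controls: int = DEFAULT_N_CONTROLS,
    maf_tol: float = DEFAULT_MAF_TOL,
    buddy_tol_rel: float = DEFAULT_BUDDY_TOL_REL,
    rng_seed: int = 0,
) -> tuple[dict[str, list[MatchedRegion]], dict[str, MatchResult]]:
    """Match and LD-expand controls for every region.

    ``profiles`` maps region index-SNP id -> profile.  Each region draws
    from an independent, deterministically derived random stream, so the
    result does not depend on region iteration order.  Returns the matched
    regions per region id (unmatched regions omitted) plus the per-region
    matching report.
    """
    matched: dict[str, list[MatchedRegion]] = {}
    report: dict[str, MatchResult] = {}
    for k, (region_id, profile) in enumerate(sorted(profiles.items())):
        rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, 101, k])
        res = match_controls(
            profile, pool, n_controls, maf_tol, buddy_tol_rel, rng_seed=rng
        )
        report[region_id] = res
        if res.unmatched:
            continue
        matched[region_id] = [
            ld_expand(panel.variant(cid), ld_index, panel) for cid in res.controls
        ]
    return matched, report
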