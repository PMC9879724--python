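"""Matched-control selection: pools, tolerance predicates, relaxation,
LD expansion, leakage and reproducibility."""

import numpy as np
import pytest

from evoenrich.matching import (
    MatchProfile,
    candidate_pool,
    ld_expand,
    match_controls,
    match_regions,
)
from evoenrich.reference_panel import build_ld_index
from evoenrich.synthetic_fixtures import SimConfig, simulate_dataset

from conftest import make_panel, random_panel


def brute_force_eligible(pool, profile, maf_tol, buddy_tol_rel):
    out = []
    for i in range(len(pool)):
        ok_maf = abs(pool.maf[i] - profile.maf) <= maf_tol + 1e-9
        slack = buddy_tol_rel * max(profile.n_buddies, 1)
        ok_bud = abs(int(pool.buddies[i]) - profile.n_buddies) <= slack + 1e-9
        if ok_maf and ok_bud:
            out.append(i)
    return np.array(out, dtype=np.int64)


@pytest.fixture(scope="module")
def medium_panel():
    rng = np.random.default_rng(77)
    return random_panel(rng, 200, 50, spacing=5_000)


@pytest.fixture(scope="module")
def medium_index(medium_panel):
    return build_ld_index(medium_panel, 0.9, 1000)


class TestCandidatePool:
    def test_all_excluded_gives_empty_pool(self, medium_panel, medium_index):
        pool = candidate_pool(
            medium_panel, medium_index, set(medium_panel.variant_ids)
        )
        assert len(pool) == 0

    def test_pool_size_is_panel_minus_excluded(self, medium_panel, medium_index):
        excluded = set(medium_panel.variant_ids[:37])
        pool = candidate_pool(medium_panel, medium_index, excluded)
        assert len(pool) == medium_panel.n_variants - 37

    @pytest.mark.parametrize("maf_tol,buddy_tol", [(0.05, 0.5), (0.02, 0.1), (0.1, 1.0)])
    def test_eligibility_matches_brute_force(
        self, medium_panel, medium_index, maf_tol, buddy_tol
    ):
        pool = candidate_pool(medium_panel, medium_index, set())
        for maf in (0.12, 0.3, 0.48):
            for buddies in (0, 1, 3):
                prof = MatchProfile(maf=maf, n_buddies=buddies)
                got = pool.eligible(prof, maf_tol, buddy_tol)
                want = brute_force_eligible(pool, prof, maf_tol, buddy_tol)
                assert np.array_equal(np.sort(got), want)


class TestToleranceBoundaries:
    def _pool(self, mafs_buddies):
        """Pool with explicit (maf, buddies) pairs, bypassing a panel."""
        from evoenrich.matching import CandidatePool

        pool = CandidatePool.__new__(CandidatePool)
        pool.ids = np.array([f"v{i}" for i in range(len(mafs_buddies))])
        pool.maf = np.array([m for m, _ in mafs_buddies])
        pool.buddies = np.array([b for _, b in mafs_buddies], dtype=np.int64)
        binned = np.floor(pool.maf * 100.0 + 1e-9).astype(np.int64)
        pool._bins = {int(b): np.flatnonzero(binned == b) for b in np.unique(binned)}
        return pool

    def test_maf_and_buddy_predicates(self):
        pool = self._pool([(0.34, 3), (0.36, 3), (0.30, 7)])
        prof = MatchProfile(maf=0.30, n_buddies=3)
        elig = pool.eligible(prof, 0.05, 0.5)
        # 0.34 within ±0.05 and buddies equal: eligible;
        # 0.36 violates MAF; 7 buddies violate ±50% of 3 (slack 1.5)
        assert list(elig) == [0]

    def test_buddy_slack_uses_max_with_one(self):
        pool = self._pool([(0.2, 0), (0.2, 1), (0.2, 2)])
        prof = MatchProfile(maf=0.2, n_buddies=0)
        # slack = 0.5 * max(0, 1) = 0.5 -> only exact zero qualifies
        assert list(pool.eligible(prof, 0.05, 0.5)) == [0]


class TestMatchControls:
    def test_returns_requested_count_when_abundant(self, medium_panel, medium_index):
        pool = candidate_pool(medium_panel, medium_index, set())
        prof = MatchProfile(maf=0.3, n_buddies=0)
        res = match_controls(prof, pool, n_controls=10, rng_seed=1)
        assert res.n_found == 10 and len(res.controls) == 10
        assert not res.unmatched and res.relax_steps == 0
        assert len(set(res.controls)) == 10  # without replacement

    def test_all_controls_satisfy_base_tolerances(self, medium_panel, medium_index):
        pool = candidate_pool(medium_panel, medium_index, set())
        prof = MatchProfile(maf=0.25, n_buddies=0)
        res = match_controls(prof, pool, n_controls=20, rng_seed=2)
        mafs = {c: medium_panel.variant(c).maf for c in res.controls}
        if res.relax_steps == 0:
            for c, m in mafs.items():
                assert abs(m - 0.25) <= 0.05 + 1e-9

    def test_relaxation_reports_final_tolerances(self):
        # panel with nothing near the profile MAF at base tolerance
        cols = {f"v{i}": [0, 1] * 10 for i in range(3)}  # all maf 0.5
        panel = make_panel(cols)
        idx = build_ld_index(panel)
        pool = candidate_pool(panel, idx, set())
        prof = MatchProfile(maf=0.42, n_buddies=2)
        res = match_controls(prof, pool, n_controls=2, rng_seed=0)
        assert res.relax_steps > 0
        assert res.final_maf_tol == pytest.approx(0.05 + res.relax_steps * 0.01)
        assert res.insufficient_fraction == 0.0

    def test_empty_pool_flags_unmatched(self, medium_panel, medium_index):
        pool = candidate_pool(medium_panel, medium_index, set(medium_panel.variant_ids))
        res = match_controls(MatchProfile(0.3, 0), pool, n_controls=5, rng_seed=0)
        assert res.unmatched and res.controls == []
        assert res.relax_steps == 5

    def test_same_seed_reproduces_different_seed_varies(
        self, medium_panel, medium_index
    ):
        pool = candidate_pool(medium_panel, medium_index, set())
        prof = MatchProfile(maf=0.3, n_buddies=0)
        a = match_controls(prof, pool, n_controls=10, rng_seed=42).controls
        b = match_controls(prof, pool, n_controls=10, rng_seed=42).controls
        c = match_controls(prof, pool, n_controls=10, rng_seed=43).controls
        assert a == b
        assert a != c


class TestLdExpand:
    def test_isolated_control_is_singleton(self, medium_panel, medium_index):
        vid = next(
            v for v, c in medium_index.buddy_count.items() if c == 0
        )
        mr = ld_expand(medium_panel.variant(vid), medium_index, medium_panel)
        assert mr.member_ids == {vid}

    def test_duplicated_control_expands_to_all_copies(self):
        col = [0, 1, 1, 0, 1, 0, 0, 1]
        panel = make_panel({f"d{i}": col for i in range(5)})
        idx = build_ld_index(panel)
        mr = ld_expand(panel.variant("d2"), idx, panel)
        assert len(mr.members) == 5
        assert mr.control_index.id == "d2"

    def test_member_count_is_buddy_count_plus_one(self, medium_panel, medium_index):
        for vid in medium_panel.variant_ids[:30]:
            mr = ld_expand(medium_panel.variant(vid), medium_index, medium_panel)
            assert len(mr.members) == medium_index.count(vid) + 1


class TestLeakage:
    def test_no_control_touches_any_trait_region(self):
        from evoenrich.pipeline import RunConfig, run_analysis

        data = simulate_dataset(
            SimConfig(n_haplotypes=100, n_snps=1000, n_blocks=200,
                      n_trait_regions=8, rng_seed=3)
        )
        res = run_analysis(
            data.panel, data.gwas, data.catalog,
            RunConfig(n_controls=30, n_sets=50, rng_seed=9),
        )
        trait_expanded = set()
        idx = build_ld_index(data.panel, 0.9, 1000)
        for region in res.regions:
            for vid in region.member_ids:
                trait_expanded.add(vid)
                trait_expanded.update(idx.buddies(vid))
        for mrs in res.matched.values():
            for mr in mrs:
                assert mr.control_index.id not in trait_expanded


class TestMatchRegions:
    def test_result_independent_of_profile_insertion_order(
        self, medium_panel, medium_index
    ):
        pool = candidate_pool(medium_panel, medium_index, set())
        profiles = {
            "r1": MatchProfile(0.2, 0),
            "r2": MatchProfile(0.35, 0),
        }
        fwd, _ = match_regions(
            profiles, pool, medium_index, medium_panel, n_controls=8, rng_seed=4
        )
        rev, _ = match_regions(
            dict(reversed(list(profiles.items()))), pool, medium_index,
            medium_panel, n_controls=8, rng_seed=4,
        )
        assert {k: [m.control_index.id for m in v] for k, v in fwd.items()} == {
            k: [m.control_index.id for m in v] for k, v in rev.items()
        }
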