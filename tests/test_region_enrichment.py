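"""Region-level enrichment: extremes, z-scores, empirical p, BH FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoenrich.measures import MeasureTrack, build_catalog
from evoenrich.region_enrichment import (
    bh_fdr,
    region_empirical_p,
    region_extreme,
    region_zscore,
    score_regions,
)
from evoenrich.reference_panel import Variant


def variants(*ids):
    return frozenset(Variant(id=i, chrom="1", pos=k + 1, maf=0.3) for k, i in enumerate(ids))


def track(scores, direction="max", name="m"):
    return MeasureTrack(name=name, scores=scores, direction=direction)


def oracle_bh(pvals):
    """Independent step-up BH: sort ascending, q_(i) = min_{j>=i} m p_(j)/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


class TestRegionExtreme:
    def test_single_scored_member(self):
        assert region_extreme(variants("a"), track({"a": 0.7})) == 0.7

    def test_direction_max(self):
        t = track({"a": 0.1, "b": 0.5, "c": 0.3})
        assert region_extreme(variants("a", "b", "c"), t) == 0.5

    def test_direction_min(self):
        t = track({"a": 0.1, "b": 0.5, "c": 0.3}, direction="min")
        assert region_extreme(variants("a", "b", "c"), t) == 0.1

    def test_absmax_keeps_sign(self):
        t = track({"a": -2.0, "b": 1.5}, direction="absmax")
        assert region_extreme(variants("a", "b"), t) == -2.0

    def test_unscored_region_is_undefined(self):
        assert region_extreme(variants("x", "y"), track({"a": 1.0})) is None

    def test_unscored_members_ignored(self):
        t = track({"a": 0.2})
        assert region_extreme(variants("a", "zzz"), t) == 0.2


class TestZscore:
    def test_observed_at_mean_is_zero(self):
        assert region_zscore(2.0, [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_one_sample_sd_above(self):
        # mean 2, sample SD 1
        assert region_zscore(3.0, [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_symmetric_below(self):
        assert region_zscore(1.0, [1.0, 2.0, 3.0]) == pytest.approx(-1.0)

    def test_zero_sd_background_flagged_nan(self):
        assert math.isnan(region_zscore(1.0, [2.0, 2.0, 2.0]))


class TestEmpiricalP:
    def test_observed_beyond_all_background(self):
        bg = np.arange(5000, dtype=float)
        assert region_empirical_p(1e9, bg, "max") == pytest.approx(1 / 5001)

    def test_observed_below_all_background_max(self):
        assert region_empirical_p(-10.0, [1.0, 2.0, 3.0], "max") == 1.0

    def test_ties_count_as_extreme(self):
        assert region_empirical_p(2.0, [2.0, 2.0, 2.0], "max") == 1.0

    def test_direction_min_counts_lower_tail(self):
        assert region_empirical_p(0.5, [1.0, 2.0, 3.0], "min") == pytest.approx(1 / 4)

    def test_absmax_counts_magnitude(self):
        assert region_empirical_p(1.5, [-2.0, 0.1, 1.0], "absmax") == pytest.approx(2 / 4)

    @given(
        obs=st.floats(-5, 5),
        delta=st.floats(0.001, 5),
        bg=st.lists(st.floats(-5, 5), min_size=1, max_size=50),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_monotone_in_observed_for_max(self, obs, delta, bg):
        assert region_empirical_p(obs + delta, bg, "max") <= region_empirical_p(
            obs, bg, "max"
        )

    def test_floor_respected(self, rng):
        bg = rng.standard_normal(100)
        for obs in rng.standard_normal(20):
            p = region_empirical_p(obs, bg, "max")
            assert 1 / 101 <= p <= 1.0


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_three_point_hand_trace(self):
        # 3*0.01/1 = 0.03; cummin over 3*0.02/2=0.03, 3*0.03/3=0.03
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_independent_step_up(self, ps):
        assert bh_fdr(ps) == pytest.approx(oracle_bh(ps))

    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_q_at_least_p_and_order_preserving(self, ps):
        qs = bh_fdr(ps)
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
        order = np.argsort(ps)
        assert all(np.diff(np.asarray(qs)[order]) >= -1e-12)


class TestScoreRegionsOracle:
    """z, p, q for the full driver match a brute-force recomputation."""

    def _dataset(self, seed, n_regions=5, n_background=100):
        rng = np.random.default_rng(seed)
        from evoenrich.clumping import Region
        from evoenrich.matching import MatchedRegion

        all_scores = {}
        regions, matched = [], {}
        counter = 0

        def new_variants(n):
            nonlocal counter
            vs = []
            for _ in range(n):
                vid = f"s{counter}"
                all_scores[vid] = float(rng.standard_normal())
                vs.append(Variant(id=vid, chrom="1", pos=counter + 1, maf=0.3))
                counter += 1
            return frozenset(vs)

        for r in range(n_regions):
            members = new_variants(int(rng.integers(1, 6)))
            index = sorted(members, key=lambda v: v.pos)[0]
            regions.append(Region(index=index, members=members, index_pvalue=1e-9))
            matched[index.id] = [
                MatchedRegion(
                    control_index=sorted(m, key=lambda v: v.pos)[0], members=m
                )
                for m in (new_variants(int(rng.integers(1, 6)))
                          for _ in range(n_background))
            ]
        catalog = build_catalog(
            [MeasureTrack(name="m", scores=all_scores, direction="max")]
        )
        return regions, matched, catalog

    @pytest.mark.parametrize("seed", [0, 1])
    def test_driver_matches_brute_force(self, seed):
        regions, matched, catalog = self._dataset(seed)
        results = score_regions(regions, matched, catalog)
        t = catalog.tracks[0]
        ps = {}
        for res in results:
            region = next(r for r in regions if r.index.id == res.region_id)
            obs = max(t.scores[v.id] for v in region.members)
            bg = [
                max(t.scores[v.id] for v in mr.members)
                for mr in matched[res.region_id]
            ]
            mean = sum(bg) / len(bg)
            sd = math.sqrt(sum((b - mean) ** 2 for b in bg) / (len(bg) - 1))
            k = sum(1 for b in bg if b >= obs)
            assert res.observed_extreme == pytest.approx(obs)
            assert res.zscore == pytest.approx((obs - mean) / sd)
            assert res.emp_p == pytest.approx((1 + k) / (1 + len(bg)))
            assert res.n_background == len(bg)
            ps[res.region_id] = res.emp_p
        region_order = [r.region_id for r in results]
        want_q = oracle_bh([ps[rid] for rid in region_order])
        assert [r.q_value for r in results] == pytest.approx(want_q)

    def test_pooled_fdr_spans_measures(self, rng):
        regions, matched, catalog = self._dataset(3)
        extra = MeasureTrack(
            name="m2",
            scores={k: float(rng.standard_normal()) for k in catalog.tracks[0].scores},
            direction="max",
        )
        catalog2 = build_catalog([catalog.tracks[0], extra])
        pooled = score_regions(regions, matched, catalog2, fdr_scope="pooled")
        want = oracle_bh([r.emp_p for r in pooled])
        assert [r.q_value for r in pooled] == pytest.approx(want)
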