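"""Filter profiles, masks, screens and the per-rule accounting contract."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from markerpanel.genodata import MISSING, GenotypeMatrix, VariantRecord, all_site_stats
from markerpanel.qcfilters import (
    FilterProfile,
    apply_profile,
    builtin_profiles,
    density_screen,
    depth_mask,
    discard_linked,
)

from conftest import make_matrix, site_from_counts


class TestBuiltinProfiles:
    def test_preset_thresholds(self):
        p = builtin_profiles()
        assert p["WGS_5X_EastCan"].max_missing == 0.30
        assert p["WGS_5X_EastCan"].min_maf == 0.2 and not p["WGS_5X_EastCan"].maf_strict
        assert p["WGS_5X_small"].max_missing == 0.50
        assert p["WGS_30X"].max_missing == 0.10
        assert p["WGS_30X"].min_depth_per_call == 12
        assert p["GBS_platypus"].min_alt_reads == 10
        assert p["GBS_platypus"].maf_strict
        assert p["GBS_platypus"].max_variants_per_window == 3
        assert p["GBS_stacks_like"].min_rare_allele_samples == 2
        assert p["GBS_stacks_like"].min_group_genotyped == 0.60
        assert all(prof.max_ho == 0.49 for name, prof in p.items())

    def test_profile_roundtrip_through_json(self, tmp_path):
        p = builtin_profiles()["GBS_platypus"]
        p.to_json(tmp_path / "p.json")
        assert FilterProfile.from_json(tmp_path / "p.json") == p


class TestDepthMask:
    def test_low_depth_cells_become_missing(self):
        d = np.array([[0, 1], [2, 1]], dtype=np.int8)
        depth = np.array([[2, 5], [3, 5]], dtype=np.int32)
        m = make_matrix(d, depth=depth)
        out = depth_mask(m, 3)
        assert out.dosage[0, 0] == MISSING
        assert out.dosage[1, 0] == 2 and out.dosage[0, 1] == 1

    def test_zero_threshold_is_identity_and_uniform_low_depth_blanks_all(self):
        d = np.ones((3, 4), dtype=np.int8)
        depth = np.full((3, 4), 5, dtype=np.int32)
        m = make_matrix(d, depth=depth)
        assert np.array_equal(depth_mask(m, 0).dosage, d)
        assert (depth_mask(m, 12).dosage == MISSING).all()

    def test_requires_depth_layer(self):
        m = make_matrix(np.ones((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            depth_mask(m, 3)


class TestDensityScreen:
    @staticmethod
    def variants_at(positions, scaffold="sc1"):
        return [VariantRecord(scaffold, p, "A", "G") for p in positions]

    def test_overfull_window_drops_all_members(self):
        vs = self.variants_at([10, 20, 30, 40])
        assert density_screen(vs, max_per_window=3, window_bp=100) == set()

    def test_at_threshold_and_sparse_kept(self):
        vs = self.variants_at([10, 20, 30])
        assert density_screen(vs, 3, 100) == {v.id for v in vs}
        far = self.variants_at([1000, 2000, 3000, 4000])
        assert density_screen(far, 3, 100) == {v.id for v in far}

    def test_window_is_per_scaffold(self):
        vs = self.variants_at([10, 20]) + self.variants_at([15, 25], scaffold="sc2")
        assert density_screen(vs, 3, 100) == {v.id for v in vs}

    def test_positions_spanning_exactly_window_not_together(self):
        # 4 variants, outer pair 100 bp apart: no single 100-base window holds all 4
        vs = self.variants_at([1, 40, 60, 101])
        assert density_screen(vs, 3, 100) == {v.id for v in vs}


class TestDiscardLinked:
    def test_nearby_identical_vectors_collapse_to_leftmost(self):
        d = np.tile(np.array([[0], [1], [2], [0], [1], [2], [0], [1], [2], [0]], dtype=np.int8), (1, 2))
        m = make_matrix(d, spacing=50)
        kept = discard_linked(m, window_bp=10_000, min_overlap=5)
        assert kept == {m.variants[0].id}

    def test_distant_or_differing_pairs_kept(self):
        d = np.tile(np.array([[0], [1], [2], [0], [1]], dtype=np.int8), (1, 2))
        far = make_matrix(d, spacing=1_000_000)
        assert len(discard_linked(far, window_bp=10_000, min_overlap=3)) == 2
        d2 = d.copy()
        d2[0, 1] = 2  # one sample differs
        near = make_matrix(d2, spacing=50)
        assert len(discard_linked(near, window_bp=10_000, min_overlap=3)) == 2

    def test_insufficient_overlap_does_not_link(self):
        d = np.tile(np.array([[0], [1], [2]], dtype=np.int8), (1, 2))
        m = make_matrix(d, spacing=50)
        assert len(discard_linked(m, window_bp=10_000, min_overlap=10)) == 2


def grid_matrix():
    """200 sites over 20 samples spanning missingness/ho/maf space."""
    rng = np.random.default_rng(3)
    cols = []
    for _ in range(200):
        n = 20
        n_missing = rng.integers(0, 10)
        called = n - n_missing
        n_het = rng.integers(0, called + 1)
        n_hom_alt = rng.integers(0, called - n_het + 1)
        col = site_from_counts(called - n_het - n_hom_alt, n_het, n_hom_alt, n_missing)
        rng.shuffle(col)
        cols.append(col)
    return make_matrix(np.array(cols, dtype=np.int8).T)


class TestApplyProfile:
    def test_accounting_identity(self):
        m = grid_matrix()
        p = FilterProfile(name="t", min_maf=0.2, max_missing=0.3, max_ho=0.49)
        rep = apply_profile(m, p)
        assert rep.input_count == rep.n_survivors + sum(rep.rule_drops.values())

    def test_survivors_satisfy_predicates_when_rechecked(self):
        m = grid_matrix()
        p = FilterProfile(name="t", min_maf=0.2, max_missing=0.3, max_ho=0.49)
        rep = apply_profile(m, p)
        stats = all_site_stats(m).loc[rep.survivors]
        assert (stats["maf"] >= 0.2).all()
        assert (stats["missingness"] <= 0.3).all()
        assert (stats["ho"] <= 0.49).all()

    def test_boundary_semantics(self):
        # ho exactly 0.50 dropped, 0.49 kept under the cap (100 samples);
        # missingness exactly at the cap kept (inclusive keep side)
        cols = [
            site_from_counts(50, 50, 0),        # ho 0.50
            site_from_counts(51, 49, 0),        # ho 0.49, maf 0.245
            site_from_counts(40, 30, 0, 30),    # missingness 0.30
        ]
        m = make_matrix(np.array(cols, dtype=np.int8).T)
        rep = apply_profile(m, FilterProfile(name="ho", max_ho=0.49), keep_dropped_ids=True)
        assert m.variant_ids[0] in rep.dropped["ho"]
        assert m.variant_ids[1] in rep.survivors
        rep2 = apply_profile(m, FilterProfile(name="miss", max_missing=0.30))
        assert m.variant_ids[2] in rep2.survivors

    def test_strict_vs_inclusive_maf(self):
        col = site_from_counts(6, 4, 0)  # maf exactly 0.2 with 10 samples
        m = make_matrix(np.array([col], dtype=np.int8).T)
        inclusive = apply_profile(m, FilterProfile(name="i", min_maf=0.2))
        strict = apply_profile(m, FilterProfile(name="s", min_maf=0.2, maf_strict=True))
        assert inclusive.n_survivors == 1
        assert strict.n_survivors == 0

    def test_empty_profile_keeps_everything(self):
        m = grid_matrix()
        rep = apply_profile(m, FilterProfile(name="empty"))
        assert rep.n_survivors == m.n_variants

    def test_rare_allele_sample_count_rule(self):
        cols = [
            site_from_counts(8, 1, 1),  # minor allele in 2 samples
            site_from_counts(9, 1, 0),  # minor allele in 1 sample
        ]
        m = make_matrix(np.array(cols, dtype=np.int8).T)
        rep = apply_profile(m, FilterProfile(name="rare", min_rare_allele_samples=2))
        assert rep.survivors == [m.variant_ids[0]]

    def test_per_group_call_rate_rule(self):
        d = np.array(
            [
                # group a fully called, group b (last 5 samples) half missing at site 0
                [1, 1], [1, 1], [1, 1], [1, 1], [0, 0],
                [MISSING, 1], [MISSING, 0], [MISSING, 1], [0, 0], [1, 1],
            ],
            dtype=np.int8,
        )
        m = make_matrix(d)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=m.samples)
        rep = apply_profile(
            m, FilterProfile(name="g", min_group_genotyped=0.60), groups=groups
        )
        assert rep.survivors == [m.variant_ids[1]]

    def test_min_alt_reads_requires_depth(self):
        m = grid_matrix()
        with pytest.raises(ValueError, match="depth"):
            apply_profile(m, FilterProfile(name="alt", min_alt_reads=10))

    def test_min_alt_reads_rule(self):
        d = np.array([[1, 1], [1, 0], [0, 0]], dtype=np.int8)
        depth = np.array([[10, 4], [8, 9], [9, 9]], dtype=np.int32)
        m = make_matrix(d, depth=depth)
        # site 0 alt support = (10 + 8)/2 = 9; site 1 = 2
        rep = apply_profile(m, FilterProfile(name="alt", min_alt_reads=9))
        assert rep.survivors == [m.variant_ids[0]]

    @given(maf_lo=st.sampled_from([0.1, 0.2, 0.3]), maf_hi=st.sampled_from([0.3, 0.4]))
    @settings(derandomize=True, max_examples=10)
    def test_monotonicity_stricter_profiles_nest(self, maf_lo, maf_hi):
        m = grid_matrix()
        loose = apply_profile(m, FilterProfile(name="lo", min_maf=maf_lo))
        strict = apply_profile(m, FilterProfile(name="hi", min_maf=max(maf_lo, maf_hi)))
        assert set(strict.survivors) <= set(loose.survivors)

    def test_monotonicity_in_missingness_and_ho(self):
        m = grid_matrix()
        loose = apply_profile(m, FilterProfile(name="l", max_missing=0.5, max_ho=0.6))
        strict = apply_profile(m, FilterProfile(name="s", max_missing=0.2, max_ho=0.4))
        assert set(strict.survivors) <= set(loose.survivors)


class TestMafArithmetic:
    def test_inclusive_floor_implies_four_minor_alleles_in_ten_diploids(self):
        """Exhaustive over all genotype compositions of n=10: the WGS MAF rule
        passes a site iff it carries at least 4 minor-allele copies."""
        passing_counts = set()
        failing_counts = set()
        for n_het in range(11):
            for n_hom_alt in range(11 - n_het):
                n_hom_ref = 10 - n_het - n_hom_alt
                col = site_from_counts(n_hom_ref, n_het, n_hom_alt)
                m = make_matrix(np.array([col], dtype=np.int8).T)
                rep = apply_profile(m, FilterProfile(name="wgs", min_maf=0.2))
                alt = n_het + 2 * n_hom_alt
                minor = min(alt, 20 - alt)
                (passing_counts if rep.n_survivors else failing_counts).add(minor)
        assert min(passing_counts) == 4
        assert max(failing_counts) == 3
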