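"""Generator contracts: determinism, target convergence, planted effects."""

import numpy as np
import pytest

import strokeconn as sc
from strokeconn.connectivity import compute_fc, edge_vector, pearson_matrix
from strokeconn.synthetic import (
    apply_edge_deltas,
    base_correlation,
    nearest_correlation,
)


class TestBaseCorrelation:
    @pytest.mark.parametrize("condition", ["seven", "seventeen"])
    def test_positive_definite_unit_diagonal(self, condition):
        scheme = sc.build_scheme(condition)
        base = base_correlation(scheme)
        assert np.allclose(np.diag(base), 1.0)
        assert np.allclose(base, base.T)
        assert np.linalg.eigvalsh(base).min() > 0

    def test_block_values(self, seven):
        base = base_correlation(seven)
        names = seven.names
        homotopic = base[names.index("Ce-IL-VN"), names.index("Ce-CL-VN")]
        within = base[names.index("Ce-IL-VN"), names.index("Cb-IL-VN")]
        background = base[names.index("Ce-IL-VN"), names.index("Ce-IL-DMN")]
        assert homotopic == pytest.approx(0.6, abs=1e-6)
        assert within == pytest.approx(0.5, abs=1e-6)
        assert background == pytest.approx(0.1, abs=1e-6)


class TestNearestCorrelation:
    def test_psd_input_unchanged(self):
        c = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(nearest_correlation(c), c)

    def test_indefinite_input_repaired(self):
        c = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        r = nearest_correlation(c)
        assert np.linalg.eigvalsh(r).min() >= 1e-4 / 2
        assert np.allclose(np.diag(r), 1.0)


class TestGenerateCohort:
    def test_same_seed_identical(self, seven):
        a = sc.generate_cohort(seven, 3, 3, T=60, seed=5)
        b = sc.generate_cohort(seven, 3, 3, T=60, seed=5)
        for ra, rb in zip(a, b):
            assert ra.id == rb.id
            assert ra.covariates == rb.covariates
            np.testing.assert_array_equal(ra.module_ts, rb.module_ts)

    def test_group_sizes_and_lesion_consistency(self, null_cohort):
        stroke = [r for r in null_cohort if r.group == "stroke"]
        control = [r for r in null_cohort if r.group == "control"]
        assert len(stroke) == 12 and len(control) == 12
        assert all(r.lesion_hemisphere in ("left", "right") for r in stroke)
        assert all(r.lesion_size >= 16 for r in stroke)
        assert all(r.lesion_hemisphere == "none" and r.lesion_size == 0
                   for r in control)

    def test_covariate_marginals(self, seven):
        cohort = sc.generate_cohort(seven, 65, 72, T=60, seed=13)
        frame = sc.synthetic.cohort_to_frames(cohort)
        stroke = frame[frame.group == "stroke"]
        assert 50 < stroke["age"].mean() < 66
        assert 1.5 < stroke["NIHSS"].mean() < 5.5
        assert stroke["NIHSS"].min() >= 0
        assert stroke["lesion_size"].between(16, 1459).all()
        assert (stroke["lesion_hemisphere"] == "left").sum() == 36

    def test_control_fc_converges_to_base(self, seven):
        base = base_correlation(seven)
        cohort = sc.generate_cohort(seven, 2, 8, T=1000, seed=17)
        controls = [r for r in cohort if r.group == "control"]
        rs = [pearson_matrix(r.module_ts)[0] for r in controls]
        mean_r = np.mean(rs, axis=0)
        off = ~np.eye(28, dtype=bool)
        assert np.abs(mean_r - base)[off].max() < 0.1

    def test_minimum_sizes_enforced(self, seven):
        with pytest.raises(ValueError):
            sc.generate_cohort(seven, 1, 5, T=60)
        with pytest.raises(ValueError):
            sc.generate_cohort(seven, 5, 5, T=40)


class TestEdgeDeltas:
    def test_family_delta_shifts_targets(self, seven):
        """A bulk family shift moves every edge of the family in the
        planted direction; the PSD projection may shrink it but the result
        stays a valid correlation matrix."""
        from strokeconn.parcellation import edge_families

        base = base_correlation(seven)
        target = apply_edge_deltas(
            base, seven, {sc.EdgeFamily.CEREBELLAR_INTER: 0.3}
        )
        fams = np.array([f.value for f in edge_families(seven)])
        iu = np.triu_indices(28, 1)
        shift = (target - base)[iu]
        hit = fams == "cerebellar_inter"
        assert shift[hit].min() > 0.0
        assert shift[hit].mean() > np.abs(shift[~hit]).mean()
        assert np.allclose(np.diag(target), 1.0)
        assert np.linalg.eigvalsh(target).min() >= 0

    def test_explicit_edge_delta(self, seven):
        base = base_correlation(seven)
        target = apply_edge_deltas(base, seven, {(0, 5): -0.2})
        assert target[0, 5] == pytest.approx(base[0, 5] - 0.2, abs=0.02)

    def test_planted_delta_detected(self, seven):
        """A +0.3 shift on one cerebellar_inter edge is recovered at
        q < 0.01 (deep-effect smoke version of the recovery property)."""
        names = seven.names
        i, j = names.index("Cb-IL-DMN"), names.index("Cb-CL-DAN")
        effect = sc.EffectSpec(edge_deltas={(i, j): 0.3})
        cohort = sc.generate_cohort(seven, 30, 30, T=200, effect=effect, seed=29)
        # a lone significant edge needs fine permutation resolution to pass
        # BH at q < 0.01 across 378 tests (p_min = 1/(P+1) <= 0.01/378)
        res = sc.compare_groups(cohort, seven, n_perm=40_000, seed=1)
        row = res[(res.i == min(i, j)) & (res.j == max(i, j))].iloc[0]
        assert row.significant
        assert row.direction == "increase"


class TestVoxelSubject:
    def _subject(self, seven, T=80, seed=3):
        return sc.generate_cohort(seven, 2, 2, T=T, seed=seed)[0]

    def test_noise_free_module_means_recover_latent(self, seven):
        rec = self._subject(seven)
        vox = sc.generate_voxel_subject(rec, voxels_per_module=3, seed=0)
        ts, missing = sc.extract_module_ts(vox.voxel, seven)
        assert not missing
        np.testing.assert_allclose(ts.to_numpy(), rec.module_ts.to_numpy(),
                                   atol=1e-10)

    def test_half_lesioned_module_mean_unchanged(self, seven):
        rec = self._subject(seven)
        vox = sc.generate_voxel_subject(
            rec, voxels_per_module=4, lesion_fraction=0.5,
            lesioned_modules=(2,), seed=0,
        )
        ts, missing = sc.extract_module_ts(vox.voxel, seven)
        assert not missing
        np.testing.assert_allclose(ts.to_numpy(), rec.module_ts.to_numpy(),
                                   atol=1e-10)

    def test_fully_lesioned_module_flagged_missing(self, seven):
        rec = self._subject(seven)
        vox = sc.generate_voxel_subject(
            rec, voxels_per_module=4, lesion_fraction=1.0,
            lesioned_modules=(0,), seed=0,
        )
        ts, missing = sc.extract_module_ts(vox.voxel, seven)
        assert missing == frozenset({0})
        assert np.isnan(ts.iloc[:, 0]).all()
        np.testing.assert_allclose(
            ts.iloc[:, 1:].to_numpy(), rec.module_ts.iloc[:, 1:].to_numpy(),
            atol=1e-10,
        )

    def test_grid_too_small_rejected(self, seven):
        rec = self._subject(seven)
        with pytest.raises(ValueError):
            sc.generate_voxel_subject(rec, grid=(2, 2, 2), voxels_per_module=4)
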