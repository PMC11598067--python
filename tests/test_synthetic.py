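"""Synthetic bunch generator, occlusion projection, and detector emulation."""

import math

import numpy as np
import pytest

from berrymetrics import (
    ErrorModel,
    RadiusErrorModel,
    SyntheticBunchParams,
    emulate_detector,
    generate_bunch,
    project_view,
    ratio_R,
    run_recovery_experiment,
)
from berrymetrics.synthetic import _visible_indices

ZERO_COUNT = ErrorModel(0, 0)
ZERO_RADIUS = RadiusErrorModel(0, 0)


class TestGenerateBunch:
    def test_determinism(self):
        a = generate_bunch(seed=42)
        b = generate_bunch(seed=42)
        assert np.array_equal(a.centers_mm, b.centers_mm)
        assert np.array_equal(a.radii_mm, b.radii_mm)
        assert all(np.array_equal(a.visible[v], b.visible[v]) for v in (1, 2, 3))
        assert a.true_r == b.true_r

    def test_single_berry_bunch(self):
        p = SyntheticBunchParams(n_berries_range=(1, 1), envelope=(30, 30, 30))
        s = generate_bunch(p, seed=0)
        assert s.n_berries == 1
        for v in (1, 2, 3):
            assert s.true_r[v] == 1.0
            assert s.visible[v].tolist() == [0]

    def test_counts_and_radii_follow_configured_distributions(self):
        """Sample means of berry count and radius track the configured
        uniform(36,76) count and truncated-normal(9.5, 0.45) radius laws."""
        scenes = [generate_bunch(seed=s) for s in range(60)]
        ms = np.array([s.n_berries for s in scenes])
        assert 36 <= ms.min() and ms.max() <= 76
        mid, half = (36 + 76) / 2, (76 - 36) / math.sqrt(12)
        assert abs(ms.mean() - mid) < 3 * half / math.sqrt(len(ms))
        radii = np.concatenate([s.radii_mm for s in scenes])
        assert radii.mean() == pytest.approx(9.5, abs=3 * 0.45 / math.sqrt(radii.size))
        assert radii.std(ddof=1) == pytest.approx(0.45, rel=0.15)
        assert np.all(radii > 0)

    def test_no_excess_overlap(self):
        p = SyntheticBunchParams()
        s = generate_bunch(p, seed=5)
        d = np.linalg.norm(s.centers_mm[:, None] - s.centers_mm[None, :], axis=2)
        rsum = s.radii_mm[:, None] + s.radii_mm[None, :]
        off = ~np.eye(s.n_berries, dtype=bool)
        assert np.all(d[off] >= p.overlap_factor * rsum[off] - 1e-9)

    def test_true_r_at_least_one(self):
        for seed in range(8):
            s = generate_bunch(seed=seed)
            for v in (1, 2, 3):
                assert s.true_r[v] >= 1.0
                assert s.visible[v].size <= s.n_berries

    def test_visible_fraction_in_realistic_band(self):
        """Per-view visible fractions should sit in the 0.4-0.8 band observed
        for real bunches."""
        fr = []
        for seed in range(25):
            s = generate_bunch(seed=seed)
            fr += [s.visible[v].size / s.n_berries for v in (1, 2, 3)]
        assert 0.40 < min(fr) and max(fr) < 0.85
        assert 0.5 < np.mean(fr) < 0.7


class TestProjectView:
    def test_single_berry_projects_exactly(self):
        p = SyntheticBunchParams(n_berries_range=(1, 1), envelope=(30, 30, 30), r_sd_mm=0)
        s = generate_bunch(p, seed=1)
        ann = project_view(s, 1)
        assert ann.n_visible == 1
        assert ann.r_mean_px == pytest.approx(9.5 * p.focal_px / p.distance_mm, rel=1e-12)

    def test_concentric_occlusion_forced(self):
        # nearer, larger berry fully covers the farther one at any threshold
        centers = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        radii = np.array([10.0, 5.0])
        vis = _visible_indices(centers, radii, threshold=1.0)
        assert vis.tolist() == [0]

    def test_visible_count_monotone_in_threshold(self):
        s = generate_bunch(seed=9)
        counts = [project_view(s, 1, occlusion_threshold=t).n_visible for t in (0.3, 0.6, 0.9)]
        assert counts == sorted(counts)

    def test_invalid_view_rejected(self):
        s = generate_bunch(seed=0)
        with pytest.raises(ValueError):
            project_view(s, 5)


class TestDetectorEmulator:
    def test_zero_noise_is_identity(self):
        s = generate_bunch(seed=3)
        ann = project_view(s, 2)
        est = emulate_detector(ann, ZERO_COUNT, ZERO_RADIUS, seed=0)
        assert est.n_est == ann.n_visible
        assert est.r_mean_est_px == pytest.approx(ann.r_mean_px)

    def test_deterministic_bias(self):
        s = generate_bunch(seed=3)
        ann = project_view(s, 1)
        est = emulate_detector(ann, ErrorModel(-2, 0), ZERO_RADIUS, seed=0)
        assert est.n_est == ann.n_visible - 2

    def test_seed_reproducibility(self):
        s = generate_bunch(seed=3)
        ann = project_view(s, 1)
        assert emulate_detector(ann, seed=11) == emulate_detector(ann, seed=11)

    def test_count_error_distribution(self, rng):
        """10^4 emulated errors match the configured N(-1.57, 1.9^2) law;
        integer rounding adds the Sheppard 1/12 variance correction."""
        s = generate_bunch(seed=4)
        ann = project_view(s, 1)
        n = 10_000
        errs = np.array(
            [emulate_detector(ann, seed=rng).n_est - ann.n_visible for _ in range(n)],
            dtype=float,
        )
        me, sd = -1.57, 1.9
        sd_rounded = math.sqrt(sd**2 + 1 / 12)
        assert abs(errs.mean() - me) < 3 * sd_rounded / math.sqrt(n)
        assert abs(errs.std(ddof=1) - sd_rounded) < 3 * sd_rounded / math.sqrt(2 * n)

    def test_radius_error_distribution(self, rng):
        s = generate_bunch(seed=4)
        ann = project_view(s, 1)
        n = 10_000
        errs = np.array(
            [emulate_detector(ann, seed=rng).r_mean_est_px - ann.r_mean_px for _ in range(n)]
        )
        assert abs(errs.mean() - 0.15) < 3 * 1.5 / math.sqrt(n)
        assert abs(errs.std(ddof=1) - 1.5) < 3 * 1.5 / math.sqrt(2 * n)


class TestRatioRecovery:
    def test_ratio_estimator_recovers_generator_truth(self):
        from berrymetrics import bunch_volume_reference

        scenes = [generate_bunch(seed=s) for s in range(30)]
        pairs, truths = [], []
        for s in scenes:
            for v in (1, 2, 3):
                v_vis = bunch_volume_reference(s.radii_mm[s.visible[v]])
                pairs.append((s.v_total_mm3, v_vis))
                truths.append(s.true_r[v])
        est = ratio_R(pairs)
        truths = np.array(truths)
        se = truths.std(ddof=1) / math.sqrt(truths.size)
        assert abs(est.r_mean - truths.mean()) < 3 * se + 1e-12
        assert est.r_sigma == pytest.approx(truths.std(ddof=1), rel=1e-9)


class TestRecoveryExperiment:
    def test_zero_noise_exact_recovery(self):
        rep = run_recovery_experiment(
            n_bunches=6,
            count_err=ZERO_COUNT,
            radius_err=ZERO_RADIUS,
            seed=3,
            exact_r=True,
            per_berry_reference=True,
        )
        rel = (rep.table["error_mm3"] / rep.table["v_true_mm3"]).abs()
        assert rel.max() < 1e-10
        assert rep.coverage == 1.0

    def test_calibration_subset_must_leave_eval_bunches(self):
        with pytest.raises(ValueError):
            run_recovery_experiment(n_bunches=2, calib_fraction=0.9, seed=0)
        with pytest.raises(ValueError):
            run_recovery_experiment(n_bunches=1, seed=0)

    def test_noisy_recovery_smoke(self):
        """Small noisy run: sane ratio, finite uncertainties, most views pass."""
        rep = run_recovery_experiment(n_bunches=20, seed=11)
        assert 1.3 < rep.ratio.r_mean < 2.5
        assert 0.05 < rep.ratio.r_sigma < 0.5
        assert (rep.table["sigma_mm3"] > 0).all()
        assert rep.coverage > 0.8
        assert rep.n_eval_views == rep.table.shape[0]
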