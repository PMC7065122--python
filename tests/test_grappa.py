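"""Tests for estimation planning, GRAPPA kernels and g-factor maps."""

import numpy as np
import pytest

import navmoco as nm
from navmoco._fft import fft2c, ifft2c
from navmoco.grappa import (EstimationJob, EstimationPlan, LinePattern,
                            apply_plan, build_estimation_plan,
                            calibrate_kernel, calibrate_for_dataset,
                            compute_gfactor, predict_lines,
                            pseudo_replica_gfactor, rss_combine_weights)
from navmoco.synthetic import _echo_kspaces


# ------------------------------------------------------------------ plans

class TestEstimationPlan:
    def test_isolated_line(self):
        mask = np.zeros(120, bool)
        mask[59] = True
        plan = build_estimation_plan(mask, np.random.default_rng(0).random(120))
        assert len(plan.jobs) == 1
        assert plan.jobs[0].lines == (60,)
        assert plan.jobs[0].kind == "1-AMCL"

    def test_three_adjacent_collapse_to_worst_pair(self):
        """Runs of >2 adjacent corrupted lines keep only the two
        worst-scoring lines as a single 2-AMCL job."""
        mask = np.zeros(120, bool)
        mask[[49, 50, 51]] = True  # lines 50, 51, 52
        scores = np.ones(120)
        scores[49], scores[50], scores[51] = 0.3, 0.1, 0.2
        plan = build_estimation_plan(mask, scores)
        assert len(plan.jobs) == 1
        assert plan.jobs[0].lines == (51, 52)
        assert plan.jobs[0].kind == "2-AMCL"
        assert plan.skipped_lines == [(50, ">2 adjacent corrupted lines")]

    def test_cap_with_isolated_lines_matches_oracle(self):
        rng = np.random.default_rng(1)
        lines = np.arange(5, 5 + 14 * 3, 3)  # 14 isolated lines
        mask = np.zeros(120, bool)
        mask[lines - 1] = True
        scores = rng.random(120)
        plan = build_estimation_plan(mask, scores, cap=12)
        # oracle: 12 worst isolated lines by brute-force sort
        worst12 = sorted(lines, key=lambda ln: scores[ln - 1])[:12]
        assert sorted(plan.all_lines()) == sorted(worst12)
        capped = [ln for ln, r in plan.skipped_lines if r == "cap"]
        assert sorted(capped) == sorted(set(lines) - set(worst12))
        # worst-first ordering
        job_scores = [j.score for j in plan.jobs]
        assert job_scores == sorted(job_scores)

    def test_empty_mask_empty_plan(self):
        plan = build_estimation_plan(np.zeros(120, bool), np.ones(120))
        assert plan.jobs == [] and plan.skipped_lines == []

    @pytest.mark.parametrize("cap", [0, 4, 7, 12])
    def test_cap_never_exceeded(self, cap):
        rng = np.random.default_rng(2)
        mask = rng.random(120) < 0.15
        plan = build_estimation_plan(mask, rng.random(120), cap=cap)
        assert plan.n_lines <= cap
        assert all(len(j.lines) <= 2 for j in plan.jobs)

    def test_pair_stays_pair(self):
        mask = np.zeros(120, bool)
        mask[[29, 30]] = True
        plan = build_estimation_plan(mask, np.ones(120))
        assert plan.jobs[0].lines == (30, 31)
        assert plan.jobs[0].kind == "2-AMCL"


# ---------------------------------------------------------------- kernels

def _planted_relation_kspace(ny=64, nx=64, ncoils=2, n_support=12, seed=0):
    """k-space obeying an exact shift-invariant source->target relation.

    An image supported on ``n_support`` pixels satisfies, for every
    placement, the GRAPPA relation whose ky/kx filter has symbol 1 at the
    support pixels; the filter coefficients are solved from that linear
    constraint (n_support <= number of coefficients)."""
    rng = np.random.default_rng(seed)
    shifts = [(w, t) for w in (-2, -1, 1, 2) for t in range(-2, 3)]
    support = [(int(y), int(x))
               for y, x in rng.integers(8, ny - 8, size=(n_support, 2))]
    basis = np.zeros((n_support, len(shifts)), complex)
    for i, (y, x) in enumerate(support):
        delta = np.zeros((ny, nx), complex)
        delta[y, x] = 1.0
        k = fft2c(delta)
        for j, (w, t) in enumerate(shifts):
            rolled = np.roll(np.roll(k, -w, axis=0), -t, axis=1)
            basis[i, j] = ifft2c(rolled)[y, x]
    coeffs, *_ = np.linalg.lstsq(basis, np.ones(n_support), rcond=None)
    assert np.abs(basis @ coeffs - 1).max() < 1e-9
    img = np.zeros((ncoils, ny, nx), complex)
    for (y, x) in support:
        img[:, y, x] = rng.standard_normal(ncoils) \
            + 1j * rng.standard_normal(ncoils)
    return fft2c(img)


class TestCalibrateKernel:
    def test_planted_kernel_exact(self):
        k = _planted_relation_kspace()
        kern = calibrate_kernel(k[:, 16:44, :], kind="1-AMCL",
                                regularization=1e-12)
        assert kern.residual < 1e-8
        pred = predict_lines(kern, k, 50)[0]
        interior = slice(2, -2)  # kx zero-padding differs from the
        truth = k[:, 50, interior]  # circular planted relation at edges
        err = np.linalg.norm(pred[:, interior] - truth)
        assert err / np.linalg.norm(truth) < 1e-8

    def test_single_coil_exactly_representable(self):
        k = _planted_relation_kspace(ncoils=1, n_support=8, seed=3)
        kern = calibrate_kernel(k[:, 16:44, :], kind="1-AMCL",
                                regularization=1e-12)
        pred = predict_lines(kern, k, 50)[0]
        interior = slice(2, -2)
        truth = k[:, 50, interior]
        assert (np.linalg.norm(pred[:, interior] - truth)
                / np.linalg.norm(truth)) < 1e-6

    def test_calib_too_narrow_raises(self):
        data = np.zeros((4, 3, 96), complex)
        with pytest.raises(ValueError, match="calib"):
            calibrate_kernel(data, kind="2-AMCL")

    def test_source_target_overlap_rejected(self):
        data = np.zeros((4, 30, 96), complex)
        with pytest.raises(ValueError):
            calibrate_kernel(data, kind="1-AMCL", source_offsets=(0, 1),
                             target_offsets=(0,))

    def test_no_encoding_limit(self):
        """With a single uniform coil and spatially white image content,
        there is no sensitivity encoding and the pair estimation fails
        (relative error ~100%), while multi-coil encoding recovers it."""
        ph = nm.make_phantom((96, 96), 0)
        rng = np.random.default_rng(2)
        white = rng.standard_normal((96, 96)) \
            + 1j * rng.standard_normal((96, 96))

        def nrmse_for(ncoils, uniform):
            co = nm.make_coil_profiles(ph, ncoils=ncoils, rng_seed=1,
                                       uniform=uniform)
            k = fft2c(co.sensitivities * white[None])
            kern = calibrate_kernel(k[:, 36:60, :], kind="2-AMCL")
            pred = predict_lines(kern, k, 19)
            truth = k[:, 19:21, :].transpose(1, 0, 2)
            return np.linalg.norm(pred - truth) / np.linalg.norm(truth)

        assert nrmse_for(1, True) > 0.8
        assert nrmse_for(4, False) < 0.5


class TestApplyPlan:
    def test_empty_plan_no_change(self, small_clean_ds):
        kernels = calibrate_for_dataset(small_clean_ds)
        out, executed = apply_plan(small_clean_ds, EstimationPlan(), kernels)
        assert np.array_equal(out.data, small_clean_ds.data)
        assert executed.jobs == []

    def test_estimate_clean_line_consistency(self, small_clean_ds):
        """Estimating a never-corrupted line reproduces it accurately."""
        kernels = calibrate_for_dataset(small_clean_ds)
        plan = EstimationPlan(jobs=[EstimationJob((30,), "1-AMCL", 0.0)])
        out, executed = apply_plan(small_clean_ds, plan, kernels,
                                   corrupted_lines={30})
        assert [j.lines for j in executed.jobs] == [(30,)]
        for sl in range(small_clean_ds.data.shape[0]):
            for e in range(small_clean_ds.data.shape[1]):
                a = out.data[sl, e, 29]
                b = small_clean_ds.data[sl, e, 29]
                assert (np.linalg.norm(a - b)
                        / np.linalg.norm(b)) < 5e-2
        # untouched lines are bit-identical
        rest = np.ones(60, bool)
        rest[29] = False
        assert np.array_equal(out.data[:, :, rest],
                              small_clean_ds.data[:, :, rest])

    def test_unclean_sources_reflagged(self, small_clean_ds):
        kernels = calibrate_for_dataset(small_clean_ds)
        # line 31 skipped (still corrupted) is a source of the job at 30
        plan = EstimationPlan(jobs=[EstimationJob((30,), "1-AMCL", 0.0)],
                              skipped_lines=[(31, "cap")])
        out, executed = apply_plan(small_clean_ds, plan, kernels)
        assert executed.jobs == []
        assert (30, "unclean source lines") in executed.skipped_lines
        assert np.array_equal(out.data, small_clean_ds.data)

    def test_edge_line_without_sources_skipped(self, small_clean_ds):
        kernels = calibrate_for_dataset(small_clean_ds)
        plan = EstimationPlan(jobs=[EstimationJob((60,), "1-AMCL", 0.0)])
        out, executed = apply_plan(small_clean_ds, plan, kernels)
        assert executed.jobs == []
        assert executed.skipped_lines[0][0] == 60


# --------------------------------------------------------------- g-factor

@pytest.fixture(scope="module")
def small_g_setup(small_phantom):
    coils = nm.make_coil_profiles(small_phantom, ncoils=4, rng_seed=1)
    sched = nm.AcquisitionSchedule(matrix_size=(96, 96), n_slices=1,
                                   n_imaging_echoes=3, navigator_echo_index=4)
    ks, kt = _echo_kspaces(small_phantom, coils, np.array([9.1]))
    kfull = (ks + kt)[0]
    rng = np.random.default_rng(5)
    calib = kfull[:, 36:60, :]
    calib = calib + 0.005 * (rng.standard_normal(calib.shape)
                             + 1j * rng.standard_normal(calib.shape))
    kernels = {kind: [calibrate_kernel(calib, kind=kind)]
               for kind in ("1-AMCL", "2-AMCL")}
    weights = rss_combine_weights(ifft2c(kfull))
    obj = small_phantom.tissue_labels > 0
    return sched, kernels, weights, obj


class TestGFactor:
    def test_empty_pattern_unity(self, small_g_setup):
        sched, kernels, weights, obj = small_g_setup
        pattern = LinePattern(ny=96, nx=96, ncoils=4,
                              acquired_rows=np.arange(60))
        g = compute_gfactor(pattern, weights)
        assert np.allclose(g.g, 1.0)
        assert np.allclose(g.retained_snr, 1.0)

    def test_matches_pseudo_replica_oracle(self, small_g_setup):
        sched, kernels, weights, obj = small_g_setup
        jobs = [EstimationJob((ln,), "1-AMCL", 0.0)
                for ln in (12, 20, 28, 36, 44, 52)]
        jobs += [EstimationJob((16, 17), "2-AMCL", 0.0)]
        pattern = LinePattern.from_plan(EstimationPlan(jobs=jobs), kernels,
                                        sched)
        g_an = compute_gfactor(pattern, weights)
        g_mc = pseudo_replica_gfactor(pattern, weights, n_replicas=200,
                                      rng_seed=11)
        rel = (g_an.g[obj] - g_mc.g[obj]) / g_mc.g[obj]
        assert np.sqrt((rel ** 2).mean()) < 0.05

    def test_coil_covariance_matches_oracle(self, small_g_setup):
        sched, kernels, weights, obj = small_g_setup
        rng = np.random.default_rng(0)
        a = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        psi = a @ a.conj().T + 4 * np.eye(4)
        jobs = [EstimationJob((24,), "1-AMCL", 0.0),
                EstimationJob((40, 41), "2-AMCL", 0.0)]
        pattern = LinePattern.from_plan(EstimationPlan(jobs=jobs), kernels,
                                        sched)
        g_an = compute_gfactor(pattern, weights, noise_covariance=psi)
        g_mc = pseudo_replica_gfactor(pattern, weights, n_replicas=200,
                                      rng_seed=3, noise_covariance=psi)
        rel = (g_an.g[obj] - g_mc.g[obj]) / g_mc.g[obj]
        assert np.sqrt((rel ** 2).mean()) < 0.05

    def test_g_not_much_below_one_on_object(self, small_g_setup):
        sched, kernels, weights, obj = small_g_setup
        jobs = [EstimationJob((30, 31), "2-AMCL", 0.0)]
        pattern = LinePattern.from_plan(EstimationPlan(jobs=jobs), kernels,
                                        sched)
        g = compute_gfactor(pattern, weights)
        assert g.g[obj].min() > 0.9

    def test_cross_feeding_pattern_rejected(self, small_g_setup):
        sched, kernels, weights, obj = small_g_setup
        jobs = [EstimationJob((30,), "1-AMCL", 0.0),
                EstimationJob((32,), "1-AMCL", 0.0)]  # 32 sources include 30
        with pytest.raises(ValueError, match="source"):
            LinePattern.from_plan(EstimationPlan(jobs=jobs), kernels, sched)


class TestPseudoReplica:
    def test_full_sampling_unity(self, small_g_setup):
        sched, kernels, weights, obj = small_g_setup
        pattern = LinePattern(ny=96, nx=96, ncoils=4,
                              acquired_rows=np.arange(60))
        g = pseudo_replica_gfactor(pattern, weights, n_replicas=60,
                                   rng_seed=0)
        assert np.allclose(g.g, 1.0)

    def test_seed_agreement(self, small_g_setup):
        sched, kernels, weights, obj = small_g_setup
        jobs = [EstimationJob((20,), "1-AMCL", 0.0),
                EstimationJob((40, 41), "2-AMCL", 0.0)]
        pattern = LinePattern.from_plan(EstimationPlan(jobs=jobs), kernels,
                                        sched)
        g_a = pseudo_replica_gfactor(pattern, weights, n_replicas=200,
                                     rng_seed=1)
        g_b = pseudo_replica_gfactor(pattern, weights, n_replicas=200,
                                     rng_seed=2)
        rel = (g_a.g[obj] - g_b.g[obj]) / g_b.g[obj]
        assert np.sqrt((rel ** 2).mean()) < 0.08

    def test_zero_noise_rejected(self, small_g_setup):
        sched, kernels, weights, obj = small_g_setup
        pattern = LinePattern(ny=96, nx=96, ncoils=4,
                              acquired_rows=np.arange(60))
        with pytest.raises(ValueError):
            pseudo_replica_gfactor(pattern, weights, noise_sd=0.0)
        with pytest.raises(ValueError):
            pseudo_replica_gfactor(pattern, weights, n_replicas=10)
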