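"""Error metrics, clinical indices, agreement and vortex analysis."""

import warnings

import numpy as np
import pytest

import hemopoint as hp
from hemopoint.evaluation import (
    MRE_FLOOR_FRACTION,
    agreement,
    compute_ffr,
    graft_flow,
    high_error_overlap,
    mre,
    nmae,
    pointwise_relative_error,
    region_mre,
    regional_report,
    sweep_fraction_seed,
    training_size_sweep,
    vorticity_field,
)
from hemopoint.exceptions import EvaluationError, PreconditionError
from hemopoint.flow import BoundaryConditions, FluidProperties, solve_network
from hemopoint.geometry import GeometryRanges, Stenosis
from conftest import single_segment_tree


def brute_force_nmae(truth, pred):
    """Independent loop implementation of the range-normalized error."""
    truth = np.atleast_2d(np.asarray(truth, dtype=float).T).T
    pred = np.atleast_2d(np.asarray(pred, dtype=float).T).T
    mags = [np.sqrt(sum(c * c for c in row)) for row in truth]
    total = 0.0
    for i in range(len(truth)):
        d = truth[i] - pred[i]
        total += np.sqrt(sum(c * c for c in d))
    return total / len(truth) / (max(mags) - min(mags)) * 100.0


def brute_force_mre(truth, pred):
    truth = np.atleast_2d(np.asarray(truth, dtype=float).T).T
    pred = np.atleast_2d(np.asarray(pred, dtype=float).T).T
    mags = [np.sqrt(sum(c * c for c in row)) for row in truth]
    floor = MRE_FLOOR_FRACTION * max(mags)
    total, n = 0.0, 0
    for i in range(len(truth)):
        if mags[i] < floor:
            continue
        d = truth[i] - pred[i]
        total += np.sqrt(sum(c * c for c in d)) / mags[i]
        n += 1
    return total / n * 100.0


class TestErrorFunctions:
    def test_hand_examples(self):
        assert nmae([1.0, 2.0], [1.1, 1.8]) == pytest.approx(15.0, rel=1e-12)
        assert mre([1.0, 2.0], [1.1, 1.8]) == pytest.approx(10.0, rel=1e-12)

    def test_perfect_prediction_is_zero(self):
        x = np.random.default_rng(0).normal(size=(50, 3))
        assert nmae(x, x) == 0.0
        assert mre(x, x) == 0.0

    def test_orthogonal_unit_vectors(self):
        assert mre(np.array([[1.0, 0, 0]]), np.array([[0, 1.0, 0]])) == pytest.approx(
            100 * np.sqrt(2), rel=1e-12
        )

    def test_constant_truth_raises(self):
        with pytest.raises(EvaluationError):
            nmae([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_brute_force_on_random_arrays(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 500))
            k = int(rng.choice([1, 3]))
            shape = (n,) if k == 1 else (n, 3)
            truth = rng.normal(size=shape) * rng.uniform(0.1, 10)
            pred = truth + rng.normal(size=shape) * 0.3
            assert nmae(truth, pred) == pytest.approx(
                brute_force_nmae(truth, pred), rel=1e-12
            )
            assert mre(truth, pred) == pytest.approx(
                brute_force_mre(truth, pred), rel=1e-12
            )

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        truth = rng.normal(size=(80, 3))
        pred = truth + 0.1 * rng.normal(size=(80, 3))
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        assert nmae(truth @ R.T, pred @ R.T) == pytest.approx(nmae(truth, pred), rel=1e-10)
        assert mre(truth @ R.T, pred @ R.T) == pytest.approx(mre(truth, pred), rel=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        truth = rng.normal(size=(60,))
        pred = truth + 0.2 * rng.normal(size=(60,))
        for c in (1e-6, 3.7, 1e8):
            assert nmae(c * truth, c * pred) == pytest.approx(nmae(truth, pred), rel=1e-9)
            assert mre(c * truth, c * pred) == pytest.approx(mre(truth, pred), rel=1e-9)


class TestRegionalReport:
    def test_perfect_predictions_all_zero(self, tiny_velocity_corpus):
        samples = tiny_velocity_corpus.test[:1]
        preds = [samples[0].query.targets.copy()]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = regional_report(samples, preds)
        for r in rep.regions:
            assert rep.nmae_mean[r] == 0.0
            assert rep.mre_std[r] == 0.0

    def test_two_model_aggregation_uses_population_std(self):
        # construct two single-region scalar models with MREs 10% and 20%
        from hemopoint.data import HemodynamicSample, QueryPointCloud
        from hemopoint.geometry import SurfacePointCloud

        samples, preds = [], []
        for rel in (0.10, 0.20):
            truth = np.array([[1.0, 0, 0], [2.0, 0, 0]])
            pred = truth * (1 + rel)
            samples.append(
                HemodynamicSample(
                    surface=SurfacePointCloud(np.zeros((1, 3)) + 1.0),
                    query=QueryPointCloud(
                        coordinates=np.zeros((2, 3)),
                        targets=truth,
                        region=np.array(["lcx", "lcx"]),
                    ),
                    op_state="preoperative", field_kind="velocity",
                    model_id="m", base_model_id="b",
                )
            )
            preds.append(pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = regional_report(samples, preds)
        assert rep.mre_mean["lcx"] == pytest.approx(15.0, rel=1e-12)
        assert rep.mre_std["lcx"] == pytest.approx(5.0, rel=1e-12)

    def test_graft_row_absent_preoperatively(self, tiny_velocity_corpus):
        preds = [s.query.targets for s in tiny_velocity_corpus.test]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = regional_report(tiny_velocity_corpus.test, preds)
        assert "graft" not in rep.regions


class TestFFR:
    def test_zero_stenosis_idealization_gives_unity(self):
        # wide LAD with a zero-rate stenosis marker: negligible resistance,
        # equal pressures up- and downstream
        tree = single_segment_tree(
            radius=0.05, length=0.08,
            stenosis=Stenosis(rate=0.0, center=0.3, extent=0.008),
        )
        ffr = compute_ffr(tree, solve_network(tree))
        assert ffr == pytest.approx(1.0, abs=1e-4)

    def test_ffr_decreases_with_stenosis_rate(self, base_tree):
        vals = []
        for s in (0.60, 0.70, 0.80, 0.90):
            r = GeometryRanges(stenosis_rate=(s, s), n_stenoses=(1, 1),
                               stenosis_center_frac=(0.4, 0.4))
            (tree,) = hp.expand_model(base_tree, r, 1, seed=17)
            vals.append(compute_ffr(tree, solve_network(tree)))
        assert all(0 < v <= 1 for v in vals)
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_offset_clamped_with_warning(self, base_tree):
        with pytest.warns(UserWarning, match="clamped"):
            compute_ffr(base_tree, solve_network(base_tree), distal_offset=10.0)

    def test_point_cloud_variant_agrees_with_accessor(self, base_tree):
        from hemopoint.evaluation import compute_ffr_from_points
        from hemopoint.flow import make_sample

        s = make_sample(base_tree, BoundaryConditions(), FluidProperties(),
                        40000, 0.01, "pressure", seed=2)
        sol = s.solution
        a = compute_ffr(base_tree, sol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = compute_ffr_from_points(
                base_tree, s.query.coordinates, s.query.region, s.scalar_targets
            )
        assert b == pytest.approx(a, abs=2e-4)


class TestGraftFlow:
    def test_area_formula_with_uniform_accessor(self, base_tree):
        post = hp.add_graft(base_tree, seed=3)
        seg = post.segments_by_role("graft")[0]

        def accessor(coords):
            # constant 0.5 m/s along the local axis is awkward; instead give a
            # constant vector and project: use axis at inlet (u ~ 0)
            t = post.tangent_at(seg, np.zeros(len(coords)))
            return 0.5 * t

        q = graft_flow(post, accessor, n_slab_points=2000, seed=1, slab_frac=0.01)
        assert q == pytest.approx(0.5 * np.pi * 0.002**2 / 4, rel=1e-6)
        assert q == pytest.approx(1.5708e-6, rel=1e-4)

    def test_zero_velocity_gives_zero(self, base_tree):
        post = hp.add_graft(base_tree, seed=3)
        q = graft_flow(post, lambda c: np.zeros((len(c), 3)), n_slab_points=500, seed=1)
        assert q == 0.0

    def test_slab_estimate_matches_network_flow(self, base_tree):
        post = hp.add_graft(base_tree, seed=3)
        sol = solve_network(post)
        q_slab = graft_flow(post, sol, n_slab_points=20000, seed=5)
        q_net = sol.segment_flows["graft"]
        assert q_slab == pytest.approx(q_net, rel=0.02)

    def test_requires_graft(self, base_tree):
        with pytest.raises(PreconditionError):
            graft_flow(base_tree, lambda c: np.zeros((len(c), 3)))


class TestAgreement:
    def test_identical_vectors(self):
        st = agreement([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert st.pearson_r == pytest.approx(1.0)
        assert st.mean_difference == 0.0
        assert st.loa_low == st.loa_high == 0.0

    def test_hand_computed_limits(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a - np.array([0.01, -0.01, 0.01, -0.01])
        st = agreement(a, b)
        assert st.mean_difference == pytest.approx(0.0, abs=1e-15)
        assert st.loa_high == pytest.approx(0.0196, rel=1e-12)
        assert st.loa_low == pytest.approx(-0.0196, rel=1e-12)
        assert st.n_within_limits == st.n == 4

    def test_anticorrelated(self):
        st = agreement([1.0, 2.0, 3.0], [5.0, 4.0, 3.0])
        assert st.pearson_r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=40)
        b = a + rng.normal(size=40) * 0.3
        st = agreement(a, b)
        from scipy.stats import pearsonr

        r_ref, p_ref = pearsonr(a, b)
        assert st.pearson_r == pytest.approx(r_ref)
        assert st.p_value == pytest.approx(p_ref)
        d = a - b
        assert st.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=0), rel=1e-12)


class TestVorticity:
    def test_rigid_rotation_recovers_twice_omega(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-1, 1, size=(4000, 3))
        omega = np.array([0.0, 0.0, 1.0])
        vel = np.cross(omega, coords)
        vf = vorticity_field(coords, vel, k_neighbors=20)
        good = ~vf.flagged
        assert np.abs(vf.magnitude[good] - 2.0).max() < 0.05

    def test_uniform_translation_has_no_vorticity(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(-1, 1, size=(2000, 3))
        vel = np.tile([0.3, -0.2, 0.1], (2000, 1))
        vf = vorticity_field(coords, vel, k_neighbors=15)
        assert vf.magnitude.max() < 0.01

    def test_poiseuille_closed_form(self):
        # |omega|(rho) = 4*ubar*rho/r ; at ubar=0.1, r=0.0015, rho=0.5 -> 133.33/s
        rng = np.random.default_rng(7)
        n = 6000
        r, ubar = 0.0015, 0.1
        x = rng.uniform(0, 0.01, size=n)
        rho = np.sqrt(rng.uniform(0, 1, size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        coords = np.column_stack([x, rho * r * np.cos(th), rho * r * np.sin(th)])
        vel = np.column_stack(
            [2 * ubar * (1 - rho**2), np.zeros(n), np.zeros(n)]
        )
        vf = vorticity_field(coords, vel, k_neighbors=25)
        sel = (np.abs(rho - 0.5) < 0.05) & ~vf.flagged
        expected = 4 * ubar * 0.5 / r  # 133.33 1/s
        assert expected == pytest.approx(133.33, rel=1e-3)
        assert np.median(vf.magnitude[sel]) == pytest.approx(expected, abs=5.0)

    def test_threshold_and_mask(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(-1, 1, size=(1000, 3))
        vel = np.cross([0, 0, 1.0], coords)
        vf = vorticity_field(coords, vel, k_neighbors=15, threshold=1.0)
        assert vf.mask.sum() > 0
        assert not vf.mask[vf.flagged].any()


class TestOverlap:
    def test_identical_sets_overlap_fully(self):
        err = np.array([50.0, 5.0, 50.0, 5.0])
        mask = err > 10
        st = high_error_overlap(err, mask)
        assert st.overlap == 1.0

    def test_disjoint_sets(self):
        err = np.array([50.0, 5.0, 50.0, 5.0])
        mask = ~(err > 10)
        assert high_error_overlap(err, mask).overlap == 0.0

    def test_no_high_error_points_reported_not_raised(self):
        st = high_error_overlap(np.array([1.0, 2.0]), np.array([True, False]))
        assert st.n_high_error == 0
        assert np.isnan(st.overlap)

    def test_independent_random_mask_matches_density(self):
        rng = np.random.default_rng(10)
        n = 10_000
        err = rng.uniform(0, 20, size=n)  # half above 10 on average
        q = 0.3
        mask = rng.uniform(size=n) < q
        st = high_error_overlap(err, mask)
        sigma = np.sqrt(q * (1 - q) / st.n_high_error)
        assert abs(st.overlap - q) < 3 * sigma


class TestSweep:
    def test_single_full_fraction_matches_standard_run(self, tiny_velocity_corpus):
        import dataclasses

        cfg = hp.NetworkConfig(epochs=2, seed=0)
        res = training_size_sweep(tiny_velocity_corpus, cfg, fractions=[1.0], seed=3)
        assert len(res.fractions) == 1
        ref_cfg = dataclasses.replace(cfg, seed=sweep_fraction_seed(3, 0))
        from hemopoint.network import PointNetRegressor, train_network

        net = PointNetRegressor(ref_cfg)
        train_network(net, tiny_velocity_corpus, ref_cfg)
        preds = [
            net.predict(s.surface.coordinates, s.query.coordinates)
            for s in tiny_velocity_corpus.test
        ]
        expected = region_mre(tiny_velocity_corpus.test, preds, "aorta_and_branches")
        assert res.mre_values[0] == pytest.approx(expected, rel=1e-12)

    def test_sweep_deterministic(self, tiny_velocity_corpus):
        cfg = hp.NetworkConfig(epochs=1, seed=0)
        r1 = training_size_sweep(tiny_velocity_corpus, cfg, fractions=[0.5, 1.0], seed=4)
        r2 = training_size_sweep(tiny_velocity_corpus, cfg, fractions=[0.5, 1.0], seed=4)
        assert r1.mre_values == r2.mre_values
        assert len(r1.fractions) == 2


def test_pointwise_relative_error_floor():
    truth = np.array([1.0, 1e-30, 2.0])
    pred = np.array([1.1, 5.0, 1.8])
    rel = pointwise_relative_error(truth, pred)
    assert np.isnan(rel[1])
    assert rel[0] == pytest.approx(10.0)


def test_bland_altman_plot_writes_figure(tmp_path):
    rng = np.random.default_rng(11)
    a = rng.normal(size=20)
    b = a + 0.1 * rng.normal(size=20)
    from hemopoint.evaluation import bland_altman_plot

    st = bland_altman_plot((a, b), tmp_path / "ba.png")
    assert (tmp_path / "ba.png").stat().st_size > 0
    assert st.loa_low < st.mean_difference < st.loa_high
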