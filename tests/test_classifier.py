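import json
import math

import numpy as np
import pytest

import mortwear as mw


def normpdf(v, mu, sigma):
    return math.exp(-0.5 * ((v - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


class TestFit:
    def test_two_point_class_parameters(self):
        sd = [1, 3, 10, 12, 20, 22]
        cv = [0.1, 0.3, 1.0, 1.2, 2.0, 2.2]
        labels = ["A", "A", "B", "B", "C", "C"]
        res = mw.DurationClassifier(sd, cv, labels).fit()
        a = res.classes["A"]
        assert a.mu_x == pytest.approx(2.0)
        assert a.sigma_x == pytest.approx(math.sqrt(2.0))
        assert a.mu_y == pytest.approx(0.2)
        assert a.prior == pytest.approx(1 / 3)

    def test_parameter_recovery_within_three_se(self, rng):
        truth = {"A": (2, 0.5, 0.15, 0.03), "B": (4, 0.8, 0.28, 0.05), "C": (5, 0.7, 0.38, 0.06)}
        n = 500
        sd, cv, labels = [], [], []
        for k, (mx, sx, my, sy) in truth.items():
            sd += list(rng.normal(mx, sx, n))
            cv += list(rng.normal(my, sy, n))
            labels += [k] * n
        res = mw.DurationClassifier(sd, cv, labels).fit()
        for k, (mx, sx, my, sy) in truth.items():
            g = res.classes[k]
            assert abs(g.mu_x - mx) < 3 * sx / math.sqrt(n)
            assert abs(g.mu_y - my) < 3 * sy / math.sqrt(n)
            assert abs(g.sigma_x - sx) < 3 * sx / math.sqrt(2 * n)
            assert abs(g.sigma_y - sy) < 3 * sy / math.sqrt(2 * n)

    def test_insufficient_class_or_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mw.DurationClassifier([1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.4, 0.5],
                                  ["A", "A", "B", "B", "C"]).fit()
        with pytest.raises(ValueError, match="zero within-class variance"):
            mw.DurationClassifier([1, 1, 3, 4, 5, 6], [0.1, 0.1, 0.3, 0.4, 0.5, 0.6],
                                  ["A", "A", "B", "B", "C", "C"]).fit()

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            mw.DurationClassifier([1, 2], [0.1, 0.2], ["A", "D"])

    def test_matches_reference_naive_bayes(self, rng):
        """Cross-check against scikit-learn's GaussianNB (ML variances)."""
        sklearn = pytest.importorskip("sklearn.naive_bayes")
        X = np.vstack(
            [
                rng.normal([2, 0.15], [0.5, 0.03], (40, 2)),
                rng.normal([4, 0.28], [0.8, 0.05], (40, 2)),
                rng.normal([5, 0.38], [0.7, 0.06], (40, 2)),
            ]
        )
        y = np.repeat(["A", "B", "C"], 40)
        res = mw.DurationClassifier(X[:, 0], X[:, 1], y).fit(ddof=0)
        ref = sklearn.GaussianNB(priors=[1 / 3] * 3, var_smoothing=1e-12).fit(X, y)
        for i, k in enumerate(["A", "B", "C"]):
            g = res.classes[k]
            assert ref.theta_[i] == pytest.approx([g.mu_x, g.mu_y], rel=1e-9)
            assert ref.var_[i] == pytest.approx([g.sigma_x**2, g.sigma_y**2], rel=1e-6)
        grid = np.column_stack(
            [rng.uniform(0, 7, 400), rng.uniform(0, 0.5, 400)]
        )
        ours = [res.classify(s, c, isolines=False).region for s, c in grid]
        assert list(ref.predict(grid)) == ours


class TestDensities:
    def test_brute_force_density_oracle(self, default_fit, rng):
        for _ in range(20):
            x, y = rng.uniform(0, 8), rng.uniform(0, 0.5)
            for k in ("A", "B", "C"):
                g = default_fit.classes[k]
                expect = g.prior * normpdf(x, g.mu_x, g.sigma_x) * normpdf(y, g.mu_y, g.sigma_y)
                assert default_fit.class_density(k, x, y) == pytest.approx(expect, abs=1e-10, rel=1e-10)

    def test_mode_value_and_tail_decay(self, default_fit):
        g = default_fit.classes["B"]
        mode = default_fit.class_density("B", g.mu_x, g.mu_y)
        assert mode == pytest.approx(g.prior / (2 * math.pi * g.sigma_x * g.sigma_y))
        assert default_fit.class_density("B", 1e4, g.mu_y) < 1e-300 * mode + 1e-300

    def test_class_density_integrates_to_prior(self, default_fit):
        from scipy import integrate

        g = default_fit.classes["A"]
        mass, _ = integrate.dblquad(
            lambda y, x: default_fit.class_density("A", x, y),
            g.mu_x - 10 * g.sigma_x, g.mu_x + 10 * g.sigma_x,
            lambda x: g.mu_y - 10 * g.sigma_y, lambda x: g.mu_y + 10 * g.sigma_y,
        )
        assert mass == pytest.approx(g.prior, abs=1e-6)


class TestClassify:
    def test_mode_dominance(self, separated_fit):
        for k in ("A", "B", "C"):
            g = separated_fit.classes[k]
            r = separated_fit.classify(g.mu_x, g.mu_y, isolines=False)
            assert r.region == k and r.posterior[k] > 0.999
            assert r.error_prob < 1e-3

    def test_posteriors_normalised_everywhere(self, default_fit, rng):
        xs, ys = rng.uniform(-1, 9, 200), rng.uniform(-0.1, 0.55, 200)
        post = default_fit.posteriors(xs, ys)
        assert post.min() >= 0
        np.testing.assert_allclose(post.sum(axis=0), 1.0, atol=1e-12)

    def test_non_finite_input_rejected(self, default_fit):
        with pytest.raises(ValueError):
            default_fit.classify(float("nan"), 0.2)

    def test_region_invariant_under_common_prior_scaling(self, rng):
        pts = mw.synthetic_training_points(seed=3)
        model = mw.DurationClassifier.from_points(pts)
        res1 = model.fit(priors=[1, 1, 1])
        res2 = model.fit(priors=[2, 2, 2])
        for _ in range(50):
            x, y = rng.uniform(0, 7), rng.uniform(0, 0.5)
            assert (
                res1.classify(x, y, isolines=False).region
                == res2.classify(x, y, isolines=False).region
            )

    def test_tie_break_order(self):
        # two identical classes: the tie goes to the earlier label (A < B)
        sd = [1, 3, 1, 3, 30, 32]
        cv = [0.1, 0.3, 0.1, 0.3, 3.0, 3.2]
        res = mw.DurationClassifier(sd, cv, ["A", "A", "B", "B", "C", "C"]).fit()
        assert res.classify(2.0, 0.2, isolines=False).region == "A"


class TestBoundaries:
    def test_symmetric_classes_give_perpendicular_bisector(self):
        # A and B share sigmas and priors -> boundary is the perpendicular
        # bisector of the segment joining the modes
        rngl = np.random.default_rng(1)
        eps_x = [-0.4, 0.4]
        sd = [2 + e for e in eps_x] + [6 + e for e in eps_x] + [40, 41]
        cv = [0.2 + 0.04 * e for e in [-1, 1]] * 2 + [4.0, 4.1]
        labels = ["A", "A", "B", "B", "C", "C"]
        grid = mw.GridSpec(x_min=0, x_max=10, y_min=-0.5, y_max=1.0, nx=600, ny=400)
        res = mw.DurationClassifier(sd, cv, labels).fit(grid=grid)
        a, b = res.classes["A"], res.classes["B"]
        assert a.sigma_x == pytest.approx(b.sigma_x)
        assert a.sigma_y == pytest.approx(b.sigma_y)
        lines = res.boundary_curve(("A", "B"))
        verts = np.concatenate(lines)
        # bisector: x = midpoint of mu_x when mu_y equal
        mid_x = 0.5 * (a.mu_x + b.mu_x)
        assert np.allclose(verts[:, 0], mid_x, atol=0.05)

    def test_boundary_vertices_have_equal_class_densities(self, default_fit):
        for pair in (("A", "B"), ("B", "C")):
            lines = default_fit.boundary_curve(pair)
            assert lines, f"no boundary found for {pair}"
            verts = np.concatenate(lines)
            gi = default_fit.class_density(pair[0], verts[:, 0], verts[:, 1])
            gj = default_fit.class_density(pair[1], verts[:, 0], verts[:, 1])
            assert np.max(np.abs(np.log(gi) - np.log(gj))) < 0.02

    def test_ac_pair_warns_but_computes(self, default_fit):
        with pytest.warns(UserWarning, match="A-C"):
            lines = default_fit.boundary_curve(("A", "C"))
        assert isinstance(lines, list)

    def test_regions_partition_the_grid(self, default_fit):
        region = default_fit.region_map()
        assert region.shape == (default_fit.grid.ny, default_fit.grid.nx)
        assert set(np.unique(region)) <= {0, 1, 2}
        # independent recomputation at a handful of nodes
        X, Y = default_fit.grid.mesh()
        for i, j in [(0, 0), (100, 200), (499, 499), (250, 50)]:
            dens = [default_fit.class_density(k, X[i, j], Y[i, j]) for k in ("A", "B", "C")]
            assert region[i, j] == int(np.argmax(dens))


class TestErrorMap:
    def test_limits(self, separated_fit, default_fit):
        emap = separated_fit.error_map()
        g = separated_fit.classes["A"]
        X, Y = separated_fit.grid.mesh()
        at_mode = emap[np.argmin(np.abs(separated_fit.grid.y_centers - g.mu_y)),
                       np.argmin(np.abs(separated_fit.grid.x_centers - g.mu_x))]
        assert at_mode < 0.01
        # on the A/B boundary of the default fit, C is negligible -> ~0.5
        verts = np.concatenate(default_fit.boundary_curve(("A", "B")))
        v = verts[np.argmin(np.abs(verts[:, 1] - 0.12))]  # low-CV stretch
        r = default_fit.classify(v[0], v[1], isolines=False)
        assert r.error_prob == pytest.approx(0.5, abs=0.05)

    def test_maxima_lie_on_boundaries(self, default_fit):
        emap = default_fit.error_map()
        X, Y = default_fit.grid.mesh()
        # the most uncertain nodes must sit within one grid cell of a boundary
        boundary = np.concatenate(
            default_fit.boundary_curve(("A", "B")) + default_fit.boundary_curve(("B", "C"))
        )
        idx = np.argsort(emap.ravel())[-20:]
        pts = np.column_stack([X.ravel()[idx], Y.ravel()[idx]])
        cell = math.hypot(default_fit.grid.dx, default_fit.grid.dy)
        for p in pts:
            d = np.min(np.hypot(*(boundary - p).T))
            assert d < 2 * cell

    def test_margin_variant(self, default_fit):
        margin = default_fit.error_map(kind="margin")
        assert margin.min() >= 0 and margin.max() <= 1
        with pytest.raises(ValueError):
            default_fit.error_map(kind="nope")


class TestIsolines:
    def test_single_gaussian_mass_calibration(self, rng):
        # three identical classes make the mixture a single Gaussian whose
        # m-isoline must enclose mass m; checked by an independent
        # Monte-Carlo oracle drawing directly from that Gaussian
        sd = [3, 4, 3, 4, 3, 4]
        cv = [0.2, 0.3, 0.2, 0.3, 0.2, 0.3]
        res = mw.DurationClassifier(sd, cv, ["A", "A", "B", "B", "C", "C"]).fit()
        g = res.classes["A"]
        draws_x = rng.normal(g.mu_x, g.sigma_x, 200_000)
        draws_y = rng.normal(g.mu_y, g.sigma_y, 200_000)
        for mass in (0.68, 0.95):
            level = res.isoline_level(mass)
            inside = (res.total_density(draws_x, draws_y) >= level).mean()
            assert inside == pytest.approx(mass, abs=0.005)

    def test_levels_descend_and_contours_nest(self, default_fit):
        isos = default_fit.isolines([0.68, 0.95, 0.995])
        levels = [iso.level for iso in isos]
        assert levels == sorted(levels, reverse=True)
        # nesting: every vertex of a tighter contour has density above the
        # looser contour's level
        for tight, loose in zip(isos, isos[1:]):
            for path in tight.paths:
                dens = default_fit.total_density(path[:, 0], path[:, 1])
                assert (dens >= loose.level * 0.999).all()

    def test_published_points_inside_a_wide_isoline(self, default_fit):
        # soft analogue of the published map: every reference sample sits
        # within the 99.5% curve of the synthetic-trained mixture
        level = default_fit.isoline_level(0.995)
        for agg in mw.load_reference_tables():
            assert default_fit.total_density(agg.sd, agg.cv) >= level

    def test_unreachable_mass_raises(self):
        sd = [3, 4, 3, 4, 3, 4]
        cv = [0.2, 0.3, 0.2, 0.3, 0.2, 0.3]
        tiny = mw.GridSpec(x_min=3.0, x_max=3.5, y_min=0.2, y_max=0.3, nx=50, ny=50)
        res = mw.DurationClassifier(sd, cv, ["A", "A", "B", "B", "C", "C"]).fit(grid=tiny)
        with pytest.raises(ValueError, match="enlarge"):
            res.isoline_level(0.95)

    def test_mass_argument_validated(self, default_fit):
        with pytest.raises(ValueError):
            default_fit.isoline_level(1.2)


class TestExpectedTotalError:
    def test_separated_classes_error_near_zero(self, separated_fit):
        err = separated_fit.expected_total_error()
        assert err.total < 1e-6

    def test_identical_a_b_gives_one_third(self):
        # A and B coincide, C is remote: all of B's mass is tied and lost to
        # the A<B tie-break, so the expected total error is 1/3
        sd = [2, 4, 2, 4, 40, 42]
        cv = [0.2, 0.4, 0.2, 0.4, 4.0, 4.2]
        grid = mw.GridSpec(x_min=-10, x_max=60, y_min=-2, y_max=6, nx=500, ny=500)
        res = mw.DurationClassifier(sd, cv, ["A", "A", "B", "B", "C", "C"]).fit(grid=grid)
        err = res.expected_total_error()
        assert err.total == pytest.approx(1 / 3, abs=1e-3)

    def test_equals_one_minus_integral_of_max(self, default_fit):
        d = default_fit._grid_densities()
        one_minus_max = 1.0 - d.max(axis=0).sum() * default_fit.grid.cell_area
        err = default_fit.expected_total_error()
        assert err.total == pytest.approx(one_minus_max, abs=1e-3)

    def test_ac_overlap_negligible_for_default_fit(self, default_fit):
        err = default_fit.expected_total_error()
        assert err.ac_overlap < 0.01
        assert err.ac_overlap < 0.1 * err.total


class TestHeldOutValidation:
    def test_held_out_extant_samples_classify_as_published(self, default_fit):
        """Low-variability reference samples land in region A, the year-long
        pronghorn sample in region B (the published held-out test)."""
        for sid in ("2a", "2b", "3a", "6", "7"):
            agg = mw.reference_sample(sid)
            assert agg.sd <= 2.8 and agg.cv <= 0.18
            assert default_fit.classify(agg.sd, agg.cv, isolines=False).region == "A"
        agg = mw.reference_sample("3b")
        assert default_fit.classify(agg.sd, agg.cv, isolines=False).region == "B"

    def test_taubach_bison_long_term_accumulation(self, default_fit):
        agg = mw.reference_sample("D1")
        assert default_fit.classify(agg.sd, agg.cv, isolines=False).region == "B"


class TestPersistence:
    def test_json_round_trip_preserves_classification(self, default_fit, tmp_path, rng):
        path = tmp_path / "model.json"
        default_fit.to_json(path)
        clone = mw.DurationClassifierResults.from_json(path)
        for _ in range(20):
            x, y = rng.uniform(0, 7), rng.uniform(0, 0.5)
            a = default_fit.classify(x, y, isolines=False)
            b = clone.classify(x, y, isolines=False)
            assert a.region == b.region
            assert a.error_prob == pytest.approx(b.error_prob)
        payload = json.loads(path.read_text())
        assert set(payload["classes"]) == {"A", "B", "C"}

    def test_summary_mentions_all_classes(self, default_fit):
        text = default_fit.summary()
        for token in ("A", "B", "C", "expected total error"):
            assert token in text
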