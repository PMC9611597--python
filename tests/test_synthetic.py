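"""Generator tests: lattice geometry, intrinsic GMRF draws, response noise,
and the nested survey structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import empowermap as em
from empowermap.items import N_LEVELS, ResponseVector
from empowermap.synthetic import (
    KM_PER_DEGREE,
    CovariateConfig,
    emit_responses,
    lattice_centroids,
)


class TestLattice:
    def test_3x4_geometry(self, lattice_3x4):
        g = lattice_3x4
        assert g.n_regions == 12
        corners = [1, 4, 9, 12]
        assert all(g.degree(c) == 2 for c in corners)
        # directed adjacency entries: 2 * (vertical 3*3 + horizontal 4*2)
        assert int(g.adjacency_matrix().sum()) == 2 * (3 * 3 + 4 * 2)

    def test_two_region_lattice(self):
        g = em.build_region_lattice(1, 2)
        assert g.neighbors[1] == frozenset({2})
        assert g.neighbors[2] == frozenset({1})

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            em.build_region_lattice(0, 3)
        with pytest.raises(ValueError):
            em.build_region_lattice(1, 1)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(rows=st.integers(1, 6), cols=st.integers(2, 6))
    def test_adjacency_symmetric_no_self_loops(self, rows, cols):
        g = em.build_region_lattice(rows, cols)
        a = g.adjacency_matrix()
        assert np.array_equal(a, a.T)
        assert np.diagonal(a).sum() == 0
        assert all(g.degree(r) >= 1 for r in g.region_ids)


class TestIntrinsicGmrf:
    def test_draws_sum_to_zero(self, lattice_4x4):
        for seed in range(5):
            s = em.sample_intrinsic_gmrf(lattice_4x4, 2.0, seed)
            assert abs(s.sum()) < 1e-10

    def test_variance_scales_with_tau2(self, lattice_4x4):
        d1 = np.array(
            [em.sample_intrinsic_gmrf(lattice_4x4, 1.0, s) for s in range(4000)]
        )
        d4 = np.array(
            [em.sample_intrinsic_gmrf(lattice_4x4, 4.0, 10_000 + s)
             for s in range(4000)]
        )
        ratio = d4.var() / d1.var()
        assert ratio == pytest.approx(4.0, rel=0.10)

    @pytest.mark.parametrize("shape", [(4, 4), (10, 10)])
    def test_neighbour_mean_slope_matches_closed_form(self, shape):
        """Pooled regression of s_j on its neighbour average.

        Oracle: with covariance pinv(Q) (the sum-to-zero constrained
        intrinsic field), slope = tr(W C) / tr(W C W') where W is the
        row-normalised adjacency.  On the larger lattice this equals 1,
        the conditional-mean property of the unconstrained prior.
        """
        g = em.build_region_lattice(*shape)
        a = g.adjacency_matrix()
        deg = a.sum(axis=1)
        q = np.diag(deg) - a
        c = np.linalg.pinv(q)
        w = a / deg[:, None]
        oracle = np.trace(w @ c) / np.trace(w @ c @ w.T)
        draws = np.array(
            [em.sample_intrinsic_gmrf(g, 1.0, s) for s in range(1500)]
        )
        nbr_mean = draws @ w.T
        slope = float(
            (nbr_mean * draws).sum() / (nbr_mean * nbr_mean).sum()
        )
        assert slope == pytest.approx(oracle, abs=0.04)
        if shape == (10, 10):
            assert oracle == pytest.approx(1.0, abs=1e-9)

    def test_disconnected_graph_rejected(self):
        g = em.RegionGraph(
            (1, 2, 3, 4),
            {1: frozenset({2}), 2: frozenset({1}),
             3: frozenset({4}), 4: frozenset({3})},
        )
        with pytest.raises(ValueError, match="disconnected"):
            em.sample_intrinsic_gmrf(g, 1.0, 0)


class TestEmitResponses:
    def test_zero_noise_reproduces_template(self, templates):
        for cat in range(1, 6):
            codes = emit_responses(cat, templates, 0.0, seed=0, size=3)
            assert np.array_equal(codes, np.tile(templates[cat - 1].to_codes(), (3, 1)))

    def test_mean_matching_distance_binomial(self, templates):
        eps = 0.2
        codes = emit_responses(1, templates, eps, seed=42, size=10_000)
        dist = (codes != templates[0].to_codes()).sum(axis=1)
        assert dist.mean() == pytest.approx(10 * eps, abs=0.06)

    def test_autonomous_template_items(self, templates):
        t4 = templates[3]
        assert (t4.d_visit, t4.d_purchase, t4.d_health) == ("self",) * 3
        assert t4.d_spend == "partner"

    def test_flips_land_on_other_admissible_levels(self, templates):
        codes = emit_responses(3, templates, 1.0, seed=7, size=500)
        base = templates[2].to_codes()
        assert (codes != base).all()
        assert (codes >= 0).all() and (codes < N_LEVELS).all()

    def test_epsilon_out_of_range_rejected(self, templates):
        with pytest.raises(ValueError):
            emit_responses(1, templates, 1.5, seed=0)


class TestSimulateSurvey:
    def test_symmetric_logit_gives_even_shares(self, lattice_3x4):
        from empowermap.synthetic import zero_age_fn

        truth = em.GroundTruth(
            beta=np.zeros((2, 8)), psu_sd=1e-8, region_sd=1e-8,
            age_fn=zero_age_fn,
        )
        truth.s = np.zeros((2, 12))
        df, gt = em.simulate_survey(
            lattice_3x4, truth, psus_per_region=6,
            respondents_per_psu_range=(40, 60), seed=9, lattice_shape=(3, 4),
        )
        shares = np.bincount(gt.labels, minlength=4)[1:] / len(df)
        assert np.allclose(shares, 1 / 3, atol=0.02)

    def test_respondent_counts_within_bounds(self, small_survey):
        df, _ = small_survey
        counts = df.groupby("psu").size()
        assert counts.between(15, 30).all()

    def test_jitter_caps_respected(self, small_survey):
        _, gt = small_survey
        disp_deg = np.linalg.norm(gt.psu_xy - gt.psu_true_xy, axis=1)
        disp_km = disp_deg * KM_PER_DEGREE
        assert (disp_km[gt.psu_urban] <= 2.0 + 1e-9).all()
        assert (disp_km[~gt.psu_urban] <= 5.0 + 1e-9).all()
        assert disp_km.max() > 2.0  # rural cap actually exercised

    def test_each_psu_in_one_region(self, small_survey):
        df, _ = small_survey
        assert (df.groupby("psu")["region"].nunique() == 1).all()

    def test_same_seed_bitwise_identical(self, lattice_3x4):
        truth_a = em.GroundTruth(beta=np.full((2, 8), 0.1))
        truth_b = em.GroundTruth(beta=np.full((2, 8), 0.1))
        df_a, _ = em.simulate_survey(lattice_3x4, truth_a, 3, (15, 20), seed=5,
                                     lattice_shape=(3, 4))
        df_b, _ = em.simulate_survey(lattice_3x4, truth_b, 3, (15, 20), seed=5,
                                     lattice_shape=(3, 4))
        pd.testing.assert_frame_equal(df_a, df_b)

    def test_intercept_raises_category_share(self, lattice_3x4):
        from empowermap.synthetic import zero_age_fn

        def share_of_k1(intercept):
            beta = np.zeros((2, 8))
            beta[0, 0] = intercept
            truth = em.GroundTruth(beta=beta, psu_sd=1e-8, region_sd=1e-8,
                                   age_fn=zero_age_fn)
            truth.s = np.zeros((2, 12))
            _, gt = em.simulate_survey(
                lattice_3x4, truth, 4, (20, 30), seed=77, lattice_shape=(3, 4)
            )
            return (gt.labels == 1).mean()

        assert share_of_k1(1.0) > share_of_k1(0.0) > share_of_k1(-1.0)

    def test_five_category_mode_emits_minorities(self, lattice_3x4):
        truth = em.GroundTruth(beta=np.zeros((2, 8)))
        _, gt = em.simulate_survey(
            lattice_3x4, truth, 3, (15, 25), seed=4, lattice_shape=(3, 4),
            n_categories=5,
        )
        assert set(np.unique(gt.labels)) >= {1, 2, 3, 4}

    def test_region_varying_covariates(self, lattice_3x4):
        probs = np.tile([0.8, 0.1, 0.1], (12, 1))
        probs[6:] = [0.1, 0.1, 0.8]
        cfg = CovariateConfig(educ_probs=probs)
        truth = em.GroundTruth(beta=np.zeros((2, 8)))
        df, _ = em.simulate_survey(
            lattice_3x4, truth, 4, (20, 30), covariate_config=cfg, seed=3,
            lattice_shape=(3, 4),
        )
        lo = df[df.region <= 6]["educ"].eq("none").mean()
        hi = df[df.region > 6]["educ"].eq("none").mean()
        assert lo > 0.6 > 0.3 > hi


class TestIo:
    def test_survey_roundtrip(self, small_survey, tmp_path):
        from empowermap.io import read_survey, write_survey

        df, _ = small_survey
        write_survey(df, tmp_path / "s.csv")
        back = read_survey(tmp_path / "s.csv")
        assert list(back.columns) == list(df.columns)
        assert len(back) == len(df)
        assert (back["age"].to_numpy() == df["age"].to_numpy()).all()

    def test_graph_roundtrip(self, lattice_3x4, tmp_path):
        from empowermap.io import read_graph, write_graph

        write_graph(lattice_3x4, tmp_path / "g.gra")
        back = read_graph(tmp_path / "g.gra")
        assert back.region_ids == lattice_3x4.region_ids
        assert back.neighbors == lattice_3x4.neighbors

    def test_ground_truth_roundtrip(self, small_survey, tmp_path):
        from empowermap.io import read_ground_truth, write_ground_truth

        _, gt = small_survey
        write_ground_truth(gt, tmp_path / "t.json")
        back = read_ground_truth(tmp_path / "t.json")
        assert np.allclose(back.beta, gt.beta)
        assert np.allclose(back.s, gt.s)
        ages = np.arange(15, 50)
        assert np.allclose(back.age_effect(ages), gt.age_effect(ages), atol=1e-9)

    def test_incomplete_survey_rejected(self, small_survey, tmp_path):
        from empowermap.io import validate_survey

        df, _ = small_survey
        bad = df.copy()
        bad.loc[0, "v_burns"] = "maybe"
        with pytest.raises(ValueError, match="inadmissible"):
            validate_survey(bad)


class TestResponseVector:
    def test_code_roundtrip(self, templates):
        for t in templates:
            assert ResponseVector.from_codes(t.to_codes()) == t

    def test_invalid_level_rejected(self):
        rv = ResponseVector(*(["no"] * 5 + ["self"] * 4 + ["maybe"]))
        with pytest.raises(ValueError):
            rv.validate()
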