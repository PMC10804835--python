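"""Perturbation operators, fixed linear models, pair generation, MLR."""

import numpy as np
import pytest

import ptmlee as p
from ptmlee.fixtures import FIXTURE_TRUE_MODEL, FixtureSpec, perturb_pairs
from ptmlee.ptml import (
    PTO_NAMES,
    BlockCache,
    MissingRoleError,
    SingularDesignError,
    fit_report,
    reaction_blocks,
)


def zero_pto(**overrides):
    vals = {name: 0.0 for name in PTO_NAMES}
    vals.update(overrides)
    return p.PTOVector(**vals)


class TestPTOVector:
    def test_identity_pair_is_zero(self, small_reaction_set):
        q = small_reaction_set[0]
        pto = p.pto_vector(q, q)
        assert np.all(pto.as_array() == 0.0)

    def test_condition_deltas(self, small_reaction_set):
        import dataclasses

        q = small_reaction_set[0]
        rec = dataclasses.replace(q.record, rxn_id="shift", T_C=q.record.T_C + 5)
        q2 = p.CanonicalReaction(rec, q.ee_R, q.mirrored)
        pto = p.pto_vector(q2, q)
        assert pto.dT == 5.0
        assert pto.dLoad == 0.0 and pto.dt == 0.0

    def test_antisymmetry_exact(self, small_reaction_set):
        cache = BlockCache()
        for q, r in zip(small_reaction_set[:10], small_reaction_set[10:20]):
            fwd = p.pto_vector(q, r, cache(q), cache(r)).as_array()
            rev = p.pto_vector(r, q, cache(r), cache(q)).as_array()
            np.testing.assert_array_equal(fwd, -rev)

    def test_missing_role(self, small_reaction_set):
        import dataclasses

        q = small_reaction_set[0]
        rec = dataclasses.replace(q.record, prod_smiles="")
        broken = p.CanonicalReaction(rec, q.ee_R, q.mirrored)
        with pytest.raises(MissingRoleError):
            reaction_blocks(broken)


class TestFixedModels:
    def test_pairwise_intercept(self):
        assert p.predict_delta_ee(zero_pto()) == pytest.approx(-0.91)

    def test_single_component_evaluation(self):
        assert p.predict_delta_ee(zero_pto(dLoad=1.0)) == pytest.approx(-1.73)

    def test_linearity_negation(self, small_reaction_set):
        q, r = small_reaction_set[0], small_reaction_set[1]
        pto = p.pto_vector(q, r)
        total = p.predict_delta_ee(pto) + p.predict_delta_ee(-pto)
        assert total == pytest.approx(2 * -0.91, abs=1e-9)

    def test_zero_perturbation_identity(self, small_reaction_set):
        q = small_reaction_set[0]
        pred = p.predict_ee_from_reference(q, q)
        assert pred.raw == pytest.approx(q.ee_R - 0.91, abs=1e-12)

    def test_clipping_flags_and_retains_raw(self, small_reaction_set):
        import dataclasses

        q = small_reaction_set[0]
        rec = dataclasses.replace(q.record, rxn_id="far", load_pct=30.0, T_C=-78.0)
        far = p.CanonicalReaction(rec, q.ee_R, q.mirrored)
        # push past +100 via large negative dT (coefficient -0.34)
        high = dataclasses.replace(q.record, rxn_id="hi", ee_pct=100.0, prod_config="R")
        src = p.CanonicalReaction(high, 100.0, False)
        pred = p.predict_ee_from_reference(far, src)
        if pred.clipped:
            assert abs(pred.ee_R) == 100.0
            assert abs(pred.raw) > 100.0
        assert pred.cip in ("R", "S", "racemic")

    def test_classic_intercept_on_zero_features(self):
        raw = float(p.CLASSIC_MODEL.coefficients @ np.zeros(12) + p.CLASSIC_MODEL.e0)
        assert raw == pytest.approx(-0.70)

    def test_classic_linearity_per_input(self, small_reaction_set):
        from ptmlee.ptml import classic_features

        q = small_reaction_set[0]
        feats = classic_features(q)
        contrib = p.CLASSIC_MODEL.coefficients * feats
        total = float(contrib.sum() + p.CLASSIC_MODEL.e0)
        assert p.predict_ee_classic(q).raw == pytest.approx(total, abs=1e-9)

    def test_sign_maps_to_cip(self, small_reaction_set):
        for q in small_reaction_set[:5]:
            pred = p.predict_ee_from_reference(q, small_reaction_set[10])
            if pred.ee_R > 0:
                assert pred.cip == "R"
            elif pred.ee_R < 0:
                assert pred.cip == "S"
            else:
                assert pred.cip == "racemic"

    def test_model_json_round_trip(self, tmp_path):
        path = tmp_path / "model.json"
        p.PAIRWISE_MODEL.to_json(path)
        back = p.LinearEEModel.from_json(path)
        assert back == p.PAIRWISE_MODEL


class TestGeneratePairs:
    def test_all_mode_count(self, small_reaction_set):
        pairs = p.generate_pairs(small_reaction_set[:3], mode="all")
        assert len(pairs) == 6
        ids = {(c.query.rxn_id, c.reference.rxn_id) for c in pairs}
        assert len(ids) == 6

    def test_sample_equals_all_when_exhaustive(self, small_reaction_set):
        sampled = p.generate_pairs(small_reaction_set[:3], mode="sample", k=6, seed=0)
        assert len(sampled) == 6
        assert {(c.query.rxn_id, c.reference.rxn_id) for c in sampled} == {
            (q.rxn_id, r.rxn_id)
            for q in small_reaction_set[:3]
            for r in small_reaction_set[:3]
            if q.rxn_id != r.rxn_id
        }

    def test_sample_seeded_reproducible(self, small_reaction_set):
        a = p.generate_pairs(small_reaction_set, mode="sample", k=50, seed=42)
        b = p.generate_pairs(small_reaction_set, mode="sample", k=50, seed=42)
        assert [(c.query.rxn_id, c.reference.rxn_id) for c in a] == [
            (c.query.rxn_id, c.reference.rxn_id) for c in b
        ]

    def test_ordered_pair_arithmetic(self):
        # n reactions give n*(n-1) ordered pairs
        rx = p.generate_reactions(FixtureSpec(n_reactions=5, seed=1))
        assert len(p.generate_pairs(rx, mode="all")) == 20

    def test_oversample_error(self, small_reaction_set):
        with pytest.raises(ValueError, match="pairs"):
            p.generate_pairs(small_reaction_set[:3], mode="sample", k=7, seed=0)


class TestFitMLR:
    def test_noise_free_exact_recovery(self, small_reaction_set):
        pairs = p.generate_pairs(small_reaction_set, mode="all")
        model = p.fit_mlr(pairs)
        np.testing.assert_allclose(
            model.coefficients, FIXTURE_TRUE_MODEL.coefficients, atol=1e-8
        )
        assert model.e0 == pytest.approx(0.0, abs=1e-8)
        assert model.stats["R2"] == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_3se(self, small_reaction_set):
        pairs = p.generate_pairs(small_reaction_set, mode="sample", k=1000, seed=5)
        noisy = perturb_pairs(pairs, 5.0, seed=6)
        model = p.fit_mlr(noisy)
        truth = np.append(FIXTURE_TRUE_MODEL.coefficients, FIXTURE_TRUE_MODEL.e0)
        est = np.append(model.coefficients, model.e0)
        se = np.array(model.stats["coef_se"])
        assert np.all(np.abs(est - truth) <= 3 * se)

    def test_residual_orthogonality(self, small_reaction_set):
        """OLS residuals orthogonal to every standardized design column."""
        pairs = p.generate_pairs(small_reaction_set, mode="sample", k=500, seed=9)
        noisy = perturb_pairs(pairs, 10.0, seed=10)
        model = p.fit_mlr(noisy)
        X = np.array([c.pto.as_array() for c in noisy])
        y = np.array([c.delta_ee_R for c in noisy])
        resid = y - (X @ model.coefficients + model.e0)
        Xs = (X - X.mean(0)) / X.std(0)
        assert np.max(np.abs(Xs.T @ resid)) < 1e-6

    def test_bias_shrinks_with_n(self):
        errs = []
        for n, k in ((30, 200), (100, 2000)):
            rx = p.generate_reactions(FixtureSpec(n_reactions=n, seed=21))
            pairs = p.generate_pairs(rx, mode="sample", k=k, seed=21)
            noisy = perturb_pairs(pairs, 5.0, seed=22)
            model = p.fit_mlr(noisy)
            errs.append(
                np.abs(model.coefficients - FIXTURE_TRUE_MODEL.coefficients).max()
            )
        assert errs[1] < errs[0]

    def test_singular_design_names_columns(self, small_reaction_set):
        pairs = p.generate_pairs(small_reaction_set[:10], mode="all")
        import dataclasses

        degenerate = [
            dataclasses.replace(
                c,
                pto=p.PTOVector(
                    **{
                        **{n: getattr(c.pto, n) for n in PTO_NAMES},
                        "d_Zv_solv_Cuns": 0.0,
                        "d_Zv_cat_Cuns": 0.0,
                    }
                ),
            )
            for c in pairs
        ]
        with pytest.raises(SingularDesignError, match="d_Zv"):
            p.fit_mlr(degenerate)

    def test_too_few_cases(self, small_reaction_set):
        pairs = p.generate_pairs(small_reaction_set[:4], mode="all")
        with pytest.raises(ValueError, match="20"):
            p.fit_mlr(pairs)

    def test_fit_report_layout(self, small_reaction_set):
        pairs = p.generate_pairs(small_reaction_set, mode="sample", k=300, seed=3)
        model = p.fit_mlr(perturb_pairs(pairs, 5.0, seed=4))
        report = fit_report(model)
        assert list(report.columns) == ["variable", "coeff", "SE", "t", "p_level"]
        assert len(report) == 13
        assert report["variable"].iloc[-1] == "intercept"
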