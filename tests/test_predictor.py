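"""Candidate enumeration, featurization and the softmax-KL profile model."""

import numpy as np
import pytest
import scipy.sparse as sp

from cas9repair import (
    FeatureSchema,
    GenerativeParams,
    Indel,
    enumerate_candidates,
    featurize,
    generate_targets,
    map_observed,
    pool,
    predict,
    sample_screen,
    train,
)
from cas9repair.io import OutcomeProfile
from cas9repair.outcomes import apply_indel, canonicalize
from cas9repair.predictor import evaluate


@pytest.fixture(scope="module")
def target():
    return next(iter(generate_targets(GenerativeParams(n_targets=1), seed=31).values()))


@pytest.fixture(scope="module")
def schema():
    return FeatureSchema()


class TestEnumerate:
    def test_pre_dedup_closed_forms(self, target):
        c = target.cut_index
        deletions = [
            (a, a + L) for L in range(1, 31) for a in range(c - L, c + 1)
        ]
        assert len(deletions) == sum(L + 1 for L in range(1, 31)) == 495
        from cas9repair.predictor import _MERS

        insertions = [(p, m) for p in range(c - 3, c + 4) for m in _MERS]
        assert len(insertions) == 7 * 20 == 140

    def test_dedup_matches_distinct_mutated_sequences(self):
        """Canonical dedup count equals the number of distinct mutated
        molecules in the raw candidate space (string-equality oracle)."""
        targets = generate_targets(GenerativeParams(n_targets=10), seed=32)
        for t in targets.values():
            c = t.cut_index
            raw = [Indel(a, a + L) for L in range(1, 31) for a in range(c - L, c + 1)]
            raw += [
                Indel(p, p, m)
                for p in range(c - 3, c + 4)
                for m in ("A", "C", "G", "T")
            ]
            raw += [
                Indel(p, p, x + y)
                for p in range(c - 3, c + 4)
                for x in "ACGT"
                for y in "ACGT"
            ]
            mutated = {apply_indel(t.sequence, r) for r in raw}
            cands = enumerate_candidates(t)
            assert len(cands.candidates) == len(mutated)
            assert {apply_indel(t.sequence, x) for x in cands.candidates} == mutated
            assert all(canonicalize(t, x) == x for x in cands.candidates)

    def test_strict_spanning_flag_drops_touching_windows(self, target):
        loose = enumerate_candidates(target, include_touching=True)
        strict = enumerate_candidates(target, include_touching=False)
        assert len(strict.candidates) < len(loose.candidates)

    def test_insufficient_context_raises(self, gattaca):
        with pytest.raises(ValueError, match="context"):
            enumerate_candidates(gattaca)


class TestFeaturize:
    def test_matrix_is_binary_with_fixed_width(self, target, schema):
        cands = enumerate_candidates(target)
        X = featurize(target, cands, schema)
        assert X.shape == (len(cands.candidates), schema.n_features)
        assert set(np.unique(X.data)) == {1.0}

    def test_deletion_row_features(self, target, schema):
        c = target.cut_index
        cand = canonicalize(target, Indel(c - 2, c + 1))
        names = [schema.feature_names[i] for i in schema.active_features(target, cand)]
        assert f"left_off={c - cand.start}" in names
        assert f"right_off={cand.end - c}" in names
        assert "type=DEL" in names
        assert not any(n.startswith("ins_") for n in names)

    def test_pairwise_features_equal_and_of_parents(self, target, schema):
        cands = enumerate_candidates(target)
        X = featurize(target, cands, schema).toarray()
        name_to_col = {n: j for j, n in enumerate(schema.feature_names)}
        pair_cols = [
            (j, n) for j, n in enumerate(schema.feature_names) if "&" in n
        ]
        rng = np.random.default_rng(0)
        for k in rng.choice(len(pair_cols), size=50, replace=False):
            j, n = pair_cols[k]
            pa, pb = n.split("&")
            expected = X[:, name_to_col[pa]] * X[:, name_to_col[pb]]
            assert np.array_equal(X[:, j], expected)


class TestMapObserved:
    def test_compound_outcomes_dropped_with_fraction(self, target):
        cands = enumerate_candidates(target)
        c = target.cut_index
        compound = canonicalize(target, Indel(c - 2, c + 1, "TT" if target.sequence[c - 2] != "T" else "GG"))
        prof = OutcomeProfile(
            target.target_id, {cands.candidates[0]: 90, compound: 10}
        )
        counts, frac = map_observed(prof, cands)
        assert counts.sum() == 90
        assert frac == pytest.approx(0.1)

    def test_all_within_space_drops_nothing(self, target):
        cands = enumerate_candidates(target)
        prof = OutcomeProfile(target.target_id, {cands.candidates[0]: 10})
        _, frac = map_observed(prof, cands)
        assert frac == 0.0


class TestTraining:
    def test_zero_weights_predict_uniform(self, target, schema):
        from cas9repair.predictor import ProfileModel

        model = ProfileModel(
            "control", np.zeros(schema.n_features), schema.feature_names,
            schema.version, 0.0, 0, 0, 0.0, True,
        )
        cands, p = predict(model, target, schema=schema)
        assert np.allclose(p, 1.0 / len(p))

    def test_prediction_sums_to_one_and_is_order_invariant(self, target, schema):
        rng = np.random.default_rng(1)
        from cas9repair.predictor import ProfileModel

        model = ProfileModel(
            "control", rng.normal(0, 0.2, schema.n_features), schema.feature_names,
            schema.version, 0.0, 0, 0, 0.0, True,
        )
        cands, p = predict(model, target, schema=schema)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        X = featurize(target, cands, schema)
        perm = rng.permutation(len(p))
        from cas9repair.predictor import CandidateSet

        cands_p = CandidateSet(target.target_id, tuple(cands.candidates[i] for i in perm))
        Xp = X[perm]
        _, pp = predict(model, target, design_entry=(cands_p, Xp))
        assert np.allclose(pp, p[perm])

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        X = sp.csr_matrix((rng.random((5, 8)) < 0.5).astype(float))
        m = rng.random(5)
        m /= m.sum()

        def loss(w):
            s = X @ w
            s = s - s.max()
            p = np.exp(s)
            p /= p.sum()
            return float(np.sum(m * (np.log(m) - np.log(p)))), X.T @ (p - m)

        w = rng.normal(0, 0.3, 8)
        _, g = loss(w)
        for i in range(8):
            e = np.zeros(8)
            e[i] = 1e-6
            fd = (loss(w + e)[0] - loss(w - e)[0]) / 2e-6
            assert fd == pytest.approx(g[i], rel=1e-5, abs=1e-9)

    def test_single_target_overfit(self, schema):
        """With no regularization the model has enough capacity to drive
        the KL on its single training profile below 0.01 bits."""
        params = GenerativeParams(n_targets=1, depth_median=5000, timepoints=("d7",))
        targets = generate_targets(params, seed=33)
        ds, _ = sample_screen(targets, params, seed=34, lines=["control"])
        pooled = pool(ds)
        model, _ = train(
            pooled, "control", schema=schema, lam=0.0, test_frac=0.0, seed=0,
            max_iter=2000,
        )
        assert model.final_loss_bits < 0.01

    def test_training_reduces_loss_vs_uniform(self, schema):
        params = GenerativeParams(n_targets=12, depth_median=1500, timepoints=("d7",))
        targets = generate_targets(params, seed=35)
        ds, _ = sample_screen(targets, params, seed=36, lines=["control"])
        pooled = pool(ds)
        model, split = train(pooled, "control", schema=schema, seed=1, test_frac=0.25)
        ev_trained = evaluate(model, pooled, split.test_targets, schema=schema)
        from cas9repair.predictor import ProfileModel

        uniform = ProfileModel(
            "control", np.zeros(schema.n_features), schema.feature_names,
            schema.version, 0.0, 0, 0, 0.0, True,
        )
        ev_uniform = evaluate(uniform, pooled, split.test_targets, schema=schema)
        assert ev_trained.mean_divergence < ev_uniform.mean_divergence

    def test_perfect_model_scores_perfectly(self, target, schema):
        """Evaluating a model against profiles that equal its own
        predictions gives zero divergence and r == 1."""
        from cas9repair.io import SampleKey, ScreenDataset
        from cas9repair.predictor import ProfileModel

        rng = np.random.default_rng(3)
        model = ProfileModel(
            "control", rng.normal(0, 0.2, schema.n_features), schema.feature_names,
            schema.version, 0.0, 0, 0, 0.0, True,
        )
        cands, p = predict(model, target, schema=schema)
        # profile whose pseudocounted frequencies equal p exactly:
        # counts = K*p - 0.5 with K large enough to keep counts positive
        K = 10.0 / max(p.min(), 1e-9)
        counts = {o: float(K * pi - 0.5) for o, pi in zip(cands.candidates, p)}
        ds = ScreenDataset(
            {target.target_id: target},
            {
                (SampleKey("control", 0, "pooled"), target.target_id): OutcomeProfile(
                    target.target_id, counts
                )
            },
        )
        ev = evaluate(model, ds, [target.target_id], schema=schema)
        assert ev.mean_divergence == pytest.approx(0.0, abs=1e-9)
        assert ev.r_outcomes == pytest.approx(1.0, abs=1e-6)
        assert ev.r_categories == pytest.approx(1.0, abs=1e-6)

    def test_in_frame_fraction_matches_direct_sum(self, target, schema):
        from cas9repair.io import SampleKey, ScreenDataset
        from cas9repair.predictor import ProfileModel

        model = ProfileModel(
            "control", np.zeros(schema.n_features), schema.feature_names,
            schema.version, 0.0, 0, 0, 0.0, True,
        )
        cands, p = predict(model, target, schema=schema)
        counts = {o: 10.0 for o in cands.candidates}
        ds = ScreenDataset(
            {target.target_id: target},
            {
                (SampleKey("control", 0, "pooled"), target.target_id): OutcomeProfile(
                    target.target_id, counts
                )
            },
        )
        ev = evaluate(model, ds, [target.target_id], schema=schema)
        m = np.full(len(cands.candidates), 1.0 / len(cands.candidates))
        direct = sum(
            mi for mi, o in zip(m, cands.candidates) if o.net_change % 3 == 0
        )
        assert 0 < direct < 1
        assert ev.inframe_measured[target.target_id] == pytest.approx(direct)
        assert ev.inframe_predicted[target.target_id] == pytest.approx(direct)
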