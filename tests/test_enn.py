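"""Emotional network: tendency inputs, dual-path forward pass, learning rule."""

import numpy as np
import pytest

from episwarm import EmotionalNetwork, SNPPattern, emotional_vector, hardlim
from episwarm.enn import ENNResults, build_inputs, enn_forward, enn_reward, enn_update
from episwarm.genotypes import LabeledGenotypes


class TestEmotionalVector:
    def test_carried_pattern_contributes_or(self):
        interactions = [
            (SNPPattern([(0, 1)]), 2.5),
            (SNPPattern([(1, 3), (3, 1)]), 7.01),
            (SNPPattern([(2, 2)]), 1.4),
        ]
        vec = emotional_vector((2, 3, 1, 1), interactions)
        assert vec.tolist() == [0.0, 7.01, 0.0]

    def test_no_pattern_zero_vector(self):
        interactions = [(SNPPattern([(0, 2)]), 3.0)]
        assert emotional_vector((1, 1), interactions).tolist() == [0.0]

    def test_entries_equal_match_times_or(self):
        rng = np.random.default_rng(0)
        interactions = [
            (SNPPattern([(int(i), int(rng.integers(1, 4)))]), float(rng.uniform(0.5, 8)))
            for i in range(5)
        ]
        for _ in range(20):
            sample = rng.integers(1, 4, size=5)
            vec = emotional_vector(sample, interactions)
            for q, (pat, orx) in enumerate(interactions):
                assert vec[q] == (orx if pat.matches(sample) else 0.0)

    def test_concatenation_layout(self):
        interactions = [(SNPPattern([(0, 1)]), 2.0)]
        s_all, s_e = build_inputs(np.array([[1, 3], [2, 3]]), interactions)
        assert s_all.shape == (2, 3) and s_e.shape == (2, 1)
        assert s_all[0].tolist() == [1.0, 3.0, 2.0]
        assert s_all[1].tolist() == [2.0, 3.0, 0.0]


class TestHardlim:
    @pytest.mark.parametrize("x,expected", [(0.0, 1), (-0.3, 0), (5.2, 1), (-1e-12, 0)])
    def test_threshold(self, x, expected):
        assert hardlim(x) == expected


class TestForward:
    def test_zero_model_outputs_control(self):
        v, w = np.zeros(4), np.zeros(3)
        e, amyg, ofc, ea1p, eo1 = enn_forward(v, w, np.array([1.0, 3.0, 2.0]), np.array([2.0]))
        assert (amyg, ofc) == (0.0, 0.0)
        assert (ea1p, eo1) == (1, 1)
        assert e == 0  # 1 - 1: neither path wins -> control

    def test_crafted_case_output(self):
        # amygdala sum positive, OFC sum negative -> E = 1 (case)
        v = np.array([1.0, 0.0, 0.0, 0.5])
        w = np.array([-1.0, 0.0, 0.0])
        s_all, s_e = np.array([2.0, 1.0, 2.0]), np.array([2.0])
        e, amyg, ofc, _, eo1 = enn_forward(v, w, s_all, s_e)
        assert amyg == pytest.approx(3.0) and ofc == pytest.approx(-2.0)
        assert eo1 == 0 and e == 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            enn_forward(np.zeros(5), np.zeros(3), np.ones(3), np.ones(1))
        with pytest.raises(ValueError):
            enn_forward(np.zeros(4), np.zeros(2), np.ones(3), np.ones(1))

    def test_collapsed_emotional_path(self):
        v, w = np.array([1.0, -1.0, 2.0]), np.zeros(3)
        s_all, s_e = np.array([1.0, 2.0, 3.0]), np.array([3.0])
        e, amyg, *_ = enn_forward(v, w, s_all, s_e, duplicate_emotional_path=False)
        assert amyg == pytest.approx(5.0)


class TestReward:
    @pytest.mark.parametrize(
        "ea1p,eo1,r1,expected",
        [
            (1, 0, 0, 1),
            (1, 1, 1, -1),
            (0, 0, 0, 0),
            (0, 0, 1, 0),
            (1, 0, 1, 0),
            (0, 1, 1, -1),
            (0, 1, 0, 0),
            (1, 1, 0, 0),
        ],
    )
    def test_truth_table(self, ea1p, eo1, r1, expected):
        assert enn_reward(ea1p, eo1, r1) == expected


class TestUpdate:
    def test_no_amygdala_update_when_unreinforced(self):
        # with Ea1' in {0,1} and R1=0, max(R1 - Ea1', 0) = 0 always
        v, w = np.array([0.2, -0.1, 0.3]), np.array([0.1, 0.1])
        v2, _ = enn_update(v, w, np.array([1.0, 2.0]), np.array([3.0]), r1=0,
                           alpha=0.5, beta=0.5, gamma=0.0)
        assert np.allclose(v2, v)

    def test_pure_decay(self):
        v, w = np.ones(3), np.ones(2)
        v2, w2 = enn_update(v, w, np.array([1.0, 2.0]), np.array([3.0]), r1=1,
                            alpha=1e-300, beta=1e-300, gamma=1.0)
        assert np.allclose(v2, 0.0, atol=1e-290) and np.allclose(w2, 0.0, atol=1e-290)

    def test_hand_computed_single_step(self):
        """One step on a 2-SNP / 1-interaction sample, checked against pencil
        arithmetic: s_all=(1,3,7.01), R1=1, alpha=.5 beta=.4 gamma=.1."""
        v = np.array([0.1, -0.2, 0.05, 0.3])
        w = np.array([0.2, -0.1, 0.02])
        s_all, s_e = np.array([1.0, 3.0, 7.01]), np.array([7.01])
        # forward: v[:3].s_all = -0.1495 -> Ea1'=0; w.s_all = 0.0402 -> Eo1=1
        e, amyg, ofc, ea1p, eo1 = enn_forward(v, w, s_all, s_e)
        assert amyg == pytest.approx(1.9535) and ofc == pytest.approx(0.0402)
        assert (ea1p, eo1, e) == (0, 1, 0)
        assert enn_reward(ea1p, eo1, r1=1) == -1
        v2, w2 = enn_update(v, w, s_all, s_e, r1=1, alpha=0.5, beta=0.4, gamma=0.1)
        # gain = 0.5*max(1-0,0) = 0.5; decay factor 0.9
        assert v2 == pytest.approx([0.59, 1.32, 3.55, 3.775], abs=1e-12)
        assert w2 == pytest.approx([-0.22, -1.29, -2.786], abs=1e-12)


class TestTraining:
    def _separable(self, seed=0):
        """Signal lives in one pattern with a huge tendency value: carriers
        are cases, non-carriers controls."""
        rng = np.random.default_rng(seed)
        m = 80
        genotypes = rng.integers(1, 4, size=(m, 4)).astype(np.int8)
        genotypes[: m // 2, 0] = 3  # cases carry (SNP1 = 3)
        genotypes[m // 2 :, 0] = rng.choice([1, 2], size=m // 2)
        labels = ["case"] * (m // 2) + ["control"] * (m // 2)
        data = LabeledGenotypes(genotypes, labels)
        interactions = [(SNPPattern([(0, 3)]), 50.0)]
        return data, interactions

    def test_separable_reaches_perfect_training_accuracy(self):
        data, interactions = self._separable()
        fitted = EmotionalNetwork(data, interactions, epochs=50, seed=1).fit()
        assert fitted.training_accuracy.max() == 1.0
        preds = fitted.predict(data)
        assert (preds["label"].to_numpy() == data.labels).mean() == 1.0

    def test_ablation_trains(self, planted_data):
        fitted = EmotionalNetwork(planted_data, [], epochs=5, seed=0).fit()
        assert fitted.v.shape == (planted_data.n,)
        assert fitted.w.shape == (planted_data.n,)

    def test_seed_determinism(self, planted_data, planted_pair):
        ints = [(planted_pair, 4.0)]
        a = EmotionalNetwork(planted_data, ints, epochs=5, seed=42).fit()
        b = EmotionalNetwork(planted_data, ints, epochs=5, seed=42).fit()
        assert np.array_equal(a.v, b.v) and np.array_equal(a.w, b.w)
        assert np.array_equal(a.training_accuracy, b.training_accuracy)

    def test_labels_consistent_with_E(self, planted_data, planted_pair):
        fitted = EmotionalNetwork(planted_data, [(planted_pair, 4.0)], epochs=5, seed=0).fit()
        preds = fitted.predict(planted_data)
        assert ((preds["E"] == 1) == (preds["label"] == "case")).all()

    def test_zero_model_predicts_all_control(self, planted_data):
        model = EmotionalNetwork(planted_data, [], epochs=1, seed=0)
        res = ENNResults(model, np.zeros(planted_data.n), np.zeros(planted_data.n), np.array([0.5]))
        preds = res.predict(planted_data)
        assert (preds["E"] == 0).all() and (preds["label"] == "control").all()

    def test_weight_boundedness(self):
        """Decay bounds the weights: |w_i| <= rate * B / gamma after burn-in."""
        data, interactions = self._separable()
        fitted = EmotionalNetwork(data, interactions, alpha=0.1, beta=0.1,
                                  gamma=0.05, epochs=100, seed=3).fit()
        bound = 0.1 * 50.0 / 0.05  # rate * max input / gamma
        assert np.max(np.abs(fitted.v)) <= bound + 1e-9
        assert np.max(np.abs(fitted.w)) <= bound + 1e-9

    def test_json_round_trip(self, planted_data, planted_pair):
        fitted = EmotionalNetwork(planted_data, [(planted_pair, 4.0)], epochs=3, seed=0).fit()
        text = fitted.to_json(planted_data.snp_ids)
        back = ENNResults.from_json(text)
        assert np.allclose(back.v, fitted.v) and np.allclose(back.w, fitted.w)
        p1 = fitted.predict(planted_data)
        p2 = back.predict(planted_data)
        assert (p1["label"] == p2["label"]).all()

    def test_standardized_model_round_trip(self, planted_data, planted_pair):
        fitted = EmotionalNetwork(planted_data, [(planted_pair, 4.0)],
                                  epochs=3, seed=0, standardize=True).fit()
        back = ENNResults.from_json(fitted.to_json(planted_data.snp_ids))
        p1, p2 = fitted.predict(planted_data), back.predict(planted_data)
        assert np.allclose(p1["score"], p2["score"])

    def test_invalid_rates(self, planted_data):
        with pytest.raises(ValueError):
            EmotionalNetwork(planted_data, [], alpha=0.0)
        with pytest.raises(ValueError):
            EmotionalNetwork(planted_data, [], gamma=1.5)


class TestScalarOracle:
    def test_vectorized_matches_scalar_reimplementation(self):
        """Pure-Python scalar loops reproduce the array implementation exactly."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n, p = int(rng.integers(1, 6)), int(rng.integers(0, 4))
            v = rng.normal(size=n + 2 * p)
            w = rng.normal(size=n + p)
            s_all = rng.normal(size=n + p)
            s_e = rng.normal(size=p)
            r1 = int(rng.integers(0, 2))
            alpha, beta, gamma = rng.uniform(0.01, 1, size=3)

            got = enn_forward(v, w, s_all, s_e)
            amyg = sum(v[i] * s_all[i] for i in range(n + p)) + sum(
                v[n + p + q] * s_e[q] for q in range(p)
            )
            ofc = sum(w[i] * s_all[i] for i in range(n + p))
            ea1p = 1 if sum(v[i] * s_all[i] for i in range(n + p)) >= 0 else 0
            eo1 = 1 if ofc >= 0 else 0
            e = (1 if amyg >= 0 else 0) - eo1
            assert got[0] == e
            assert got[1] == pytest.approx(amyg, abs=1e-12)
            assert got[2] == pytest.approx(ofc, abs=1e-12)
            assert (got[3], got[4]) == (ea1p, eo1)

            r0 = (max(ea1p - 1, 0) - eo1) if r1 == 1 else max(ea1p - eo1, 0)
            v2, w2 = enn_update(v, w, s_all, s_e, r1, alpha, beta, gamma)
            gain = alpha * max(r1 - ea1p, 0)
            for i in range(n + p):
                assert v2[i] == pytest.approx((1 - gamma) * v[i] + gain * s_all[i], abs=1e-12)
            for q in range(p):
                assert v2[n + p + q] == pytest.approx(
                    (1 - gamma) * v[n + p + q] + gain * s_e[q], abs=1e-12
                )
            for i in range(n + p):
                assert w2[i] == pytest.approx((1 - gamma) * w[i] + beta * r0 * s_all[i], abs=1e-12)
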