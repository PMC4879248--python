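"""Emotional neural network risk classifier with interaction-tendency inputs.

The model mimics the brain's dual emotional pathway.  For a sample with n
genotype codes S and p discovered interactions, the *emotional vector* S_e
has entry q equal to the q-th interaction's odds ratio when the sample
carries that pattern and 0 otherwise; the full input is S_all = (S, S_e) of
length n+p.  Two threshold units then compete:

* the excitatory amygdala path, weights v of length n+2p — it sees S_all
  once and the emotional vector a second time through a dedicated short
  path, so tendency inputs reach it twice;
* the inhibitory orbitofrontal-cortex (OFC) path, weights w of length n+p.

The output is E = hardlim(sum v.input) - hardlim(sum w.S_all); E = 1 labels
the sample a case.  Training is online reinforcement: presenting a case sets
the reinforcement bit R1 = 1, a control sets R1 = 0; the amygdala weights
grow by alpha*max(R1 - Ea1', 0) per input, the OFC weights by beta*R0 where
the reward R0 is derived from the two path activations, and both decay at
rate gamma.

A consequence of the learning rule worth knowing: with the conventional
all-zero initialization, non-negative inputs and hardlim(0) = 1, the
amygdala activation Ea1' is 1 from the first sample on, so max(R1 - Ea1', 0)
is always 0 and the amygdala weights never leave zero — the trainable part
of the model is the OFC path, which behaves as a decayed perceptron whose
negative activation votes "case".  The emotional inputs still matter: they
enter the OFC's input vector with odds-ratio magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .genotypes import (
    LabeledGenotypes,
    SNPPattern,
    carrier_mask,
    patterns_from_json,
)

CASE, CONTROL = "case", "control"


def hardlim(x) -> int:
    """Hard-limit transfer: 1 for x >= 0, else 0."""
    return 1 if x >= 0 else 0


def emotional_vector(sample, interactions) -> np.ndarray:
    """Per-sample tendency vector: OR of each carried interaction, else 0."""
    sample = np.asarray(sample)
    out = np.zeros(len(interactions))
    for q, (pattern, or_q) in enumerate(interactions):
        if pattern.matches(sample):
            out[q] = or_q
    return out


def build_inputs(genotypes, interactions) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (S_all, S_e) for an m x n genotype matrix.

    S_all is m x (n+p): the genotype codes followed by the emotional vector.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    m = genotypes.shape[0]
    p = len(interactions)
    s_e = np.zeros((m, p))
    for q, (pattern, or_q) in enumerate(interactions):
        s_e[carrier_mask(pattern, genotypes), q] = or_q
    return np.hstack([genotypes, s_e]), s_e


def enn_forward(v, w, s_all, s_e, duplicate_emotional_path: bool = True):
    """Single-sample forward pass.

    Returns (E, amygdala_sum, ofc_sum, Ea1', Eo1).  The amygdala sum is
    v[:n+p].S_all + v[n+p:].S_e (the short emotional path); Ea1' and Eo1 are
    the hardlims of the two long-path sums and drive learning.
    """
    s_all = np.asarray(s_all, dtype=float)
    s_e = np.asarray(s_e, dtype=float)
    np_len = s_all.shape[0]
    if duplicate_emotional_path:
        if v.shape[0] != np_len + s_e.shape[0]:
            raise ValueError(f"amygdala weights must have length n+2p, got {v.shape[0]}")
        amygdala = float(v[:np_len] @ s_all + v[np_len:] @ s_e)
    else:
        if v.shape[0] != np_len:
            raise ValueError(f"amygdala weights must have length n+p, got {v.shape[0]}")
        amygdala = float(v @ s_all)
    if w.shape[0] != np_len:
        raise ValueError(f"OFC weights must have length n+p, got {w.shape[0]}")
    ofc = float(w @ s_all)
    ea1p = hardlim(float(v[:np_len] @ s_all))
    eo1 = hardlim(ofc)
    return hardlim(amygdala) - hardlim(ofc), amygdala, ofc, ea1p, eo1


def enn_reward(ea1_prime: int, eo1: int, r1: int) -> int:
    """Reward driving OFC learning: -Eo1 when the goal is presented (R1 = 1),
    max(Ea1' - Eo1, 0) otherwise."""
    if r1 == 1:
        return max(ea1_prime - 1, 0) - eo1
    return max(ea1_prime - eo1, 0)


def enn_update(v, w, s_all, s_e, r1, alpha, beta, gamma, duplicate_emotional_path=True):
    """One online learning step; returns new (v, w).

    v_i <- (1-gamma) v_i + alpha * max(R1 - Ea1', 0) * input_i  with input
    S_all for i <= n+p and S_e beyond; w_i <- (1-gamma) w_i + beta * R0 *
    S_all_i.
    """
    s_all = np.asarray(s_all, dtype=float)
    s_e = np.asarray(s_e, dtype=float)
    np_len = s_all.shape[0]
    ea1p = hardlim(float(v[:np_len] @ s_all))
    eo1 = hardlim(float(w @ s_all))
    r0 = enn_reward(ea1p, eo1, r1)
    gain = alpha * max(r1 - ea1p, 0)
    v_new = (1.0 - gamma) * v.copy()
    v_new[:np_len] += gain * s_all
    if duplicate_emotional_path:
        v_new[np_len:] += gain * s_e
    w_new = (1.0 - gamma) * w + beta * r0 * s_all
    return v_new, w_new


@dataclass
class ENNPrediction:
    label: str
    E: int
    amygdala_sum: float
    ofc_sum: float

    @property
    def score(self) -> float:
        """Continuous risk score (margin): amygdala sum minus OFC sum."""
        return self.amygdala_sum - self.ofc_sum


class EmotionalNetwork:
    """Emotional-network risk model over a labeled genotype dataset.

    Parameters
    ----------
    data : LabeledGenotypes
        Training samples; cases are the reinforced class.
    interactions : list of (SNPPattern, odds_ratio)
        The p tendency inputs (may be empty: the no-emotion ablation).
    alpha, beta : float
        Amygdala / OFC learning rates, default 0.1.
    gamma : float
        Weight decay per step, default 0.01.
    epochs : int
        Online passes over the shuffled data, default 100.
    duplicate_emotional_path : bool
        Keep the second, dedicated amygdala route for the emotional inputs
        (the faithful architecture); ``False`` collapses it so the emotional
        values enter once through S_all.
    standardize : bool
        Z-score the genotype codes before training (off by default: raw codes
        {1,2,3} are fed as-is).
    """

    def __init__(
        self,
        data: LabeledGenotypes,
        interactions=(),
        *,
        alpha: float = 0.1,
        beta: float = 0.1,
        gamma: float = 0.01,
        epochs: int = 100,
        seed: int = 0,
        duplicate_emotional_path: bool = True,
        standardize: bool = False,
    ):
        for name, rate in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            if not 0 < rate <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {rate}")
        self.data = data
        self.interactions = list(interactions)
        self.alpha, self.beta, self.gamma = alpha, beta, gamma
        self.epochs = epochs
        self.seed = seed
        self.duplicate_emotional_path = duplicate_emotional_path
        self.standardize = standardize
        self._mean = self._std = None
        if standardize:
            g = data.genotypes.astype(float)
            self._mean = g.mean(axis=0)
            self._std = np.where(g.std(axis=0) > 0, g.std(axis=0), 1.0)

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def p(self) -> int:
        return len(self.interactions)

    def _features(self, genotypes) -> tuple[np.ndarray, np.ndarray]:
        s_all, s_e = build_inputs(genotypes, self.interactions)
        if self.standardize:
            s_all[:, : self.n] = (s_all[:, : self.n] - self._mean) / self._std
        return s_all, s_e

    def fit(self) -> "ENNResults":
        n, p = self.n, self.p
        v = np.zeros(n + 2 * p if self.duplicate_emotional_path else n + p)
        w = np.zeros(n + p)
        s_all, s_e = self._features(self.data.genotypes)
        r1_vec = self.data.is_case.astype(int)
        rng = np.random.default_rng(self.seed)
        trace = np.empty(self.epochs)
        for epoch in range(self.epochs):
            for i in rng.permutation(self.data.m):
                v, w = enn_update(
                    v, w, s_all[i], s_e[i], int(r1_vec[i]),
                    self.alpha, self.beta, self.gamma,
                    self.duplicate_emotional_path,
                )
            trace[epoch] = self._accuracy(v, w, s_all, s_e, r1_vec)
        return ENNResults(self, v, w, trace)

    def _accuracy(self, v, w, s_all, s_e, r1_vec) -> float:
        e = _forward_batch(v, w, s_all, s_e, self.duplicate_emotional_path)[0]
        return float(np.mean((e == 1) == r1_vec.astype(bool)))


def _forward_batch(v, w, s_all, s_e, duplicate):
    np_len = s_all.shape[1]
    if duplicate:
        amyg = s_all @ v[:np_len] + s_e @ v[np_len:]
    else:
        amyg = s_all @ v
    ofc = s_all @ w
    e = (amyg >= 0).astype(int) - (ofc >= 0).astype(int)
    return e, amyg, ofc


class ENNResults:
    """Fitted emotional network: weights, training trace, prediction."""

    def __init__(self, model: EmotionalNetwork, v, w, training_accuracy):
        self.model = model
        self.v = np.asarray(v, dtype=float)
        self.w = np.asarray(w, dtype=float)
        self.training_accuracy = np.asarray(training_accuracy, dtype=float)

    def predict(self, data) -> "pd.DataFrame":
        """Score samples; returns a frame with label, E, path sums and score.

        ``data`` may be a LabeledGenotypes or a bare genotype matrix with the
        model's n SNPs.
        """
        import pandas as pd

        genotypes = data.genotypes if isinstance(data, LabeledGenotypes) else np.asarray(data)
        if genotypes.shape[1] != self.model.n:
            raise ValueError(
                f"model expects {self.model.n} SNPs, got {genotypes.shape[1]}"
            )
        s_all, s_e = self.model._features(genotypes)
        e, amyg, ofc = _forward_batch(
            self.v, self.w, s_all, s_e, self.model.duplicate_emotional_path
        )
        return pd.DataFrame(
            {
                "label": np.where(e == 1, CASE, CONTROL),
                "E": e,
                "amygdala_sum": amyg,
                "ofc_sum": ofc,
                "score": amyg - ofc,
            }
        )

    def predict_one(self, sample) -> ENNPrediction:
        row = self.predict(np.asarray(sample)[None, :]).iloc[0]
        return ENNPrediction(row["label"], int(row["E"]), row["amygdala_sum"], row["ofc_sum"])

    def summary(self) -> str:
        m = self.model
        lines = [
            "Emotional network risk classifier",
            f"  n SNPs: {m.n}   p interactions: {m.p}   "
            f"amygdala weights: {self.v.shape[0]}   OFC weights: {self.w.shape[0]}",
            f"  alpha={m.alpha} beta={m.beta} gamma={m.gamma} epochs={m.epochs} seed={m.seed}",
            f"  final training accuracy: {self.training_accuracy[-1]:.4f}",
        ]
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------

    def to_json(self, snp_ids) -> str:
        m = self.model
        return json.dumps(
            {
                "v": self.v.tolist(),
                "w": self.w.tolist(),
                "alpha": m.alpha,
                "beta": m.beta,
                "gamma": m.gamma,
                "epochs": m.epochs,
                "seed": m.seed,
                "duplicate_emotional_path": m.duplicate_emotional_path,
                "standardize": m.standardize,
                "feature_mean": None if m._mean is None else m._mean.tolist(),
                "feature_std": None if m._std is None else m._std.tolist(),
                "snp_ids": list(snp_ids),
                "interactions": [
                    {"pattern": pat.to_json_obj(snp_ids), "odds_ratio": float(o)}
                    for pat, o in m.interactions
                ],
                "training_accuracy": self.training_accuracy.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ENNResults":
        obj = json.loads(text)
        snp_ids = obj["snp_ids"]
        interactions = patterns_from_json(json.dumps(obj["interactions"]), snp_ids)
        n = len(snp_ids)
        # reconstruct a model shell with a dummy single-sample dataset
        dummy = LabeledGenotypes(
            np.ones((2, n), dtype=np.int8), ["case", "control"], snp_ids=snp_ids
        )
        model = EmotionalNetwork(
            dummy,
            interactions,
            alpha=obj["alpha"],
            beta=obj["beta"],
            gamma=obj["gamma"],
            epochs=obj["epochs"],
            seed=obj["seed"],
            duplicate_emotional_path=obj["duplicate_emotional_path"],
            standardize=False,
        )
        if obj.get("standardize"):
            model.standardize = True
            model._mean = np.array(obj["feature_mean"])
            model._std = np.array(obj["feature_std"])
        return cls(model, np.array(obj["v"]), np.array(obj["w"]), np.array(obj["training_accuracy"]))
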