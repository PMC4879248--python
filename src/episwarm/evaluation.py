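"""Confusion-matrix statistics and the stratified 5-fold evaluation protocol.

Positive class is "case" throughout.  The five reported statistics are

    Sn  = TP/(TP+FN)            Sp  = TN/(FP+TN)
    Acc = (TP+TN)/total         RR  = TP*(FP+TN) / (FP*(TP+FN))
    OR  = TP*TN / (FP*FN)

A zero denominator makes the statistic undefined; it is surfaced as such
(never a silent NaN) and excluded from cross-fold means with a count.

Cross-validation is leakage-free by construction: inside each fold the
interaction patterns are discovered (or their odds ratios re-estimated) on
the training split only, the network is trained on the training split, and
the confusion statistics come from the held-out fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .enn import CASE, EmotionalNetwork
from .genotypes import LabeledGenotypes
from .interaction_stats import UndefinedStatisticError, odds_ratio as table_odds_ratio
from .genotypes import carrier_counts
from .swarm import BPSOHS, SwarmConfig

STAT_NAMES = ("sensitivity", "specificity", "accuracy", "risk_ratio", "odds_ratio")


@dataclass(frozen=True)
class ConfusionMetrics:
    """TP/TN/FP/FN with the five derived statistics (None where undefined)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def _ratio(self, num, den):
        return num / den if den != 0 else None

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self):
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return self._ratio(self.tn, self.fp + self.tn)

    @property
    def accuracy(self):
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def risk_ratio(self):
        return self._ratio(self.tp * (self.fp + self.tn), self.fp * (self.tp + self.fn))

    @property
    def odds_ratio(self):
        return self._ratio(self.tp * self.tn, self.fp * self.fn)

    def as_dict(self) -> dict:
        out = {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}
        for name in STAT_NAMES:
            out[name] = getattr(self, name)
        return out


def confusion(true_labels, predicted_labels) -> ConfusionMetrics:
    """Tally the 2x2 confusion table; positive class is "case"."""
    t = np.asarray(true_labels) == CASE
    p = np.asarray(predicted_labels) == CASE
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionMetrics(
        tp=int(np.count_nonzero(t & p)),
        tn=int(np.count_nonzero(~t & ~p)),
        fp=int(np.count_nonzero(~t & p)),
        fn=int(np.count_nonzero(t & ~p)),
    )


@dataclass
class KFoldReport:
    """Per-fold confusion metrics plus mean/sd across folds."""

    folds: list[ConfusionMetrics]
    fold_interactions: list[list]

    def to_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.folds]
        return pd.DataFrame(rows, index=[f"fold{i+1}" for i in range(len(rows))])

    def mean(self) -> dict:
        """Cross-fold mean of each statistic, skipping undefined folds.

        Returns {stat: (mean, sd, n_undefined)}.
        """
        out = {}
        for name in STAT_NAMES:
            vals = [getattr(m, name) for m in self.folds]
            ok = [v for v in vals if v is not None]
            n_undef = len(vals) - len(ok)
            if ok:
                out[name] = (float(np.mean(ok)), float(np.std(ok)), n_undef)
            else:
                out[name] = (None, None, n_undef)
        return out

    def summary(self) -> str:
        lines = [f"Stratified {len(self.folds)}-fold cross-validation", self.to_frame().to_string()]
        lines.append("means over folds (undefined folds excluded):")
        for name, (mu, sd, nu) in self.mean().items():
            if mu is None:
                lines.append(f"  {name}: undefined in all folds")
            else:
                extra = f"  ({nu} undefined fold(s) excluded)" if nu else ""
                lines.append(f"  {name}: {mu:.4f} +/- {sd:.4f}{extra}")
        return "\n".join(lines)


def stratified_folds(data: LabeledGenotypes, k: int = 5, seed: int = 0):
    """Stratified (train_idx, test_idx) splits preserving the class ratio."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(data.m), data.is_case.astype(int)))


def estimate_interaction_ors(patterns, train: LabeledGenotypes):
    """(pattern, OR) pairs with odds ratios from the training split only.

    Zero-cell tables fall back to the Haldane-Anscombe corrected OR so the
    emotional input stays finite.
    """
    out = []
    for pat in patterns:
        counts = carrier_counts(pat, train)
        try:
            orx = table_odds_ratio(counts)
        except UndefinedStatisticError:
            orx = table_odds_ratio(counts, correction=True)
        out.append((pat, orx))
    return out


def kfold_evaluate(
    data: LabeledGenotypes,
    k: int = 5,
    seed: int = 0,
    *,
    known_patterns=None,
    n_interactions: int = 5,
    swarm_config: SwarmConfig | None = None,
    enn_params: dict | None = None,
) -> KFoldReport:
    """Stratified k-fold evaluation of the detect-then-classify pipeline.

    Per fold: interaction patterns are either discovered on the training
    split by the swarm search (``known_patterns=None``; the top
    ``n_interactions`` archive entries are used) or taken as given
    (``known_patterns``, a list of SNPPattern — the "OR re-estimation only"
    mode used for ablation studies).  In both modes the emotional odds
    ratios come from the training split, the network is trained on the
    training split, and metrics are computed on the held-out fold.
    """
    enn_params = dict(enn_params or {})
    folds, fold_interactions = [], []
    for fold_i, (train_idx, test_idx) in enumerate(stratified_folds(data, k, seed)):
        train, test = data.subset(train_idx), data.subset(test_idx)
        if train.n_case == 0 or train.n_control == 0 or test.n_case == 0 or test.n_control == 0:
            raise ValueError(f"fold {fold_i + 1} lost a class; use stratified data")
        if known_patterns is None:
            cfg = swarm_config or SwarmConfig()
            cfg = replace(cfg, seed=cfg.seed + fold_i)
            results = BPSOHS(train, cfg).fit()
            patterns = [r.pattern for r in results.records[:n_interactions]]
        else:
            patterns = list(known_patterns)
        interactions = estimate_interaction_ors(patterns, train)
        enn_params.setdefault("seed", seed)
        fitted = EmotionalNetwork(train, interactions, **enn_params).fit()
        preds = fitted.predict(test)
        folds.append(confusion(test.labels, preds["label"].to_numpy()))
        fold_interactions.append(interactions)
    return KFoldReport(folds=folds, fold_interactions=fold_interactions)
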