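"""Synthetic case-control genotype simulator with planted interaction patterns.

Background SNPs are drawn independently per-SNP from a genotype-frequency
triple over the codes (1, 2, 3), identically in cases and controls — by
default (0.49, 0.09, 0.42), the Hardy-Weinberg proportions at minor-allele
frequency 0.3 under the major-hom/minor-hom/het coding.  Each planted
pattern is given a carrier probability per class: carrier status is
Bernoulli per sample, carriers receive the pattern's genotypes at its SNPs,
and non-carriers have those SNPs redrawn from the background frequencies
conditional on NOT matching the full pattern (rejection sampling).  Choosing
the two carrier probabilities sets the pattern's population odds ratio;
:func:`or_to_carrier_probs` inverts the odds-ratio definition so a target OR
can be planted directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GENOTYPE_CODES, LabeledGenotypes, SNPPattern, carrier_mask

DEFAULT_GENOTYPE_FREQS = (0.49, 0.09, 0.42)
_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class PlantedPattern:
    """One planted interaction: the pattern plus its per-class carrier rates."""

    pattern: SNPPattern
    case_carrier_prob: float
    control_carrier_prob: float

    def __post_init__(self):
        for p in (self.case_carrier_prob, self.control_carrier_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"carrier probability {p} outside [0, 1]")


@dataclass
class SimulationSpec:
    """Study design of a synthetic dataset.

    ``genotype_freqs`` is a single triple applied to every SNP or an
    n_snps x 3 array of per-SNP triples; each triple must sum to 1.
    Planted patterns must occupy disjoint SNP sets.
    """

    m_case: int
    m_control: int
    n_snps: int
    genotype_freqs: object = DEFAULT_GENOTYPE_FREQS
    planted: list[PlantedPattern] = field(default_factory=list)
    seed: int = 0

    def freq_matrix(self) -> np.ndarray:
        f = np.asarray(self.genotype_freqs, dtype=float)
        if f.ndim == 1:
            f = np.tile(f, (self.n_snps, 1))
        if f.shape != (self.n_snps, 3):
            raise ValueError(f"genotype_freqs must be a triple or {self.n_snps}x3, got {f.shape}")
        if (f < 0).any() or not np.allclose(f.sum(axis=1), 1.0):
            raise ValueError("each genotype-frequency triple must be non-negative and sum to 1")
        return f

    def __post_init__(self):
        if self.m_case <= 0 or self.m_control <= 0:
            raise ValueError("both classes need at least one sample")
        self.freq_matrix()
        used = set()
        for pp in self.planted:
            idx = set(pp.pattern.snp_indices)
            if max(idx, default=-1) >= self.n_snps:
                raise ValueError("planted pattern index outside the SNP panel")
            if idx & used:
                raise ValueError("planted patterns must use disjoint SNP sets")
            used |= idx


def or_to_carrier_probs(target_or: float, control_prob: float) -> float:
    """Case carrier probability realizing ``target_or`` against ``control_prob``.

    Inverts OR = odds(case)/odds(control): case_prob = t/(1+t) with
    t = OR * control_prob/(1-control_prob).
    """
    if target_or <= 0:
        raise ValueError("target odds ratio must be positive")
    if not 0 < control_prob < 1:
        raise ValueError("control carrier probability must be in (0, 1)")
    t = target_or * control_prob / (1.0 - control_prob)
    return t / (1.0 + t)


def _pattern_mass(pattern: SNPPattern, freqs: np.ndarray) -> float:
    mass = 1.0
    for i, g in pattern.entries:
        mass *= freqs[i, g - 1]
    return mass


def simulate_case_control(spec: SimulationSpec) -> LabeledGenotypes:
    """Draw a labeled genotype matrix per the spec; fully seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    m = spec.m_case + spec.m_control
    freqs = spec.freq_matrix()

    # background: per-SNP categorical draws, identical mechanism in both classes
    genotypes = np.empty((m, spec.n_snps), dtype=np.int8)
    codes = np.array(GENOTYPE_CODES, dtype=np.int8)
    for j in range(spec.n_snps):
        genotypes[:, j] = rng.choice(codes, size=m, p=freqs[j])

    is_case = np.zeros(m, dtype=bool)
    is_case[: spec.m_case] = True

    for pp in spec.planted:
        if _pattern_mass(pp.pattern, freqs) >= 0.999:
            raise ValueError(
                f"pattern {pp.pattern.entries} covers almost all genotype mass; "
                "non-carriers cannot be drawn"
            )
        prob = np.where(is_case, pp.case_carrier_prob, pp.control_carrier_prob)
        carriers = rng.random(m) < prob
        cols = list(pp.pattern.snp_indices)
        for i, g in pp.pattern.entries:
            genotypes[carriers, i] = g
        # non-carriers: redraw the pattern's SNPs until the full pattern fails
        pending = np.flatnonzero(~carriers)
        for _ in range(_MAX_REDRAWS):
            if pending.size == 0:
                break
            for j in cols:
                genotypes[np.ix_(pending, [j])] = rng.choice(
                    codes, size=(pending.size, 1), p=freqs[j]
                )
            still = carrier_mask(pp.pattern, genotypes[pending][:, :])
            pending = pending[still]
        else:
            raise ValueError("rejection sampling for non-carriers did not terminate")

    labels = np.where(is_case, "case", "control")
    return LabeledGenotypes(genotypes, labels)


def ground_truth(spec: SimulationSpec, data: LabeledGenotypes) -> list[dict]:
    """Sidecar describing each planted pattern with its realized counts."""
    from .interaction_stats import summarize_pattern

    out = []
    for pp in spec.planted:
        rec = summarize_pattern(pp.pattern, data)
        out.append(
            {
                "pattern": pp.pattern.to_json_obj(data.snp_ids),
                "case_carrier_prob": pp.case_carrier_prob,
                "control_carrier_prob": pp.control_carrier_prob,
                "realized_case_carriers": rec.counts.a,
                "realized_control_carriers": rec.counts.c,
                "realized_odds_ratio": None if np.isnan(rec.odds_ratio) else rec.odds_ratio,
                "fitness": rec.fitness,
            }
        )
    return out
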