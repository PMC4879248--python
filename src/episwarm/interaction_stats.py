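"""Association statistics on a pattern's 2x2 carrier table.

For a pattern with case carriers ``a`` (of ``a+b`` cases) and control
carriers ``c`` (of ``c+d`` controls):

* fitness  F = |a/(a+b) - c/(c+d)|, the carrier-proportion difference used
  as the swarm's objective;
* odds ratio  OR = a*d / (b*c);
* Woolf (log-normal) confidence interval
  exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d));
* Fisher's exact p-value (the package's default significance measure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes import CarrierCounts, LabeledGenotypes, SNPPattern, carrier_counts


class UndefinedStatisticError(ValueError):
    """An association statistic is undefined for this table (zero cell)."""


def pattern_fitness(counts: CarrierCounts) -> float:
    """Absolute difference of carrier proportions between cases and controls."""
    if counts.n_case == 0 or counts.n_control == 0:
        raise UndefinedStatisticError("fitness needs both classes non-empty")
    return abs(counts.a / counts.n_case - counts.c / counts.n_control)


def odds_ratio(counts: CarrierCounts, correction: bool = False) -> float:
    """Cross-product odds ratio a*d/(b*c).

    With ``correction`` a Haldane-Anscombe +0.5 is added to every cell,
    allowing zero-cell tables; otherwise a zero in b*c (or a*d) raises.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif b * c == 0 or a * d == 0:
        raise UndefinedStatisticError(f"odds ratio undefined for zero-cell table {counts}")
    return (a * d) / (b * c)


def woolf_ci(
    counts: CarrierCounts, level: float = 0.95, correction: bool = False
) -> tuple[float, float]:
    """Woolf log-normal confidence interval for the odds ratio.

    Requires all four cells > 0 unless the +0.5 correction is requested.
    """
    if not 0 <= level < 1:
        raise ValueError(f"confidence level must be in [0, 1), got {level}")
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif min(a, b, c, d) == 0:
        raise UndefinedStatisticError(f"Woolf CI undefined for zero-cell table {counts}")
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def fisher_exact_p(counts: CarrierCounts, sided: str = "two") -> float:
    """Fisher's exact (hypergeometric) p-value for the carrier table.

    ``sided`` is "two" (sum of tables at most as probable as observed) or
    "one" (greater-carrier-odds tail).
    """
    table = [[counts.a, counts.b], [counts.c, counts.d]]
    alternative = {"two": "two-sided", "one": "greater"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    return float(stats.fisher_exact(table, alternative=alternative).pvalue)


@dataclass(frozen=True)
class InteractionRecord:
    """One report row for a genotype-pattern interaction.

    ``difference`` is |a - c| (exact when the groups have equal size, the
    design this package targets; for unequal groups it is the proportion
    difference scaled by the smaller group, flagged via ``difference_scaled``).
    OR and CI are NaN when a zero cell makes them undefined.
    """

    pattern: SNPPattern
    counts: CarrierCounts
    difference: int
    fitness: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    difference_scaled: bool = False

    def row(self, snp_ids=None) -> dict:
        """Flatten to a Table-style report row (1-based SNP naming)."""
        return {
            "pattern": self.pattern.to_string(snp_ids),
            "order": self.pattern.order,
            "case_carriers": self.counts.a,
            "control_carriers": self.counts.c,
            "difference": self.difference,
            "fitness": round(self.fitness, 6),
            "odds_ratio": _round_or(self.odds_ratio),
            "ci_95": _format_ci(self.ci_low, self.ci_high),
            "p_value": self.p_value,
        }


def _round_or(x: float) -> float:
    if math.isnan(x):
        return x
    # Table style: 3 d.p. below 10, 2 d.p. at or above.
    return round(x, 2 if x >= 10 else 3)


def _format_ci(lo: float, hi: float) -> str:
    if math.isnan(lo):
        return "undefined"
    return f"{float(f'{lo:.4g}'):g}-{float(f'{hi:.4g}'):g}"


def summarize_pattern(
    pattern: SNPPattern, data: LabeledGenotypes, level: float = 0.95
) -> InteractionRecord:
    """Assemble counts, difference, fitness, OR, Woolf CI and Fisher p for a pattern."""
    counts = carrier_counts(pattern, data)
    fitness = pattern_fitness(counts)
    if counts.n_case == counts.n_control:
        difference, scaled = abs(counts.a - counts.c), False
    else:
        difference, scaled = round(fitness * min(counts.n_case, counts.n_control)), True
    try:
        orx = odds_ratio(counts)
        lo, hi = woolf_ci(counts, level)
    except UndefinedStatisticError:
        orx = lo = hi = float("nan")
    return InteractionRecord(
        pattern=pattern,
        counts=counts,
        difference=difference,
        fitness=fitness,
        odds_ratio=orx,
        ci_low=lo,
        ci_high=hi,
        p_value=fisher_exact_p(counts),
        difference_scaled=scaled,
    )


def records_to_frame(records, snp_ids=None):
    """Tabulate InteractionRecords as a pandas DataFrame (report order preserved)."""
    import pandas as pd

    return pd.DataFrame([r.row(snp_ids) for r in records])
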