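"""Mut:WT* selection statistics for knock-in experiments.

The central quantity is the ratio of mutation-of-interest to synonymous
internal-control knock-in read counts,

    r = count(MUT_KI) / count(WTSTAR_KI),

normalized to the baseline timepoint within each condition,

    R(t) = r(t) / r(baseline),

so that R = 1 means no selection on the mutant relative to the control.
A per-day selection coefficient s = ln(R)/dt summarizes the endpoint,
and replicate-level paired or Welch t-tests compare conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import MUT_KI, WTSTAR_KI, OutcomeTable
from .stats import TestResult, t_test_paired, t_test_welch


class UndefinedRatioError(ZeroDivisionError):
    """Mut:WT* is undefined because the WT* count is zero."""


def mut_wtstar_ratio(table: OutcomeTable) -> float:
    """Raw Mut:WT* ratio of one sample.

    Only the classified knock-in categories enter; ambiguous and
    discarded reads are excluded. A zero MUT_KI count with nonzero WT*
    yields 0 with a warning (observable extinction of the mutant arm);
    a zero WT* count raises :class:`UndefinedRatioError`.
    """
    n_mut = table.counts[MUT_KI]
    n_wts = table.counts[WTSTAR_KI]
    if n_wts == 0:
        raise UndefinedRatioError(
            f"WT* count is zero at D{table.timepoint} {table.condition} "
            f"rep{table.replicate}: Mut:WT* undefined"
        )
    if n_mut == 0:
        warnings.warn(
            f"zero MUT_KI count at D{table.timepoint} {table.condition} "
            f"rep{table.replicate}; ratio is 0 (mutant extinct)",
            stacklevel=2,
        )
    return n_mut / n_wts


def normalize_to_baseline(
    ratios: Mapping[int, float], baseline_day: int
) -> dict[int, float]:
    """Normalize per-timepoint ratios to the baseline day: R(t)=r(t)/r(base)."""
    if baseline_day not in ratios:
        raise KeyError(f"baseline day {baseline_day} missing from ratios")
    base = ratios[baseline_day]
    if base <= 0:
        raise ValueError("baseline ratio must be positive")
    return {day: r / base for day, r in ratios.items()}


def selection_coefficient(R: float, dt_days: float) -> float:
    """Per-day selection coefficient s = ln(R)/dt."""
    if R <= 0:
        raise ValueError("R must be positive")
    if dt_days <= 0:
        raise ValueError("dt must be positive")
    return log(R) / dt_days


def compare_conditions(
    R_treated: Sequence[float],
    R_untreated: Sequence[float],
    paired: bool = True,
) -> TestResult:
    """Replicate-level t-test of normalized R between conditions.

    Paired (within-replicate differences) by default, matching the
    triplicate design; Welch unpaired for cross-cell-line comparisons.
    """
    if paired:
        return t_test_paired(np.asarray(R_treated), np.asarray(R_untreated))
    return t_test_welch(np.asarray(R_treated), np.asarray(R_untreated))


@dataclass
class SelectResult:
    """Full selection analysis of one variant's outcome tables."""

    variant: str
    baseline_day: int
    raw_ratios: dict  # (day, condition, replicate) -> r
    normalized: dict  # (day, condition, replicate) -> R
    coefficients: dict  # (day, condition, replicate) -> s (days past baseline)
    tests: dict[str, TestResult] = field(default_factory=dict)

    def replicate_R(self, day: int, condition: str) -> list[float]:
        return [
            R
            for (d, c, _rep), R in sorted(self.normalized.items())
            if d == day and c == condition
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant": self.variant,
                "timepoint": day,
                "condition": cond,
                "replicate": rep,
                "r": self.raw_ratios[(day, cond, rep)],
                "R": R,
                "s": self.coefficients.get((day, cond, rep), float("nan")),
            }
            for (day, cond, rep), R in sorted(self.normalized.items())
        ]
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        days = sorted({d for d, _, _ in self.normalized})
        conds = sorted({c for _, c, _ in self.normalized})
        for day in days:
            for cond in conds:
                Rs = self.replicate_R(day, cond)
                if not Rs:
                    continue
                rows.append(
                    {
                        "variant": self.variant,
                        "timepoint": day,
                        "condition": cond,
                        "n_replicates": len(Rs),
                        "mean_R": float(np.mean(Rs)),
                        "sd_R": float(np.std(Rs, ddof=1)) if len(Rs) > 1 else float("nan"),
                    }
                )
        df = pd.DataFrame(rows)
        for name, test in self.tests.items():
            df[f"{name}_t"] = test.statistic
            df[f"{name}_p"] = test.p
        return df


def analyze_select(
    tables: Iterable[OutcomeTable],
    variant: str = "variant",
    baseline_day: int | None = None,
    endpoint_day: int | None = None,
    paired: bool = True,
) -> SelectResult:
    """Compute ratios, normalized R, s, and the endpoint condition test.

    Each replicate is normalized independently to its own baseline
    within each condition; replicates are never pooled before testing.
    """
    tables = list(tables)
    days = sorted({t.timepoint for t in tables})
    if baseline_day is None:
        baseline_day = days[0]
    if endpoint_day is None:
        endpoint_day = days[-1]

    raw: dict = {}
    for t in tables:
        raw[(t.timepoint, t.condition, t.replicate)] = mut_wtstar_ratio(t)

    normalized: dict = {}
    coefficients: dict = {}
    for (day, cond, rep), r in raw.items():
        base = raw.get((baseline_day, cond, rep))
        if base is None:
            raise KeyError(f"missing baseline D{baseline_day} for {cond} rep{rep}")
        R = r / base
        normalized[(day, cond, rep)] = R
        if day != baseline_day and R > 0:
            coefficients[(day, cond, rep)] = selection_coefficient(R, day - baseline_day)

    result = SelectResult(
        variant=variant,
        baseline_day=baseline_day,
        raw_ratios=raw,
        normalized=normalized,
        coefficients=coefficients,
    )

    conds = sorted({c for _, c, _ in normalized})
    if len(conds) == 2:
        # convention: test treated vs untreated normalized R at endpoint
        lo, hi = conds
        treated = "treated" if "treated" in conds else hi
        untreated = [c for c in conds if c != treated][0]
        Rt = result.replicate_R(endpoint_day, treated)
        Ru = result.replicate_R(endpoint_day, untreated)
        if len(Rt) >= 2 and len(Ru) >= 2:
            result.tests["treated_vs_untreated"] = compare_conditions(Rt, Ru, paired=paired)
    return result
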