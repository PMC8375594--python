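"""Cost-sweep orchestration and top-K performance curves.

The network cost is swept over 8-44% in 1% steps (37 levels); at each cost
and for each requested selector, the nested-CV evaluation is repeated for
K = 1..30 retained features.  The *best* cost for a contrast is the one
maximizing the mean out-of-fold AUC over K, with ties resolved toward the
lower variance over K and then the lower cost ("best and most stable").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import NestedCVConfig, _check_Xy, _evaluate_loocv, fold_rankings, report_from_folds
from .cohort import SubjectRecord
from .features import build_design_matrix
from .stats import ClassificationReport

#: the full printed sweep: 8% to 44% at 1% intervals.
COST_GRID: tuple[float, ...] = tuple(round(c / 100.0, 2) for c in range(8, 45))

DEFAULT_K_VALUES: tuple[int, ...] = tuple(range(1, 31))


@dataclass
class SweepResult:
    """Reports per (cost, selector, K) plus the best-cost rule."""

    reports: dict[tuple[float, str, int], ClassificationReport]
    costs: tuple[float, ...]
    selectors: tuple[str, ...]
    k_values: tuple[int, ...]
    contrast: tuple[str, str] = ("", "")
    fold_selections: dict = field(default_factory=dict)

    def auc_curve(self, cost: float, selector: str) -> dict[int, float]:
        return {k: self.reports[(cost, selector, k)].auc for k in self.k_values}

    def best_cost(self, selector: str) -> float:
        """Max mean AUC over K; ties by lower AUC variance over K, then lower cost."""
        rows = []
        for cost in self.costs:
            aucs = np.array([self.reports[(cost, selector, k)].auc for k in self.k_values])
            rows.append((-aucs.mean(), aucs.var(), cost))
        rows.sort()
        return rows[0][2]

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for (cost, selector, k), rep in self.reports.items():
            records.append(
                {
                    "cost": cost,
                    "selector": selector,
                    "k": k,
                    "acc": rep.acc,
                    "sen": rep.sen,
                    "spe": rep.spe,
                    "bac": rep.bac,
                    "auc": rep.auc,
                }
            )
        return pd.DataFrame.from_records(records)


def topk_curve(
    X, y, config: NestedCVConfig, k_values: Sequence[int] = DEFAULT_K_VALUES
) -> dict[int, ClassificationReport]:
    """Nested-CV reports as a function of the number of retained features.

    Feature rankings are computed once per outer fold and reused across K,
    so every K shares the identical selection.
    """
    X, y = _check_Xy(X, y)
    config.validate()
    max_k = max(k_values)
    if max_k > X.shape[1]:
        raise ValueError(f"K={max_k} exceeds the {X.shape[1]} available features")
    rankings = fold_rankings(X, y, config)
    out = {}
    for k in k_values:
        folds = _evaluate_loocv(X, y, replace(config, top_k=int(k)), rankings)
        out[int(k)] = report_from_folds(folds)
    return out


def run_sweep(
    cohort: Sequence[SubjectRecord],
    contrast: tuple[str, str],
    selectors: Sequence[str],
    config: NestedCVConfig,
    costs: Sequence[float] = COST_GRID,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    **assemble_kwargs,
) -> SweepResult:
    """Evaluate every (cost, selector, K) combination for one contrast."""
    reports: dict[tuple[float, str, int], ClassificationReport] = {}
    for cost in costs:
        fm = build_design_matrix(cohort, contrast, cost, **assemble_kwargs)
        for selector in selectors:
            cfg = replace(config, selector=selector)
            per_k = topk_curve(fm.values, fm.y, cfg, k_values=k_values)
            for k, rep in per_k.items():
                reports[(float(cost), selector, int(k))] = rep
    return SweepResult(
        reports=reports,
        costs=tuple(float(c) for c in costs),
        selectors=tuple(selectors),
        k_values=tuple(int(k) for k in k_values),
        contrast=tuple(contrast),
    )
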