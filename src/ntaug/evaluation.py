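"""Performance metrics and replicate/seed aggregation.

Regression performance is Spearman's rank correlation between predicted and
measured fitness; classification performance is the Matthews correlation
coefficient (MCC), which stays informative under class imbalance. Both lie
in [-1, 1]. Test metrics are computed on each of the five reverse-translated
test replicates, averaged per seed, then summarized across seeds as mean,
standard deviation and a normal-approximation 95% confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from .errors import AggregationError, UndefinedMetricError

__all__ = ["MetricResult", "spearman_rho", "mcc", "aggregate", "compare_runs"]


def spearman_rho(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Spearman's Rho: Pearson correlation of average ranks (ties averaged)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise UndefinedMetricError("inputs must be equal-length 1-D vectors")
    if pred.size < 2:
        raise UndefinedMetricError("Spearman's Rho needs at least 2 observations")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise UndefinedMetricError("Spearman's Rho is undefined for a constant vector")
    return float(stats.spearmanr(pred, truth).statistic)


def mcc(pred: Sequence[int], truth: Sequence[int]) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is zero."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise UndefinedMetricError("inputs must be equal-length 1-D vectors")
    if pred.size == 0:
        raise UndefinedMetricError("MCC needs at least 1 observation")
    for name, v in (("pred", pred), ("truth", truth)):
        if not np.isin(v, (0, 1)).all():
            raise UndefinedMetricError(f"{name} must be binary (0/1)")
    # sklearn implements the zero-denominator -> 0 convention
    return float(matthews_corrcoef(truth, pred))


@dataclass(frozen=True)
class MetricResult:
    """Aggregated metric: per-seed means over replicates, summarized over seeds."""

    metric: str
    per_seed: tuple[float, ...]
    mean: float
    sd: float
    n_seeds: int
    ci95: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "per_seed": list(self.per_seed),
            "mean": self.mean,
            "sd": self.sd,
            "n_seeds": self.n_seeds,
            "ci95": list(self.ci95) if self.ci95 else None,
        }


def aggregate(per_seed_replicates: Sequence[Sequence[float]], metric: str) -> MetricResult:
    """Aggregate raw metric values: mean over each seed's replicates, then
    mean / sd / CI95 over seeds.

    ``per_seed_replicates[s]`` holds one value per test replicate for seed
    ``s``; every seed must supply the same number of replicates. The CI is
    ``mean +/- 1.96 * sd / sqrt(n_seeds)`` and is absent for a single seed.
    """
    if not per_seed_replicates:
        raise AggregationError("no results to aggregate")
    counts = {len(r) for r in per_seed_replicates}
    if len(counts) != 1 or counts == {0}:
        raise AggregationError(f"mismatched replicate counts across seeds: {sorted(counts)}")
    per_seed = tuple(float(np.mean(r)) for r in per_seed_replicates)
    n = len(per_seed)
    mean = float(np.mean(per_seed))
    sd = float(np.std(per_seed, ddof=1)) if n > 1 else 0.0
    ci = None
    if n > 1:
        half = 1.96 * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    return MetricResult(metric=metric, per_seed=per_seed, mean=mean, sd=sd, n_seeds=n, ci95=ci)


def compare_runs(
    baselines: dict[str, MetricResult],
    nta_conditions: dict[str, MetricResult],
) -> dict:
    """Tabulate baselines against augmentation conditions.

    Returns a JSON-serializable report; ``render_report`` turns it into a
    plain-text table. Deltas are each condition's mean minus the best
    baseline mean.
    """
    metrics = {r.metric for r in baselines.values()} | {
        r.metric for r in nta_conditions.values()
    }
    if len(metrics) > 1:
        raise AggregationError(f"cannot compare different metrics: {sorted(metrics)}")
    best_baseline = max((r.mean for r in baselines.values()), default=float("nan"))
    report = {
        "metric": next(iter(metrics)) if metrics else None,
        "baselines": {k: v.to_dict() for k, v in baselines.items()},
        "conditions": {
            k: {**v.to_dict(), "delta_vs_best_baseline": v.mean - best_baseline}
            for k, v in nta_conditions.items()
        },
    }
    return report


def render_report(report: dict) -> str:
    """Plain-text table view of a ``compare_runs`` report."""
    lines = [f"metric: {report['metric']}"]
    width = max(
        [len(k) for k in report["baselines"]] + [len(k) for k in report["conditions"]] + [9]
    )
    lines.append(f"{'condition':<{width}}  {'mean':>7}  {'sd':>6}  {'delta':>7}")
    for name, r in report["baselines"].items():
        lines.append(f"{name:<{width}}  {r['mean']:>7.3f}  {r['sd']:>6.3f}  {'--':>7}")
    for name, r in report["conditions"].items():
        lines.append(
            f"{name:<{width}}  {r['mean']:>7.3f}  {r['sd']:>6.3f}  "
            f"{r['delta_vs_best_baseline']:>+7.3f}"
        )
    return "\n".join(lines)


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
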