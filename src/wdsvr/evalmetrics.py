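"""Regression performance measures: RMSE, RMSRE, Pearson, Spearman.

RMSRE is returned as a fraction; reports multiply by 100 where a percentage
is wanted. Spearman uses average ranks for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats


class UndefinedCorrelationError(ValueError):
    """Correlation of a constant vector is undefined."""


def _check(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, truth


def rmse(pred, truth) -> float:
    pred, truth = _check(pred, truth)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def rmsre(pred, truth) -> float:
    """Root mean square relative error, relative to the true values."""
    pred, truth = _check(pred, truth)
    if (truth == 0).any():
        raise ValueError("RMSRE undefined: zero entry in truth")
    return float(np.sqrt(np.mean(((pred - truth) / truth) ** 2)))


def pearson(pred, truth) -> float:
    pred, truth = _check(pred, truth)
    if pred.size < 2:
        raise ValueError("need n >= 2 for correlation")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise UndefinedCorrelationError("constant vector")
    return float(stats.pearsonr(pred, truth).statistic)


def spearman(pred, truth) -> float:
    pred, truth = _check(pred, truth)
    if pred.size < 2:
        raise ValueError("need n >= 2 for correlation")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise UndefinedCorrelationError("constant vector")
    return float(stats.spearmanr(pred, truth).statistic)


@dataclass
class MetricsReport:
    rmse: float
    rmsre: float
    pearson: float
    spearman: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_tsv_row(self, header: bool = True) -> str:
        lines = []
        if header:
            lines.append("rmse\trmsre_pct\tpearson\tspearman\tn")
        lines.append(
            f"{self.rmse:.6g}\t{100 * self.rmsre:.6g}\t{self.pearson:.6g}\t"
            f"{self.spearman:.6g}\t{self.n}"
        )
        return "\n".join(lines) + "\n"


def report(pred, truth) -> MetricsReport:
    """All four measures in one record."""
    pred, truth = _check(pred, truth)
    return MetricsReport(
        rmse=rmse(pred, truth),
        rmsre=rmsre(pred, truth),
        pearson=pearson(pred, truth),
        spearman=spearman(pred, truth),
        n=int(pred.size),
    )
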