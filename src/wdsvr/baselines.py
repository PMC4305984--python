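"""Baseline predictors: mononucleotide PWM on ln K_d and a plain one-round
WD-kernel SVR, plus a small comparison harness.

The PWM is the additive independence model: ln K_d is assumed to be a sum of
one contribution per (position, nucleotide), fit by minimum-norm least
squares on the one-hot design matrix. The one-hot blocks are rank deficient
(each position's four columns sum to the constant vector), so only fitted
values — not individual weights — are identifiable; the pseudo-inverse
resolves the gauge. Predictions are mapped back to the affinity scale by
exponentiation before any metric is computed, so comparisons against the
kernel methods are like-for-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqdata import AffinityDataset
from .wdkernel import KernelConfig, encode, kernel_matrix, cross_kernel_matrix
from . import svr_engine
from . import evalmetrics


@dataclass
class PWMModel:
    """weights[4*p + c] = ln-affinity contribution of nucleotide c at
    0-based position p (identifiable only up to per-position offsets)."""

    weights: np.ndarray
    L: int
    z: int = 4

    @property
    def u(self) -> int:
        return self.L * self.z


def _one_hot(seqs: Sequence[str], L: int) -> np.ndarray:
    codes = encode(seqs)
    if codes.shape[1] != L:
        raise ValueError(f"sequence length {codes.shape[1]} != model L {L}")
    n = codes.shape[0]
    A = np.zeros((n, 4 * L))
    cols = 4 * np.arange(L)[None, :] + codes
    A[np.arange(n)[:, None], cols] = 1.0
    return A


def pwm_fit(ds: AffinityDataset) -> PWMModel:
    """Least-squares fit of A x = ln(affinity) over the one-hot design."""
    y = ds.affinities
    if (y <= 0).any():
        raise ValueError("PWM requires positive affinities (ln transform)")
    A = _one_hot(ds.sequences, ds.length)
    x, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
    return PWMModel(weights=x, L=ds.length)


def pwm_predict(model: PWMModel, seqs: Sequence[str]) -> np.ndarray:
    """Predicted affinities exp(A x), back on the K_d / relative scale."""
    A = _one_hot(seqs, model.L)
    return np.exp(A @ model.weights)


def wdsvr_baseline(
    train: AffinityDataset,
    test_seqs: Sequence[str],
    d: int = 7,
    C: float | None = None,
    epsilon: float | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """One-round SVR on the plain WD kernel (no shifts, no mismatches, no
    selection stage). Returns predictions for ``test_seqs``."""
    y = train.affinities
    if C is None:
        C = 1.0
    if epsilon is None:
        epsilon = 0.1 * float(np.std(y))
    cfg = KernelConfig(d=d, s=0, m=0, normalize=normalize)
    K = kernel_matrix(train.sequences, cfg)
    model = svr_engine.fit(K, y, C=C, epsilon=epsilon)
    model.kernel_config = cfg
    model.training_sequences = list(train.sequences)
    Kc = cross_kernel_matrix(list(test_seqs), train.sequences, cfg)
    return svr_engine.predict(model, Kc)


def comparison_table(
    train: AffinityDataset,
    test: AffinityDataset,
    methods: Sequence[str] = ("tworound", "wdsvr", "pwm"),
    pipeline_config=None,
    external: dict[str, np.ndarray] | None = None,
) -> dict[str, evalmetrics.MetricsReport]:
    """Four-metric comparison of the requested methods on one train/test
    split. ``external`` maps a method name to externally produced test-set
    predictions (e.g. loaded from a TSV), scored identically."""
    from . import tworound

    out: dict[str, evalmetrics.MetricsReport] = {}
    truth = test.affinities
    for method in methods:
        if method == "tworound":
            cfg = pipeline_config or tworound.PipelineConfig.preset_gcn4_hitsflip()
            res = tworound.fit(train, cfg)
            pred = tworound.predict(res, test.sequences)
        elif method == "wdsvr":
            pred = wdsvr_baseline(train, test.sequences)
        elif method == "pwm":
            pred = pwm_predict(pwm_fit(train), test.sequences)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[method] = evalmetrics.report(pred, truth)
    for name, pred in (external or {}).items():
        out[name] = evalmetrics.report(np.asarray(pred, dtype=float), truth)
    return out
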