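"""The two-round workflow: kernel SVR as feature selector, then as predictor.

Round 1 trains an SVR on the full shift/mismatch WD kernel, expands the
learned function into positional k-mer weights, and selects — per degree k —
the anchors with the strongest expected effect on the target in each
direction. Round 2 retrains on the kernel restricted to those anchors
(shifts allowed, mismatches off) and is the final predictor.

Hyperparameters (d, s, m for Round 1; d, s for Round 2) are chosen by
grid search over cross-validated Pearson correlation on the training data
only. Within every CV fold the Round-1 fit and the anchor selection are
recomputed from that fold's training portion, so no test-fold record ever
influences kernel construction, selection, or hyperparameter choice; each
fold's report carries fingerprints of the exact sequence sets used so the
discipline is checkable after the fact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqdata import AffinityDataset, kfold_split
from .wdkernel import KernelConfig, kernel_matrix, cross_kernel_matrix
from . import svr_engine
from .svr_engine import SVRModel
from .importance import KmerSelection, all_importances, select_kmers
from . import evalmetrics

logger = logging.getLogger(__name__)


def _default_round1_grid() -> tuple[tuple[int, int, int], ...]:
    return tuple(
        (d, s, m) for d in range(2, 10) for s in range(0, 8) for m in range(0, min(d, 3) + 1)
    )


def _default_round2_grid() -> tuple[tuple[int, int], ...]:
    return tuple((d, s) for d in range(2, 10) for s in range(0, 8))


@dataclass
class PipelineConfig:
    """Grids, selection size, SVR constants, CV layout, and seed.

    ``C``/``epsilon`` may be "auto": C = 1.0 (kernels are cosine-normalized
    by default, making C scale-free) and epsilon = 0.1 * std(y). Round 2
    never uses mismatches.
    """

    round1_grid: tuple[tuple[int, int, int], ...] = field(default_factory=_default_round1_grid)
    round2_grid: tuple[tuple[int, int], ...] = field(default_factory=_default_round2_grid)
    n_per_side: int = 10
    C: float | str = "auto"
    epsilon: float | str = "auto"
    cv_folds: int = 10
    seed: int = 0
    normalize: bool = True
    normalize_round2: bool = False
    selection_metric: str = "pearson"

    @classmethod
    def preset_gcn4_hitsflip(cls, **kw) -> "PipelineConfig":
        """The hyperparameters reported best for the Gcn4p 12-mer data:
        Round 1 (d=7, s=1, m=1), Round 2 (d=7, s=0). Singleton grids, so
        grid search is a no-op and only the two fits run."""
        return cls(round1_grid=((7, 1, 1),), round2_grid=((7, 0),), **kw)

    def to_dict(self) -> dict:
        return {
            "round1_grid": [list(g) for g in self.round1_grid],
            "round2_grid": [list(g) for g in self.round2_grid],
            "n_per_side": self.n_per_side,
            "C": self.C,
            "epsilon": self.epsilon,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "normalize": self.normalize,
            "normalize_round2": self.normalize_round2,
            "selection_metric": self.selection_metric,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "round1_grid" in d:
            d["round1_grid"] = tuple(tuple(g) for g in d["round1_grid"])
        if "round2_grid" in d:
            d["round2_grid"] = tuple(tuple(g) for g in d["round2_grid"])
        return cls(**d)


def resolve_svr_params(y: np.ndarray, C, epsilon) -> tuple[float, float]:
    C = 1.0 if C == "auto" or C is None else float(C)
    epsilon = 0.1 * float(np.std(y)) if epsilon == "auto" or epsilon is None else float(epsilon)
    return C, epsilon


def _fingerprint(seqs: Sequence[str]) -> str:
    h = hashlib.sha256("\n".join(sorted(seqs)).encode())
    return h.hexdigest()[:16]


def _train_svr(train: AffinityDataset, cfg: KernelConfig, C: float, epsilon: float) -> SVRModel:
    K = kernel_matrix(train.sequences, cfg)
    model = svr_engine.fit(K, y=train.affinities, C=C, epsilon=epsilon)
    model.kernel_config = cfg
    model.training_sequences = list(train.sequences)
    return model


def fit_round1(
    train: AffinityDataset,
    d: int,
    s: int,
    m: int,
    C: float | str = "auto",
    epsilon: float | str = "auto",
    normalize: bool = True,
    n_per_side: int = 10,
) -> tuple[SVRModel, KmerSelection]:
    """Full-kernel SVR fit plus positional-importance anchor selection."""
    if len(train) == 0:
        raise ValueError("empty training dataset")
    C, epsilon = resolve_svr_params(train.affinities, C, epsilon)
    cfg = KernelConfig(d=d, s=s, m=m, normalize=normalize)
    model = _train_svr(train, cfg, C, epsilon)
    selection = select_kmers(all_importances(model), n_per_side=n_per_side)
    return model, selection


def fit_round2(
    train: AffinityDataset,
    selection: KmerSelection,
    d: int,
    s: int,
    C: float | str = "auto",
    epsilon: float | str = "auto",
    normalize: bool = False,
) -> SVRModel:
    """SVR on the kernel restricted to the selected anchors (m = 0).

    The restricted kernel is kept raw by default: it is an inner product over
    a small sparse anchor-indicator feature space, where cosine normalization
    both distorts (a sequence carrying one incidental anchor is inflated to
    unit self-similarity) and degenerates (a sequence carrying none has zero
    self-similarity). The dense Round-1 kernel has neither problem.
    """
    anchors = selection.anchors(max_k=d)
    if not anchors:
        raise ValueError("empty anchor selection")
    y = train.affinities
    C, epsilon = resolve_svr_params(y, C, epsilon)
    cfg = KernelConfig(d=d, s=s, m=0, normalize=normalize, restriction=anchors)
    K = kernel_matrix(train.sequences, cfg)
    model = svr_engine.fit(K, y, C=C, epsilon=epsilon)
    model.kernel_config = cfg
    model.training_sequences = list(train.sequences)
    return model


def predict_model(model: SVRModel, seqs: Sequence[str]) -> np.ndarray:
    """Predictions from a fitted model for new sequences (builds the
    cross-kernel with the model's own config, including any restriction)."""
    if model.training_sequences is None or model.kernel_config is None:
        raise ValueError("model lacks kernel_config/training_sequences")
    L = len(model.training_sequences[0])
    for q in seqs:
        if len(q) != L:
            raise ValueError(f"sequence length {len(q)} != training length {L}")
    Kc = cross_kernel_matrix(list(seqs), model.training_sequences, model.kernel_config)
    return svr_engine.predict(model, Kc)


def grid_search(
    train: AffinityDataset,
    cfg: PipelineConfig,
    stage: str,
    round1_params: tuple[int, int, int] | None = None,
) -> tuple:
    """Best grid point by mean CV Pearson on the training data.

    stage='round1' searches (d, s, m); stage='round2' searches (d, s) with
    the Round-1 fit and selection recomputed once per fold at
    ``round1_params``. The same seeded fold partition is used for every grid
    point, so comparisons are paired. Ties break toward the smaller tuple.
    """
    folds = kfold_split(len(train), min(cfg.cv_folds, len(train)), cfg.seed)
    y = train.affinities
    C, epsilon = resolve_svr_params(y, cfg.C, cfg.epsilon)

    if stage == "round1":
        grid = list(cfg.round1_grid)
        if not grid:
            raise ValueError("empty round1 grid")
        if len(grid) == 1:
            return grid[0]
        scores = {}
        for (d, s, m) in grid:
            rs = []
            for tr, te in folds:
                sub, hold = train.subset(tr), train.subset(te)
                # selection is not needed to score a Round-1 grid point
                model = _train_svr(
                    sub, KernelConfig(d=d, s=s, m=m, normalize=cfg.normalize), C, epsilon
                )
                pred = predict_model(model, hold.sequences)
                rs.append(evalmetrics.pearson(pred, hold.affinities))
            scores[(d, s, m)] = float(np.mean(rs))
            logger.info("grid round1 (d=%d,s=%d,m=%d): CV pearson %.4f", d, s, m, scores[(d, s, m)])
        best = max(sorted(scores), key=lambda t: (scores[t], tuple(-v for v in t)))
        return best

    if stage == "round2":
        if round1_params is None:
            raise ValueError("round2 grid search needs round1_params")
        grid = list(cfg.round2_grid)
        if not grid:
            raise ValueError("empty round2 grid")
        if len(grid) == 1:
            return grid[0]
        d1, s1, m1 = round1_params
        # one Round-1 fit + selection per fold, shared across the grid
        fold_sel = []
        for tr, te in folds:
            sub = train.subset(tr)
            _model, sel = fit_round1(sub, d1, s1, m1, C, epsilon, cfg.normalize,
                                     cfg.n_per_side)
            fold_sel.append(sel)
        scores = {}
        for (d, s) in grid:
            rs = []
            for (tr, te), sel in zip(folds, fold_sel):
                sub, hold = train.subset(tr), train.subset(te)
                m2 = fit_round2(sub, sel, d, s, C, epsilon, cfg.normalize_round2)
                pred = predict_model(m2, hold.sequences)
                rs.append(evalmetrics.pearson(pred, hold.affinities))
            scores[(d, s)] = float(np.mean(rs))
            logger.info("grid round2 (d=%d,s=%d): CV pearson %.4f", d, s, scores[(d, s)])
        best = max(sorted(scores), key=lambda t: (scores[t], tuple(-v for v in t)))
        return best

    raise ValueError(f"unknown stage {stage!r}")


@dataclass
class FitResult:
    round1_model: SVRModel
    selection: KmerSelection
    round2_model: SVRModel
    chosen_configs: dict
    cv_report: dict

    def to_dict(self) -> dict:
        return {
            "round1_model": self.round1_model.to_dict(),
            "selection": {str(k): v for k, v in self.selection.per_k.items()},
            "round2_model": self.round2_model.to_dict(),
            "chosen_configs": self.chosen_configs,
            "cv_report": self.cv_report,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        sel = KmerSelection()
        for k, sides in d["selection"].items():
            sel.per_k[int(k)] = {
                side: [tuple(e) for e in entries] for side, entries in sides.items()
            }
        return cls(
            round1_model=SVRModel.from_dict(d["round1_model"]),
            selection=sel,
            round2_model=SVRModel.from_dict(d["round2_model"]),
            chosen_configs=d["chosen_configs"],
            cv_report=d["cv_report"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _cv_report(train: AffinityDataset, cfg: PipelineConfig,
               r1: tuple[int, int, int], r2: tuple[int, int]) -> dict:
    """Per-fold four-metric report for both rounds at the chosen settings,
    with fingerprints of the exact train/test sequence sets of each fold."""
    folds = kfold_split(len(train), min(cfg.cv_folds, len(train)), cfg.seed)
    y = train.affinities
    C, epsilon = resolve_svr_params(y, cfg.C, cfg.epsilon)
    d1, s1, m1 = r1
    d2, s2 = r2
    per_fold = []
    for fold_idx, (tr, te) in enumerate(folds):
        sub, hold = train.subset(tr), train.subset(te)
        m1_model, sel = fit_round1(sub, d1, s1, m1, C, epsilon, cfg.normalize, cfg.n_per_side)
        m2_model = fit_round2(sub, sel, d2, s2, C, epsilon, cfg.normalize_round2)
        entry = {
            "fold": fold_idx,
            "train_fingerprint": _fingerprint(sub.sequences),
            "test_fingerprint": _fingerprint(hold.sequences),
            "selection_input_fingerprint": _fingerprint(m1_model.training_sequences),
            "n_train": len(sub),
            "n_test": len(hold),
        }
        for name, model in (("round1", m1_model), ("round2", m2_model)):
            pred = predict_model(model, hold.sequences)
            entry[name] = evalmetrics.report(pred, hold.affinities).to_dict()
        per_fold.append(entry)
    means = {}
    for name in ("round1", "round2"):
        means[name] = {
            m: float(np.mean([f[name][m] for f in per_fold]))
            for m in ("rmse", "rmsre", "pearson", "spearman")
        }
    return {"folds": per_fold, "mean": means}


def fit(train: AffinityDataset, cfg: PipelineConfig | None = None) -> FitResult:
    """End-to-end: grid-search Round 1, fit + select, grid-search Round 2,
    fit the restricted model, and cross-validate both rounds."""
    if cfg is None:
        cfg = PipelineConfig()
    if len(train) == 0:
        raise ValueError("empty training dataset")
    t0 = time.time()
    r1 = grid_search(train, cfg, "round1")
    logger.info("round 1 config (d,s,m) = %s [%.1fs]", r1, time.time() - t0)
    model1, selection = fit_round1(
        train, *r1, cfg.C, cfg.epsilon, cfg.normalize, cfg.n_per_side
    )
    r2 = grid_search(train, cfg, "round2", round1_params=r1)
    logger.info("round 2 config (d,s) = %s [%.1fs]", r2, time.time() - t0)
    model2 = fit_round2(train, selection, *r2, cfg.C, cfg.epsilon, cfg.normalize_round2)
    report = _cv_report(train, cfg, r1, r2)
    logger.info(
        "CV mean pearson: round1 %.4f, round2 %.4f [%.1fs]",
        report["mean"]["round1"]["pearson"], report["mean"]["round2"]["pearson"],
        time.time() - t0,
    )
    return FitResult(
        round1_model=model1,
        selection=selection,
        round2_model=model2,
        chosen_configs={"round1": list(r1), "round2": list(r2)},
        cv_report=report,
    )


def predict(fit_result: FitResult, seqs: Sequence[str]) -> np.ndarray:
    """Final predictions: the Round-2 restricted kernel model."""
    return predict_model(fit_result.round2_model, seqs)
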