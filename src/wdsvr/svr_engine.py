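"""ε-insensitive support vector regression on precomputed string kernels.

The quadratic program itself is solved by scikit-learn's libsvm backend
(``SVR(kernel="precomputed")``); this module owns the surrounding contract:
validation of the kernel matrix, bookkeeping of the dual solution against the
training sequences, prediction from cross-kernel blocks, JSON round-tripping,
and — the piece the importance analysis depends on — expansion of the learned
function into explicit per-(k-mer, position) linear weights.

For every kernel in this package the learned function

    f(x) = sum_j c_j K(x_j, x) + b

is exactly linear in the positional k-mer indicator features of x, because
each kernel term against a fixed support vector x_j is a finite sum of
indicators I[x carries k-mer sigma at position i] (a mismatch term sums the
indicators over the exact-Hamming-distance neighborhood of the support
vector's window). ``linear_weights`` materializes that expansion; it is exact
for raw (unnormalized) kernels at any shift/mismatch setting. Cosine-
normalized kernels make f nonlinear through the test-side normalizer
1/sqrt(K(x,x)); with ``approximate=True`` that factor is replaced by its
training-set mean, which is the only approximation made.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVR as _SkSVR

from .wdkernel import (
    KernelConfig,
    encode,
    omega,
    self_kernel_diag,
    window_codes,
)

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass
class SVRModel:
    """Fitted ε-SVR over a precomputed kernel.

    ``dual_coef`` holds one coefficient (alpha_i - alpha_i*) per training
    point (zero for non-support vectors); prediction against a cross-kernel
    block K_cross (rows = new points, columns = training points) is
    K_cross @ dual_coef + intercept.
    """

    dual_coef: np.ndarray
    intercept: float
    C: float
    epsilon: float
    kernel_config: KernelConfig | None = None
    training_sequences: list[str] | None = None

    @property
    def fitted_values(self) -> np.ndarray | None:
        return getattr(self, "_fitted", None)

    def to_dict(self) -> dict:
        return {
            "dual_coef": [float(v) for v in self.dual_coef],
            "intercept": float(self.intercept),
            "C": self.C,
            "epsilon": self.epsilon,
            "kernel_config": None if self.kernel_config is None else self.kernel_config.to_dict(),
            "training_sequences": self.training_sequences,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        kc = d.get("kernel_config")
        return cls(
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            epsilon=float(d["epsilon"]),
            kernel_config=None if kc is None else KernelConfig.from_dict(kc),
            training_sequences=d.get("training_sequences"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SVRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit(
    K: np.ndarray,
    y: Sequence[float],
    C: float = 1.0,
    epsilon: float = 0.1,
    tol: float = 1e-6,
) -> SVRModel:
    """Solve the ε-SVR dual on a precomputed n×n kernel matrix."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"kernel matrix must be square, got {K.shape}")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel matrix must be symmetric")
    if y.shape != (K.shape[0],):
        raise ValueError(f"y has length {y.size}, kernel is {K.shape[0]}x{K.shape[0]}")
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    svr = _SkSVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol, max_iter=-1)
    try:
        svr.fit(K, y)
    except Exception as e:  # pragma: no cover - solver failure path
        raise TrainingError(f"SVR solver failed: {e}") from e
    coef = np.zeros(K.shape[0])
    coef[svr.support_] = svr.dual_coef_[0]
    model = SVRModel(
        dual_coef=coef,
        intercept=float(svr.intercept_[0]),
        C=float(C),
        epsilon=float(epsilon),
    )
    model._fitted = K @ coef + model.intercept
    return model


def predict(model: SVRModel, K_cross: np.ndarray) -> np.ndarray:
    """Apply the dual expansion to a (n_test × n_train) cross-kernel block."""
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != model.dual_coef.size:
        raise ValueError(
            f"cross-kernel has {K_cross.shape[1]} columns, model has "
            f"{model.dual_coef.size} training points"
        )
    return K_cross @ model.dual_coef + model.intercept


class LinearWeights:
    """Explicit feature-space weights w(k, sigma, i) of a fitted model.

    Stored densely per degree: ``arrays[k]`` has shape (4^k, L-k+1), rows in
    lexicographic k-mer order, columns 0-based start positions. Satisfies
    f(x) = sum_{k,i} arrays[k][code(x_k(i)), i] + intercept for raw kernels.
    """

    def __init__(self, arrays: dict[int, np.ndarray], intercept: float, L: int,
                 kernel_config: KernelConfig):
        self.arrays = arrays
        self.intercept = float(intercept)
        self.L = L
        self.kernel_config = kernel_config

    def weight(self, k: int, kmer: str, position: int) -> float:
        """Weight of ``kmer`` anchored at 1-based ``position``."""
        from .wdkernel import kmer_code

        return float(self.arrays[k][kmer_code(kmer), position - 1])

    def evaluate(self, seqs: Sequence[str]) -> np.ndarray:
        """f(x) via the feature expansion (independent of kernel evaluation)."""
        codes = encode(seqs)
        out = np.full(len(seqs), self.intercept)
        for k, W in self.arrays.items():
            wc = window_codes(codes, k)  # (n, P)
            P = wc.shape[1]
            out += W[wc, np.arange(P)[None, :]].sum(axis=1)
        return out


def _exact_hamming_variants(codes: np.ndarray, k: int, m: int):
    """Yield every code array at Hamming distance exactly m from ``codes``
    (windows of length k, base-4 integer encoding)."""
    if m == 0:
        yield codes
        return
    # digit t counts from the right: value 4^t
    for positions in combinations(range(k), m):
        for deltas in product((1, 2, 3), repeat=m):
            v = codes.copy()
            for t, delta in zip(positions, deltas):
                p4 = 4**t
                old = (codes // p4) % 4
                v = v + (((old + delta) % 4) - old) * p4
            yield v


def linear_weights(model: SVRModel, approximate: bool = False) -> LinearWeights:
    """Expand a fitted model into per-(k, k-mer, position) weights.

    Exact for raw kernels (any shift/mismatch setting, restricted or not).
    A cosine-normalized model is refused unless ``approximate`` is set, in
    which case the per-test-point normalizer is replaced by its training mean.
    """
    cfg = model.kernel_config
    if cfg is None or model.training_sequences is None:
        raise ValueError("model lacks kernel_config/training_sequences")
    if cfg.normalize and not approximate:
        raise ValueError(
            "linear weights of a normalized model are approximate; "
            "pass approximate=True to accept the training-mean normalizer"
        )
    seqs = model.training_sequences
    L = len(seqs[0])
    gamma = cfg.gamma_array(L)
    beta = cfg.beta()
    coef = model.dual_coef.copy()
    intercept = model.intercept
    if cfg.normalize:
        raw_cfg = _raw(cfg)
        diag = self_kernel_diag(seqs, raw_cfg)
        coef = coef / np.sqrt(diag)
        zbar = float(np.mean(np.sqrt(diag)))
        coef = coef / zbar
        logger.info(
            "linear_weights: normalized kernel, using training-mean test "
            "normalizer %.6g (approximation)", zbar,
        )
        cfg = raw_cfg
    codes = encode(seqs)

    arrays: dict[int, np.ndarray] = {}
    for k in range(1, cfg.d + 1):
        P = L - k + 1
        W = np.zeros((4**k, P))
        wc = window_codes(codes, k)  # (n, P)
        if cfg.restriction is not None:
            from .wdkernel import kmer_code

            for anc in sorted(set(cfg.restriction)):
                if anc.k != k:
                    continue
                i = anc.position - 1
                code = kmer_code(anc.kmer)
                for sp in range(0, cfg.s + 1):
                    if i + sp > P - 1:
                        break
                    w = beta[k - 1] * gamma[i] * omega(sp)
                    pres_shift = (wc[:, i + sp] == code).astype(float)
                    pres_home = (wc[:, i] == code).astype(float)
                    W[code, i] += w * float(coef @ pres_shift)
                    W[code, i + sp] += w * float(coef @ pres_home)
        else:
            for sp in range(0, cfg.s + 1):
                npos = P - sp
                if npos <= 0:
                    continue
                # direction 1: SV window at i+sp constrains x at i;
                # direction 2: SV window at i constrains x at i+sp.
                # At sp = 0 the two coincide and are both counted (mu term).
                for sv_cols, x_pos in (
                    (wc[:, sp:], np.arange(npos)),
                    (wc[:, :npos], np.arange(sp, sp + npos)),
                ):
                    base_w = gamma[:npos] * omega(sp)  # gamma indexed by unshifted i
                    for mp in range(0, min(cfg.m, k) + 1):
                        bkm = beta[k - 1] * cfg.mismatch_decay**mp
                        wmat = (coef[:, None] * base_w[None, :]) * bkm
                        pos_idx = np.broadcast_to(x_pos, sv_cols.shape)
                        for variant in _exact_hamming_variants(sv_cols, k, mp):
                            np.add.at(W, (variant.ravel(), pos_idx.ravel()), wmat.ravel())
        arrays[k] = W
    return LinearWeights(arrays, intercept, L, cfg)


def _raw(cfg: KernelConfig) -> KernelConfig:
    from dataclasses import replace

    return replace(cfg, normalize=False)
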