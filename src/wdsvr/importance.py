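"""Positional k-mer importance of a trained model and anchor selection.

The importance of carrying k-mer sigma at start position i is the expected
change of the learned function under a uniform i.i.d. background over
{A,C,G,T}^L:

    Q(sigma, i) = E[f(x) | x_k(i) = sigma] - E[f(x)].

Because f expands exactly into positional k-mer indicator weights
(``svr_engine.linear_weights``), both expectations are computed in closed
form: a feature (k', tau, j) whose window overlaps the conditioned window
contributes w * (I[tau agrees with sigma on the overlap] * 4^-(k'-ov)
- 4^-k'), where ov is the overlap length; non-overlapping features cancel.
Q therefore recenters to zero under the background at every position.

A low (negative) Q means the k-mer is expected to *decrease* the regression
target; when the target is K_d, that is the high-affinity direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqdata import AffinityDataset
from .svr_engine import SVRModel, LinearWeights, linear_weights
from .wdkernel import SelectedAnchor, code_to_kmer

logger = logging.getLogger(__name__)

_DIGITS_CACHE: dict[int, np.ndarray] = {}


def _digits(k: int) -> np.ndarray:
    """(4^k, k) array of base-4 digits of every k-mer code, leftmost first."""
    if k not in _DIGITS_CACHE:
        codes = np.arange(4**k)
        D = np.empty((4**k, k), dtype=np.int64)
        for t in range(k):
            D[:, t] = (codes // 4 ** (k - 1 - t)) % 4
        _DIGITS_CACHE[k] = D
    return _DIGITS_CACHE[k]


@dataclass
class PositionalImportance:
    """Q matrix for one k: rows = lexicographic k-mers, columns = 1-based
    start positions 1..L-k+1."""

    k: int
    Q: np.ndarray
    L: int
    background: str = "uniform_iid"

    @property
    def n_positions(self) -> int:
        return self.Q.shape[1]

    def kmer_labels(self) -> list[str]:
        return [code_to_kmer(c, self.k) for c in range(4**self.k)]


def positional_importance_from_weights(lw: LinearWeights, k: int) -> PositionalImportance:
    """Exact Q from an explicit weight map under the uniform background."""
    L = lw.L
    if not (1 <= k <= max(lw.arrays)):
        raise ValueError(f"k={k} outside 1..{max(lw.arrays)}")
    P = L - k + 1
    Q = np.zeros((4**k, P))
    Dk = _digits(k)
    for kp, W in lw.arrays.items():
        Dkp = _digits(kp)
        Pp = L - kp + 1
        for j in range(Pp):
            col = W[:, j]
            if not col.any():
                continue
            for i in range(P):
                o = max(i, j)
                e = min(i + k, j + kp)  # exclusive end of overlap
                ov = e - o
                if ov <= 0:
                    continue
                pw = 4 ** np.arange(ov - 1, -1, -1)
                # group feature weights by their overlap substring
                proj_tau = Dkp[:, o - j : e - j] @ pw
                Wg = np.bincount(proj_tau, weights=col, minlength=4**ov)
                proj_sigma = Dk[:, o - i : e - i] @ pw
                Q[:, i] += 4.0 ** -(kp - ov) * Wg[proj_sigma] - 4.0**-kp * Wg.sum()
    return PositionalImportance(k=k, Q=Q, L=L)


def positional_importance(model: SVRModel, k: int) -> PositionalImportance:
    """Q for one k from a fitted model; normalized models use the
    training-mean normalizer approximation (logged by linear_weights)."""
    lw = linear_weights(model, approximate=bool(model.kernel_config.normalize))
    return positional_importance_from_weights(lw, k)


def all_importances(model: SVRModel) -> list[PositionalImportance]:
    """Q for every k = 1..d, sharing one weight expansion."""
    lw = linear_weights(model, approximate=bool(model.kernel_config.normalize))
    return [positional_importance_from_weights(lw, k) for k in range(1, model.kernel_config.d + 1)]


@dataclass
class KmerSelection:
    """Per k, the anchors steering the target down (``high_affinity``, most
    negative Q — for a K_d target these raise affinity) and up
    (``low_affinity``, most positive Q). Entries are (kmer, 1-based position,
    Q score)."""

    per_k: dict[int, dict[str, list[tuple[str, int, float]]]] = field(default_factory=dict)

    def anchors(self, max_k: int | None = None) -> frozenset[SelectedAnchor]:
        out = set()
        for k, sides in self.per_k.items():
            if max_k is not None and k > max_k:
                continue
            for side in ("high_affinity", "low_affinity"):
                for kmer, pos, _ in sides[side]:
                    out.add(SelectedAnchor(k, kmer, pos))
        return frozenset(out)

    def total(self) -> int:
        return sum(len(s["high_affinity"]) + len(s["low_affinity"]) for s in self.per_k.values())

    def high_affinity(self, k: int) -> list[tuple[str, int, float]]:
        return self.per_k[k]["high_affinity"]

    def low_affinity(self, k: int) -> list[tuple[str, int, float]]:
        return self.per_k[k]["low_affinity"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tkmer\tposition\tscore\tside\n")
            for k in sorted(self.per_k):
                for side in ("high_affinity", "low_affinity"):
                    for kmer, pos, score in self.per_k[k][side]:
                        fh.write(f"{k}\t{kmer}\t{pos}\t{score:.10g}\t{side}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerSelection":
        sel = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                k, kmer, pos, score, side = line.rstrip("\n").split("\t")
                k = int(k)
                sel.per_k.setdefault(k, {"high_affinity": [], "low_affinity": []})
                sel.per_k[k][side].append((kmer, int(pos), float(score)))
        return sel


def select_kmers(
    importances: Sequence[PositionalImportance], n_per_side: int = 10
) -> KmerSelection:
    """Pick, per k, the n_per_side anchors with the most negative Q
    (high-affinity side first) and the n_per_side most positive Q from the
    remainder. Ties break lexicographically by (kmer, position), which makes
    the selection deterministic and the two lists disjoint."""
    sel = KmerSelection()
    for imp in importances:
        k, Q = imp.k, imp.Q
        nk, P = Q.shape
        capacity = nk * P
        n_high = min(n_per_side, capacity)
        n_low = min(n_per_side, capacity - n_high)
        if 2 * n_per_side > capacity:
            logger.warning(
                "k=%d has only %d anchors; selecting all instead of 2x%d",
                k, capacity, n_per_side,
            )
        flat = [(float(Q[c, p]), code_to_kmer(c, k), p + 1) for c in range(nk) for p in range(P)]
        asc = sorted(flat, key=lambda t: (t[0], t[1], t[2]))
        high = asc[:n_high]
        low = sorted(asc[n_high:], key=lambda t: (-t[0], t[1], t[2]))[:n_low]
        sel.per_k[k] = {
            "high_affinity": [(kmer, pos, q) for q, kmer, pos in high],
            "low_affinity": [(kmer, pos, q) for q, kmer, pos in low],
        }
    return sel


def export_importance_matrix(
    imp: PositionalImportance, path: str | Path, heatmap: str | Path | None = None
) -> None:
    """Write the Q matrix as TSV (rows = k-mers, columns = 1-based positions);
    optionally render a diverging heatmap (blue = affinity-raising negative Q,
    red = affinity-lowering positive Q)."""
    labels = imp.kmer_labels()
    with open(path, "w") as fh:
        fh.write("kmer\t" + "\t".join(str(i + 1) for i in range(imp.n_positions)) + "\n")
        for lab, row in zip(labels, imp.Q):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    if heatmap is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vmax = max(np.abs(imp.Q).max(), 1e-12)
        fig, ax = plt.subplots(figsize=(max(4, imp.n_positions * 0.6), max(4, len(labels) * 0.12)))
        im = ax.imshow(imp.Q, aspect="auto", cmap="RdYlBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xlabel("start position")
        ax.set_ylabel(f"{imp.k}-mer (lexicographic)")
        ax.set_xticks(range(imp.n_positions), [str(i + 1) for i in range(imp.n_positions)])
        fig.colorbar(im, ax=ax, label="Q")
        fig.tight_layout()
        fig.savefig(heatmap, dpi=120)
        plt.close(fig)


def load_importance_matrix(path: str | Path) -> PositionalImportance:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_pos = len(header) - 1
        rows = []
        k = None
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            k = len(parts[0])
            rows.append([float(v) for v in parts[1:]])
    Q = np.array(rows)
    return PositionalImportance(k=k, Q=Q, L=n_pos + k - 1)


@dataclass
class KmerStats:
    """Affinity statistics of the sequences containing a k-mer anywhere."""

    kmer: str
    freq: int
    min: float
    max: float
    mean: float
    sd: float


def kmer_affinity_stats(ds: AffinityDataset, kmer: str) -> KmerStats:
    """freq = number of sequences containing ``kmer`` as a substring (each
    sequence counted once); min/max/mean over those sequences' affinities;
    sd is the sample standard deviation (n-1). A k-mer absent from every
    sequence reports NaN statistics, not zeros."""
    kmer = kmer.upper()
    if len(kmer) > ds.length:
        raise ValueError(f"k-mer longer than sequences ({len(kmer)} > {ds.length})")
    hits = [r.affinity for r in ds.records if kmer in r.sequence]
    if not hits:
        return KmerStats(kmer, 0, math.nan, math.nan, math.nan, math.nan)
    arr = np.asarray(hits)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return KmerStats(
        kmer, int(arr.size), float(arr.min()), float(arr.max()), float(arr.mean()), sd
    )
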