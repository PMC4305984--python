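"""Weighted-degree string kernels on fixed-length DNA.

Three kernels are provided, all comparing two sequences of one common
length L:

* the plain WD kernel — position-aligned exact k-mer matches up to degree d,
  weighted by per-length coefficients beta_k;
* the WD kernel with shifts and mismatches — matches may be displaced by up
  to s positions (shift weight omega_s = 1/(2(s+1)), both directions) and may
  carry exactly m' Hamming mismatches (weight beta_{k,m'} = beta_k *
  lambda^m'), summed over m' = 0..m;
* the restricted kernel — identical bookkeeping with m = 0, but a term at
  (k, i, shift) counts only when the matched k-mer string is one of a given
  set of position-anchored k-mers (the Round-2 kernel of the two-round
  method).

Each kernel has an optimized implementation (used by ``kernel_matrix``) and a
naive enumeration oracle (``naive_*``) that follows the defining sums
literally; the test suite holds the two equal to machine precision.

Conventions fixed here and relied on throughout the package:

* the mu term counts both displacement directions even at zero shift, so with
  omega_0 = 1/2 the shift kernel at s = 0, m = 0 reduces *exactly* to the
  plain WD kernel;
* "m' mismatches" means Hamming distance exactly m'; the sum over m' <= m
  supplies the at-most behavior;
* both compared windows must lie inside [1, L]; displaced windows that would
  overrun the sequence are skipped;
* anchor positions are 1-based in all user-facing structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


class SelectedAnchor(NamedTuple):
    """A k-mer anchored at a fixed (1-based) start position in the L-window."""

    k: int
    kmer: str
    position: int


@dataclass(frozen=True)
class KernelConfig:
    """All kernel hyperparameters.

    d : maximum k-mer length; s : maximum shift; m : maximum mismatches;
    beta_scheme : 'standard' (beta_k = 2(d-k+1)/(d(d+1)), summing to 1) or
    'uniform' (all 1); mismatch_decay : lambda in beta_{k,m} = beta_k *
    lambda^m; gamma : optional per-position weights (length L), default all 1;
    normalize : unit-diagonal (cosine) normalization of kernel matrices;
    restriction : optional frozenset of SelectedAnchor (Round-2 kernel).
    """

    d: int
    s: int = 0
    m: int = 0
    beta_scheme: str = "standard"
    mismatch_decay: float = 0.5
    gamma: tuple[float, ...] | None = None
    normalize: bool = False
    restriction: frozenset[SelectedAnchor] | None = None

    def __post_init__(self):
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.s < 0 or self.m < 0:
            raise ValueError("s and m must be >= 0")
        if self.m > self.d:
            raise ValueError(f"m={self.m} exceeds d={self.d}")
        if not (0 < self.mismatch_decay <= 1):
            raise ValueError("mismatch_decay must be in (0, 1]")
        if self.restriction is not None and self.m != 0:
            raise ValueError("restricted kernel allows shifts but not mismatches (m must be 0)")

    def gamma_array(self, L: int) -> np.ndarray:
        if self.gamma is None:
            return np.ones(L)
        g = np.asarray(self.gamma, dtype=float)
        if g.shape != (L,):
            raise ValueError(f"gamma has length {g.size}, sequences have length {L}")
        if (g < 0).any():
            raise ValueError("gamma weights must be nonnegative")
        return g

    def beta(self) -> np.ndarray:
        return beta_weights(self.d, self.beta_scheme)

    def beta_km(self, k: int, m: int) -> float:
        return float(self.beta()[k - 1] * self.mismatch_decay**m)

    def to_dict(self) -> dict:
        d = {
            "d": self.d, "s": self.s, "m": self.m,
            "beta_scheme": self.beta_scheme,
            "mismatch_decay": self.mismatch_decay,
            "gamma": None if self.gamma is None else list(self.gamma),
            "normalize": self.normalize,
            "restriction": None if self.restriction is None
            else sorted([a.k, a.kmer, a.position] for a in self.restriction),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelConfig":
        restriction = d.get("restriction")
        if restriction is not None:
            restriction = frozenset(SelectedAnchor(int(k), kmer, int(p)) for k, kmer, p in restriction)
        gamma = d.get("gamma")
        return cls(
            d=int(d["d"]), s=int(d["s"]), m=int(d["m"]),
            beta_scheme=d.get("beta_scheme", "standard"),
            mismatch_decay=float(d.get("mismatch_decay", 0.5)),
            gamma=None if gamma is None else tuple(gamma),
            normalize=bool(d.get("normalize", False)),
            restriction=restriction,
        )


def beta_weights(d: int, scheme: str = "standard") -> np.ndarray:
    """Per-length k-mer weights beta_1..beta_d.

    'standard' is the canonical WD weighting beta_k = 2(d-k+1)/(d(d+1)),
    which sums to 1; 'uniform' sets every beta_k = 1.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if scheme == "standard":
        k = np.arange(1, d + 1)
        return 2.0 * (d - k + 1) / (d * (d + 1))
    if scheme == "uniform":
        return np.ones(d)
    raise ValueError(f"unknown beta scheme {scheme!r}")


def omega(s: int) -> float:
    """Shift weight omega_s = 1/(2(s+1))."""
    return 1.0 / (2.0 * (s + 1))


def feature_space_size(d: int) -> int:
    """Number of positional k-mer species encoded up to degree d: sum 4^k."""
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    return sum(4**k for k in range(1, d + 1))


def encode(seqs: Sequence[str]) -> np.ndarray:
    """Encode DNA strings as a (n, L) uint8 matrix over {0,1,2,3}."""
    if isinstance(seqs, str):
        raise TypeError("pass a list of sequences, not a single string")
    n = len(seqs)
    L = len(seqs[0])
    out = np.empty((n, L), dtype=np.uint8)
    for r, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError(f"sequence lengths differ: {len(s)} vs {L}")
        try:
            out[r] = [_CODE[c] for c in s.upper()]
        except KeyError as e:
            raise ValueError(f"non-ACGT symbol {e.args[0]!r} in sequence {r}") from None
    return out


def kmer_code(kmer: str) -> int:
    """Lexicographic integer code of a k-mer (A=0 < C < G < T, base 4)."""
    c = 0
    for ch in kmer.upper():
        c = c * 4 + _CODE[ch]
    return c


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-windows: (n, L-k+1) from an (n, L) code matrix."""
    n, L = codes.shape
    out = np.zeros((n, L - k + 1), dtype=np.int64)
    for t in range(k):
        out = out * 4 + codes[:, t : t + L - k + 1]
    return out


# ---------------------------------------------------------------------------
# naive enumeration oracles (reference implementations for tests)
# ---------------------------------------------------------------------------

def naive_wd_kernel(a: str, b: str, cfg: KernelConfig) -> float:
    """Literal triple loop over (k, i): position-aligned exact matches."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    L = len(a)
    beta = cfg.beta()
    total = 0.0
    for k in range(1, cfg.d + 1):
        for i in range(L - k + 1):
            if a[i : i + k] == b[i : i + k]:
                total += beta[k - 1]
    return total


def _hamming(u: str, v: str) -> int:
    return sum(x != y for x, y in zip(u, v))


def naive_wds_kernel(a: str, b: str, cfg: KernelConfig) -> float:
    """Literal quadruple loop over (k, m', i, s') with the symmetrized mu term."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    L = len(a)
    a, b = a.upper(), b.upper()
    gamma = cfg.gamma_array(L)
    total = 0.0
    for k in range(1, cfg.d + 1):
        for mp in range(0, min(cfg.m, k) + 1):
            bkm = cfg.beta_km(k, mp)
            for i in range(L - k + 1):
                for sp in range(0, cfg.s + 1):
                    if i + sp > L - k:
                        continue
                    mu = 0
                    if _hamming(a[i + sp : i + sp + k], b[i : i + k]) == mp:
                        mu += 1
                    if _hamming(a[i : i + k], b[i + sp : i + sp + k]) == mp:
                        mu += 1
                    total += bkm * gamma[i] * omega(sp) * mu
    return total


def naive_restricted_kernel(
    a: str, b: str, cfg: KernelConfig, selection: Iterable[SelectedAnchor]
) -> float:
    """Shift-kernel sum in which a term at (k, i, s') counts only when the
    matched string is ``kmer`` of an anchor with that k and position i."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    L = len(a)
    a, b = a.upper(), b.upper()
    gamma = cfg.gamma_array(L)
    beta = cfg.beta()
    total = 0.0
    for anc in selection:
        k, sigma, i = anc.k, anc.kmer.upper(), anc.position - 1
        if k > cfg.d or i < 0 or i > L - k:
            continue
        for sp in range(0, cfg.s + 1):
            if i + sp > L - k:
                continue
            mu = 0
            if a[i + sp : i + sp + k] == sigma and b[i : i + k] == sigma:
                mu += 1
            if a[i : i + k] == sigma and b[i + sp : i + sp + k] == sigma:
                mu += 1
            total += beta[k - 1] * gamma[i] * omega(sp) * mu
    return total


# ---------------------------------------------------------------------------
# optimized kernels
# ---------------------------------------------------------------------------

def _wds_cross_raw(A: np.ndarray, B: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """Raw shift/mismatch kernel between code matrices A (na,L) and B (nb,L).

    For each displacement s', window mismatch counts are obtained from a
    cumulative sum of positionwise inequality, and each exact count m' <= m
    is weighted by beta_{k,m'} * gamma_i * omega_s'. The two mu directions are
    the (A shifted vs B) and (B shifted vs A) alignments; at s' = 0 they
    coincide and are counted twice.
    """
    na, L = A.shape
    nb = B.shape[0]
    gamma = cfg.gamma_array(L)
    beta = cfg.beta()
    K = np.zeros((na, nb))
    for sp in range(0, cfg.s + 1):
        if sp > L - 1:
            break
        w_s = omega(sp)
        # direction 1: A window at i+sp vs B window at i; direction 2 swaps roles
        neq1 = (A[:, None, sp:] != B[None, :, : L - sp]).astype(np.int32)
        cum1 = np.concatenate(
            [np.zeros((na, nb, 1), dtype=np.int32), np.cumsum(neq1, axis=2)], axis=2
        )
        if sp == 0:
            cum2 = cum1
        else:
            neq2 = (A[:, None, : L - sp] != B[None, :, sp:]).astype(np.int32)
            cum2 = np.concatenate(
                [np.zeros((na, nb, 1), dtype=np.int32), np.cumsum(neq2, axis=2)], axis=2
            )
        for k in range(1, cfg.d + 1):
            nwin = L - k + 1 - sp  # window starts i = 0..L-k-sp
            if nwin <= 0:
                continue
            g = gamma[:nwin]
            ham1 = cum1[:, :, k : k + nwin] - cum1[:, :, :nwin]
            ham2 = cum2[:, :, k : k + nwin] - cum2[:, :, :nwin]
            for mp in range(0, min(cfg.m, k) + 1):
                bkm = cfg.beta_km(k, mp)
                contrib = (ham1 == mp) @ g + (ham2 == mp) @ g
                K += bkm * w_s * contrib
    return K


def _restricted_cross_raw(
    A: np.ndarray, B: np.ndarray, cfg: KernelConfig, selection: Iterable[SelectedAnchor]
) -> np.ndarray:
    """Raw Round-2 kernel: sum of per-anchor rank-one contributions."""
    na, L = A.shape
    nb = B.shape[0]
    gamma = cfg.gamma_array(L)
    beta = cfg.beta()
    K = np.zeros((na, nb))
    anchors = sorted(set(selection))
    by_k: dict[int, list[SelectedAnchor]] = {}
    for anc in anchors:
        if anc.k <= cfg.d:
            by_k.setdefault(anc.k, []).append(anc)
    for k, group in by_k.items():
        WA = window_codes(A, k)
        WB = WA if B is A else window_codes(B, k)
        for anc in group:
            i = anc.position - 1
            if i < 0 or i > L - k:
                raise ValueError(f"anchor {anc} out of range for L={L}")
            code = kmer_code(anc.kmer)
            pa_i = (WA[:, i] == code).astype(float)
            pb_i = (WB[:, i] == code).astype(float)
            for sp in range(0, cfg.s + 1):
                if i + sp > L - k:
                    break
                w = beta[k - 1] * gamma[i] * omega(sp)
                if sp == 0:
                    K += (2 * w) * np.outer(pa_i, pb_i)
                else:
                    pa_s = (WA[:, i + sp] == code).astype(float)
                    pb_s = (WB[:, i + sp] == code).astype(float)
                    K += w * (np.outer(pa_s, pb_i) + np.outer(pa_i, pb_s))
    return K


def wd_kernel(a: str, b: str, cfg: KernelConfig) -> float:
    """Plain WD kernel value for one pair (requires cfg.s == 0, cfg.m == 0)."""
    if cfg.s != 0 or cfg.m != 0:
        raise ValueError("wd_kernel requires s = 0 and m = 0; use wds_kernel")
    A = encode([a])
    B = encode([b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("sequences must have equal length")
    return float(_wds_cross_raw(A, B, cfg)[0, 0])


def wds_kernel(a: str, b: str, cfg: KernelConfig) -> float:
    """Shift/mismatch WD kernel value for one pair (raw, unnormalized)."""
    A = encode([a])
    B = encode([b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("sequences must have equal length")
    return float(_wds_cross_raw(A, B, cfg)[0, 0])


def restricted_kernel(
    a: str, b: str, cfg: KernelConfig, selection: Iterable[SelectedAnchor]
) -> float:
    """Round-2 kernel value for one pair; empty selection gives 0."""
    if cfg.m != 0:
        raise ValueError("restricted kernel requires m = 0")
    A = encode([a])
    B = encode([b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("sequences must have equal length")
    return float(_restricted_cross_raw(A, B, cfg, selection)[0, 0])


def _raw_matrix(A: np.ndarray, B: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    if cfg.restriction is not None:
        return _restricted_cross_raw(A, B, cfg, cfg.restriction)
    return _wds_cross_raw(A, B, cfg)


def kernel_matrix(seqs: Sequence[str], cfg: KernelConfig) -> np.ndarray:
    """Symmetric kernel matrix over a sequence list; cosine-normalized to a
    unit diagonal when cfg.normalize is set."""
    A = encode(seqs)
    K = _raw_matrix(A, A, cfg)
    K = (K + K.T) / 2.0  # exact symmetrization of accumulated float error
    if cfg.normalize:
        diag = np.diag(K).copy()
        if (diag <= 0).any():
            raise ValueError("degenerate kernel: zero self-similarity under normalization")
        K = K / np.sqrt(np.outer(diag, diag))
    return K


def cross_kernel_matrix(
    test_seqs: Sequence[str], train_seqs: Sequence[str], cfg: KernelConfig
) -> np.ndarray:
    """Kernel between test rows and train columns, with the same cosine
    normalization as ``kernel_matrix`` when cfg.normalize is set."""
    A = encode(test_seqs)
    B = encode(train_seqs)
    if A.shape[1] != B.shape[1]:
        raise ValueError("test/train sequence lengths differ")
    K = _raw_matrix(A, B, cfg)
    if cfg.normalize:
        da = np.einsum("ii->i", _raw_matrix(A, A, cfg)).copy()
        db = np.einsum("ii->i", _raw_matrix(B, B, cfg)).copy()
        if (da <= 0).any() or (db <= 0).any():
            raise ValueError("degenerate kernel: zero self-similarity under normalization")
        K = K / np.sqrt(np.outer(da, db))
    return K


def self_kernel_diag(seqs: Sequence[str], cfg: KernelConfig) -> np.ndarray:
    """K(x, x) for each sequence (raw, ignoring cfg.normalize)."""
    A = encode(seqs)
    n, L = A.shape
    out = np.empty(n)
    for i in range(n):
        out[i] = _raw_matrix(A[i : i + 1], A[i : i + 1], cfg)[0, 0]
    return out


# ---------------------------------------------------------------------------
# kernel matrix serialization: dense TSV with one JSON header line
# ---------------------------------------------------------------------------

def save_kernel_tsv(K: np.ndarray, cfg: KernelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(cfg.to_dict()) + "\n")
        for row in np.asarray(K):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def load_kernel_tsv(path: str | Path) -> tuple[np.ndarray, KernelConfig]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing JSON config header line")
        cfg = KernelConfig.from_dict(json.loads(header[1:]))
        K = np.array(
            [[float(v) for v in line.split("\t")] for line in fh if line.strip()]
        )
    return K, cfg
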