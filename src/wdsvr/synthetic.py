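"""Synthetic affinity landscapes with known ground truth.

Sequences are uniform random DNA; the log-affinity is an additive model

    ln K_d = baseline + mono effects + planted k-mer effects + N(0, noise_sd)

and K_d = exp(.) clipped to a configured range. Effects act on the ln scale,
consistent with treating ln K_d as (proportional to) binding free energy, so
a landscape built from mononucleotide effects alone is *exactly* additive —
the regime where a PWM is the correct model — while planted k-mer anchors
(k >= 2) inject the context-dependent structure that only the kernel methods
can capture.

Each planted anchor carries an ``implant_frac``: that fraction of sequences
has the k-mer written in at the anchor's position before affinities are
computed. Uniform random 12-mers would contain a given positioned 7-mer with
probability 4^-7, so without enrichment no carriers would exist at realistic
n; real high-affinity datasets are strongly motif-enriched (a filtered
optimal-site set carries its consensus k-mer in the majority of sequences),
and the implant step reproduces that shape. Whether an anchor *fires* for a
sequence is decided from the final sequence content, never from carrier
bookkeeping, so chance occurrences count too.

The presets emulate the statistical shape of two published assay types:
``hitsflip_like`` — 12-mers with K_d in [8, 1000] nM, one strong positioned
7-mer motif plus a weaker anywhere 10-mer interaction; ``mitomi_like`` —
52-mers on a relative-affinity scale in (0, 1].
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .seqdata import AffinityDataset, AffinityRecord, KD_NM, RELATIVE
from .wdkernel import _BASES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedAnchor:
    """A k-mer effect on ln-affinity: positioned (1-based start) or
    position-free (``position=None`` fires on occurrence anywhere)."""

    kmer: str
    position: int | None
    effect: float
    implant_frac: float = 0.0


@dataclass
class LandscapeSpec:
    n: int
    L: int
    planted_anchors: tuple[PlantedAnchor, ...] = ()
    mono_weights: np.ndarray | None = None  # (L, 4) ln-scale effects
    baseline: float = 0.0
    noise_sd: float = 0.0
    affinity_range: tuple[float, float] = (1e-6, 1e6)
    seed: int = 0
    scale: str = KD_NM

    def __post_init__(self):
        lo, hi = self.affinity_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid affinity range {self.affinity_range}")
        for a in self.planted_anchors:
            if len(a.kmer) > self.L:
                raise ValueError(f"anchor {a.kmer} longer than L={self.L}")
            if a.position is not None and not (1 <= a.position <= self.L - len(a.kmer) + 1):
                raise ValueError(f"anchor {a.kmer} position {a.position} out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_anchors"] = [asdict(a) for a in self.planted_anchors]
        if self.mono_weights is not None:
            d["mono_weights"] = np.asarray(self.mono_weights).tolist()
        return d


def generate_landscape(spec: LandscapeSpec) -> tuple[AffinityDataset, np.ndarray]:
    """Generate a dataset plus the noiseless ln-affinity of each sequence.

    Deterministic given ``spec.seed``. Clipping events are counted and
    logged.
    """
    rng = np.random.default_rng(spec.seed)
    codes = rng.integers(0, 4, size=(spec.n, spec.L))
    # implant anchors into their carrier fractions
    for a in spec.planted_anchors:
        if a.implant_frac <= 0:
            continue
        carriers = rng.random(spec.n) < a.implant_frac
        kcodes = [_BASES.index(c) for c in a.kmer.upper()]
        kk = len(kcodes)
        if a.position is not None:
            starts = np.full(spec.n, a.position - 1)
        else:
            starts = rng.integers(0, spec.L - kk + 1, size=spec.n)
        for i in np.flatnonzero(carriers):
            codes[i, starts[i] : starts[i] + kk] = kcodes

    seqs = ["".join(_BASES[c] for c in row) for row in codes]

    ln_truth = np.full(spec.n, float(spec.baseline))
    if spec.mono_weights is not None:
        W = np.asarray(spec.mono_weights, dtype=float)
        if W.shape != (spec.L, 4):
            raise ValueError(f"mono_weights must be (L, 4), got {W.shape}")
        ln_truth += W[np.arange(spec.L)[None, :], codes].sum(axis=1)
    for a in spec.planted_anchors:
        kmer = a.kmer.upper()
        if a.position is not None:
            fired = np.array(
                [s[a.position - 1 : a.position - 1 + len(kmer)] == kmer for s in seqs]
            )
        else:
            fired = np.array([kmer in s for s in seqs])
        ln_truth += a.effect * fired

    ln_kd = ln_truth + rng.normal(0.0, spec.noise_sd, size=spec.n)
    kd = np.exp(ln_kd)
    lo, hi = spec.affinity_range
    n_clip = int(((kd < lo) | (kd > hi)).sum())
    if n_clip:
        logger.info("generate_landscape: clipped %d/%d affinities to [%g, %g]",
                    n_clip, spec.n, lo, hi)
    kd = np.clip(kd, lo, hi)
    ds = AffinityDataset.from_arrays(seqs, kd, scale=spec.scale)
    return ds, ln_truth


def noise_ceiling(ln_truth: np.ndarray, noise_sd: float) -> float:
    """Best attainable Pearson correlation on the ln scale:
    sqrt(Var(signal) / (Var(signal) + noise_sd^2))."""
    v = float(np.var(ln_truth))
    return math.sqrt(v / (v + noise_sd**2)) if v > 0 else 0.0


#: consensus motif of the strong preset anchor (Gcn4p-like bZIP site)
HITSFLIP_MOTIF = "TGACTCA"
HITSFLIP_MOTIF_POSITION = 3
HITSFLIP_10MER = "TATGACTCAT"


def hitsflip_spec(seed: int, n: int = 400, noise_sd: float = 0.25) -> LandscapeSpec:
    """Optimal-recognition-site-shaped 12-mer landscape: K_d in [8, 1000] nM
    around a central 150 nM, one strong positioned 7-mer (effect 4x the noise
    sd on the ln scale) and a weaker anywhere 10-mer interaction."""
    return LandscapeSpec(
        n=n,
        L=12,
        planted_anchors=(
            PlantedAnchor(HITSFLIP_MOTIF, HITSFLIP_MOTIF_POSITION, -4.0 * noise_sd, 0.55),
            PlantedAnchor(HITSFLIP_10MER, None, -2.0 * noise_sd, 0.10),
        ),
        baseline=math.log(150.0),
        noise_sd=noise_sd,
        affinity_range=(8.0, 1000.0),
        seed=seed,
        scale=KD_NM,
    )


def hitsflip_like(seed: int, n: int = 400, noise_sd: float = 0.25) -> tuple[AffinityDataset, np.ndarray]:
    return generate_landscape(hitsflip_spec(seed, n=n, noise_sd=noise_sd))


def mitomi_spec(seed: int, n: int = 300) -> LandscapeSpec:
    """52-bp relative-affinity landscape in (0, 1] with one anywhere 6-mer
    (E-box-like) raising the relative affinity."""
    return LandscapeSpec(
        n=n,
        L=52,
        planted_anchors=(PlantedAnchor("CACGTG", None, 1.0, 0.4),),
        baseline=math.log(0.15),
        noise_sd=0.3,
        affinity_range=(0.005, 1.0),
        seed=seed,
        scale=RELATIVE,
    )


def mitomi_like(seed: int, n: int = 300) -> tuple[AffinityDataset, np.ndarray]:
    return generate_landscape(mitomi_spec(seed, n=n))


def write_ground_truth(ln_truth: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(ln_truth):
            fh.write(f"{i}\t{v:.10g}\n")


def write_spec_json(spec: LandscapeSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1)
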