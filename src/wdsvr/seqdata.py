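"""Fixed-length sequence/affinity datasets: I/O, cleaning, filtering, CV folds.

A dataset couples DNA sequences of one common length L with measured binding
affinities — either dissociation constants K_d in nM (low K_d = strong
binding) or dimensionless relative affinities. All downstream kernel code
requires the uniform length, which is enforced here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
_VALID = frozenset(DNA_ALPHABET)

#: affinity scale markers
KD_NM = "kd_nM"
RELATIVE = "relative"


class DatasetError(ValueError):
    """Malformed dataset input (bad symbol, bad affinity field, empty file)."""


@dataclass(frozen=True)
class AffinityRecord:
    """One DNA sequence with its measured affinity.

    ``affinity`` may be NaN on a freshly loaded record; :func:`clean_dataset`
    removes such records. Everything downstream of cleaning assumes a finite
    positive value.
    """

    id: str
    sequence: str
    affinity: float

    def is_valid_sequence(self) -> bool:
        return bool(self.sequence) and set(self.sequence) <= _VALID


@dataclass(frozen=True)
class AffinityDataset:
    """Ordered collection of records sharing one sequence length L."""

    records: tuple[AffinityRecord, ...]
    length: int
    scale: str = KD_NM

    def __post_init__(self):
        for r in self.records:
            if len(r.sequence) != self.length:
                raise DatasetError(
                    f"record {r.id!r} has length {len(r.sequence)}, expected {self.length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def affinities(self) -> np.ndarray:
        return np.array([r.affinity for r in self.records], dtype=float)

    def subset(self, indices: Iterable[int]) -> "AffinityDataset":
        recs = tuple(self.records[i] for i in indices)
        return replace(self, records=recs)

    @classmethod
    def from_arrays(
        cls,
        sequences: Sequence[str],
        affinities: Sequence[float],
        scale: str = KD_NM,
        ids: Sequence[str] | None = None,
    ) -> "AffinityDataset":
        if len(sequences) == 0:
            raise DatasetError("empty dataset")
        if ids is None:
            ids = [f"seq{i}" for i in range(len(sequences))]
        recs = tuple(
            AffinityRecord(i, s.upper(), float(a))
            for i, s, a in zip(ids, sequences, affinities)
        )
        return cls(records=recs, length=len(recs[0].sequence), scale=scale)


def _parse_affinity(token: str, where: str) -> float:
    try:
        return float(token)
    except ValueError:
        if token.strip().lower() == "nan":
            return math.nan
        raise DatasetError(f"unparsable affinity field {token!r} at {where}")


def load_dataset(
    path: str | Path,
    format: str = "tsv",
    scale: str = KD_NM,
    header: bool = False,
    strict: bool = True,
) -> AffinityDataset:
    """Load a dataset from a two-column TSV (``sequence<TAB>affinity``) or a
    FASTA whose headers carry ``kd=<float>``.

    Sequences are uppercased. With ``strict`` (default), a record containing a
    symbol outside {A,C,G,T} raises; otherwise it is dropped with a log line.
    Records are returned in file order; mixed lengths raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[AffinityRecord] = []
    if format == "tsv":
        with open(path) as fh:
            lines = fh.read().splitlines()
        if header:
            lines = lines[1:]
        for ln, line in enumerate(lines, start=1 + int(header)):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DatasetError(f"expected sequence<TAB>affinity at line {ln}")
            seq = parts[0].strip().upper()
            aff = _parse_affinity(parts[1], f"line {ln}")
            records.append(AffinityRecord(f"line{ln}", seq, aff))
    elif format == "fasta":
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            kd = None
            for tok in rec.description.split():
                if tok.lower().startswith("kd="):
                    kd = _parse_affinity(tok[3:], f"record {rec.id}")
            if kd is None:
                raise DatasetError(f"FASTA header of {rec.id!r} lacks kd=<value>")
            records.append(AffinityRecord(rec.id, str(rec.seq).upper(), kd))
    else:
        raise ValueError(f"unknown format {format!r}")

    if not records:
        raise DatasetError(f"empty dataset: {path}")

    bad = [r for r in records if not r.is_valid_sequence()]
    if bad:
        if strict:
            raise DatasetError(
                f"{len(bad)} record(s) contain non-ACGT symbols (first: {bad[0].id!r})"
            )
        logger.info("dropping %d record(s) with non-ACGT symbols", len(bad))
        records = [r for r in records if r.is_valid_sequence()]
        if not records:
            raise DatasetError("all records dropped (non-ACGT symbols)")

    L = len(records[0].sequence)
    mixed = {len(r.sequence) for r in records}
    if len(mixed) > 1:
        raise DatasetError(f"mixed sequence lengths {sorted(mixed)}")
    return AffinityDataset(records=tuple(records), length=L, scale=scale)


def clean_dataset(ds: AffinityDataset) -> AffinityDataset:
    """Drop records with missing (NaN/non-finite/non-positive) affinities and
    merge exact duplicate sequences into one record carrying the arithmetic
    mean of their affinities. First-occurrence order is preserved. Idempotent.
    """
    n_dropped = 0
    groups: dict[str, list[AffinityRecord]] = {}
    order: list[str] = []
    for r in ds.records:
        if not math.isfinite(r.affinity) or r.affinity <= 0:
            n_dropped += 1
            continue
        if r.sequence not in groups:
            groups[r.sequence] = []
            order.append(r.sequence)
        groups[r.sequence].append(r)
    merged: list[AffinityRecord] = []
    n_merged = 0
    for seq in order:
        grp = groups[seq]
        if len(grp) == 1:
            merged.append(grp[0])
        else:
            n_merged += len(grp) - 1
            mean_aff = float(np.mean([g.affinity for g in grp]))
            merged.append(AffinityRecord(grp[0].id, seq, mean_aff))
    logger.info("clean_dataset: dropped %d, merged %d duplicate record(s)", n_dropped, n_merged)
    return replace(ds, records=tuple(merged))


def filter_by_affinity(ds: AffinityDataset, max_affinity: float) -> AffinityDataset:
    """Keep records with affinity strictly below ``max_affinity`` (the optimal
    recognition-site cut, e.g. K_d < 100 nM), preserving order."""
    kept = tuple(r for r in ds.records if r.affinity < max_affinity)
    return replace(ds, records=kept)


def kfold_split(
    ds: AffinityDataset | int, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold partition: list of (train_idx, test_idx) arrays.

    Test sets are disjoint, cover all indices, and their sizes differ by at
    most one. The same (n, k, seed) always yields the same partition.
    """
    n = ds if isinstance(ds, int) else len(ds)
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


def write_tsv(ds: AffinityDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ds.records:
            fh.write(f"{r.sequence}\t{r.affinity:g}\n")


def write_folds(folds: list[tuple[np.ndarray, np.ndarray]], path: str | Path) -> None:
    """Write fold assignments as ``index<TAB>fold`` TSV."""
    assignment: dict[int, int] = {}
    for f, (_, test) in enumerate(folds):
        for i in test:
            assignment[int(i)] = f
    with open(path, "w") as fh:
        for i in sorted(assignment):
            fh.write(f"{i}\t{assignment[i]}\n")
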