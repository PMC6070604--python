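"""V/J/length grouping and the distance-to-nearest distribution.

Clonally related B cells share the V gene, J gene and junction length of
their common ancestor, so sequences are first split into groups sharing
those three keys. Within each group, every sequence's minimum
length-normalized Hamming distance to a *non-identical* group member is
computed; pooled over groups these minima form the bimodal
distance-to-nearest distribution that the mixture model is fitted to
(low mode: sequences with clonal relatives; high mode: singletons).

``N`` characters mismatch everything, including another ``N``: ambiguity
never deflates a distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError
from .io import Dataset, collapse_gene_call

__all__ = [
    "PartitionGroup",
    "DistanceToNearest",
    "normalized_hamming",
    "partition_by_vjl",
    "partition_by_length",
    "distance_to_nearest",
    "distance_to_nearest_of",
]

# chunk row budget so the pairwise mismatch tensor stays < ~64 MB
_PAIRWISE_BYTES = 64 * 2**20


@dataclass(frozen=True)
class PartitionGroup:
    """Sequences sharing one (v_key, j_key, junction_length) key."""

    key: tuple[str, str, int]
    member_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class DistanceToNearest:
    """Per-sequence minimum distance to a non-identical neighbor.

    ``values`` maps sequence_id to a distance in (0, 1], or ``None`` when no
    non-identical neighbor exists in the sequence's group (singleton groups
    or groups of exact duplicates).
    """

    values: dict[str, float | None]
    n_defined: int

    def defined(self) -> tuple[list[str], np.ndarray]:
        """Ids and distances of sequences with a defined value."""
        ids = [k for k, v in self.values.items() if v is not None]
        return ids, np.array([self.values[k] for k in ids], dtype=float)


def normalized_hamming(a: str, b: str) -> float:
    """Length-normalized Hamming distance between equal-length sequences.

    Mismatch count divided by length; case-insensitive; any position
    involving ``N`` counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    a, b = a.upper(), b.upper()
    mismatches = sum(
        1 for ca, cb in zip(a, b) if ca != cb or ca == "N" or cb == "N"
    )
    return mismatches / len(a)


def partition_by_vjl(
    dataset: Dataset, v_level: str = "gene", j_level: str = "gene"
) -> list[PartitionGroup]:
    """Group records by (collapsed V call, collapsed J call, junction length).

    Groups are returned in sorted key order; members keep input order.
    """
    groups: dict[tuple[str, str, int], list[str]] = {}
    for rec in dataset:
        key = (
            collapse_gene_call(rec.v_call, v_level),
            collapse_gene_call(rec.j_call, j_level),
            rec.junction_length,
        )
        groups.setdefault(key, []).append(rec.sequence_id)
    return [PartitionGroup(k, tuple(groups[k])) for k in sorted(groups)]


def partition_by_length(dataset: Dataset) -> list[PartitionGroup]:
    """Group records by junction length only (global nearest-neighbor scope).

    The V/J key components are empty strings so downstream code sees the
    same group structure.
    """
    groups: dict[tuple[str, str, int], list[str]] = {}
    for rec in dataset:
        key = ("", "", rec.junction_length)
        groups.setdefault(key, []).append(rec.sequence_id)
    return [PartitionGroup(k, tuple(groups[k])) for k in sorted(groups)]


def _encode(junctions: list[str]) -> np.ndarray:
    """Encode equal-length junction strings as a (m, L) uint8 matrix.

    ``N`` is mapped to a per-row-unique sentinel so that N mismatches every
    base *and* every other N.
    """
    arr = np.frombuffer("".join(junctions).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(junctions), -1).copy()
    is_n = arr == ord("N")
    if is_n.any():
        # distinct negative codes per row: N in row i never equals anything
        arr = arr.astype(np.int32)
        rows = np.arange(len(junctions), dtype=np.int32)[:, None]
        arr[is_n] = (-1 - rows * np.ones_like(arr))[is_n]
    return arr


def duplicate_index_sets(
    junctions: list[str], include_unique: bool = False
) -> list[list[int]]:
    """Index sets of string-identical junctions (singletons optional)."""
    seen: dict[str, list[int]] = {}
    for idx, s in enumerate(junctions):
        seen.setdefault(s, []).append(idx)
    return [v for v in seen.values() if include_unique or len(v) > 1]


def pairwise_mismatches(junctions: list[str]) -> np.ndarray:
    """(m, m) matrix of Hamming mismatch counts within one group."""
    arr = _encode(junctions)
    m, length = arr.shape
    out = np.empty((m, m), dtype=np.int64)
    chunk = max(1, _PAIRWISE_BYTES // max(1, m * length))
    for start in range(0, m, chunk):
        stop = min(m, start + chunk)
        out[start:stop] = (arr[start:stop, None, :] != arr[None, :, :]).sum(axis=2)
    return out


def distance_to_nearest(
    groups: list[PartitionGroup], junctions: dict[str, str]
) -> DistanceToNearest:
    """Minimum normalized Hamming distance to a non-identical group member.

    Sequences in singleton groups, or whose group holds only exact copies
    of themselves, get ``None``. Exact duplicates share the distance to
    their common nearest non-identical neighbor.
    """
    values: dict[str, float | None] = {}
    for group in groups:
        members = list(group.member_ids)
        seqs = [junctions[sid].upper() for sid in members]
        length = group.key[2]
        if any(len(s) != length for s in seqs):
            raise ConsistencyError(
                f"junction length mismatch inside group {group.key}"
            )
        if len(members) == 1:
            values[members[0]] = None
            continue
        counts = pairwise_mismatches(seqs)
        # exclude string-identical neighbors (incl. self); string identity
        # overrides the N-mismatch rule, so mask by equality, not by count
        masked = counts.copy()
        for idxs in duplicate_index_sets(seqs, include_unique=True):
            masked[np.ix_(idxs, idxs)] = np.iinfo(np.int64).max
        nearest = masked.min(axis=1)
        for sid, cnt in zip(members, nearest):
            values[sid] = None if cnt == np.iinfo(np.int64).max else int(cnt) / length
    n_defined = sum(1 for v in values.values() if v is not None)
    return DistanceToNearest(values, n_defined)


def distance_to_nearest_of(
    dataset: Dataset,
    v_level: str = "gene",
    j_level: str = "gene",
    scope: str = "group",
) -> DistanceToNearest:
    """Convenience: partition a dataset and compute distance-to-nearest.

    ``scope="group"`` searches within V/J/length groups (the same groups
    the clonal clustering operates on); ``scope="global"`` searches across
    all sequences of equal junction length regardless of V/J calls.
    """
    if scope == "group":
        groups = partition_by_vjl(dataset, v_level, j_level)
    elif scope == "global":
        groups = partition_by_length(dataset)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return distance_to_nearest(groups, dataset.junctions())
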