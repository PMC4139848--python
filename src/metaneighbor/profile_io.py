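"""Profile collections: the data model, delimited-text I/O, abundance
normalization, k-mer profiling from FASTA, and mapping-based projection.

A *profile* is a vector of nonnegative per-feature abundances (protein
domains, KEGG orthologs, taxa, GO terms, or oligonucleotide frequencies)
summarizing one sequenced community sample.  A :class:`ProfileCollection`
holds the samples-by-features count matrix together with sample/feature
identifiers and optional habitat labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProfileCollection",
    "MappingTable",
    "read_profile_table",
    "write_profile_table",
    "normalize_relative",
    "kmer_feature_ids",
    "kmer_profile",
    "kmer_collection_from_fasta",
    "read_fasta_sequences",
    "read_mapping_table",
    "project_profiles",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ProfileCollection:
    """Samples x features nonnegative abundance matrix with identifiers.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    feature_ids
        Unique feature identifiers, one per matrix column.
    counts
        Nonnegative abundance matrix of shape ``(n_samples, n_features)``.
    labels
        Optional habitat label per sample (e.g. body site or biome).
    normalized
        True when every row is a relative-abundance vector summing to 1.
    """

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    counts: np.ndarray
    labels: tuple[str, ...] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "counts", counts)
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-dimensional, got shape {counts.shape}")
        n, d = counts.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample IDs for {n} rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature IDs for {d} columns")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample ID {dup!r}")
        if len(set(self.feature_ids)) != d:
            dup = _first_duplicate(self.feature_ids)
            raise ValueError(f"duplicate feature ID {dup!r}")
        if not np.all(np.isfinite(counts)):
            i, j = np.argwhere(~np.isfinite(counts))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative value {counts[i, j]} at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.labels is not None and len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if self.normalized:
            sums = counts.sum(axis=1)
            bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValueError(
                    f"normalized flag set but row for sample "
                    f"{self.sample_ids[i]!r} sums to {sums[i]!r}"
                )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def subset(self, indices: Sequence[int]) -> "ProfileCollection":
        """Return the collection restricted to the given sample rows."""
        idx = list(indices)
        return ProfileCollection(
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            feature_ids=self.feature_ids,
            counts=self.counts[idx],
            labels=None if self.labels is None else tuple(self.labels[i] for i in idx),
            normalized=self.normalized,
        )

    def with_labels(self, labels: Sequence[str]) -> "ProfileCollection":
        return replace(self, labels=tuple(labels))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.feature_ids)
        )


@dataclass(frozen=True)
class MappingTable:
    """Many-to-many source-feature -> target-feature association set."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", frozenset((str(a), str(b)) for a, b in self.pairs)
        )

    @property
    def sources(self) -> set[str]:
        return {a for a, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {b for _, b in self.pairs}


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""


def read_profile_table(
    path: str | Path,
    delimiter: str = "\t",
    label_column: str | None = None,
) -> ProfileCollection:
    """Read a delimited profile table (samples in rows, features in columns).

    The first column holds sample IDs, the header row feature IDs.  When
    ``label_column`` is given, that column is detached and used as the
    per-sample habitat label.  Negative, missing or non-numeric cells are
    rejected with the offending sample/feature named.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    labels: tuple[str, ...] | None = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {path}")
        labels = tuple(df.pop(label_column).astype(str))
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    counts = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            i = int(np.argmax(converted.isna().to_numpy()))
            raise ValueError(
                f"non-numeric cell {df[col].iloc[i]!r} at sample "
                f"{df.index[i]!r}, feature {col!r}"
            )
        counts[:, j] = converted.to_numpy()
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"negative value {counts[i, j]} at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r}"
        )
    return ProfileCollection(
        sample_ids=tuple(df.index),
        feature_ids=tuple(str(c) for c in df.columns),
        counts=counts,
        labels=labels,
    )


def write_profile_table(
    collection: ProfileCollection,
    path: str | Path,
    delimiter: str = "\t",
    label_column: str = "label",
) -> None:
    """Write a collection in the dialect :func:`read_profile_table` reads."""
    df = collection.to_dataframe()
    if collection.labels is not None:
        df[label_column] = list(collection.labels)
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter)


def normalize_relative(collection: ProfileCollection) -> ProfileCollection:
    """Convert counts to relative abundances (each row divided by its sum)."""
    sums = collection.counts.sum(axis=1)
    if np.any(sums <= 0):
        i = int(np.argmax(sums <= 0))
        raise ValueError(
            f"sample {collection.sample_ids[i]!r} has zero total count; "
            "cannot normalize"
        )
    return replace(collection, counts=collection.counts / sums[:, None], normalized=True)


# --- k-mer profiling -------------------------------------------------------

_BASE_CODES = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[_b + 32] = _i  # lower case


def kmer_feature_ids(k: int) -> tuple[str, ...]:
    """All k-mers over {A,C,G,T} in lexicographic order (AA..A first)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return tuple("".join(p) for p in itertools.product("ACGT", repeat=k))


def kmer_profile(sequences: Iterable[str], k: int) -> np.ndarray:
    """Count all overlapping forward-strand k-mers across the sequences.

    Windows containing a character outside {A,C,G,T} (case-insensitive)
    contribute nothing; there is no reverse-complement canonicalization.
    Returns a vector of length ``4**k`` in lexicographic feature order.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = np.zeros(4**k, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for seq in sequences:
        arr = _BASE_CODES[np.frombuffer(str(seq).encode("ascii"), dtype=np.uint8)]
        if arr.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        valid = np.all(windows >= 0, axis=1)
        if not np.any(valid):
            continue
        codes = (windows[valid] * weights).sum(axis=1)
        counts += np.bincount(codes, minlength=4**k)
    return counts


def read_fasta_sequences(path: str | Path) -> list[str]:
    """Sequences of a (multi-record, wrapped or unwrapped) FASTA file."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def kmer_collection_from_fasta(
    paths: Sequence[str | Path], k: int
) -> ProfileCollection:
    """One k-mer profile per FASTA file; sample ID = file stem."""
    sample_ids = []
    rows = []
    for p in paths:
        p = Path(p)
        sample_ids.append(p.stem)
        rows.append(kmer_profile(read_fasta_sequences(p), k))
    return ProfileCollection(
        sample_ids=tuple(sample_ids),
        feature_ids=kmer_feature_ids(k),
        counts=np.array(rows, dtype=float),
    )


# --- mapping-based projection ---------------------------------------------


def read_mapping_table(path: str | Path, delimiter: str = "\t") -> MappingTable:
    """Two-column (source, target) delimited file; '#' comment lines ignored."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"line {line_no} of {path} has fewer than 2 columns")
            pairs.add((parts[0].strip(), parts[1].strip()))
    return MappingTable(pairs=frozenset(pairs))


def project_profiles(
    collection: ProfileCollection, mapping: MappingTable
) -> ProfileCollection:
    """Project profiles onto the mapping's target feature space.

    The count of target ``g`` for a sample is the sum of the sample's counts
    over every source feature associated with ``g``; a source associated with
    several targets contributes its full count to each of them (association
    counting, not count splitting).  Source features without any association
    are dropped.
    """
    if not mapping.pairs:
        raise ValueError("empty mapping table")
    if collection.normalized:
        raise ValueError("projection requires unnormalized counts")
    targets = sorted(mapping.targets)
    target_index = {t: j for j, t in enumerate(targets)}
    source_index = {s: j for j, s in enumerate(collection.feature_ids)}
    proj = np.zeros((len(collection.feature_ids), len(targets)))
    for src, tgt in mapping.pairs:
        if src in source_index:
            proj[source_index[src], target_index[tgt]] = 1.0
    return ProfileCollection(
        sample_ids=collection.sample_ids,
        feature_ids=tuple(targets),
        counts=collection.counts @ proj,
        labels=collection.labels,
    )
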