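"""Database curation filters for profile collections.

Mirrors the screening steps used when compiling a reference database of
metagenome profiles: minimum total feature hits, minimum number of distinct
features, an externally supplied quality score (FDU, fraction of domains
unexplained) and redundancy removal by profile correlation.  Virus-enriched
or otherwise exempted habitat labels can bypass the redundancy step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .profile_io import ProfileCollection

__all__ = [
    "CurationReport",
    "filter_min_total",
    "filter_min_features",
    "filter_fdu",
    "deduplicate",
    "read_fdu_table",
]


@dataclass(frozen=True)
class CurationReport:
    """Which samples a curation step kept or dropped, and why.

    ``dropped`` maps each removed sample ID to the single rule that removed
    it.  ``clusters`` lists redundancy groups (members plus the chosen
    representative); empty for threshold filters.
    """

    kept_ids: tuple[str, ...]
    dropped: dict[str, str]
    clusters: tuple[dict, ...] = ()
    warnings: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept_ids": list(self.kept_ids),
                "dropped": self.dropped,
                "clusters": list(self.clusters),
                "warnings": list(self.warnings),
            },
            indent=2,
        )


def _apply_keep(
    collection: ProfileCollection, keep: Sequence[bool], rule: str, clusters=(), warnings=()
) -> tuple[ProfileCollection, CurationReport]:
    idx = [i for i, kp in enumerate(keep) if kp]
    report = CurationReport(
        kept_ids=tuple(collection.sample_ids[i] for i in idx),
        dropped={
            collection.sample_ids[i]: rule for i, kp in enumerate(keep) if not kp
        },
        clusters=tuple(clusters),
        warnings=tuple(warnings),
    )
    return collection.subset(idx), report


def filter_min_total(
    collection: ProfileCollection, min_hits: int = 1000
) -> tuple[ProfileCollection, CurationReport]:
    """Drop samples with fewer than ``min_hits`` total feature hits."""
    if collection.normalized:
        raise ValueError("total-hit filtering requires unnormalized counts")
    sums = collection.counts.sum(axis=1)
    return _apply_keep(collection, sums >= min_hits, f"total_hits<{min_hits}")


def filter_min_features(
    collection: ProfileCollection, min_nonzero: int = 400
) -> tuple[ProfileCollection, CurationReport]:
    """Drop samples with hits to fewer than ``min_nonzero`` distinct features."""
    if collection.normalized:
        raise ValueError("feature-count filtering requires unnormalized counts")
    nnz = (collection.counts > 0).sum(axis=1)
    return _apply_keep(collection, nnz >= min_nonzero, f"distinct_features<{min_nonzero}")


def filter_fdu(
    collection: ProfileCollection,
    fdu: Mapping[str, float],
    max_fdu: float = 0.6,
) -> tuple[ProfileCollection, CurationReport]:
    """Drop samples whose FDU quality value exceeds ``max_fdu``.

    FDU (fraction of domains unexplained) is computed by external taxonomic
    profiling tools; here it is only consumed.  Every sample must have a
    value in [0, 1].
    """
    values = []
    for sid in collection.sample_ids:
        if sid not in fdu:
            raise ValueError(f"missing FDU value for sample {sid!r}")
        v = float(fdu[sid])
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"FDU value {v} for sample {sid!r} outside [0, 1]")
        values.append(v)
    keep = [v <= max_fdu for v in values]
    return _apply_keep(collection, keep, f"fdu>{max_fdu}")


def read_fdu_table(path: str | Path, delimiter: str = "\t") -> dict[str, float]:
    """Two-column (sample ID, FDU) delimited file; '#' comments ignored."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"line {line_no} of {path} has fewer than 2 columns")
            out[parts[0].strip()] = float(parts[1])
    return out


def deduplicate(
    collection: ProfileCollection,
    corr_threshold: float = 0.995,
    exempt_labels: set[str] | frozenset[str] = frozenset(),
) -> tuple[ProfileCollection, CurationReport]:
    """Collapse groups of near-identical profiles to one representative.

    Samples whose pairwise Pearson profile correlation exceeds
    ``corr_threshold`` are linked; within each connected component the sample
    with the largest total count is kept (ties broken by lexicographically
    smallest ID).  Samples whose habitat label is in ``exempt_labels`` bypass
    the procedure entirely.  Constant profiles (undefined correlation) are
    kept as singletons with a warning.
    """
    n = collection.n_samples
    if n < 1:
        raise ValueError("empty collection")
    if not 0.0 < corr_threshold < 1.0:
        raise ValueError(f"corr_threshold must be in (0, 1), got {corr_threshold}")
    exempt_labels = set(exempt_labels)
    if exempt_labels and collection.labels is None:
        raise ValueError("exempt_labels given but collection has no labels")

    warnings: list[str] = []
    exempt = np.zeros(n, dtype=bool)
    if collection.labels is not None:
        exempt = np.array([lab in exempt_labels for lab in collection.labels])

    X = collection.counts
    stds = X.std(axis=1)
    constant = stds == 0
    for i in np.nonzero(constant & ~exempt)[0]:
        warnings.append(
            f"sample {collection.sample_ids[i]!r} has a constant profile; "
            "correlation undefined, kept as singleton"
        )
    participating = np.nonzero(~exempt & ~constant)[0]

    keep = np.ones(n, dtype=bool)
    clusters: list[dict] = []
    if participating.size >= 2:
        sub = X[participating]
        corr = np.corrcoef(sub)
        adj = np.triu(corr > corr_threshold, 1)
        n_comp, comp = connected_components(csr_matrix(adj), directed=False)
        for c in range(n_comp):
            members = participating[comp == c]
            if members.size < 2:
                continue
            best = min(
                members,
                key=lambda i: (-X[i].sum(), collection.sample_ids[i]),
            )
            clusters.append(
                {
                    "members": [collection.sample_ids[i] for i in sorted(members)],
                    "representative": collection.sample_ids[best],
                }
            )
            for i in members:
                if i != best:
                    keep[i] = False
    return _apply_keep(
        collection,
        keep,
        f"redundant(corr>{corr_threshold})",
        clusters=clusters,
        warnings=warnings,
    )
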