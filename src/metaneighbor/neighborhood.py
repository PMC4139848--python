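"""k-nearest-neighbor retrieval and leave-one-out neighborhood accuracy.

For every sample in a labeled collection the k nearest other samples are
retrieved from a distance matrix; the neighborhood accuracy is the fraction
of those neighbors sharing the query's habitat label, averaged over all
samples (leave-one-out cross-validation).  Per-label accuracies and a
query-label x neighbor-label confusion matrix summarize where habitats
overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import DistanceMatrix

__all__ = [
    "NeighborhoodReport",
    "k_nearest",
    "loocv_accuracy",
    "confusion_percentages",
    "format_report",
    "write_report",
]


@dataclass(frozen=True)
class NeighborhoodReport:
    """Neighbor lists, label-agreement fractions and confusion matrix.

    ``confusion`` rows are query labels, columns neighbor labels; each row
    holds the percentage of neighbor slots (unrounded rows sum to 100).
    ``per_label_accuracy`` is the mean of per-sample accuracies within each
    label (see :func:`loocv_accuracy` for the pooled alternative).
    """

    k: int
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    neighbor_ids: tuple[tuple[str, ...], ...]
    per_sample_accuracy: np.ndarray
    per_label_accuracy: dict[str, float]
    overall_accuracy: float
    confusion: pd.DataFrame


def k_nearest(distances: DistanceMatrix, query_index: int, k: int) -> list[int]:
    """Indices of the k nearest other samples, ascending by distance.

    Exact distance ties are broken by ascending sample-ID order, which makes
    the result invariant to the storage order of samples.  If ``k`` exceeds
    ``n - 1`` all other samples are returned.
    """
    n = distances.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples for neighbor retrieval")
    if not 0 <= query_index < n:
        raise ValueError(f"query index {query_index} out of range for {n} samples")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    row = distances.values[query_index]
    ids = distances.sample_ids
    others = [j for j in range(n) if j != query_index]
    others.sort(key=lambda j: (row[j], ids[j]))
    return others[: min(k, n - 1)]


def loocv_accuracy(
    distances: DistanceMatrix,
    labels: Sequence[str | None],
    k: int = 10,
    label_average: str = "mean",
) -> NeighborhoodReport:
    """Leave-one-out neighborhood accuracy over all samples.

    Each sample in turn is the query against all remaining samples; its
    accuracy is the fraction of its (at most) k nearest neighbors that share
    its label.  ``overall_accuracy`` is the unweighted mean over samples.

    ``label_average`` controls the per-label summary: ``"mean"`` averages the
    per-sample fractions within each label, ``"pooled"`` pools all neighbor
    slots of the label's queries before dividing.
    """
    n = distances.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} samples")
    if label_average not in ("mean", "pooled"):
        raise ValueError(f"label_average must be 'mean' or 'pooled', got {label_average!r}")
    for sid, lab in zip(distances.sample_ids, labels):
        if lab is None or (isinstance(lab, float) and math.isnan(lab)) or str(lab) == "":
            raise ValueError(f"missing label for sample {sid!r}")
    labels = tuple(str(l) for l in labels)
    label_order = sorted(set(labels))
    li = {lab: i for i, lab in enumerate(label_order)}

    neighbor_ids: list[tuple[str, ...]] = []
    per_sample = np.empty(n)
    slot_counts = np.zeros((len(label_order), len(label_order)))
    for i in range(n):
        nbrs = k_nearest(distances, i, k)
        neighbor_ids.append(tuple(distances.sample_ids[j] for j in nbrs))
        same = sum(1 for j in nbrs if labels[j] == labels[i])
        per_sample[i] = same / len(nbrs)
        for j in nbrs:
            slot_counts[li[labels[i]], li[labels[j]]] += 1

    per_label: dict[str, float] = {}
    for lab in label_order:
        idx = [i for i in range(n) if labels[i] == lab]
        if label_average == "mean":
            per_label[lab] = float(per_sample[idx].mean())
        else:
            r = li[lab]
            per_label[lab] = float(slot_counts[r, r] / slot_counts[r].sum())
    confusion = pd.DataFrame(
        100.0 * slot_counts / slot_counts.sum(axis=1, keepdims=True),
        index=label_order,
        columns=label_order,
    )
    return NeighborhoodReport(
        k=k,
        sample_ids=distances.sample_ids,
        labels=labels,
        neighbor_ids=tuple(neighbor_ids),
        per_sample_accuracy=per_sample,
        per_label_accuracy=per_label,
        overall_accuracy=float(per_sample.mean()),
        confusion=confusion,
    )


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(values + 0.5).astype(int)


def confusion_percentages(report: NeighborhoodReport) -> pd.DataFrame:
    """Confusion matrix as integer percentages, rounded half-up."""
    return pd.DataFrame(
        _round_half_up(report.confusion.to_numpy()),
        index=report.confusion.index,
        columns=report.confusion.columns,
    )


def format_report(report: NeighborhoodReport) -> str:
    """Human-readable report: per-sample rows, per-label summary, confusion.

    Confusion entries below 0.5% are rendered blank, matching the convention
    of omitting sub-rounding values from printed matrices.
    """
    lines = [f"# k = {report.k}", "# sample_id\tlabel\taccuracy\tneighbors"]
    for sid, lab, acc, nbrs in zip(
        report.sample_ids, report.labels, report.per_sample_accuracy, report.neighbor_ids
    ):
        lines.append(f"{sid}\t{lab}\t{acc:.4f}\t{','.join(nbrs)}")
    lines.append("")
    lines.append("# per-label accuracy")
    for lab, acc in report.per_label_accuracy.items():
        lines.append(f"{lab}\t{acc:.4f}")
    lines.append(f"overall\t{report.overall_accuracy:.4f}")
    lines.append("")
    lines.append("# confusion matrix (query rows x neighbor columns, % of slots)")
    raw = report.confusion.to_numpy()
    rounded = _round_half_up(raw)
    cols = list(report.confusion.columns)
    lines.append("\t" + "\t".join(cols))
    for r, lab in enumerate(report.confusion.index):
        cells = [
            str(rounded[r, c]) if raw[r, c] >= 0.5 else "" for c in range(len(cols))
        ]
        lines.append(lab + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def write_report(report: NeighborhoodReport, path_prefix: str | Path) -> None:
    """Write ``<prefix>.txt`` (human-readable) and ``<prefix>.json`` (machine)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".txt"), "w") as fh:
        fh.write(format_report(report))
    payload = {
        "k": report.k,
        "overall_accuracy": report.overall_accuracy,
        "per_label_accuracy": report.per_label_accuracy,
        "per_sample": [
            {"sample_id": sid, "label": lab, "accuracy": acc, "neighbors": list(nbrs)}
            for sid, lab, acc, nbrs in zip(
                report.sample_ids,
                report.labels,
                report.per_sample_accuracy.tolist(),
                report.neighbor_ids,
            )
        ],
        "confusion_percent": {
            row: dict(zip(report.confusion.columns, report.confusion.loc[row]))
            for row in report.confusion.index
        },
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2)
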