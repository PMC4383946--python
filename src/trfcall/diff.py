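"""Two-group differential-abundance comparison of fragment RPM profiles.

Deliberately descriptive: per-fragment mean RPM per group, a
pseudocount-stabilized log2 fold change, a detection filter (>20 RPM by
default), and per-type class summaries.  No p-values are computed — with
two replicates per group formal inference is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_MIN_RPM = 20.0
DEFAULT_PSEUDOCOUNT = 1.0

TRF_TYPES = ("tRF-5", "tRF-3", "tRF-1")


@dataclass(frozen=True)
class GroupComparison:
    trf_id: str
    trf_type: str
    mean_rpm_a: float
    mean_rpm_b: float
    log2_fold_change: float
    detected: bool


def _detected(row_a, row_b, min_rpm: float, mode: str) -> bool:
    if mode == "group-mean":
        return max(row_a.mean(), row_b.mean()) > min_rpm
    if mode == "per-library-any":
        return bool((row_a > min_rpm).any() or (row_b > min_rpm).any())
    if mode == "per-library-all":
        return bool((row_a > min_rpm).all() and (row_b > min_rpm).all())
    raise ValueError(f"unknown detection mode {mode!r}")


def compare_groups(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    trf_types: Mapping[str, str],
    min_rpm: float = DEFAULT_MIN_RPM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    detect_mode: str = "group-mean",
) -> list[GroupComparison]:
    """Compare mean RPM between two library groups, fragment by fragment.

    ``matrix`` is the RPM matrix (rows fragments, columns libraries);
    ``trf_types`` maps fragment ID to type.  Only fragments passing the
    detection filter are returned, ordered by |log2 fold change| descending
    (ties by ID).  log2FC = log2((mean_B + p) / (mean_A + p)).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    for lib in list(group_a) + list(group_b):
        if lib not in matrix.columns:
            raise KeyError(f"unknown library {lib!r}")
    out = []
    for trf_id, row in matrix.iterrows():
        row_a, row_b = row[list(group_a)], row[list(group_b)]
        if not _detected(row_a, row_b, min_rpm, detect_mode):
            continue
        mean_a, mean_b = float(row_a.mean()), float(row_b.mean())
        lfc = math.log2((mean_b + pseudocount) / (mean_a + pseudocount))
        out.append(
            GroupComparison(
                trf_id=str(trf_id),
                trf_type=trf_types.get(str(trf_id), "unknown"),
                mean_rpm_a=mean_a,
                mean_rpm_b=mean_b,
                log2_fold_change=lfc,
                detected=True,
            )
        )
    out.sort(key=lambda c: (-abs(c.log2_fold_change), c.trf_id))
    return out


def class_summary(
    comparisons: Iterable[GroupComparison], lfc_threshold: float = 1.0
) -> pd.DataFrame:
    """Per-type aggregate: count, median log2FC, up/down/flat tallies.

    "Up"/"down" use |log2FC| >= ``lfc_threshold``; a type with no detected
    fragments is reported with count 0 and NaN median.
    """
    rows = []
    by_type: dict[str, list[GroupComparison]] = {t: [] for t in TRF_TYPES}
    for c in comparisons:
        by_type.setdefault(c.trf_type, []).append(c)
    for trf_type, items in by_type.items():
        lfcs = sorted(c.log2_fold_change for c in items)
        median = float(pd.Series(lfcs).median()) if lfcs else float("nan")
        rows.append(
            {
                "trf_type": trf_type,
                "n": len(items),
                "median_log2fc": median,
                "n_up": sum(1 for c in items if c.log2_fold_change >= lfc_threshold),
                "n_down": sum(1 for c in items if c.log2_fold_change <= -lfc_threshold),
                "n_flat": sum(1 for c in items if abs(c.log2_fold_change) < lfc_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("trf_type")


def write_comparisons(comparisons: Iterable[GroupComparison], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("trf_id\ttype\tmean_rpm_A\tmean_rpm_B\tlog2_fold_change\tdetected\n")
        for c in comparisons:
            fh.write(
                f"{c.trf_id}\t{c.trf_type}\t{c.mean_rpm_a:.2f}\t{c.mean_rpm_b:.2f}\t"
                f"{c.log2_fold_change:.4f}\t{int(c.detected)}\n"
            )
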