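"""Barcode-gap detection.

Two complementary views are provided.  The distribution-level view
compares the full intraspecific and interspecific distance
distributions (ranges, means, medians and an overlap flag).  The
per-sequence view applies the stricter test of comparing, for every
specimen, its greatest distance to a conspecific against its smallest
distance to any other species: the specimen shows a gap only when the
latter strictly exceeds the former.  Singleton species have no
conspecific distances; their maximum intraspecific distance is taken as
zero (so any positive distance to the nearest other species counts as a
gap), which follows the convention of the R toolchain commonly used for
these analyses and is flagged because it inflates gap counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceMatrix, round_half_up
from .io_alignments import SpecimenRecord


@dataclass(frozen=True)
class GapRecord:
    """Greatest-intra vs smallest-inter comparison for one specimen."""

    specimen_id: str
    species: str
    max_intra: float
    min_inter: float
    singleton: bool

    @property
    def has_gap(self) -> bool:
        return self.min_inter > self.max_intra


@dataclass(frozen=True)
class GapSummary:
    """Counts and integer percentage of specimens showing a gap."""

    n_sequences: int
    n_with_gap: int
    n_excluded: int = 0

    @property
    def n_without_gap(self) -> int:
        return self.n_sequences - self.n_with_gap

    @property
    def pct_with_gap(self) -> int:
        return round_half_up(100.0 * self.n_with_gap / self.n_sequences)


def gap_records(
    matrix: DistanceMatrix, specimens: Sequence[SpecimenRecord]
) -> tuple[list[GapRecord], int]:
    """Per-specimen gap records plus the count of excluded specimens.

    ``max_intra`` is the specimen's greatest defined distance to a
    conspecific (0 for singletons); ``min_inter`` its smallest defined
    distance to a heterospecific.  Specimens with no defined
    interspecific distance are excluded and counted.
    """
    species = {s.specimen_id: s.species for s in specimens}
    missing = [lab for lab in matrix.labels if lab not in species]
    if missing:
        raise ValueError(f"labels without species assignment: {missing[:5]}")
    sp = np.array([species[lab] for lab in matrix.labels])
    if len(set(sp)) < 2:
        raise ValueError("gap analysis needs at least 2 species")
    records: list[GapRecord] = []
    excluded = 0
    n = matrix.n
    for i in range(n):
        row = matrix.d[i]
        defined = ~np.isnan(row)
        defined[i] = False
        same = sp == sp[i]
        inter = row[defined & ~same]
        if len(inter) == 0:
            excluded += 1
            continue
        intra = row[defined & same]
        singleton = (same.sum() == 1)
        max_intra = float(intra.max()) if len(intra) else 0.0
        records.append(
            GapRecord(
                specimen_id=matrix.labels[i],
                species=str(sp[i]),
                max_intra=max_intra,
                min_inter=float(inter.min()),
                singleton=singleton,
            )
        )
    return records, excluded


def gap_summary(records: Sequence[GapRecord], n_excluded: int = 0) -> GapSummary:
    """Aggregate gap records into counts and a half-up integer percentage."""
    if not records:
        raise ValueError("no gap records to summarise")
    n_gap = sum(r.has_gap for r in records)
    return GapSummary(
        n_sequences=len(records), n_with_gap=n_gap, n_excluded=n_excluded
    )


def write_gap_table(
    records: Sequence[GapRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["specimen_id", "species", "max_intra", "min_inter", "has_gap", "singleton"]
        )
        for r in records:
            writer.writerow(
                [
                    r.specimen_id,
                    r.species,
                    f"{r.max_intra:.10g}",
                    f"{r.min_inter:.10g}",
                    r.has_gap,
                    r.singleton,
                ]
            )


@dataclass(frozen=True)
class OverlapReport:
    """Distribution-level comparison of intra vs inter distances.

    ``overlap`` is True when the largest intraspecific distance reaches
    or exceeds the smallest interspecific distance (i.e. the two
    distributions are not separated); None when either list is empty.
    """

    intra_summary: Optional[dict[str, float]]
    inter_summary: Optional[dict[str, float]]
    overlap: Optional[bool]


def _five_numbers(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "mean": float(values.mean()),
    }


def distribution_overlap(
    intra: Sequence[float], inter: Sequence[float]
) -> OverlapReport:
    """Five-number summaries of both distance sets plus the overlap flag."""
    inter_arr = np.asarray(inter, dtype=float)
    inter_arr = inter_arr[~np.isnan(inter_arr)]
    if len(inter_arr) == 0:
        raise ValueError("interspecific distance list is empty")
    intra_arr = np.asarray(intra, dtype=float)
    intra_arr = intra_arr[~np.isnan(intra_arr)]
    if len(intra_arr) == 0:
        return OverlapReport(
            intra_summary=None,
            inter_summary=_five_numbers(inter_arr),
            overlap=None,
        )
    return OverlapReport(
        intra_summary=_five_numbers(intra_arr),
        inter_summary=_five_numbers(inter_arr),
        overlap=bool(intra_arr.max() >= inter_arr.min()),
    )
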