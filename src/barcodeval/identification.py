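"""Distance-based species identification criteria and threshold optimisation.

Three leave-one-out criteria are implemented, matching the rule tables
used in barcode-evaluation practice:

* **Near Neighbour** — success iff at least one of the query's nearest
  sequences (ties included) is conspecific.  Threshold-free.
* **Best Close Match** — consider only sequences within the threshold;
  the co-minimal ones among them determine the call: all conspecific ->
  correct, none -> incorrect, mixed -> ambiguous; nothing within the
  threshold -> no identification.
* **Threshold identification (BOLD rule)** — the candidate set is *all*
  sequences within the threshold (1% by default); its purity determines
  the call with the same four categories.

The query is always excluded from its own candidate set.  Thresholds
are optimised from the pooled pairwise-distance distribution: a
Gaussian kernel density estimate is scanned for its first local
minimum, interpreted as the intra/inter-specific transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceMatrix, round_half_up
from .io_alignments import SpecimenRecord

CRITERIA = ("near_neighbour", "best_close_match", "thresh_id")
NN_CATEGORIES = ("true", "false")
ID_CATEGORIES = ("ambiguous", "correct", "incorrect", "no_id")

#: default threshold when KDE optimisation finds no interior minimum
FALLBACK_THRESHOLD = 0.01


@dataclass(frozen=True)
class IdOutcome:
    """Identification call for one query specimen under one criterion."""

    specimen_id: str
    species: str
    criterion: str
    category: str
    distance_to_best: Optional[float] = None
    threshold_used: Optional[float] = None

    def __post_init__(self) -> None:
        legal = NN_CATEGORIES if self.criterion == "near_neighbour" else ID_CATEGORIES
        if self.category not in legal:
            raise ValueError(
                f"{self.criterion}: illegal category {self.category!r} "
                f"(legal: {legal})"
            )


@dataclass(frozen=True)
class IdSummary:
    """Integer percentages per category for one criterion."""

    criterion: str
    n_queries: int
    n_excluded: int
    percentages: dict[str, int]
    counts: dict[str, int]


def _apportion_percentages(counts: dict[str, int], n: int) -> dict[str, int]:
    """Integer percentages by largest-remainder apportionment.

    Guarantees the categories sum to exactly 100, the convention the
    printed identification tables follow; ties in the remainders are
    broken by category order for determinism.
    """
    exact = {c: 100.0 * k / n for c, k in counts.items()}
    floors = {c: int(exact[c]) for c in counts}
    leftover = 100 - sum(floors.values())
    order = sorted(counts, key=lambda c: -(exact[c] - floors[c]))
    for c in order[:leftover]:
        floors[c] += 1
    return floors


def summarize_outcomes(outcomes: Sequence[IdOutcome], n_excluded: int = 0) -> IdSummary:
    """Integer percentages per category over a single criterion."""
    if not outcomes:
        raise ValueError("no outcomes to summarise")
    criteria = {o.criterion for o in outcomes}
    if len(criteria) != 1:
        raise ValueError(f"mixed criteria in one summary: {sorted(criteria)}")
    criterion = outcomes[0].criterion
    legal = NN_CATEGORIES if criterion == "near_neighbour" else ID_CATEGORIES
    counts = {c: 0 for c in legal}
    for o in outcomes:
        counts[o.category] += 1
    n = len(outcomes)
    percentages = _apportion_percentages(counts, n)
    return IdSummary(
        criterion=criterion,
        n_queries=n,
        n_excluded=n_excluded,
        percentages=percentages,
        counts=counts,
    )


def _query_rows(matrix: DistanceMatrix, specimens: Sequence[SpecimenRecord]):
    """Yield (label, species, distances-to-others, conspecific mask) per
    query with a defined row; fully UNDEFINED rows are counted, not
    yielded."""
    species = {s.specimen_id: s.species for s in specimens}
    sp = np.array([species[lab] for lab in matrix.labels])
    n = matrix.n
    excluded = 0
    for i in range(n):
        row = matrix.d[i].copy()
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        defined = mask & ~np.isnan(row)
        if not defined.any():
            excluded += 1
            continue
        yield matrix.labels[i], sp[i], row, defined, sp == sp[i]
    # communicate the exclusion count through the generator return value
    return excluded


def _run_queries(matrix, specimens, fn):
    gen = _query_rows(matrix, specimens)
    outcomes = []
    while True:
        try:
            item = next(gen)
        except StopIteration as stop:
            return outcomes, (stop.value or 0)
        outcomes.append(fn(*item))


def near_neighbour(
    matrix: DistanceMatrix, specimens: Sequence[SpecimenRecord]
) -> tuple[list[IdOutcome], IdSummary]:
    """Nearest-sequence identification: true iff any co-minimal
    neighbour is conspecific.  Singleton-species queries are scored
    (necessarily false)."""
    _check_inputs(matrix, specimens)

    def call(label, sp_i, row, defined, same) -> IdOutcome:
        dmin = np.nanmin(row[defined])
        at_min = defined & (row == dmin)
        ok = bool((at_min & same).any())
        return IdOutcome(
            specimen_id=label,
            species=sp_i,
            criterion="near_neighbour",
            category="true" if ok else "false",
            distance_to_best=float(dmin),
        )

    outcomes, excluded = _run_queries(matrix, specimens, call)
    return outcomes, summarize_outcomes(outcomes, n_excluded=excluded)


def best_close_match(
    matrix: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    threshold: float,
) -> tuple[list[IdOutcome], IdSummary]:
    """Best-close-match identification at ``threshold`` (inclusive).

    No sequence within the threshold -> no_id; otherwise the co-minimal
    sequences within it decide: all conspecific -> correct, none ->
    incorrect, mixed -> ambiguous.
    """
    _check_inputs(matrix, specimens, threshold)

    def call(label, sp_i, row, defined, same) -> IdOutcome:
        within = defined & (row <= threshold)
        if not within.any():
            return IdOutcome(
                specimen_id=label,
                species=sp_i,
                criterion="best_close_match",
                category="no_id",
                threshold_used=threshold,
            )
        dmin = row[within].min()
        at_min = within & (row == dmin)
        category = _purity(at_min, same)
        return IdOutcome(
            specimen_id=label,
            species=sp_i,
            criterion="best_close_match",
            category=category,
            distance_to_best=float(dmin),
            threshold_used=threshold,
        )

    outcomes, excluded = _run_queries(matrix, specimens, call)
    return outcomes, summarize_outcomes(outcomes, n_excluded=excluded)


def thresh_id(
    matrix: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    threshold: float = FALLBACK_THRESHOLD,
) -> tuple[list[IdOutcome], IdSummary]:
    """Threshold (BOLD-style) identification at ``threshold`` (inclusive).

    The candidate set is every sequence within the threshold; all
    conspecific -> correct, none -> incorrect, mixed -> ambiguous,
    empty -> no_id.
    """
    _check_inputs(matrix, specimens, threshold)

    def call(label, sp_i, row, defined, same) -> IdOutcome:
        within = defined & (row <= threshold)
        if not within.any():
            return IdOutcome(
                specimen_id=label,
                species=sp_i,
                criterion="thresh_id",
                category="no_id",
                threshold_used=threshold,
            )
        category = _purity(within, same)
        return IdOutcome(
            specimen_id=label,
            species=sp_i,
            criterion="thresh_id",
            category=category,
            distance_to_best=float(row[within].min()),
            threshold_used=threshold,
        )

    outcomes, excluded = _run_queries(matrix, specimens, call)
    return outcomes, summarize_outcomes(outcomes, n_excluded=excluded)


def _purity(candidates: np.ndarray, same: np.ndarray) -> str:
    n_con = int((candidates & same).sum())
    n_het = int((candidates & ~same).sum())
    if n_con and not n_het:
        return "correct"
    if n_het and not n_con:
        return "incorrect"
    return "ambiguous"


def _check_inputs(matrix, specimens, threshold: Optional[float] = None) -> None:
    if matrix.n < 2:
        raise ValueError("identification needs at least 2 specimens")
    species = {s.specimen_id: s.species for s in specimens}
    missing = [lab for lab in matrix.labels if lab not in species]
    if missing:
        raise ValueError(f"labels without species assignment: {missing[:5]}")
    if len({species[lab] for lab in matrix.labels}) < 2:
        raise ValueError("identification needs at least 2 species")
    if threshold is not None and threshold <= 0:
        raise ValueError("threshold must be > 0")


# ---------------------------------------------------------------------------
# threshold optimisation


@dataclass(frozen=True)
class ThresholdEstimate:
    """Data-driven distance threshold from the pooled-distance KDE.

    ``threshold`` is the smallest interior local minimum of the density;
    when none exists (unimodal distances) the fixed fallback is used and
    flagged.
    """

    threshold: float
    all_local_minima: tuple[float, ...]
    bandwidth: float
    n_distances: int
    fallback: bool = False

    @property
    def threshold_pct(self) -> float:
        return 100.0 * self.threshold


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    n = len(x)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def kde_on_grid(
    x: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian KDE evaluated on ``grid`` (unnormalised constants kept)."""
    z = (grid[:, None] - x[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(x) * bandwidth * math.sqrt(2 * math.pi))


def local_minima_threshold(
    distances: Sequence[float], grid_size: int = 512
) -> ThresholdEstimate:
    """Optimised threshold at the first KDE local minimum.

    A Gaussian kernel density estimate (Silverman bandwidth) is
    evaluated on a ``grid_size``-point grid from the smallest to the
    largest distance; interior grid points whose density is strictly
    below both neighbours are local minima and the smallest is the
    threshold.  With no interior minimum the fixed fallback (1%) is
    returned flagged.
    """
    x = np.asarray(distances, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 10:
        raise ValueError(f"threshold optimisation needs >= 10 distances, got {len(x)}")
    bw = silverman_bandwidth(x)
    if bw <= 0 or x.min() == x.max():
        return ThresholdEstimate(
            threshold=FALLBACK_THRESHOLD,
            all_local_minima=(),
            bandwidth=max(bw, 0.0),
            n_distances=len(x),
            fallback=True,
        )
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde_on_grid(x, grid, bw)
    interior = np.arange(1, grid_size - 1)
    is_min = (dens[interior] < dens[interior - 1]) & (dens[interior] < dens[interior + 1])
    minima = grid[interior[is_min]]
    if len(minima) == 0:
        return ThresholdEstimate(
            threshold=FALLBACK_THRESHOLD,
            all_local_minima=(),
            bandwidth=bw,
            n_distances=len(x),
            fallback=True,
        )
    return ThresholdEstimate(
        threshold=float(minima[0]),
        all_local_minima=tuple(float(m) for m in minima),
        bandwidth=bw,
        n_distances=len(x),
    )
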