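"""Pairwise K2P distances and per-dataset divergence summaries.

The Kimura two-parameter estimator corrects observed transition (P) and
transversion (Q) proportions for multiple hits:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites where either sequence carries a gap or missing state are excluded
per pair (pairwise deletion).  Cells where no site is comparable, or
where the logarithms are inadmissible (estimator saturation), are
UNDEFINED and carried as NaN; downstream stages skip and count them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_alignments import BarcodeDataset, SpecimenRecord

#: encoding of bases for vectorised comparison: A,C,G,T -> 0..3, missing -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

METHODS = ("K2P", "raw_substitutions")


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SitePairCounts:
    """Comparable-site, transition and transversion counts for one pair."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("more substitutions than compared sites")

    @property
    def P(self) -> float:
        """Transition proportion (0 when nothing is comparable)."""
        return self.n_transitions / self.n_compared if self.n_compared else 0.0

    @property
    def Q(self) -> float:
        """Transversion proportion (0 when nothing is comparable)."""
        return self.n_transversions / self.n_compared if self.n_compared else 0.0


def encode_sequences(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode sequences into a (n, L) uint8 matrix; A,C,G,T -> 0..3, other -> 4."""
    labels = list(sequences)
    mat = np.frombuffer(
        "".join(sequences[sid] for sid in labels).encode("ascii"), dtype=np.uint8
    ).reshape(len(labels), -1)
    return labels, _CODE[mat]


def count_site_pairs(seq_a: str, seq_b: str) -> SitePairCounts:
    """Count comparable sites, transitions and transversions for one pair.

    Transitions are A<->G and C<->T; every other mismatch among the four
    bases is a transversion.  Columns with a gap, N or ? in either
    sequence are excluded.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = _CODE[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    # with coding A=0,C=1,G=2,T=3, purines are even codes: a transition
    # preserves parity, a transversion flips it
    transitions = diff & ((a & 1) == (b & 1))
    n_ts = int(transitions.sum())
    return SitePairCounts(
        n_compared=int(valid.sum()),
        n_transitions=n_ts,
        n_transversions=int(diff.sum()) - n_ts,
    )


def k2p_distance(counts: SitePairCounts) -> float:
    """K2P distance from site-pair counts; NaN when undefined.

    Undefined when no sites are comparable or when 1-2P-Q <= 0 or
    1-2Q <= 0 (the estimator saturates and the logs leave their domain).
    """
    if counts.n_compared == 0:
        return math.nan
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric specimen-by-specimen distance matrix; NaN marks UNDEFINED."""

    labels: tuple[str, ...]
    d: np.ndarray
    method: str = "K2P"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, label_a: str, label_b: str) -> float:
        return float(self.d[self.index_of(label_a), self.index_of(label_b)])

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.d)

    def to_csv(self, path: str | Path) -> None:
        """Write as a square CSV; UNDEFINED cells serialized as NA."""
        df = pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))
        df.to_csv(path, na_rep="NA", float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, method: str = "K2P") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls(labels=tuple(df.index), d=df.to_numpy(dtype=float), method=method)


def distance_matrix(dataset: BarcodeDataset, method: str = "K2P") -> DistanceMatrix:
    """All-pairs distance matrix over a dataset's (concatenated) sequences.

    ``method="K2P"`` gives substitution-corrected distances;
    ``"raw_substitutions"`` gives the integer transition+transversion
    count per pair (the basis of the divergence index K).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    seqs = dataset.concatenated_sequences()
    if len(seqs) < 2:
        raise ValueError("distance matrix needs at least 2 specimens")
    labels, enc = encode_sequences(seqs)
    n = len(labels)
    valid = enc < 4
    out = np.zeros((n, n), dtype=float)
    parity = enc & 1
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = both & (enc[i] != enc[i + 1 :])
        ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1).astype(float)
        subs = diff.sum(axis=1).astype(float)
        tv = subs - ts
        if method == "raw_substitutions":
            row = np.where(both.sum(axis=1) > 0, subs, np.nan)
        else:
            m = both.sum(axis=1).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                P = np.where(m > 0, ts / m, np.nan)
                Q = np.where(m > 0, tv / m, np.nan)
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                row = np.where(
                    (w1 > 0) & (w2 > 0),
                    -0.5 * np.log(np.maximum(w1, 1e-300))
                    - 0.25 * np.log(np.maximum(w2, 1e-300))
                    + 0.0,
                    np.nan,
                )
        out[i, i + 1 :] = row
        out[i + 1 :, i] = row
    if np.isnan(out[np.triu_indices(n, k=1)]).all():
        raise ValueError("all pairwise distances are undefined")
    return DistanceMatrix(labels=tuple(labels), d=out, method=method)


@dataclass(frozen=True)
class PartitionedDistances:
    """Defined off-diagonal distances split into intra/inter-specific sets."""

    intra: np.ndarray
    inter: np.ndarray
    n_skipped: int

    @property
    def n_pairs(self) -> int:
        return len(self.intra) + len(self.inter) + self.n_skipped

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.intra, self.inter])


def partition_distances(
    matrix: DistanceMatrix, specimens: Sequence[SpecimenRecord]
) -> PartitionedDistances:
    """Split defined pairwise distances into intra- and interspecific lists.

    UNDEFINED cells are skipped and counted.  Each unordered pair is
    assigned exactly once.
    """
    species = {s.specimen_id: s.species for s in specimens}
    missing = [lab for lab in matrix.labels if lab not in species]
    if missing:
        raise ValueError(f"labels without species assignment: {missing}")
    sp = np.array([species[lab] for lab in matrix.labels])
    iu = np.triu_indices(matrix.n, k=1)
    vals = matrix.d[iu]
    same = sp[iu[0]] == sp[iu[1]]
    defined = ~np.isnan(vals)
    return PartitionedDistances(
        intra=vals[defined & same],
        inter=vals[defined & ~same],
        n_skipped=int((~defined).sum()),
    )


@dataclass(frozen=True)
class DistanceSummary:
    """Per-dataset divergence statistics (one row of the marker table).

    ``K`` is the divergence index: the mean number of substitutions
    between any two sequences, rounded half-up to an integer (the
    unrounded mean is kept in ``K_unrounded``).  Intra fields are None
    when the dataset has no conspecific pair; inter fields are None when
    it has a single species.  ``threshold_pct`` is filled in later by
    the threshold optimiser.
    """

    n_sequences: int
    seq_length: int
    K: Optional[int]
    K_unrounded: Optional[float]
    inter_range: Optional[tuple[float, float]]
    inter_mean: Optional[float]
    inter_sd: Optional[float]
    inter_median: Optional[float]
    intra_range: Optional[tuple[float, float]]
    intra_mean: Optional[float]
    intra_sd: Optional[float]
    intra_median: Optional[float]
    n_skipped_pairs: int = 0
    threshold_pct: Optional[float] = None


def _stats(values: np.ndarray) -> tuple:
    if len(values) == 0:
        return (None, None, None, None)
    rng = (float(values.min()), float(values.max()))
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    median = float(np.median(values))
    return (rng, mean, sd, median)


def summarize(
    matrix_k2p: DistanceMatrix,
    matrix_raw: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    seq_length: int,
) -> DistanceSummary:
    """Build the marker-table row: K index plus intra/inter statistics."""
    if matrix_k2p.labels != matrix_raw.labels:
        raise ValueError("K2P and raw matrices must share labels")
    iu = np.triu_indices(matrix_raw.n, k=1)
    raw_vals = matrix_raw.d[iu]
    raw_defined = raw_vals[~np.isnan(raw_vals)]
    if len(raw_defined):
        k_mean = float(raw_defined.mean())
        K, K_un = round_half_up(k_mean), k_mean
    else:
        K, K_un = None, None
    parts = partition_distances(matrix_k2p, specimens)
    inter_rng, inter_mean, inter_sd, inter_median = _stats(parts.inter)
    intra_rng, intra_mean, intra_sd, intra_median = _stats(parts.intra)
    return DistanceSummary(
        n_sequences=matrix_k2p.n,
        seq_length=seq_length,
        K=K,
        K_unrounded=K_un,
        inter_range=inter_rng,
        inter_mean=inter_mean,
        inter_sd=inter_sd,
        inter_median=inter_median,
        intra_range=intra_rng,
        intra_mean=intra_mean,
        intra_sd=intra_sd,
        intra_median=intra_median,
        n_skipped_pairs=parts.n_skipped,
    )
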