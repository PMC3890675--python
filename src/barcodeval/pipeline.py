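"""End-to-end marker evaluation: distances, gap, identification, monophyly.

For every requested dataset (single markers, then marker combinations)
and every requested taxonomic level the pipeline computes the
divergence summary, the per-sequence barcode-gap proportion, the three
identification criteria (best close match at the policy threshold, the
BOLD rule at a fixed 1%, and near neighbour) and neighbour-joining
species monophyly.  Everything is deterministic given the configuration
and seed; degenerate subsets are flagged, never silently dropped.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import barcode_gap, identification, io_alignments, trees
from .distances import (
    DistanceMatrix,
    DistanceSummary,
    distance_matrix,
    partition_distances,
    summarize,
)
from .io_alignments import BarcodeDataset, MarkerAlignment, SpecimenRecord
from .synthetic_data import SimParams, simulate_dataset

THRESHOLD_POLICIES = ("level_optimised", "family_level", "fixed")
#: sections need this many distinct species to be evaluated
MIN_SECTION_SPECIES = 3


@dataclass(frozen=True)
class EvalConfig:
    """Declarative description of one evaluation run.

    Exactly one of ``sim`` or (``marker_files`` + ``metadata_path``)
    must be given.  ``combinations`` lists marker-name lists to
    concatenate; ``None`` selects the default panel: every single
    marker, the core pair (first two markers), core plus each remaining
    marker, and all markers together.  ``threshold_policy`` is
    ``"level_optimised"`` (re-optimise per subset), ``"family_level"``
    (reuse the family-level optimum at lower levels) or ``"fixed"``
    with ``fixed_threshold``.  The BOLD rule always runs at
    ``bold_threshold`` regardless of the policy.
    """

    sim: Optional[SimParams] = None
    marker_files: Optional[dict[str, str]] = None
    metadata_path: Optional[str] = None
    combinations: Optional[tuple[tuple[str, ...], ...]] = None
    levels: tuple[tuple[str, str], ...] = (("family", "ALL"),)
    threshold_policy: str = "level_optimised"
    fixed_threshold: Optional[float] = None
    bold_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.marker_files is None):
            raise ValueError("give either sim params or marker files, not both")
        if self.marker_files is not None and self.metadata_path is None:
            raise ValueError("marker files require a metadata path")
        if self.threshold_policy not in THRESHOLD_POLICIES:
            raise ValueError(
                f"unknown threshold policy {self.threshold_policy!r}; "
                f"use one of {THRESHOLD_POLICIES}"
            )
        if self.threshold_policy == "fixed" and (
            self.fixed_threshold is None or self.fixed_threshold <= 0
        ):
            raise ValueError("fixed policy requires a positive fixed_threshold")
        if self.bold_threshold <= 0:
            raise ValueError("bold_threshold must be > 0")
        for level, _ in self.levels:
            if level not in io_alignments.TAXON_LEVELS:
                raise ValueError(f"unknown level {level!r}")

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict() if self.sim else None,
            "marker_files": dict(self.marker_files) if self.marker_files else None,
            "metadata_path": self.metadata_path,
            "combinations": [list(c) for c in self.combinations]
            if self.combinations
            else None,
            "levels": [list(lv) for lv in self.levels],
            "threshold_policy": self.threshold_policy,
            "fixed_threshold": self.fixed_threshold,
            "bold_threshold": self.bold_threshold,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class EvalBlock:
    """All statistics for one (dataset, level, taxon) cell of the report."""

    dataset_label: str
    level: str
    taxon: str
    n_specimens: int
    n_species: int
    n_dropped_missing_marker: int
    n_dropped_undefined: int
    degenerate: bool = False
    degenerate_reason: Optional[str] = None
    distance_summary: Optional[DistanceSummary] = None
    gap_summary: Optional[barcode_gap.GapSummary] = None
    gap_records: tuple = ()
    overlap: Optional[barcode_gap.OverlapReport] = None
    threshold: Optional[identification.ThresholdEstimate] = None
    id_summaries: dict = field(default_factory=dict)
    id_outcomes: dict = field(default_factory=dict)
    monophyly: Optional[trees.MonophylyReport] = None
    nj_newick: Optional[str] = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class EvalReport:
    config: EvalConfig
    blocks: tuple[EvalBlock, ...]
    n_input_specimens: int

    def block(self, dataset_label: str, level: str = "family", taxon: str = "ALL"):
        for b in self.blocks:
            if (b.dataset_label, b.level, b.taxon) == (dataset_label, level, taxon):
                return b
        raise KeyError((dataset_label, level, taxon))


def default_combinations(marker_names: Sequence[str]) -> tuple[tuple[str, ...], ...]:
    """Singles, the core pair, core + each supplement, and all markers."""
    names = list(marker_names)
    combos: list[tuple[str, ...]] = [(n,) for n in names]
    if len(names) >= 2:
        core = tuple(names[:2])
        combos.append(core)
        for extra in names[2:]:
            combos.append(core + (extra,))
        if len(names) > 3:
            combos.append(tuple(names))
    return tuple(combos)


def _load_inputs(
    config: EvalConfig,
) -> tuple[dict[str, MarkerAlignment], tuple[SpecimenRecord, ...]]:
    if config.sim is not None:
        sim = simulate_dataset(config.sim)
        return dict(sim.alignments), sim.specimens
    alignments = {
        name: io_alignments.read_fasta_alignment(path, name)
        for name, path in config.marker_files.items()
    }
    specimens = tuple(io_alignments.read_metadata(config.metadata_path))
    return alignments, specimens


def _build_dataset(
    combo: Sequence[str],
    alignments: dict[str, MarkerAlignment],
    specimens: Sequence[SpecimenRecord],
) -> BarcodeDataset:
    missing = [m for m in combo if m not in alignments]
    if missing:
        raise ValueError(f"combination references unknown markers: {missing}")
    if len(combo) == 1:
        return io_alignments.single_marker_dataset(alignments[combo[0]], specimens)
    return io_alignments.concatenate(
        [alignments[m] for m in combo], specimens, label="+".join(combo)
    )


def apply_threshold_policy(
    config: EvalConfig,
    pooled_distances,
    family_estimate: Optional[identification.ThresholdEstimate],
    level: str,
) -> tuple[identification.ThresholdEstimate, list[str]]:
    """Pick the best-close-match threshold for one block.

    ``level_optimised`` re-optimises on the block's own pooled
    distances, falling back to the family estimate when fewer than 10
    are available; ``family_level`` reuses the family estimate below
    family rank; ``fixed`` wraps the configured constant.
    """
    warnings: list[str] = []
    if config.threshold_policy == "fixed":
        est = identification.ThresholdEstimate(
            threshold=config.fixed_threshold,
            all_local_minima=(),
            bandwidth=0.0,
            n_distances=len(pooled_distances),
            fallback=False,
        )
        return est, warnings
    if config.threshold_policy == "family_level" and level != "family":
        if family_estimate is None:
            raise ValueError("family_level policy needs a family-level estimate")
        return family_estimate, warnings
    if len(pooled_distances) < 10:
        if family_estimate is not None:
            warnings.append(
                "THRESHOLD_FALLBACK_FAMILY: fewer than 10 distances; "
                "reusing family-level threshold"
            )
            return family_estimate, warnings
        warnings.append(
            "THRESHOLD_FALLBACK_DEFAULT: fewer than 10 distances; using 1%"
        )
        return (
            identification.ThresholdEstimate(
                threshold=identification.FALLBACK_THRESHOLD,
                all_local_minima=(),
                bandwidth=0.0,
                n_distances=len(pooled_distances),
                fallback=True,
            ),
            warnings,
        )
    est = identification.local_minima_threshold(pooled_distances)
    if est.fallback:
        warnings.append("THRESHOLD_FALLBACK_KDE: no interior KDE minimum; using 1%")
    return est, warnings


def _evaluate_block(
    dataset: BarcodeDataset,
    level: str,
    taxon: str,
    config: EvalConfig,
    family_estimate: Optional[identification.ThresholdEstimate],
    n_input_specimens: int,
) -> EvalBlock:
    warnings: list[str] = []
    ids = dataset.specimen_ids
    n_dropped_missing = n_input_specimens - len(ids)
    base = dict(
        dataset_label=dataset.combination_label,
        level=level,
        taxon=taxon,
        n_specimens=len(ids),
        n_species=dataset.n_species,
        n_dropped_missing_marker=n_dropped_missing,
    )
    if dataset.n_species < 2:
        return EvalBlock(
            **base,
            n_dropped_undefined=0,
            degenerate=True,
            degenerate_reason="fewer than 2 species",
        )
    if level == "section" and dataset.n_species < MIN_SECTION_SPECIES:
        return EvalBlock(
            **base,
            n_dropped_undefined=0,
            degenerate=True,
            degenerate_reason=(
                f"section has {dataset.n_species} species; "
                f"at least {MIN_SECTION_SPECIES} required"
            ),
        )

    specimens = [dataset.record_of(sid) for sid in ids]
    m_k2p = distance_matrix(dataset, method="K2P")
    m_raw = distance_matrix(dataset, method="raw_substitutions")
    summary = summarize(m_k2p, m_raw, specimens, dataset.total_length)
    parts = partition_distances(m_k2p, specimens)
    overlap = barcode_gap.distribution_overlap(parts.intra, parts.inter)
    records, gap_excluded = barcode_gap.gap_records(m_k2p, specimens)
    gsum = barcode_gap.gap_summary(records, n_excluded=gap_excluded)

    est, thr_warnings = apply_threshold_policy(
        config, parts.pooled(), family_estimate, level
    )
    warnings.extend(thr_warnings)

    nn_out, nn_sum = identification.near_neighbour(m_k2p, specimens)
    bcm_out, bcm_sum = identification.best_close_match(m_k2p, specimens, est.threshold)
    bold_out, bold_sum = identification.thresh_id(
        m_k2p, specimens, config.bold_threshold
    )

    # NJ monophyly on specimens with fully defined distances
    defined_rows = [
        i for i in range(m_k2p.n) if not np.isnan(np.delete(m_k2p.d[i], i)).any()
    ]
    n_dropped_undefined = m_k2p.n - len(defined_rows)
    monophyly = None
    nj_newick = None
    if n_dropped_undefined:
        warnings.append(
            f"DROPPED_UNDEFINED_DISTANCE: {n_dropped_undefined} specimen(s) "
            "excluded from the NJ tree"
        )
    if len(defined_rows) >= 3:
        sub = DistanceMatrix(
            labels=tuple(m_k2p.labels[i] for i in defined_rows),
            d=m_k2p.d[np.ix_(defined_rows, defined_rows)],
            method="K2P",
        )
        tree = trees.nj_tree(sub)
        monophyly = trees.species_monophyly(tree, specimens)
        nj_newick = tree.newick()
    else:
        warnings.append("NJ_SKIPPED: fewer than 3 specimens with complete distances")

    summary = replace(summary, threshold_pct=est.threshold_pct)
    n_singletons = sum(1 for r in records if r.singleton)
    if n_singletons:
        warnings.append(f"SINGLETON_SPECIES: {n_singletons} singleton specimen(s)")
    return EvalBlock(
        **base,
        n_dropped_undefined=n_dropped_undefined,
        degenerate=dataset.degenerate,
        distance_summary=summary,
        gap_summary=gsum,
        gap_records=tuple(records),
        overlap=overlap,
        threshold=est,
        id_summaries={
            "near_neighbour": nn_sum,
            "best_close_match": bcm_sum,
            "thresh_id": bold_sum,
        },
        id_outcomes={
            "near_neighbour": tuple(nn_out),
            "best_close_match": tuple(bcm_out),
            "thresh_id": tuple(bold_out),
        },
        monophyly=monophyly,
        nj_newick=nj_newick,
        warnings=tuple(warnings),
    )


def run_evaluation(config: EvalConfig) -> EvalReport:
    """Run the full evaluation grid defined by ``config``."""
    alignments, specimens = _load_inputs(config)
    combos = config.combinations or default_combinations(list(alignments))
    n_input = len(specimens)
    blocks: list[EvalBlock] = []
    for combo in combos:
        dataset = _build_dataset(combo, alignments, specimens)
        family_block = _evaluate_block(
            dataset, "family", "ALL", config, None, n_input
        )
        family_est = family_block.threshold
        blocks.append(family_block)
        for level, taxon in config.levels:
            if level == "family":
                continue
            taxa = (
                sorted(
                    {
                        getattr(s, level)
                        for s in dataset.specimens
                        if getattr(s, level) is not None
                    }
                )
                if taxon == "ALL"
                else [taxon]
            )
            for name in taxa:
                try:
                    sub = io_alignments.subset_by_taxon(dataset, level, name)
                except io_alignments.DatasetError as exc:
                    blocks.append(
                        EvalBlock(
                            dataset_label=dataset.combination_label,
                            level=level,
                            taxon=name,
                            n_specimens=0,
                            n_species=0,
                            n_dropped_missing_marker=n_input,
                            n_dropped_undefined=0,
                            degenerate=True,
                            degenerate_reason=str(exc),
                        )
                    )
                    continue
                blocks.append(
                    _evaluate_block(sub, level, name, config, family_est, n_input)
                )
    return EvalReport(
        config=config, blocks=tuple(blocks), n_input_specimens=n_input
    )


# ---------------------------------------------------------------------------
# rendering


def _fmt(x, digits: int = 6) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:.{digits}g}"
    return str(x)


def render_report(report: EvalReport, outdir: str | Path) -> list[Path]:
    """Write the report as CSV tables plus a plain-text summary.

    Deterministic: identical reports produce byte-identical files.
    Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def table(name: str, header: list[str], rows: list[list]) -> None:
        path = outdir / name
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            writer.writerows(rows)
        written.append(path)

    # marker statistics (divergence summary per dataset x level)
    rows = []
    for b in report.blocks:
        s = b.distance_summary
        rows.append(
            [
                b.dataset_label,
                b.level,
                b.taxon,
                b.n_specimens,
                _fmt(s.seq_length if s else None),
                _fmt(s.K if s else None),
                _fmt(s.inter_range[0] if s and s.inter_range else None),
                _fmt(s.inter_range[1] if s and s.inter_range else None),
                _fmt(s.inter_mean if s else None),
                _fmt(s.inter_sd if s else None),
                _fmt(s.inter_median if s else None),
                _fmt(s.intra_range[0] if s and s.intra_range else None),
                _fmt(s.intra_range[1] if s and s.intra_range else None),
                _fmt(s.intra_mean if s else None),
                _fmt(s.intra_sd if s else None),
                _fmt(s.intra_median if s else None),
                _fmt(s.threshold_pct if s else None, 4),
                b.degenerate,
            ]
        )
    table(
        "marker_summary.csv",
        [
            "dataset",
            "level",
            "taxon",
            "n_seq",
            "seq_length",
            "K",
            "inter_min",
            "inter_max",
            "inter_mean",
            "inter_sd",
            "inter_median",
            "intra_min",
            "intra_max",
            "intra_mean",
            "intra_sd",
            "intra_median",
            "threshold_pct",
            "degenerate",
        ],
        rows,
    )

    # barcode gap
    rows = [
        [
            b.dataset_label,
            b.level,
            b.taxon,
            b.gap_summary.n_sequences,
            b.gap_summary.n_without_gap,
            b.gap_summary.pct_with_gap,
            b.gap_summary.n_excluded,
        ]
        for b in report.blocks
        if b.gap_summary
    ]
    table(
        "gap_summary.csv",
        ["dataset", "level", "taxon", "n_seq", "n_without_gap", "pct_with_gap", "n_excluded"],
        rows,
    )

    # identification
    rows = []
    for b in report.blocks:
        for crit in ("near_neighbour", "thresh_id", "best_close_match"):
            s = b.id_summaries.get(crit)
            if s is None:
                continue
            for category, pct in s.percentages.items():
                rows.append(
                    [
                        b.dataset_label,
                        b.level,
                        b.taxon,
                        crit,
                        category,
                        s.counts[category],
                        pct,
                        _fmt(
                            b.threshold.threshold_pct
                            if crit == "best_close_match" and b.threshold
                            else (
                                100.0 * report.config.bold_threshold
                                if crit == "thresh_id"
                                else None
                            ),
                            4,
                        ),
                    ]
                )
    table(
        "identification.csv",
        ["dataset", "level", "taxon", "criterion", "category", "count", "pct", "threshold_pct"],
        rows,
    )

    # monophyly
    rows = []
    for b in report.blocks:
        if b.monophyly is None:
            continue
        m = b.monophyly
        rows.append(
            [
                b.dataset_label,
                b.level,
                b.taxon,
                m.n_species,
                m.n_monophyletic,
                m.pct_monophyletic,
                _fmt(m.pct_monophyletic_multi),
            ]
        )
    table(
        "monophyly_summary.csv",
        [
            "dataset",
            "level",
            "taxon",
            "n_species",
            "n_monophyletic",
            "pct_monophyletic",
            "pct_monophyletic_multi",
        ],
        rows,
    )

    # per-species monophyly
    rows = []
    for b in report.blocks:
        if b.monophyly is None:
            continue
        for r in b.monophyly.records:
            rows.append(
                [b.dataset_label, b.level, b.taxon, r.species, r.n_specimens, r.monophyletic, r.singleton]
            )
    table(
        "monophyly_species.csv",
        ["dataset", "level", "taxon", "species", "n_specimens", "monophyletic", "singleton"],
        rows,
    )

    # per-query outcomes
    rows = []
    for b in report.blocks:
        for crit, outcomes in sorted(b.id_outcomes.items()):
            for o in outcomes:
                rows.append(
                    [
                        b.dataset_label,
                        b.level,
                        b.taxon,
                        crit,
                        o.specimen_id,
                        o.species,
                        o.category,
                        _fmt(o.distance_to_best),
                        _fmt(o.threshold_used, 4),
                    ]
                )
    table(
        "query_outcomes.csv",
        [
            "dataset",
            "level",
            "taxon",
            "criterion",
            "specimen_id",
            "species",
            "category",
            "distance_to_best",
            "threshold_used",
        ],
        rows,
    )

    # per-specimen gap records
    rows = []
    for b in report.blocks:
        for r in b.gap_records:
            rows.append(
                [
                    b.dataset_label,
                    b.level,
                    b.taxon,
                    r.specimen_id,
                    r.species,
                    _fmt(r.max_intra),
                    _fmt(r.min_inter),
                    r.has_gap,
                    r.singleton,
                ]
            )
    table(
        "gap_records.csv",
        ["dataset", "level", "taxon", "specimen_id", "species", "max_intra", "min_inter", "has_gap", "singleton"],
        rows,
    )

    # NJ trees
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    for b in report.blocks:
        if b.nj_newick is None:
            continue
        safe = f"{b.dataset_label}_{b.level}_{b.taxon}".replace("+", "-").replace(" ", "_")
        path = tree_dir / f"{safe}.nwk"
        path.write_text(b.nj_newick + "\n")
        written.append(path)

    # warnings and provenance
    rows = [
        [b.dataset_label, b.level, b.taxon, w]
        for b in report.blocks
        for w in b.warnings
    ]
    table("warnings.csv", ["dataset", "level", "taxon", "warning"], rows)

    config_json = json.dumps(report.config.to_dict(), sort_keys=True, indent=2)
    provenance = {
        "config": report.config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": report.config.seed,
        "n_input_specimens": report.n_input_specimens,
        "n_blocks": len(report.blocks),
    }
    prov_path = outdir / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(prov_path)

    # human-readable digest
    lines = [f"barcode evaluation: {len(report.blocks)} blocks", ""]
    for b in report.blocks:
        head = f"[{b.dataset_label} | {b.level} | {b.taxon}]"
        if b.degenerate and b.distance_summary is None:
            lines.append(f"{head} degenerate: {b.degenerate_reason}")
            continue
        parts = [f"n={b.n_specimens}", f"species={b.n_species}"]
        if b.gap_summary:
            parts.append(f"gap%={b.gap_summary.pct_with_gap}")
        bcm = b.id_summaries.get("best_close_match")
        if bcm:
            parts.append(f"BCM correct%={bcm.percentages['correct']}")
        if b.monophyly:
            parts.append(f"monophyly%={b.monophyly.pct_monophyletic}")
        lines.append(f"{head} " + " ".join(parts))
    summary_path = outdir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    written.append(summary_path)
    return written
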