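"""Reading, validation and assembly of aligned barcode datasets.

A *dataset* couples one or more per-marker alignments (equal-length,
gapped FASTA) with a specimen metadata table carrying the taxonomic
hierarchy (species, genus, subgenus, section).  Multi-marker datasets are
built by concatenation over the specimens shared by every member marker,
so identification statistics are always computed on a complete matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN-?")
#: states excluded from pairwise comparisons
MISSING_STATES = frozenset("N-?")

TAXON_LEVELS = ("family", "subgenus", "section")


class AlignmentError(ValueError):
    """Malformed or inconsistent sequence alignment."""


class MetadataError(ValueError):
    """Malformed specimen metadata table."""


class DatasetError(ValueError):
    """Inconsistent combination of alignments and metadata."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One voucher/accession with its taxonomic placement.

    ``species`` is the binomial used for intra/interspecific
    partitioning; ``subgenus`` and ``section`` are optional ranks used
    for level-stratified analyses.  A record with a section must also
    carry a subgenus.
    """

    specimen_id: str
    species: str
    genus: Optional[str] = None
    subgenus: Optional[str] = None
    section: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise MetadataError("specimen_id must be non-empty")
        if not self.species:
            raise MetadataError(f"specimen {self.specimen_id!r}: species must be non-empty")
        if self.section is not None and self.subgenus is None:
            raise MetadataError(
                f"specimen {self.specimen_id!r}: section set without subgenus"
            )


@dataclass(frozen=True)
class MarkerAlignment:
    """An aligned set of sequences for one marker.

    Sequences are stored uppercase over ``{A,C,G,T,N,-,?}``; all must
    have exactly ``length`` columns.
    """

    marker_name: str
    sequences: Mapping[str, str]
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AlignmentError(f"{self.marker_name}: non-positive alignment length")
        if len(self.sequences) < 2:
            raise AlignmentError(
                f"{self.marker_name}: alignment needs at least 2 sequences, "
                f"got {len(self.sequences)}"
            )
        for sid, seq in self.sequences.items():
            if len(seq) != self.length:
                raise AlignmentError(
                    f"{self.marker_name}: sequence {sid!r} has length {len(seq)}, "
                    f"expected {self.length}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise AlignmentError(
                    f"{self.marker_name}: sequence {sid!r} has illegal character "
                    f"{seq[pos]!r} at column {pos + 1}"
                )

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class MarkerPartition:
    """1-based inclusive column range of one marker in a concatenation."""

    marker_name: str
    start: int
    end: int


@dataclass(frozen=True)
class BarcodeDataset:
    """Alignments joined to metadata for one marker or marker combination."""

    specimens: tuple[SpecimenRecord, ...]
    alignments: tuple[MarkerAlignment, ...]
    combination_label: str
    partitions: tuple[MarkerPartition, ...] = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.alignments:
            raise DatasetError("dataset needs at least one alignment")
        known = {s.specimen_id for s in self.specimens}
        if len(known) != len(self.specimens):
            raise DatasetError("duplicate specimen_id in metadata")
        for aln in self.alignments:
            missing = set(aln.sequences) - known
            if missing:
                raise DatasetError(
                    f"specimens {sorted(missing)} in alignment "
                    f"{aln.marker_name!r} lack metadata"
                )
        if len(self.alignments) > 1:
            shared = set.intersection(*(set(a.sequences) for a in self.alignments))
            for aln in self.alignments:
                if set(aln.sequences) != shared:
                    raise DatasetError(
                        "multi-marker dataset must hold identical specimen sets "
                        "per member alignment (use concatenate())"
                    )

    @property
    def specimen_ids(self) -> list[str]:
        """Specimens present in every member alignment, in metadata order."""
        shared = set.intersection(*(set(a.sequences) for a in self.alignments))
        return [s.specimen_id for s in self.specimens if s.specimen_id in shared]

    @property
    def species_of(self) -> dict[str, str]:
        return {s.specimen_id: s.species for s in self.specimens}

    @property
    def n_species(self) -> int:
        ids = set(self.specimen_ids)
        return len({s.species for s in self.specimens if s.specimen_id in ids})

    @property
    def total_length(self) -> int:
        return sum(a.length for a in self.alignments)

    def concatenated_sequences(self) -> dict[str, str]:
        """Per-specimen sequences joined across member alignments."""
        return {
            sid: "".join(a.sequences[sid] for a in self.alignments)
            for sid in self.specimen_ids
        }

    def record_of(self, specimen_id: str) -> SpecimenRecord:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)


def _header_token(description: str) -> str:
    """First pipe/whitespace-delimited token of a FASTA header."""
    return description.replace("|", " ").split()[0]


def read_fasta_alignment(path: str | Path, marker_name: str) -> MarkerAlignment:
    """Read an aligned FASTA file into a :class:`MarkerAlignment`.

    The specimen id is the first pipe/whitespace-delimited header token.
    Characters are uppercased and U is mapped to T.  Raises
    :class:`AlignmentError` on ragged lengths, duplicate ids or illegal
    characters.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    length: Optional[int] = None
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = _header_token(rec.description or rec.id)
        if sid in sequences:
            raise AlignmentError(f"{path.name}: duplicate specimen id {sid!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"{path.name}: sequence {sid!r} has length {len(seq)}, "
                f"expected {length}"
            )
        sequences[sid] = seq
    if length is None:
        raise AlignmentError(f"{path.name}: no FASTA records found")
    return MarkerAlignment(marker_name=marker_name, sequences=sequences, length=length)


def write_fasta_alignment(alignment: MarkerAlignment, path: str | Path) -> None:
    """Write an alignment as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in alignment.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read a delimited specimen table (CSV or TSV, sniffed from header).

    Mandatory columns: ``specimen_id``, ``species``.  Optional:
    ``genus``, ``subgenus``, ``section`` (empty cells left unset).
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.DictReader(text.splitlines(), delimiter=delimiter))
    if not rows:
        raise MetadataError(f"{path.name}: empty metadata table")
    cols = set(rows[0])
    for mandatory in ("specimen_id", "species"):
        if mandatory not in cols:
            raise MetadataError(f"{path.name}: missing mandatory column {mandatory!r}")
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for row in rows:
        sid = (row["specimen_id"] or "").strip()
        if sid in seen:
            raise MetadataError(f"{path.name}: duplicate specimen_id {sid!r}")
        seen.add(sid)
        optional = {
            k: (row.get(k) or "").strip() or None
            for k in ("genus", "subgenus", "section")
        }
        records.append(
            SpecimenRecord(specimen_id=sid, species=(row["species"] or "").strip(), **optional)
        )
    return records


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "species", "genus", "subgenus", "section"])
        for r in records:
            writer.writerow(
                [r.specimen_id, r.species, r.genus or "", r.subgenus or "", r.section or ""]
            )


def single_marker_dataset(
    alignment: MarkerAlignment,
    specimens: Iterable[SpecimenRecord],
    label: Optional[str] = None,
) -> BarcodeDataset:
    """Couple one alignment to metadata, keeping only sequenced specimens."""
    kept = tuple(s for s in specimens if s.specimen_id in alignment.sequences)
    return BarcodeDataset(
        specimens=kept,
        alignments=(alignment,),
        combination_label=label or alignment.marker_name,
        partitions=(MarkerPartition(alignment.marker_name, 1, alignment.length),),
    )


def concatenate(
    alignments: Sequence[MarkerAlignment],
    specimens: Iterable[SpecimenRecord],
    label: Optional[str] = None,
) -> BarcodeDataset:
    """Concatenate ≥2 marker alignments over their shared specimens.

    Only specimens sequenced for *every* member marker are retained
    (intersection rule), so the combined specimen count never exceeds
    the smallest member count.  Marker boundaries are recorded as
    1-based inclusive column ranges.
    """
    if len(alignments) < 2:
        raise DatasetError("concatenate() needs at least 2 alignments")
    shared = set.intersection(*(set(a.sequences) for a in alignments))
    if len(shared) < 2:
        raise DatasetError(
            f"concatenation leaves {len(shared)} shared specimen(s); "
            "at least 2 are required"
        )
    trimmed = tuple(
        MarkerAlignment(
            marker_name=a.marker_name,
            sequences={sid: a.sequences[sid] for sid in a.sequences if sid in shared},
            length=a.length,
        )
        for a in alignments
    )
    partitions = []
    offset = 0
    for a in trimmed:
        partitions.append(MarkerPartition(a.marker_name, offset + 1, offset + a.length))
        offset += a.length
    kept = tuple(s for s in specimens if s.specimen_id in shared)
    return BarcodeDataset(
        specimens=kept,
        alignments=trimmed,
        combination_label=label or "+".join(a.marker_name for a in alignments),
        partitions=tuple(partitions),
    )


def write_partition_sidecar(dataset: BarcodeDataset, path: str | Path) -> None:
    """Write marker boundary offsets (marker, start, end; 1-based inclusive)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["marker_name", "start", "end"])
        for p in dataset.partitions:
            writer.writerow([p.marker_name, p.start, p.end])


def subset_by_taxon(dataset: BarcodeDataset, level: str, name: str) -> BarcodeDataset:
    """Restrict a dataset to one taxon at ``level``.

    ``family`` level returns the dataset unchanged.  A subset retaining
    fewer than two species is returned flagged as degenerate
    (identification statistics are undefined on it).
    """
    if level not in TAXON_LEVELS:
        raise DatasetError(f"unknown taxonomic level {level!r}; use one of {TAXON_LEVELS}")
    if level == "family":
        return dataset
    keep_ids = {
        s.specimen_id for s in dataset.specimens if getattr(s, level) == name
    }
    if not keep_ids:
        raise DatasetError(f"no specimens with {level} == {name!r}")
    kept_specimens = tuple(s for s in dataset.specimens if s.specimen_id in keep_ids)
    new_alignments = []
    for a in dataset.alignments:
        seqs = {sid: seq for sid, seq in a.sequences.items() if sid in keep_ids}
        if len(seqs) < 2:
            raise DatasetError(
                f"{level} {name!r}: fewer than 2 sequenced specimens for "
                f"marker {a.marker_name!r}"
            )
        new_alignments.append(
            MarkerAlignment(marker_name=a.marker_name, sequences=seqs, length=a.length)
        )
    n_species = len({s.species for s in kept_specimens})
    return BarcodeDataset(
        specimens=kept_specimens,
        alignments=tuple(new_alignments),
        combination_label=dataset.combination_label,
        partitions=dataset.partitions,
        degenerate=n_species < 2,
    )
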