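"""Alignment, clade-map and domain-annotation I/O plus coordinate conversion.

The central container is :class:`LabeledAlignment`: an aligned protein
family whose sequences carry clade labels, with one designated reference
sequence per clade.  Site positions reported downstream are residue numbers
in the ungapped coordinates of the focal clade's reference sequence, which
is how conserved-site tables are conventionally numbered.

File formats
------------
* Alignment: aligned FASTA ('-' canonical gap, '.' normalised to '-',
  residues uppercased).
* Clade map: TSV ``seq_id<TAB>clade[<TAB>ref]`` — a third field ``ref``
  (or ``*``/``reference``) flags the clade's reference sequence.  When no
  member of a clade is flagged, the first member in file order is used.
* Domain annotation: a header line ``reference<TAB><seq_id>[<TAB><length>]``
  followed by rows ``label<TAB>start<TAB>end`` (1-based inclusive, reference
  ungapped coordinates, non-overlapping, sorted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    ColumnOutOfRangeError,
    DomainRangeError,
    DuplicateSequenceError,
    RaggedAlignmentError,
    ReferenceError_,
    UnmappedSequenceError,
)

GAP = "-"
_REF_FLAGS = {"ref", "reference", "*", "1", "true", "yes"}

PathLike = Union[str, Path]


def _normalize_row(row: str) -> str:
    return row.upper().replace(".", GAP)


@dataclass(frozen=True)
class LabeledAlignment:
    """Equal-length gapped sequences with clade labels and per-clade references.

    Invariants (checked on construction): all rows equal length >= 1, unique
    seq ids, every id mapped to a clade, >= 2 distinct clades, each reference
    a member of its own clade.
    """

    records: tuple[tuple[str, str], ...]
    clade_of: dict[str, str]
    reference_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        records = tuple((sid, _normalize_row(row)) for sid, row in self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise RaggedAlignmentError("alignment has no sequences")
        length = len(records[0][1])
        if length < 1:
            raise RaggedAlignmentError("alignment rows must have length >= 1")
        seen: set[str] = set()
        for sid, row in records:
            if len(row) != length:
                raise RaggedAlignmentError(
                    f"ragged alignment: {sid!r} has length {len(row)}, expected {length}"
                )
            if sid in seen:
                raise DuplicateSequenceError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
            if sid not in self.clade_of:
                raise UnmappedSequenceError(f"unmapped sequence: {sid!r} not in clade map")
        clades = set(self.clade_of[sid] for sid, _ in records)
        if len(clades) < 2:
            raise UnmappedSequenceError("need at least 2 distinct clades")
        reference_of = dict(self.reference_of)
        for clade in sorted(clades):
            ref = reference_of.get(clade)
            if ref is None:
                ref = next(sid for sid, _ in records if self.clade_of[sid] == clade)
                reference_of[clade] = ref
            elif ref not in seen or self.clade_of[ref] != clade:
                raise ReferenceError_(
                    f"reference {ref!r} for clade {clade!r} is not a member of that clade"
                )
        object.__setattr__(self, "reference_of", reference_of)

    # -- basic accessors -------------------------------------------------

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def seq_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    @property
    def clades(self) -> tuple[str, ...]:
        """Distinct clade labels, sorted."""
        return tuple(sorted(set(self.clade_of[sid] for sid in self.seq_ids)))

    def row(self, seq_id: str) -> str:
        for sid, r in self.records:
            if sid == seq_id:
                return r
        raise KeyError(seq_id)

    def members(self, clade: str) -> tuple[str, ...]:
        return tuple(sid for sid in self.seq_ids if self.clade_of[sid] == clade)

    def column(self, column: int) -> str:
        """Characters of a 1-based column, in row order."""
        self._check_column(column)
        return "".join(row[column - 1] for _, row in self.records)

    def to_array(self) -> np.ndarray:
        """(n_sequences, n_columns) array of single characters."""
        return np.array([list(row) for _, row in self.records], dtype="<U1")

    def _check_column(self, column: int) -> None:
        if not 1 <= column <= self.n_columns:
            raise ColumnOutOfRangeError(
                f"column {column} out of range 1..{self.n_columns}"
            )


# -- reading and writing -------------------------------------------------


def read_clade_map(path: PathLike) -> tuple[dict[str, str], dict[str, str]]:
    """Parse a clade-map TSV into (clade_of, reference_of)."""
    clade_of: dict[str, str] = {}
    reference_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise UnmappedSequenceError(
                    f"{path}:{lineno}: expected seq_id<TAB>clade, got {line!r}"
                )
            sid, clade = fields[0].strip(), fields[1].strip()
            if sid in clade_of:
                raise DuplicateSequenceError(f"{path}:{lineno}: duplicate seq_id {sid!r}")
            clade_of[sid] = clade
            if len(fields) >= 3 and fields[2].strip().lower() in _REF_FLAGS:
                reference_of[clade] = sid
    return clade_of, reference_of


def read_alignment(fasta_path: PathLike, clade_map_path: PathLike) -> LabeledAlignment:
    """Read an aligned FASTA plus clade-map TSV into a validated alignment.

    '.' gaps are normalised to '-' and residues uppercased.  Distinct named
    errors are raised for ragged rows, duplicate ids and FASTA ids missing
    from the clade map.
    """
    records = tuple(
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")
    )
    clade_of, reference_of = read_clade_map(clade_map_path)
    return LabeledAlignment(records=records, clade_of=clade_of, reference_of=reference_of)


def write_alignment(aln: LabeledAlignment, fasta_path: PathLike,
                    clade_map_path: Optional[PathLike] = None) -> None:
    """Write aligned FASTA (and optionally the clade map with ref flags)."""
    seqs = [SeqRecord(Seq(row), id=sid, description="") for sid, row in aln.records]
    with open(fasta_path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")
    if clade_map_path is not None:
        with open(clade_map_path, "w") as fh:
            for sid in aln.seq_ids:
                clade = aln.clade_of[sid]
                flag = "\tref" if aln.reference_of.get(clade) == sid else ""
                fh.write(f"{sid}\t{clade}{flag}\n")


# -- coordinate conversion -----------------------------------------------


def column_to_refpos(aln: LabeledAlignment, ref_id: str, column: int) -> Optional[int]:
    """Residue number of 1-based ``column`` in ``ref_id``'s ungapped sequence.

    Counts non-gap characters of the reference row up to and including the
    column; returns ``None`` when the reference itself has a gap there.
    """
    aln._check_column(column)
    try:
        row = aln.row(ref_id)
    except KeyError:
        raise ReferenceError_(f"no sequence {ref_id!r} in alignment") from None
    if row[column - 1] == GAP:
        return None
    return column - row.count(GAP, 0, column)


def refpos_map(aln: LabeledAlignment, ref_id: str) -> np.ndarray:
    """Vector of residue numbers per column for ``ref_id``; 0 where it has a gap."""
    row = np.array(list(aln.row(ref_id)), dtype="<U1")
    nongap = row != GAP
    return np.where(nongap, np.cumsum(nongap), 0)


def strip_gap_columns(aln: LabeledAlignment) -> LabeledAlignment:
    """Keep exactly the columns where no sequence has a gap (complete deletion).

    Row order is preserved; an empty result triggers a warning, not an error.
    """
    arr = aln.to_array()
    keep = ~(arr == GAP).any(axis=0)
    if not keep.any():
        warnings.warn("no gap-free columns remain after complete deletion")
    stripped = arr[:, keep]
    records = tuple(
        (sid, "".join(stripped[i])) for i, (sid, _) in enumerate(aln.records)
    )
    if stripped.shape[1] == 0:
        # LabeledAlignment requires length >= 1; represent emptiness explicitly.
        records = tuple((sid, "") for sid, _ in aln.records)
        obj = object.__new__(LabeledAlignment)
        object.__setattr__(obj, "records", records)
        object.__setattr__(obj, "clade_of", dict(aln.clade_of))
        object.__setattr__(obj, "reference_of", dict(aln.reference_of))
        return obj
    return LabeledAlignment(records=records, clade_of=dict(aln.clade_of),
                            reference_of=dict(aln.reference_of))


# -- domain annotation ----------------------------------------------------


@dataclass(frozen=True)
class DomainAnnotation:
    """Ordered, non-overlapping domain regions in reference coordinates.

    ``regions`` are ``(label, start, end)``, 1-based inclusive residue
    numbers of the ungapped reference.  ``reference_length`` (optional)
    enables out-of-range checks.
    """

    reference_id: str
    regions: tuple[tuple[str, int, int], ...]
    reference_length: Optional[int] = None

    def __post_init__(self) -> None:
        prev_end = 0
        for label, start, end in self.regions:
            if not 1 <= start <= end:
                raise DomainRangeError(f"region {label!r}: bad range {start}..{end}")
            if start <= prev_end:
                raise DomainRangeError(
                    f"region {label!r} overlaps or is out of order at {start}"
                )
            if self.reference_length is not None and end > self.reference_length:
                raise DomainRangeError(
                    f"region {label!r} ends past reference length {self.reference_length}"
                )
            prev_end = end


def assign_domain(ann: DomainAnnotation, refpos: int) -> str:
    """Domain label containing reference residue ``refpos``.

    Positions before the first annotated region are labelled ``N-terminal``,
    positions between two regions ``linker``, and positions after the last
    region ``C-terminal``.
    """
    if refpos < 1 or (ann.reference_length is not None and refpos > ann.reference_length):
        raise DomainRangeError(f"refpos {refpos} out of reference range")
    if not ann.regions:
        return "linker"
    for i, (label, start, end) in enumerate(ann.regions):
        if start <= refpos <= end:
            return label
        if refpos < start:
            return "N-terminal" if i == 0 else "linker"
    return "C-terminal"


def read_domains(path: PathLike) -> DomainAnnotation:
    """Read a domain TSV (see module docstring for the format)."""
    reference_id: Optional[str] = None
    reference_length: Optional[int] = None
    regions: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip().lower() == "reference":
                reference_id = fields[1].strip()
                if len(fields) >= 3 and fields[2].strip():
                    reference_length = int(fields[2])
                continue
            if len(fields) != 3:
                raise DomainRangeError(
                    f"{path}:{lineno}: expected label<TAB>start<TAB>end"
                )
            regions.append((fields[0].strip(), int(fields[1]), int(fields[2])))
    if reference_id is None:
        raise DomainRangeError(f"{path}: missing 'reference<TAB><seq_id>' header line")
    return DomainAnnotation(reference_id=reference_id,
                            regions=tuple(regions),
                            reference_length=reference_length)


def write_domains(ann: DomainAnnotation, path: PathLike) -> None:
    with open(path, "w") as fh:
        if ann.reference_length is not None:
            fh.write(f"reference\t{ann.reference_id}\t{ann.reference_length}\n")
        else:
            fh.write(f"reference\t{ann.reference_id}\n")
        for label, start, end in ann.regions:
            fh.write(f"{label}\t{start}\t{end}\n")
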