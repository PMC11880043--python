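"""Sequence and transmembrane-annotation I/O.

Protein sequences travel as FASTA; transmembrane (TM) segments travel as a
small tab-separated table (``id<TAB>start<TAB>end[<TAB>kind]``, 1-based
inclusive, the UniProt TRANSMEM convention).  Both are combined into
:class:`ProteinRecord` objects that the rest of the package consumes.

TM segments are an *input*: helix assignments come from UniProt or prior
structural work, and no TM-prediction algorithm is provided here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STANDARD_AA",
    "TMSegment",
    "ProteinRecord",
    "SequenceError",
    "read_fasta",
    "write_fasta",
    "read_tm_annotations",
    "write_tm_annotations",
    "attach_segments",
]

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

PathLike = Union[str, Path]


class SequenceError(ValueError):
    """Invalid sequence content or inconsistent TM annotation."""


@dataclass(frozen=True, order=True)
class TMSegment:
    """A contiguous membrane-spanning stretch, 1-based inclusive."""

    start: int
    end: int
    kind: str = field(default="helix", compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"invalid TM segment: start={self.start}, end={self.end} "
                "(need 1 <= start <= end)"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional TM-segment annotations.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to the first whitespace).
    sequence : str
        Uppercase one-letter codes. Strict mode admits the 20 standard
        residues; lenient mode additionally admits ``X``.
    description : str
        Remainder of the FASTA header.
    segments : tuple of TMSegment
        Non-overlapping, sorted by start, within ``[1, len(sequence)]``.
    """

    id: str
    sequence: str
    description: str = ""
    segments: tuple[TMSegment, ...] = ()

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, strict=False, record_id=self.id)
        object.__setattr__(self, "segments", tuple(sorted(self.segments)))
        _validate_segments(self.segments, len(self.sequence), self.id)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def tm_length(self) -> int:
        """Total number of residues inside TM segments."""
        return sum(len(s) for s in self.segments)

    def in_tm(self, pos: int) -> bool:
        """True if 1-based position ``pos`` lies in any TM segment."""
        return any(pos in s for s in self.segments)


def validate_sequence(seq: str, *, strict: bool = True, record_id: str = "?") -> None:
    """Raise :class:`SequenceError` on illegal residue letters.

    Strict mode allows only the 20 standard codes; lenient mode also
    allows ``X`` (unknown).  Other letters are never coerced silently.
    """
    allowed = STANDARD_AA if strict else STANDARD_AA | {"X"}
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise SequenceError(
                f"record {record_id!r}: illegal residue {ch!r} at position {i}"
            )


def _validate_segments(
    segments: Sequence[TMSegment], seq_len: int, record_id: str
) -> None:
    prev_end = 0
    for seg in segments:
        if seg.start <= prev_end:
            raise SequenceError(
                f"record {record_id!r}: TM segments overlap at position {seg.start}"
            )
        if seg.end > seq_len:
            raise SequenceError(
                f"record {record_id!r}: TM segment {seg.start}-{seg.end} "
                f"exceeds sequence length {seq_len}"
            )
        prev_end = seg.end


def read_fasta(path: PathLike, *, strict: bool = True) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; gap characters (``-``, ``.``) and internal
    whitespace are removed.  Record order is preserved; segments are empty
    (attach them with :func:`attach_segments`).
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        validate_sequence(seq, strict=strict, record_id=rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Sequence[ProteinRecord], path: PathLike, *, line_width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips id and sequence."""
    if not records:
        raise SequenceError("refusing to write an empty record list")
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seqrecords)


def read_tm_annotations(path: PathLike) -> dict[str, list[TMSegment]]:
    """Parse a TM-annotation TSV into ``{record id: [TMSegment, ...]}``.

    Expected columns: ``id``, ``start``, ``end`` and optionally ``kind``;
    a header row naming them is allowed and skipped.  Segments are grouped
    per id, sorted, and checked for overlap.
    """
    out: dict[str, list[TMSegment]] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[:3] == ["id", "start", "end"]:
            continue
        if len(parts) < 3:
            raise SequenceError(
                f"{path}:{lineno}: expected id<TAB>start<TAB>end[<TAB>kind]"
            )
        rid, s, e = parts[0], parts[1], parts[2]
        kind = parts[3] if len(parts) > 3 and parts[3] else "helix"
        try:
            seg = TMSegment(int(s), int(e), kind)
        except ValueError as exc:
            raise SequenceError(f"{path}:{lineno}: {exc}") from exc
        out.setdefault(rid, []).append(seg)
    for rid, segs in out.items():
        segs.sort()
        prev_end = 0
        for seg in segs:
            if seg.start <= prev_end:
                raise SequenceError(
                    f"record {rid!r}: overlapping TM segments "
                    f"(... {prev_end}) and ({seg.start} ...)"
                )
            prev_end = seg.end
    return out


def write_tm_annotations(
    segments: Mapping[str, Iterable[TMSegment]], path: PathLike
) -> None:
    """Serialize TM segments back to the TSV format (idempotent round-trip)."""
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tkind\n")
        for rid in segments:
            for seg in sorted(segments[rid]):
                fh.write(f"{rid}\t{seg.start}\t{seg.end}\t{seg.kind}\n")


def attach_segments(
    record: ProteinRecord, segments: Iterable[TMSegment]
) -> ProteinRecord:
    """Return a copy of ``record`` with ``segments`` attached.

    Validates bounds and overlap against the record length; the input
    record is unchanged.
    """
    return replace(record, segments=tuple(sorted(segments)))
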