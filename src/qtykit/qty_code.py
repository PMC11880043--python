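"""The QTY substitution code.

The QTY code converts the hydrophobic transmembrane (TM) face of an
integral membrane protein into a hydrophilic one by four deterministic
pairwise substitutions chosen for their near-identical backbone electron
density: leucine → glutamine (L→Q), isoleucine and valine → threonine
(I→T, V→T), and phenylalanine → tyrosine (F→Y).  Substitution is applied
only inside annotated TM segments: the soluble domains are left untouched,
which is what keeps the analog's molecular weight and isoelectric point
close to the native protein's.

Two variation percentages summarize a design: the TM variation
(substitutions over summed TM-segment length) and the overall variation
(substitutions over full sequence length).  TM variation is always the
larger of the two when, as here, substitutions are confined to TM
segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from types import MappingProxyType
from typing import Mapping, Sequence

from .seq_io import ProteinRecord, SequenceError, TMSegment

__all__ = [
    "DEFAULT_QTY_MAP",
    "VariationStats",
    "QTYResult",
    "apply_qty",
    "variation_stats",
    "render_alignment",
]

#: The canonical four-pair QTY map.  Frozen: custom maps may be passed to
#: :func:`apply_qty`, but the default never changes and no reverse map
#: (Q→L etc.) is shipped.
DEFAULT_QTY_MAP: Mapping[str, str] = MappingProxyType(
    {"L": "Q", "I": "T", "V": "T", "F": "Y"}
)


@dataclass(frozen=True)
class VariationStats:
    """Substitution counts and percentages for a native/analog pair."""

    n_substitutions: int
    tm_length: int
    total_length: int

    @property
    def tm_variation_pct(self) -> float:
        """100 × substitutions / TM length (0 if no TM residues)."""
        if self.tm_length == 0:
            return 0.0
        return 100.0 * self.n_substitutions / self.tm_length

    @property
    def overall_variation_pct(self) -> float:
        """100 × substitutions / full sequence length."""
        if self.total_length == 0:
            return 0.0
        return 100.0 * self.n_substitutions / self.total_length

    def as_row(self) -> dict:
        """Display form: percentages rounded to 2 decimals."""
        return {
            "n_sub": self.n_substitutions,
            "tm_len": self.tm_length,
            "total_len": self.total_length,
            "tm_pct": round(self.tm_variation_pct, 2),
            "overall_pct": round(self.overall_variation_pct, 2),
        }


@dataclass(frozen=True)
class QTYResult:
    """Outcome of applying the QTY code to one record."""

    native: ProteinRecord
    analog: ProteinRecord
    substitutions: tuple[tuple[int, str, str], ...]  # (1-based pos, from, to)
    stats: VariationStats


def apply_qty(
    record: ProteinRecord,
    substitution_map: Mapping[str, str] = DEFAULT_QTY_MAP,
) -> QTYResult:
    """Apply the QTY code within the record's TM segments.

    Positions outside TM segments are never modified.  The operation is
    idempotent: Q, T and Y are not map keys, so re-applying the code to an
    analog yields zero substitutions.

    Raises
    ------
    SequenceError
        If the record carries no TM segments.
    """
    if not record.segments:
        raise SequenceError(
            f"record {record.id!r}: no transmembrane segments annotated"
        )
    seq = list(record.sequence)
    subs: list[tuple[int, str, str]] = []
    for seg in record.segments:
        for pos in range(seg.start, seg.end + 1):
            aa = seq[pos - 1]
            target = substitution_map.get(aa)
            if target is not None:
                seq[pos - 1] = target
                subs.append((pos, aa, target))
    analog_seq = "".join(seq)
    analog = replace(record, id=f"{record.id}_QTY", sequence=analog_seq)
    stats = variation_stats(record.sequence, analog_seq, record.segments)
    return QTYResult(
        native=record, analog=analog, substitutions=tuple(subs), stats=stats
    )


def variation_stats(
    native: str, analog: str, segments: Sequence[TMSegment]
) -> VariationStats:
    """Count differing positions and compute the two variation percentages.

    ``tm_length`` is the summed length of ``segments``; the overall
    denominator is the full sequence length.  Differences outside every
    segment are counted in the overall numerator but trigger a warning,
    since QTY output never produces them.
    """
    if len(native) != len(analog):
        raise SequenceError(
            f"sequence lengths differ: {len(native)} vs {len(analog)}"
        )
    diff_positions = [
        i for i in range(1, len(native) + 1) if native[i - 1] != analog[i - 1]
    ]
    tm_length = sum(len(s) for s in segments)
    outside = [p for p in diff_positions if not any(p in s for s in segments)]
    if outside:
        warnings.warn(
            f"{len(outside)} differing position(s) outside TM segments "
            f"(first at {outside[0]})",
            stacklevel=2,
        )
    return VariationStats(
        n_substitutions=len(diff_positions),
        tm_length=tm_length,
        total_length=len(native),
    )


def render_alignment(
    native: ProteinRecord, analog: ProteinRecord, *, width: int = 60
) -> str:
    """Render a native/analog alignment as fixed-width text blocks.

    Each block holds four lines: a TM line (``H`` under helix positions),
    the native sequence, a marker line (``|`` identical, ``*`` different),
    and the analog sequence.  Sequences must be equal length.
    """
    if len(native.sequence) != len(analog.sequence):
        raise SequenceError(
            f"cannot align sequences of different length: "
            f"{len(native)} vs {len(analog)}"
        )
    n = len(native.sequence)
    marker = "".join(
        "|" if a == b else "*" for a, b in zip(native.sequence, analog.sequence)
    )
    tm_line = "".join(
        "H" if native.in_tm(i) else " " for i in range(1, n + 1)
    )
    blocks: list[str] = []
    for off in range(0, n, width):
        lo, hi = off, min(off + width, n)
        blocks.append(
            "\n".join(
                [
                    tm_line[lo:hi].rstrip(),
                    native.sequence[lo:hi],
                    marker[lo:hi],
                    analog.sequence[lo:hi],
                ]
            )
        )
    return "\n\n".join(blocks) + "\n"
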