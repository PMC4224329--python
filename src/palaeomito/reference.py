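"""Reference coordinate frame, hotspot masks, and substitution-variant arithmetic.

All public coordinates are 1-based inclusive, matching mtDNA variant
nomenclature (``C10822A`` names position 10822 of the reference frame).
The mitochondrial genome is circular: position arithmetic wraps modulo the
frame length, so position ``length + 1`` is position 1.  Conversion to
0-based half-open coordinates happens only inside the alignment layer.

The substitution-only model means every genome handled by the pipeline is
the same length as its reference frame; indels are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from . import _seq
from .errors import ConsistencyError, ParseError, RangeError

__all__ = [
    "CircularReference",
    "RegionMask",
    "Variant",
    "GenomeRecord",
    "parse_variant",
    "apply_variants",
    "masked_length",
    "STANDARD_HOTSPOT_MASK",
    "CODING_REGION",
    "MT_FRAME_LENGTH",
]

#: Length of the standard human mtDNA coordinate frame (rCRS convention).
MT_FRAME_LENGTH = 16569

#: Coding-region window (1-based inclusive) used for region-restricted analyses.
CODING_REGION = (577, 16023)


@dataclass(frozen=True)
class CircularReference:
    """A circular reference sequence defining the coordinate frame.

    Parameters
    ----------
    name:
        Text label for the frame.
    sequence:
        Base string over ``{A, C, G, T, N}``; its length *is* the frame length.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ParseError("reference sequence is empty")
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ParseError(f"reference contains non-ACGTN characters: {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wrap(self, position: int) -> int:
        """Map any integer position onto the 1-based circular frame."""
        return (position - 1) % self.length + 1

    def base(self, position: int) -> str:
        """Base at a 1-based (circularly wrapped) position."""
        return self.sequence[(position - 1) % self.length]

    def fetch(self, start: int, length: int) -> str:
        """Circular substring of ``length`` bases starting at 1-based ``start``."""
        if length < 0:
            raise RangeError(f"negative fetch length {length}")
        i = (start - 1) % self.length
        doubled = self.sequence + self.sequence
        if length > self.length:
            raise RangeError(f"fetch length {length} exceeds frame length {self.length}")
        return doubled[i : i + length]

    def codes(self) -> np.ndarray:
        return _seq.encode(self.sequence)


class RegionMask:
    """A set of 1-based inclusive intervals excluded from analysis.

    Intervals are normalized on construction: sorted, overlap/adjacency
    merged.  Normalization is idempotent and the number of masked positions
    is invariant under reordering or splitting of the input intervals.
    """

    def __init__(self, intervals: Iterable[Tuple[int, int]] = ()):
        self.intervals: list[tuple[int, int]] = self._normalize(intervals)

    @staticmethod
    def _normalize(intervals: Iterable[Tuple[int, int]]) -> list[tuple[int, int]]:
        ivs = []
        for start, end in intervals:
            start, end = int(start), int(end)
            if start < 1:
                raise RangeError(f"interval start {start} < 1")
            if start > end:
                raise RangeError(f"interval start {start} > end {end}")
            ivs.append((start, end))
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for start, end in ivs:
            if merged and start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        return merged

    @property
    def n_masked(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)

    def __contains__(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionMask) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"RegionMask({self.intervals!r})"

    def bool_array(self, frame_length: int) -> np.ndarray:
        """Boolean array of length ``frame_length``; True where masked.

        Index ``i`` corresponds to 1-based position ``i + 1``.
        """
        arr = np.zeros(frame_length, dtype=bool)
        for start, end in self.intervals:
            if end > frame_length:
                raise RangeError(
                    f"mask interval ({start}, {end}) outside frame of length {frame_length}"
                )
            arr[start - 1 : end] = True
        return arr


#: Hypermutable regions conventionally excluded from mtDNA phylogenetics:
#: the two poly-C runs (303-315, 16182-16194), the AC repeat (515-525) and
#: the hypervariable site 16519.
STANDARD_HOTSPOT_MASK = RegionMask([(303, 315), (515, 525), (16182, 16194), (16519, 16519)])


@dataclass(frozen=True)
class Variant:
    """A single-base substitution in reference coordinates.

    The canonical text form is ``<ref><pos><alt>``, e.g. ``C10822A``.
    """

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise ParseError(
                f"variant bases must be in ACGT, got {self.ref_base!r}/{self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise ParseError(
                f"degenerate variant at position {self.position}: "
                f"ref and alt are both {self.ref_base!r}"
            )
        if self.position < 1:
            raise RangeError(f"variant position {self.position} < 1")

    @property
    def label(self) -> str:
        return f"{self.ref_base}{self.position}{self.alt_base}"

    def reversed(self) -> "Variant":
        """The inverse substitution (alt back to ref)."""
        return Variant(self.position, self.alt_base, self.ref_base)

    def __str__(self) -> str:
        return self.label


_VARIANT_RE = re.compile(r"^([ACGTacgt])(\d+)([ACGTacgt])$")


def parse_variant(label: str, frame_length: Optional[int] = None) -> Variant:
    """Parse a ``<ref><pos><alt>`` substitution label such as ``C10822A``.

    Raises
    ------
    ParseError
        If the label is malformed or ref equals alt.
    RangeError
        If ``frame_length`` is given and the position falls outside it.
    """
    m = _VARIANT_RE.match(label.strip())
    if not m:
        raise ParseError(f"malformed variant label {label!r}: expected <base><pos><base>")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if pos < 1:
        raise RangeError(f"variant position {pos} < 1 in {label!r}")
    if frame_length is not None and pos > frame_length:
        raise RangeError(f"variant position {pos} outside frame of length {frame_length}")
    return Variant(pos, ref, alt)


@dataclass(frozen=True)
class GenomeRecord:
    """A genome expressed in its reference frame (same length, N allowed)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        return self.sequence[(position - 1) % self.length]

    def codes(self) -> np.ndarray:
        return _seq.encode(self.sequence)


def apply_variants(
    genome: GenomeRecord, variants: Sequence[Variant], new_id: Optional[str] = None
) -> GenomeRecord:
    """Apply substitution variants to a genome, checking reference bases.

    Every variant's ``ref_base`` must match the genome at its position;
    otherwise a :class:`ConsistencyError` is raised listing the offending
    position, the expected base and the base found.
    """
    seq = list(genome.sequence)
    for v in variants:
        if v.position > genome.length:
            raise RangeError(
                f"variant {v.label} outside genome of length {genome.length}"
            )
        found = seq[v.position - 1]
        if found != v.ref_base:
            raise ConsistencyError(
                f"variant {v.label}: expected {v.ref_base} at position "
                f"{v.position}, found {found}"
            )
        seq[v.position - 1] = v.alt_base
    return GenomeRecord(new_id if new_id is not None else genome.id, "".join(seq))


def masked_length(
    frame_length: int,
    mask: RegionMask,
    window: Optional[Tuple[int, int]] = None,
) -> int:
    """Number of unmasked positions in a window (whole frame if no window).

    With the standard hotspot mask on the 16,569-position frame this yields
    16,531 positions genome-wide and 15,447 inside the 577-16023 coding
    window.
    """
    for start, end in mask.intervals:
        if end > frame_length:
            raise RangeError(
                f"mask interval ({start}, {end}) outside frame of length {frame_length}"
            )
    if window is None:
        window = (1, frame_length)
    ws, we = window
    if ws < 1 or we > frame_length or ws > we:
        raise RangeError(f"window {window} invalid for frame of length {frame_length}")
    total = we - ws + 1
    masked = 0
    for start, end in mask.intervals:
        lo, hi = max(start, ws), min(end, we)
        if lo <= hi:
            masked += hi - lo + 1
    return total - masked
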