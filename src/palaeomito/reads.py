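"""Read containers shared by the simulator, aligner and downstream modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SequencingRead:
    """A sequenced fragment with per-base Phred qualities."""

    id: str
    bases: str
    qualities: np.ndarray  # int array, one Phred score per base

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignedRead:
    """An ungapped placement of a read on the circular reference frame.

    ``bases`` and ``qualities`` are stored in *reference orientation*
    (reverse-complemented for minus-strand placements), with index 0 at
    ``ref_start``.  ``strand`` records the sequenced orientation so that
    damage profiling can re-orient to molecule ends.  Coordinates are
    1-based inclusive and wrap circularly, so ``ref_end`` may be numerically
    smaller than ``ref_start`` for origin-spanning placements.
    """

    read_id: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    bases: str
    qualities: np.ndarray
    score: float = 0.0

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities differ in length")

    @property
    def length(self) -> int:
        return len(self.bases)

    def key(self) -> tuple[int, int, str]:
        """Unique-molecule key: identical (start, end, strand) placements
        are treated as PCR duplicates of one original fragment."""
        return (self.ref_start, self.ref_end, self.strand)

    def positions(self, frame_length: int) -> np.ndarray:
        """1-based reference positions covered, in reference orientation."""
        return (self.ref_start - 1 + np.arange(self.length)) % frame_length + 1
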