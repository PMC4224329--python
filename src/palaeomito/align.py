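"""Ungapped alignment of short reads to a circular reference.

Placements are found by exact k-mer seeding (default k=12) followed by
full scoring of every seeded offset, for the read and its reverse
complement.  Circularity is handled by scoring against the reference
extended by wrap bases; coordinates are reported modulo the frame length.

Scoring is match/mismatch only (substitution model).  Damage-aware modes
reduce the mismatch penalty for the two deamination-consistent mismatch
types *in reference frame* — read T over reference C, and read A over
reference G — which covers 5′ C→T and 3′ G→A damage on both strands:

* ``"off"``  — full penalty for all mismatches;
* ``"half"`` — half penalty for damage-consistent mismatches (default);
* ``"full"`` — no penalty for damage-consistent mismatches.

Read or reference N bases contribute neither match nor mismatch.  Ties
between placements are broken deterministically: higher score, then plus
strand before minus, then smaller reference start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from . import _seq
from .reads import AlignedRead, SequencingRead
from .reference import CircularReference

__all__ = ["ScoringParams", "KmerIndex", "align_read", "brute_force_align"]

_DAMAGE_WEIGHT = {"off": 1.0, "half": 0.5, "full": 0.0}


@dataclass(frozen=True)
class ScoringParams:
    """Match/mismatch scores and seeding parameters.

    ``min_score_fraction`` is the acceptance threshold as a fraction of the
    perfect score (``match * read_length``); placements scoring below it
    are reported as no-hit.
    """

    match: float = 1.0
    mismatch: float = -1.0
    damage_mode: str = "half"
    min_score_fraction: float = 0.3
    k: int = 12

    def __post_init__(self) -> None:
        if self.damage_mode not in _DAMAGE_WEIGHT:
            raise ValueError(f"damage_mode must be one of {sorted(_DAMAGE_WEIGHT)}")
        if self.k < 4:
            raise ValueError("seed length k must be >= 4")

    @property
    def damage_weight(self) -> float:
        return _DAMAGE_WEIGHT[self.damage_mode]


def _kmer_ints(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 integers of all k-mers plus a validity mask (no N inside)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = (windows < 4).all(axis=1)
    vals = (np.where(windows < 4, windows, 0) @ powers)
    return vals, valid


def _fold_damage(codes: np.ndarray) -> np.ndarray:
    """Collapse the two deamination pairs: C folds onto T, G onto A.

    A read carrying any amount of C→T/G→A damage folds to the same string
    as its undamaged template, so folded k-mers seed heavily deaminated
    reads that no longer share an exact k-mer with the reference.
    """
    out = codes.copy()
    out[codes == 1] = 3  # C -> T
    out[codes == 2] = 0  # G -> A
    return out


def _build_lookup(codes: np.ndarray, k: int) -> Dict[int, np.ndarray]:
    vals, valid = _kmer_ints(codes, k)
    index: Dict[int, np.ndarray] = {}
    order = np.argsort(vals[valid], kind="stable")
    positions = np.flatnonzero(valid)[order]
    sorted_vals = vals[positions]
    if len(sorted_vals):
        splits = np.flatnonzero(np.diff(sorted_vals)) + 1
        starts = np.r_[0, splits]
        for s, group in zip(starts, np.split(positions, splits)):
            index[int(sorted_vals[s])] = group
    return index


class KmerIndex:
    """Exact and damage-folded k-mer indexes over all circular offsets."""

    def __init__(self, ref: CircularReference, k: int = 12):
        self.ref = ref
        self.k = k
        codes = ref.codes()
        self.ext_codes = np.concatenate([codes, codes])  # wrap buffer
        circular = self.ext_codes[: ref.length + k - 1]
        self._index = _build_lookup(circular, k)
        self._folded_index = _build_lookup(_fold_damage(circular), k)

    def _offsets(self, codes: np.ndarray, index: Dict[int, np.ndarray]) -> np.ndarray:
        vals, valid = _kmer_ints(codes, self.k)
        offsets = set()
        for i in np.flatnonzero(valid):
            hits = index.get(int(vals[i]))
            if hits is not None:
                for p in hits:
                    offsets.add((int(p) - int(i)) % self.ref.length)
        return np.fromiter(sorted(offsets), dtype=np.int64, count=len(offsets))

    def candidate_offsets(self, codes: np.ndarray) -> np.ndarray:
        """0-based reference offsets sharing at least one k-mer with ``codes``."""
        return self._offsets(codes, self._index)

    def folded_candidate_offsets(self, codes: np.ndarray) -> np.ndarray:
        """Offsets sharing a damage-folded k-mer (C≡T, G≡A) with ``codes``."""
        return self._offsets(_fold_damage(codes), self._folded_index)


def _score_at(
    ext_ref: np.ndarray,
    read_codes: np.ndarray,
    offset: int,
    scoring: ScoringParams,
) -> float:
    s = ext_ref[offset : offset + len(read_codes)]
    r = read_codes
    both = (s < 4) & (r < 4)
    eq = both & (s == r)
    mm = both & (s != r)
    dmg = mm & (((s == 1) & (r == 3)) | ((s == 2) & (r == 0)))
    n_dmg = int(dmg.sum())
    n_mm = int(mm.sum()) - n_dmg
    return (
        scoring.match * float(eq.sum())
        + scoring.mismatch * (n_mm + scoring.damage_weight * n_dmg)
    )


def _best_placement(
    read: SequencingRead,
    ref: CircularReference,
    scoring: ScoringParams,
    offsets_by_strand,
    ext_ref: np.ndarray,
) -> Optional[AlignedRead]:
    m = len(read)
    best = None  # (score, strand_rank, start0, strand, oriented_codes, oriented_quals)
    for strand, oriented, quals, offsets in offsets_by_strand:
        strand_rank = 0 if strand == "+" else 1
        for off in offsets:
            score = _score_at(ext_ref, oriented, int(off), scoring)
            key = (-score, strand_rank, int(off))
            if best is None or key < best[0]:
                best = (key, score, int(off), strand, oriented, quals)
    if best is None:
        return None
    _, score, off, strand, oriented, quals = best
    if score < scoring.min_score_fraction * scoring.match * m:
        return None
    return AlignedRead(
        read_id=read.id,
        ref_start=off + 1,
        ref_end=(off + m - 1) % ref.length + 1,
        strand=strand,
        bases=_seq.decode(oriented),
        qualities=quals,
        score=score,
    )


def align_read(
    read: SequencingRead,
    ref: CircularReference,
    scoring: ScoringParams = ScoringParams(),
    index: Optional[KmerIndex] = None,
) -> Optional[AlignedRead]:
    """Best ungapped circular placement of a read, or None for no-hit.

    Reads shorter than the seed length cannot be seeded and are no-hits.
    Pass a prebuilt :class:`KmerIndex` when aligning many reads to one
    reference.
    """
    if len(read) < scoring.k:
        return None
    if index is None:
        index = KmerIndex(ref, scoring.k)
    elif index.k != scoring.k or index.ref is not ref:
        index = KmerIndex(ref, scoring.k)
    fwd = _seq.encode(read.bases)
    rev = _seq.revcomp_codes(fwd)
    quals = np.asarray(read.qualities)
    plans = [
        ("+", fwd, quals, index.candidate_offsets(fwd)),
        ("-", rev, quals[::-1].copy(), index.candidate_offsets(rev)),
    ]
    hit = _best_placement(read, ref, scoring, plans, index.ext_codes)
    if hit is None:
        # deamination may have destroyed every exact seed; retry with
        # damage-folded k-mers before declaring a no-hit
        plans = [
            ("+", fwd, quals, index.folded_candidate_offsets(fwd)),
            ("-", rev, quals[::-1].copy(), index.folded_candidate_offsets(rev)),
        ]
        hit = _best_placement(read, ref, scoring, plans, index.ext_codes)
    return hit


def brute_force_align(
    read: SequencingRead,
    ref: CircularReference,
    scoring: ScoringParams = ScoringParams(),
) -> Optional[AlignedRead]:
    """Exhaustively score every circular offset on both strands.

    Independent oracle for the seeded aligner; identical selection and
    threshold rules, no seeding shortcut.
    """
    if len(read) < scoring.k:
        return None
    codes = ref.codes()
    ext_ref = np.concatenate([codes, codes])
    fwd = _seq.encode(read.bases)
    rev = _seq.revcomp_codes(fwd)
    all_offsets = np.arange(ref.length)
    plans = [
        ("+", fwd, np.asarray(read.qualities), all_offsets),
        ("-", rev, np.asarray(read.qualities)[::-1].copy(), all_offsets),
    ]
    return _best_placement(read, ref, scoring, plans, ext_ref)
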