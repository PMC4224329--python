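"""Deterministic study fixture: reference frame, clade genomes and mini-tree.

The bundled reference is a synthetic, deterministically generated
16,569-base circular sequence (fixed internal seed), constrained so that
the reference base at every position named by the study-style variant
labels matches the label (C at 10822, C at 16355, G at 3591, T at 408, and
so on).  It is a stand-in coordinate frame for testing and demonstration;
a real mtDNA reference (e.g. the rCRS) can be supplied by the user
anywhere a :class:`~palaeomito.reference.CircularReference` is accepted.

:func:`make_study_fixture` reconstructs, from printed-style variant lists,
the genomes of a small L0d-like clade: an ancestral L0d2c1-like genome;
an ancient "StHe-like" genome carrying the two subclade-defining variants
plus nine private variants; two contemporary "NAM-like" genomes carrying
only the defining variants (and one additional substitution, G3591A,
separating them); sister-subclade genomes; a divergent modern contaminant
and an outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np

from . import _seq, io
from .phylo import HaplogroupNode, write_haplogroup_tree_tsv
from .reference import (
    STANDARD_HOTSPOT_MASK,
    CircularReference,
    GenomeRecord,
    MT_FRAME_LENGTH,
    RegionMask,
    Variant,
    apply_variants,
    parse_variant,
)

__all__ = [
    "bundled_reference",
    "make_study_fixture",
    "StudyFixture",
    "STHE_PRIVATE_VARIANT_LABELS",
    "L0D2C1C_DEFINING_LABELS",
    "NAM_PAIR_DIFFERENCE_LABEL",
]

_REFERENCE_SEED = 424242

#: Bases the generated reference is pinned to, so that every printed-style
#: variant label's ref base is consistent with the frame.
_CONSTRAINED_BASES = {
    408: "T",
    2581: "A",
    3591: "G",
    4824: "A",
    10822: "C",
    11279: "C",
    11431: "C",
    11884: "A",
    16086: "T",
    16261: "C",
    16355: "C",
    16399: "A",
}

#: The nine private variants separating the ancient genome from the two
#: contemporary clade members (all outside the hotspot mask).
STHE_PRIVATE_VARIANT_LABELS = [
    "T408A",
    "A2581G",
    "A4824G",
    "C11279T",
    "C11431T",
    "A11884G",
    "T16086C",
    "C16261T",
    "A16399C",
]

#: Variants defining the new terminal subclade.
L0D2C1C_DEFINING_LABELS = ["C10822A", "C16355T"]

#: The single site at which the two contemporary genomes differ.
NAM_PAIR_DIFFERENCE_LABEL = "G3591A"

# Synthetic defining-variant positions for the upper clades and sister
# subclades of the mini-tree (the real tree's variants are not reproduced
# here); alt alleles are derived from the generated reference at run time.
_SYNTHETIC_CLADE_POSITIONS = {
    "L0d2c": [1048, 2245, 5442],
    "L0d2c1": [4232, 7146],
    "L0d2c1a": [6185, 9755],
    "L0d2c1b": [8152, 13799],
}

_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}

_cached_reference: CircularReference | None = None


def bundled_reference() -> CircularReference:
    """The deterministic 16,569-base synthetic reference frame."""
    global _cached_reference
    if _cached_reference is None:
        rng = np.random.default_rng(_REFERENCE_SEED)
        codes = rng.integers(0, 4, MT_FRAME_LENGTH).astype(np.uint8)
        seq = list(_seq.decode(codes))
        for pos, base in _CONSTRAINED_BASES.items():
            seq[pos - 1] = base
        _cached_reference = CircularReference("mito-fixture-frame", "".join(seq))
    return _cached_reference


def _synthetic_variants(ref: CircularReference, positions: List[int]) -> List[Variant]:
    return [Variant(p, ref.base(p), _NEXT_BASE[ref.base(p)]) for p in positions]


@dataclass
class StudyFixture:
    """Bundle of fixture genomes, defining variants, mask and mini-tree."""

    reference: CircularReference
    genomes: Dict[str, GenomeRecord]
    defining_variants: Dict[str, List[Variant]]
    private_variants: List[Variant]
    mask: RegionMask
    tree: HaplogroupNode

    def genome(self, name: str) -> GenomeRecord:
        return self.genomes[name]

    def write(self, outdir) -> None:
        """Write the bundle as plain-text FASTA/TSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(
            [GenomeRecord(self.reference.name, self.reference.sequence)],
            outdir / "reference.fasta",
        )
        io.write_fasta(list(self.genomes.values()), outdir / "genomes.fasta")
        io.write_mask_tsv(self.mask, outdir / "hotspot_mask.tsv")
        io.write_variants_tsv(self.private_variants, outdir / "sthe_private_variants.tsv")
        write_haplogroup_tree_tsv(self.tree, outdir / "haplogroup_tree.tsv")


def make_study_fixture(seed: int = 0) -> StudyFixture:
    """Build the clade genomes and mini haplogroup tree from variant lists.

    The seed only affects the randomly placed substitutions of the modern
    contaminant and outgroup genomes; the clade genomes are fully
    determined by their variant lists.
    """
    ref = bundled_reference()
    base = GenomeRecord("frame", ref.sequence)
    mask = STANDARD_HOTSPOT_MASK

    defining: Dict[str, List[Variant]] = {
        name: _synthetic_variants(ref, pos)
        for name, pos in _SYNTHETIC_CLADE_POSITIONS.items()
    }
    defining["L0d2c1c"] = [parse_variant(s, ref.length) for s in L0D2C1C_DEFINING_LABELS]
    privates = [parse_variant(s, ref.length) for s in STHE_PRIVATE_VARIANT_LABELS]
    nam_diff = parse_variant(NAM_PAIR_DIFFERENCE_LABEL, ref.length)

    ancestral = apply_variants(
        base, defining["L0d2c"] + defining["L0d2c1"], new_id="ancestral_L0d2c1"
    )
    nam117 = apply_variants(ancestral, defining["L0d2c1c"], new_id="NAM117_like")
    nam168 = apply_variants(nam117, [nam_diff], new_id="NAM168_like")
    sthe = apply_variants(
        ancestral, defining["L0d2c1c"] + privates, new_id="StHe_like"
    )
    sister_a = apply_variants(ancestral, defining["L0d2c1a"], new_id="L0d2c1a_like")
    sister_b = apply_variants(ancestral, defining["L0d2c1b"], new_id="L0d2c1b_like")

    # Divergent modern contaminant (>=30 substitutions) and a deeper
    # outgroup, at seeded random unmasked positions not already in use.
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9021]))
    used = set(_CONSTRAINED_BASES) | {
        p for ps in _SYNTHETIC_CLADE_POSITIONS.values() for p in ps
    }
    masked = mask.bool_array(ref.length)
    pool = [
        p for p in range(1, ref.length + 1) if p not in used and not masked[p - 1]
    ]
    picks = rng.choice(len(pool), size=100, replace=False)
    contam_pos = sorted(pool[i] for i in picks[:40])
    outgroup_pos = sorted(pool[i] for i in picks[40:])
    contam_vars = _synthetic_variants(ref, contam_pos)
    outgroup_vars = _synthetic_variants(ref, outgroup_pos)
    contaminant = apply_variants(base, contam_vars, new_id="modern_contaminant")
    outgroup = apply_variants(base, outgroup_vars, new_id="outgroup")

    tree = HaplogroupNode(
        "root",
        [],
        [
            HaplogroupNode(
                "L0d2c",
                defining["L0d2c"],
                [
                    HaplogroupNode(
                        "L0d2c1",
                        defining["L0d2c1"],
                        [
                            HaplogroupNode("L0d2c1a", defining["L0d2c1a"], []),
                            HaplogroupNode("L0d2c1b", defining["L0d2c1b"], []),
                            HaplogroupNode("L0d2c1c", defining["L0d2c1c"], []),
                        ],
                    )
                ],
            )
        ],
    )

    genomes = {
        g.id: g
        for g in [ancestral, nam117, nam168, sthe, sister_a, sister_b, contaminant, outgroup]
    }
    return StudyFixture(
        reference=ref,
        genomes=genomes,
        defining_variants=defining,
        private_variants=privates,
        mask=mask,
        tree=tree,
    )
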