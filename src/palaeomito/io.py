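"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA and FASTQ go through Biopython's ``SeqIO``; Newick goes through
dendropy.  All paths are accepted plain or gzipped (detected by the
``.gz`` suffix).  Masks are ``start<TAB>end`` TSV, variant lists are one
``<ref><pos><alt>`` label per line.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import List, Sequence, Union

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .reads import SequencingRead
from .reference import GenomeRecord, RegionMask, Variant, parse_variant

PathLike = Union[str, Path]

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_mask_tsv",
    "write_mask_tsv",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_newick",
    "write_newick",
    "read_molecules_tsv",
    "write_molecules_tsv",
]


def _open(path: PathLike, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t") if "b" not in mode else gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> List[GenomeRecord]:
    with _open(path, "r") as fh:
        try:
            return [GenomeRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Sequence[GenomeRecord], path: PathLike, width: int = 60) -> None:
    with _open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: PathLike) -> List[SequencingRead]:
    reads = []
    with _open(path, "r") as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
                reads.append(SequencingRead(rec.id, str(rec.seq), quals))
        except ValueError as exc:
            raise ParseError(f"{path}: record {len(reads) + 1}: {exc}") from exc
    return reads


def write_fastq(reads: Sequence[SequencingRead], path: PathLike) -> None:
    with _open(path, "w") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.bases), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in read.qualities]
            SeqIO.write(rec, fh, "fastq")


def read_mask_tsv(path: PathLike) -> RegionMask:
    intervals = []
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'start<TAB>end', got {line!r}")
            try:
                intervals.append((int(parts[0]), int(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer bound in {line!r}") from exc
    return RegionMask(intervals)


def write_mask_tsv(mask: RegionMask, path: PathLike) -> None:
    with _open(path, "w") as fh:
        for start, end in mask.intervals:
            fh.write(f"{start}\t{end}\n")


def read_variants_tsv(path: PathLike) -> List[Variant]:
    variants = []
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                variants.append(parse_variant(line))
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return variants


def write_variants_tsv(variants: Sequence[Variant], path: PathLike) -> None:
    with _open(path, "w") as fh:
        for v in variants:
            fh.write(v.label + "\n")


_MOLECULE_COLUMNS = ["read_id", "ref_start", "ref_end", "strand", "score", "bases", "qualities"]


def write_molecules_tsv(molecules, path: PathLike) -> None:
    """Per-molecule table (placement, bases, comma-joined qualities)."""
    with _open(path, "w") as fh:
        fh.write("\t".join(_MOLECULE_COLUMNS) + "\n")
        for mol in molecules:
            quals = ",".join(str(int(q)) for q in mol.qualities)
            fh.write(
                f"{mol.read_id}\t{mol.ref_start}\t{mol.ref_end}\t{mol.strand}\t"
                f"{mol.score:.10g}\t{mol.bases}\t{quals}\n"
            )


def read_molecules_tsv(path: PathLike):
    from .reads import AlignedRead

    molecules = []
    with _open(path, "r") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MOLECULE_COLUMNS:
            raise ParseError(f"{path}:1: unexpected molecule columns {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_MOLECULE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_MOLECULE_COLUMNS)} fields")
            rid, start, end, strand, score, bases, quals = parts
            molecules.append(
                AlignedRead(
                    read_id=rid,
                    ref_start=int(start),
                    ref_end=int(end),
                    strand=strand,
                    bases=bases,
                    qualities=np.array([int(q) for q in quals.split(",")], dtype=np.int16),
                    score=float(score),
                )
            )
    return molecules


def read_newick(path: PathLike) -> dendropy.Tree:
    with _open(path, "r") as fh:
        text = fh.read()
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"{path}: {exc}") from exc


def write_newick(tree_or_text: Union[dendropy.Tree, str], path: PathLike) -> None:
    if isinstance(tree_or_text, dendropy.Tree):
        text = tree_or_text.as_string(schema="newick").strip()
    else:
        text = tree_or_text.strip()
    with _open(path, "w") as fh:
        fh.write(text + "\n")
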