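"""Conserved-region trimming of cross-species ortholog annotations.

Orthologous genes differ in length across species; count-based comparisons
that assume identical gene lengths are biased by indels.  This module finds
alignment blocks in which no species carries a gap run longer than
``max_gap`` (150 bp by default, strict inequality: a run of exactly 150 is
kept) and emits per-species "trimmed" exon annotations restricted to those
blocks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class SpeciesAnchor:
    """Genomic placement of one species' row of an alignment.

    ``offset`` is the 1-based genomic coordinate of the base at the first
    non-gap column; on the minus strand genomic coordinates decrease as
    alignment columns increase.
    """

    offset: int
    strand: str = "+"
    contig: str = "chr1"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class AnchoredAlignment:
    """Multi-species DNA alignment with per-species genomic anchors."""

    sequences: dict[str, str]  # species -> aligned sequence ('-' gaps)
    anchors: dict[str, SpeciesAnchor]
    gene_id: str = "gene"

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        missing = set(self.sequences) - set(self.anchors)
        if missing:
            raise ValueError(f"species without anchors: {sorted(missing)}")

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def gap_mask(self, species: str) -> np.ndarray:
        return np.frombuffer(self.sequences[species].encode(), dtype="S1") == b"-"

    def genomic_positions(self, species: str) -> np.ndarray:
        """1-based genomic coordinate per column; -1 at gap columns."""
        mask = self.gap_mask(species)
        anchor = self.anchors[species]
        step = 1 if anchor.strand == "+" else -1
        pos = np.full(self.n_columns, -1, dtype=int)
        k = np.cumsum(~mask) - 1
        pos[~mask] = anchor.offset + step * k[~mask]
        return pos


@dataclass
class ConservedBlock:
    """Alignment block with no per-species gap run exceeding the threshold.

    ``aln_start``/``aln_end`` are 0-based half-open alignment columns;
    ``genomic`` maps species to (contig, start, end, strand) with 1-based
    inclusive coordinates (GTF convention), or None if the species has no
    aligned base inside the block.
    """

    gene_id: str
    aln_start: int
    aln_end: int
    genomic: dict[str, tuple[str, int, int, str] | None] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.aln_end - self.aln_start


def _long_gap_columns(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Boolean column mask marking gap runs strictly longer than max_gap."""
    out = np.zeros(len(mask), dtype=bool)
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > max_gap:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def find_conserved_blocks(
    alignment: AnchoredAlignment,
    max_gap: int = 150,
    species: list[str] | None = None,
    min_block_len: int = 1,
) -> list[ConservedBlock]:
    """Partition the alignment into maximal blocks free of long gap runs.

    A column is excluded iff it lies inside a gap run strictly longer than
    ``max_gap`` in at least one species; retained columns form maximal
    contiguous blocks.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if species is not None:
        missing = set(species) - set(alignment.species)
        if missing:
            raise ValueError(f"species missing from alignment: {sorted(missing)}")
    else:
        species = alignment.species
    L = alignment.n_columns
    if L == 0:
        return []
    excluded = np.zeros(L, dtype=bool)
    for sp in species:
        excluded |= _long_gap_columns(alignment.gap_mask(sp), max_gap)
    blocks: list[ConservedBlock] = []
    i = 0
    while i < L:
        if not excluded[i]:
            j = i
            while j < L and not excluded[j]:
                j += 1
            if j - i >= min_block_len:
                blocks.append(_make_block(alignment, species, i, j))
            i = j
        else:
            i += 1
    return blocks


def _make_block(
    alignment: AnchoredAlignment, species: list[str], start: int, end: int
) -> ConservedBlock:
    genomic: dict[str, tuple[str, int, int, str] | None] = {}
    for sp in species:
        pos = alignment.genomic_positions(sp)[start:end]
        pos = pos[pos >= 0]
        if pos.size == 0:
            genomic[sp] = None
        else:
            anchor = alignment.anchors[sp]
            genomic[sp] = (anchor.contig, int(pos.min()), int(pos.max()), anchor.strand)
    return ConservedBlock(alignment.gene_id, start, end, genomic)


def blocks_to_gtf(blocks: list[ConservedBlock], species: str) -> list[str]:
    """Emit one GTF2.2 exon record per block for one species.

    Blocks in which the species has no aligned base are skipped with a
    logged warning.  Coordinates are 1-based inclusive; start < end holds on
    both strands.
    """
    records = []
    for k, block in enumerate(blocks):
        if species not in block.genomic:
            raise KeyError(f"block carries no anchors for species {species!r}")
        g = block.genomic[species]
        if g is None:
            logger.warning(
                "gene %s block %d: no aligned bases in %s; skipped",
                block.gene_id,
                k,
                species,
            )
            continue
        contig, gstart, gend, strand = g
        attrs = (
            f'gene_id "{block.gene_id}"; transcript_id "{block.gene_id}.t1"; '
            f'block "{k}";'
        )
        records.append(
            "\t".join(
                [
                    contig,
                    "exprevo",
                    "exon",
                    str(gstart),
                    str(gend),
                    ".",
                    strand,
                    ".",
                    attrs,
                ]
            )
        )
    return records


def write_gtf(records: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(records) + ("\n" if records else ""))
    return path


def blocks_table(blocks: list[ConservedBlock]) -> pd.DataFrame:
    rows = []
    for k, b in enumerate(blocks):
        for sp, g in b.genomic.items():
            rows.append(
                {
                    "gene": b.gene_id,
                    "block": k,
                    "aln_start": b.aln_start,
                    "aln_end": b.aln_end,
                    "species": sp,
                    "contig": g[0] if g else None,
                    "genomic_start": g[1] if g else None,
                    "genomic_end": g[2] if g else None,
                    "strand": g[3] if g else None,
                }
            )
    return pd.DataFrame(rows)


# ---- FASTA / anchor IO ----------------------------------------------------


def write_alignment_fasta(
    alignment: AnchoredAlignment, fasta_path: str | Path, anchors_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="")
        for sp, seq in alignment.sequences.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [
            {
                "species": sp,
                "offset": a.offset,
                "strand": a.strand,
                "contig": a.contig,
            }
            for sp, a in alignment.anchors.items()
        ]
    ).to_csv(anchors_path, sep="\t", index=False)


def read_alignment_fasta(
    fasta_path: str | Path, anchors_path: str | Path, gene_id: str = "gene"
) -> AnchoredAlignment:
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    anchors = {
        row.species: SpeciesAnchor(int(row.offset), row.strand, row.contig)
        for row in pd.read_csv(anchors_path, sep="\t").itertuples()
    }
    return AnchoredAlignment(sequences, anchors, gene_id)
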