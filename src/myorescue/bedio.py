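"""Reading and writing of the plain-text formats the pipeline consumes.

Long reads are exchanged as BED12 (tab-separated, 0-based half-open,
blockStarts relative to chromStart), the toy gene as GTF, and tabular data
as TSV.  Minus-strand BED records are accepted as-is: coordinates in BED are
always given on the forward strand, so block arithmetic is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .splicemodel import ToyGeneModel

__all__ = ["BedRead", "read_bed12", "write_bed12", "write_gene_gtf", "read_events_tsv", "write_events_tsv"]


@dataclass(frozen=True)
class BedRead:
    """One block-aligned long read. ``blocks`` are absolute genomic
    0-based half-open intervals, sorted and non-overlapping."""

    chrom: str
    name: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "+"
    score: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.name!r} has zero blocks")
        blocks = tuple(sorted(self.blocks))
        object.__setattr__(self, "blocks", blocks)
        for s, e in blocks:
            if e <= s:
                raise ValueError(f"read {self.name!r} has a zero/negative-length block ({s}, {e})")
        for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise ValueError(f"read {self.name!r} has overlapping blocks")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def to_bed12_fields(self) -> list[str]:
        start, end = self.start, self.end
        sizes = ",".join(str(e - s) for s, e in self.blocks) + ","
        starts = ",".join(str(s - start) for s, _ in self.blocks) + ","
        return [
            self.chrom, str(start), str(end), self.name, str(self.score),
            self.strand, str(start), str(end), "0,0,0",
            str(len(self.blocks)), sizes, starts,
        ]


def write_bed12(reads: Iterable[BedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write("\t".join(read.to_bed12_fields()) + "\n")


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def read_bed12(path: str | Path) -> list[BedRead]:
    reads: list[BedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            chrom, start = fields[0], int(fields[1])
            sizes = _parse_int_list(fields[10])
            starts = _parse_int_list(fields[11])
            if len(sizes) != int(fields[9]) or len(starts) != int(fields[9]):
                raise ValueError(f"{path}:{lineno}: blockCount does not match block lists")
            blocks = tuple(
                (start + off, start + off + size) for off, size in zip(starts, sizes)
            )
            reads.append(
                BedRead(chrom=chrom, name=fields[3], blocks=blocks,
                        strand=fields[5], score=int(float(fields[4])))
            )
    return reads


def write_gene_gtf(gene: ToyGeneModel, path: str | Path, gene_id: str = "toygene") -> None:
    """Write the toy gene's constitutive exons (plus event intervals as
    attributes-tagged features) as GTF, 1-based inclusive per the format."""
    rows = []
    span = gene.span
    attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.canonical";'
    rows.append((gene.chrom, "myorescue", "transcript", span[0] + 1, span[1], ".", gene.strand, ".", attrs))
    for i, (s, e) in enumerate(gene.exons, 1):
        rows.append((gene.chrom, "myorescue", "exon", s + 1, e, ".", gene.strand, ".",
                     attrs + f' exon_number "{i}";'))
    for ev, (s, e, cls) in gene.event_map.items():
        ev_attrs = f'gene_id "{gene_id}"; event_id "{ev}"; event_class "{cls}";'
        rows.append((gene.chrom, "myorescue", "splice_event", s + 1, e, ".", gene.strand, ".", ev_attrs))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_events_tsv(gene: ToyGeneModel, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"event_id": ev, "class": cls, "chrom": gene.chrom, "start": s, "end": e}
            for ev, (s, e, cls) in gene.event_map.items()
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"event_id", "class", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df
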