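"""Gene models and their mapping onto contact-matrix bins.

Gene borders (TSS and TES) are where fine-scale contact domains anchor, so
the caller needs strand-aware gene intervals.  Internally coordinates are
1-based inclusive; BED input is converted from its 0-based half-open
convention on read and back on write.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GeneModel", "read_genes", "write_bed_genes", "gene_bins"]


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene interval.

    ``start``/``end`` are genomic left/right (1-based inclusive) regardless
    of strand; the TSS is the 5' border (``start`` on '+', ``end`` on '-')
    and the TES the opposite border.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


def _parse_gff3(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name") or f"gene_{lineno}"
            genes.append(
                GeneModel(gid, cols[0], int(cols[3]), int(cols[4]), cols[6])
            )
    return genes


def _parse_bed(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 requires 6 columns (strand needed)"
                )
            genes.append(
                GeneModel(cols[3], cols[0], int(cols[1]) + 1, int(cols[2]), cols[5])
            )
    return genes


def read_genes(path: str, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features only) or BED6.

    Output is sorted by ``(chrom, start, end)``; overlapping genes are all
    retained and tested independently downstream.
    """
    if format == "gff3":
        genes = _parse_gff3(path)
    elif format == "bed":
        genes = _parse_bed(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end))


def write_bed_genes(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def gene_bins(g: GeneModel, resolution: int) -> tuple[int, int]:
    """First and last bin index covered by the gene at ``resolution``."""
    return (g.start - 1) // resolution, (g.end - 1) // resolution
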