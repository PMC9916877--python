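"""Gene annotation container with interval queries, GFF3 and FASTA round trips.

Coordinates are 1-based inclusive throughout (GFF convention). The container
deliberately stays small: two DataFrames (genes, exons) plus per-chromosome
numpy arrays for overlap scans — annotations handled here are toy- to
small-genome scale, so no interval tree is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Annotation:
    """Genes with exon structure.

    ``genes``: gene_id, chrom, start, end, strand.
    ``exons``: gene_id, exon_number, chrom, start, end, strand.
    ``chrom_lengths``: optional chromosome sizes for bounds checking.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None
    _by_chrom: dict = field(default_factory=dict, repr=False)
    _exon_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        for chrom, sub in self.genes.groupby("chrom"):
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["strand"].to_numpy(),
                sub["gene_id"].to_numpy(),
            )

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[str]:
        """Gene ids overlapping [start, end] on ``chrom`` (optionally stranded)."""
        if chrom not in self._by_chrom:
            return []
        gs, ge, gstrand, gid = self._by_chrom[chrom]
        hit = (gs <= end) & (ge >= start)
        if strand is not None:
            hit &= gstrand == strand
        return list(gid[hit])

    def gene_record(self, gene_id: str) -> pd.Series:
        sub = self.genes.loc[self.genes["gene_id"] == gene_id]
        if sub.empty:
            raise KeyError(gene_id)
        return sub.iloc[0]

    def exon_intervals(self, gene_id: str) -> list[tuple[int, int]]:
        """Sorted exon (start, end) pairs of a gene."""
        if gene_id not in self._exon_cache:
            sub = self.exons.loc[self.exons["gene_id"] == gene_id]
            self._exon_cache[gene_id] = sorted(zip(sub["start"], sub["end"]))
        return self._exon_cache[gene_id]

    def intron_intervals(self, gene_id: str) -> list[tuple[int, int]]:
        exons = self.exon_intervals(gene_id)
        return [(a_end + 1, b_start - 1) for (_, a_end), (b_start, _) in zip(exons, exons[1:])]

    @property
    def has_introns(self) -> bool:
        counts = self.exons.groupby("gene_id").size()
        return bool((counts > 1).any())

    # -- IO ----------------------------------------------------------------
    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in self.genes.sort_values(["chrom", "start"]).iterrows():
                fh.write(
                    f"{g.chrom}\tcircheterosis\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )
                sub = self.exons.loc[self.exons["gene_id"] == g.gene_id].sort_values("start")
                for _, e in sub.iterrows():
                    fh.write(
                        f"{e.chrom}\tcircheterosis\texon\t{e.start}\t{e.end}\t.\t{e.strand}\t.\t"
                        f"ID={g.gene_id}.exon{e.exon_number};Parent={g.gene_id}\n"
                    )

    @classmethod
    def read_gff3(cls, path, chrom_lengths: dict[str, int] | None = None) -> "Annotation":
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        gene_rows, exon_rows = [], []
        for g in db.features_of_type("gene"):
            gene_rows.append(
                {"gene_id": g.id, "chrom": g.seqid, "start": g.start, "end": g.end,
                 "strand": g.strand}
            )
        for e in db.features_of_type("exon"):
            parent = e.attributes.get("Parent", [None])[0]
            exon_rows.append(
                {"gene_id": parent, "chrom": e.seqid, "start": e.start, "end": e.end,
                 "strand": e.strand}
            )
        exons = pd.DataFrame(exon_rows).sort_values(["gene_id", "start"])
        exons["exon_number"] = exons.groupby("gene_id").cumcount() + 1
        return cls(pd.DataFrame(gene_rows), exons.reset_index(drop=True), chrom_lengths)


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_sequence(
    genome: dict[str, str],
    annotation: Annotation,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    origin_class: str,
    gene_id: str | None = None,
) -> str:
    """circRNA sequence: spliced exon concatenation for exonic circRNAs,
    contiguous genomic sequence otherwise; reverse-complemented on minus strand.
    """
    if origin_class == "exonic":
        if gene_id is None:
            raise ValueError("exonic extraction needs the parent gene")
        parts = []
        for ex_start, ex_end in annotation.exon_intervals(gene_id):
            lo, hi = max(ex_start, start), min(ex_end, end)
            if lo <= hi:
                parts.append(genome[chrom][lo - 1 : hi])
        seq = "".join(parts)
    else:
        seq = genome[chrom][start - 1 : end]
    return revcomp(seq) if strand == "-" else seq
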