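"""Back-splice call integration and genomic-origin classification.

Two callers' per-sample back-splice tables are merged into one catalog:
calls whose start AND end coordinates agree within a tolerance (default
10 nt) on the same chromosome and strand are combined into one group, the
group takes the coordinates of its best-supported call, and per-sample read
counts are averaged where both callers report. Catalog entries are then
classified as intergenic / exonic / intronic / exon_intron by where the
back-splice span falls relative to the gene annotation, and mapped to their
parent genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import Annotation

CALL_COLUMNS = ["chrom", "start", "end", "strand", "n_reads", "sample_id"]


def _validate_calls(calls: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = set(CALL_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"{name} missing columns: {sorted(missing)}")
    if len(calls) and (calls["end"] < calls["start"]).any():
        raise ValueError(f"{name} has negative-length calls; check the coordinate convention")
    if len(calls) and (calls["n_reads"] < 0).any():
        raise ValueError(f"{name} has negative read counts")
    return calls


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def merge_calls(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    tolerance: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrate two callers' back-splice calls into one circRNA catalog.

    Grouping is single-link: two calls join one group iff same chromosome and
    strand, |dstart| <= tolerance and |dend| <= tolerance. The group
    representative is the call with the highest total read support (ties:
    caller A, then smaller start). Per-sample merged counts average the two
    callers where both report; a single-caller count is used un-averaged.

    Returns
    -------
    (catalog, counts)
        ``catalog``: circ_id, chrom, start, end, strand, length, n_callers,
        total_support. ``counts``: circ_id x sample_id merged read counts.
    """
    calls_a = _validate_calls(calls_a, "calls_a").assign(caller="A")
    calls_b = _validate_calls(calls_b, "calls_b").assign(caller="B")
    calls = pd.concat([calls_a, calls_b], ignore_index=True)
    if calls.empty:
        empty_cat = pd.DataFrame(
            columns=["circ_id", "chrom", "start", "end", "strand", "length",
                     "n_callers", "total_support"]
        )
        return empty_cat, pd.DataFrame()

    uniq = (
        calls.groupby(["caller", "chrom", "start", "end", "strand"], as_index=False)
        ["n_reads"].sum().rename(columns={"n_reads": "total_reads"})
    )
    uniq["group"] = -1
    next_group = 0
    for (_, _), block_idx in uniq.groupby(["chrom", "strand"]).groups.items():
        block = uniq.loc[block_idx].sort_values("start")
        idx = block.index.to_numpy()
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        uf = _UnionFind(len(idx))
        for i in range(len(idx)):
            j = i + 1
            while j < len(idx) and starts[j] - starts[i] <= tolerance:
                if abs(int(ends[j]) - int(ends[i])) <= tolerance:
                    uf.union(i, j)
                j += 1
        roots = [uf.find(i) for i in range(len(idx))]
        labels = {}
        for i, r in enumerate(roots):
            if r not in labels:
                labels[r] = next_group
                next_group += 1
            uniq.loc[idx[i], "group"] = labels[r]

    # representative per group: highest support, then caller A, then smaller start
    reps = (
        uniq.sort_values(["group", "total_reads", "caller", "start"],
                         ascending=[True, False, True, True])
        .groupby("group", as_index=False).first()
    )
    reps = reps.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    reps["circ_id"] = [f"novel_circ_{i + 1:06d}" for i in range(len(reps))]
    group_to_id = dict(zip(reps["group"], reps["circ_id"]))

    key_cols = ["caller", "chrom", "start", "end", "strand"]
    calls = calls.merge(uniq[key_cols + ["group"]], on=key_cols, how="left")
    calls["circ_id"] = calls["group"].map(group_to_id)

    per_caller = (
        calls.groupby(["circ_id", "sample_id", "caller"])["n_reads"].sum().unstack("caller")
    )
    merged = per_caller.mean(axis=1, skipna=True)  # single-caller counts pass through
    counts = merged.unstack("sample_id").fillna(0.0)
    counts = counts.reindex(reps["circ_id"])

    n_callers = calls.groupby("circ_id")["caller"].nunique()
    total_support = counts.sum(axis=1)
    catalog = reps[["circ_id", "chrom", "start", "end", "strand"]].copy()
    catalog["length"] = catalog["end"] - catalog["start"] + 1
    catalog["n_callers"] = catalog["circ_id"].map(n_callers).astype(int)
    catalog["total_support"] = catalog["circ_id"].map(total_support)
    return catalog, counts


def classify_origin(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    annotation: Annotation,
) -> tuple[str, list[str], bool]:
    """Classify one back-splice span; returns (origin_class, parent_gene_ids,
    strand_rescued).

    exonic: both ends fall in exons of one gene and the span stays within that
    gene. intronic: the span lies entirely within a single intron. exon_intron:
    gene-overlapping but neither purely exonic nor purely intronic. intergenic:
    no gene overlap. Overlap is tested on the matching strand first, then
    rescued strand-agnostically (antisense-derived circRNAs; flagged).
    """
    if annotation.chrom_lengths is not None:
        length = annotation.chrom_lengths.get(chrom)
        if length is not None and (start < 1 or end > length):
            raise ValueError(f"circRNA {chrom}:{start}-{end} outside chromosome bounds")
    hits = annotation.genes_overlapping(chrom, start, end, strand=strand)
    rescued = False
    if not hits:
        hits = annotation.genes_overlapping(chrom, start, end, strand=None)
        rescued = bool(hits)
    if not hits:
        return "intergenic", [], False

    def _in_any(intervals, pos):
        return any(lo <= pos <= hi for lo, hi in intervals)

    for gid in hits:
        g = annotation.gene_record(gid)
        if g.start <= start and end <= g.end:
            exons = annotation.exon_intervals(gid)
            if _in_any(exons, start) and _in_any(exons, end):
                return "exonic", hits, rescued
            for ilo, ihi in annotation.intron_intervals(gid):
                if ilo <= start and end <= ihi:
                    return "intronic", hits, rescued
            return "exon_intron", hits, rescued
    return "exon_intron", hits, rescued


def classify_catalog(catalog: pd.DataFrame, annotation: Annotation) -> pd.DataFrame:
    """Vector wrapper over :func:`classify_origin`; adds ``origin_class``,
    ``parent_gene_ids`` (comma-joined) and ``strand_rescued`` columns."""
    out = catalog.copy()
    results = [
        classify_origin(r.chrom, r.start, r.end, r.strand, annotation)
        for r in catalog.itertuples()
    ]
    out["origin_class"] = [r[0] for r in results]
    out["parent_gene_ids"] = [",".join(r[1]) for r in results]
    out["strand_rescued"] = [r[2] for r in results]
    return out


def assign_parent_genes(
    classified: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """circRNA -> parent-gene map plus the circRNAs-per-gene distribution.

    Returns (mapping, per_gene_counts, summary) where ``summary`` bins parent
    genes by how many circRNAs they host (1, 2, 3+) with fractions.
    """
    rows = []
    for r in classified.itertuples():
        if r.origin_class == "intergenic" or not r.parent_gene_ids:
            continue
        for gid in r.parent_gene_ids.split(","):
            rows.append({"circ_id": r.circ_id, "gene_id": gid})
    mapping = pd.DataFrame(rows, columns=["circ_id", "gene_id"])
    per_gene = mapping.groupby("gene_id")["circ_id"].nunique() if len(mapping) else pd.Series(dtype=int)
    per_gene.name = "n_circ"
    binned = per_gene.map(lambda n: "1" if n == 1 else ("2" if n == 2 else "3+"))
    summary = (
        binned.value_counts().reindex(["1", "2", "3+"], fill_value=0).rename("n_genes").to_frame()
    )
    total = summary["n_genes"].sum()
    summary["fraction"] = summary["n_genes"] / total if total else 0.0
    return mapping, per_gene, summary.reset_index(names="circ_per_gene")


def catalog_to_bed(catalog: pd.DataFrame) -> pd.DataFrame:
    """BED-like view (0-based half-open start) of the catalog."""
    bed = pd.DataFrame(
        {
            "chrom": catalog["chrom"],
            "start": catalog["start"] - 1,
            "end": catalog["end"],
            "name": catalog["circ_id"],
            "score": catalog["total_support"],
            "strand": catalog["strand"],
        }
    )
    return bed
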