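"""Fully labelled synthetic study generator.

Emulates the stated trial design — two parents (FP high growth potential, MP
low) and five F1 hybrids (three high-, two low-growth) with three biological
replicates each — and plants every label the downstream pipeline must
recover: genomic origin classes, additive/non-additive heterosis classes and
their Stupar subtypes, the SPE-F/SPE-M/CoPE/SFE parental taxonomy as exact
structural zeros, dual-caller back-splice calls with bounded coordinate
jitter, perfect-complement miRNA target sites, and junction-spanning open
reading frames written into the genome before sequence extraction.

Count noise is negative binomial (Gamma-Poisson); ``dispersion=0`` degrades
to Poisson. All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .annotation import Annotation, extract_sequence, revcomp, write_fasta
from .design import SampleDesign, default_design

ORIGIN_CLASSES = ("intergenic", "exonic", "intronic", "exon_intron")
HETEROSIS_CLASSES = ("additive", "AHP", "HP", "LP", "BLP")
PATTERNS = ("CoPE", "SPE_F", "SPE_M", "SFE")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: realized fractions of the published catalog (3722 circRNAs: 612+529 SPE,
#: 392 parent-co-expressed, 2189 F1-specific)
DEFAULT_PATTERN_MIX = {"CoPE": 0.105, "SPE_F": 0.164, "SPE_M": 0.142, "SFE": 0.589}
#: additive expression dominates (~90-95% of tested circRNAs); HP is rare (0-1.6%)
DEFAULT_CLASS_MIX = {"additive": 0.92, "AHP": 0.03, "HP": 0.005, "LP": 0.025, "BLP": 0.02}
DEFAULT_ORIGIN_MIX = (0.572, 0.402, 0.010, 0.016)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated study."""

    circ_truth: pd.DataFrame  # circ_id, chrom, start, end, strand, origin_class, parent_gene_id, sequence
    annotation: Annotation
    genome: dict[str, str]
    class_labels: pd.DataFrame | None = None  # circ_id, f1_genotype, heterosis_class
    parental_pattern: pd.Series | None = None  # circ_id -> CoPE/SPE_F/SPE_M/SFE
    planted_targets: pd.DataFrame | None = None  # circ_id, mirna_id, offset
    planted_orfs: pd.DataFrame = None  # circ_id, offset, length_nt, spans_junction
    rpm_means: pd.DataFrame | None = None  # circ x genotype planted RPM means
    seed: int = 0

    @property
    def circ_ids(self) -> list[str]:
        return list(self.circ_truth["circ_id"])

    @property
    def sequences(self) -> dict[str, str]:
        return dict(zip(self.circ_truth["circ_id"], self.circ_truth["sequence"]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_annotation(
    seed: int,
    n_chroms: int = 3,
    n_genes: int = 60,
    exon_length_range: tuple[int, int] = (80, 300),
    intron_length_range: tuple[int, int] = (60, 200),
    exons_per_gene: tuple[int, int] = (1, 4),
    intergenic_gap: tuple[int, int] = (250, 800),
) -> tuple[Annotation, dict[str, str]]:
    """Lay non-overlapping genes with exon/intron structure along random chromosomes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name, rng_pair in [
        ("exon_length_range", exon_length_range),
        ("intron_length_range", intron_length_range),
        ("intergenic_gap", intergenic_gap),
    ]:
        if rng_pair[0] <= 0 or rng_pair[1] < rng_pair[0]:
            raise ValueError(f"{name} must be a positive (lo, hi) pair")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    cursors = {c: 0 for c in chrom_names}
    gene_rows, exon_rows = [], []
    for i in range(n_genes):
        chrom = chrom_names[i % n_chroms]
        strand = rng.choice(["+", "-"])
        gene_id = f"gene_{i + 1:04d}"
        pos = cursors[chrom] + int(rng.integers(*intergenic_gap, endpoint=True))
        n_exons = int(rng.integers(*exons_per_gene, endpoint=True))
        start = pos + 1
        for k in range(n_exons):
            ex_len = int(rng.integers(*exon_length_range, endpoint=True))
            exon_rows.append(
                {"gene_id": gene_id, "exon_number": k + 1, "chrom": chrom,
                 "start": pos + 1, "end": pos + ex_len, "strand": strand}
            )
            pos += ex_len
            if k < n_exons - 1:
                pos += int(rng.integers(*intron_length_range, endpoint=True))
        gene_rows.append(
            {"gene_id": gene_id, "chrom": chrom, "start": start, "end": pos,
             "strand": strand}
        )
        cursors[chrom] = pos
    genome = {}
    for chrom in chrom_names:
        length = cursors[chrom] + int(rng.integers(*intergenic_gap, endpoint=True))
        genome[chrom] = _random_seq(rng, length)
    lengths = {c: len(s) for c, s in genome.items()}
    ann = Annotation(pd.DataFrame(gene_rows), pd.DataFrame(exon_rows), lengths)
    return ann, genome


def _sample_span(rng, lo: int, hi: int, length_range) -> tuple[int, int]:
    """A (start, end) pair inside [lo, hi], targeting the 100-700 nt range."""
    room = hi - lo + 1
    min_len = min(length_range[0], room)
    max_len = min(length_range[1], room)
    length = int(rng.integers(min_len, max_len, endpoint=True))
    start = lo + int(rng.integers(0, room - length, endpoint=True))
    return start, start + length - 1


def _separated(placed: list[tuple[int, int]], start: int, end: int, min_sep: int = 25) -> bool:
    """Reject candidates whose start AND end both sit within merge-ambiguity
    distance of an existing circRNA (keeps jittered caller calls unambiguous)."""
    return all(
        abs(start - s) > min_sep or abs(end - e) > min_sep for s, e in placed
    )


def generate_circ_truth(
    annotation: Annotation,
    genome: dict[str, str],
    n_circ: int = 300,
    origin_mix: tuple[float, float, float, float] = DEFAULT_ORIGIN_MIX,
    length_range: tuple[int, int] = (100, 700),
    orf_rate: float = 0.08,
    orf_codon_range: tuple[int, int] = (21, 40),
    seed: int = 0,
) -> SyntheticTruth:
    """Plant circRNA coordinates of the four origin classes and extract sequences.

    ``origin_mix`` is (intergenic, exonic, intronic, exon_intron) and must sum
    to 1. A fraction ``orf_rate`` of intergenic circRNAs receives a
    junction-spanning ORF (ATG + non-stop codons + stop) written into the
    genome before extraction, so every sequence still equals its genomic
    subsequence.
    """
    if abs(sum(origin_mix) - 1.0) > 1e-9:
        raise ValueError("origin_mix must sum to 1")
    rng = np.random.default_rng(seed)
    if origin_mix[2] > 0 and not annotation.has_introns:
        raise ValueError("annotation has no introns but intronic proportion > 0")
    class_counts = rng.multinomial(n_circ, origin_mix)
    classes = [c for c, n in zip(ORIGIN_CLASSES, class_counts) for _ in range(n)]
    rng.shuffle(classes)

    genes = annotation.genes
    multi_exon = [g for g in genes["gene_id"] if len(annotation.exon_intervals(g)) > 1]
    chrom_names = list(genome)
    placed_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    intergenic_occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    rows = []
    for cls in classes:
        for _ in range(500):  # rejection sampling
            if cls == "intergenic":
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                strand = rng.choice(["+", "-"])
                gs = genes.loc[genes["chrom"] == chrom]
                bounds = sorted(zip(gs["start"], gs["end"]))
                # a 6-nt margin from chromosome ends keeps jittered caller
                # coordinates within bounds
                gaps, prev = [], 6
                for s, e in bounds:
                    if s - 1 - prev >= length_range[0] + 2:
                        gaps.append((prev + 1, s - 1))
                    prev = max(prev, e)
                if len(genome[chrom]) - 6 - prev >= length_range[0] + 2:
                    gaps.append((prev + 1, len(genome[chrom]) - 6))
                if not gaps:
                    continue
                lo, hi = gaps[int(rng.integers(len(gaps)))]
                start, end = _sample_span(rng, lo, hi, length_range)
                # intergenic circRNAs stay mutually non-overlapping so ORF
                # planting can edit the genome without corrupting neighbours
                if any(start <= e and end >= s for s, e in intergenic_occupied[chrom]):
                    continue
                gene_id = None
            else:
                if cls == "exonic":
                    g = genes.iloc[int(rng.integers(len(genes)))]
                    exons = annotation.exon_intervals(g.gene_id)
                    i = int(rng.integers(len(exons)))
                    j = int(rng.integers(i, len(exons)))
                    s_lo, s_hi = exons[i]
                    e_lo, e_hi = exons[j]
                    start = int(rng.integers(s_lo, s_hi, endpoint=True))
                    end = int(rng.integers(max(e_lo, start), e_hi, endpoint=True))
                    if end - start + 1 < 60:
                        continue
                elif cls == "intronic":
                    if not multi_exon:
                        continue
                    gid = multi_exon[int(rng.integers(len(multi_exon)))]
                    g = annotation.gene_record(gid)
                    introns = annotation.intron_intervals(gid)
                    lo, hi = introns[int(rng.integers(len(introns)))]
                    if hi - lo + 1 < 40:
                        continue
                    start, end = _sample_span(rng, lo, hi, (40, length_range[1]))
                else:  # exon_intron: start inside an exon, end inside the next intron
                    if not multi_exon:
                        continue
                    gid = multi_exon[int(rng.integers(len(multi_exon)))]
                    g = annotation.gene_record(gid)
                    exons = annotation.exon_intervals(gid)
                    introns = annotation.intron_intervals(gid)
                    k = int(rng.integers(len(introns)))
                    start = int(rng.integers(exons[k][0], exons[k][1], endpoint=True))
                    ilo, ihi = introns[k]
                    if ihi - ilo < 4:
                        continue
                    end = int(rng.integers(ilo + 1, ihi - 1, endpoint=True))
                chrom, strand, gene_id = g.chrom, g.strand, g.gene_id
            if not _separated(placed_by_chrom[chrom], start, end):
                continue
            placed_by_chrom[chrom].append((start, end))
            if cls == "intergenic":
                intergenic_occupied[chrom].append((start, end))
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "strand": strand,
                 "origin_class": cls, "parent_gene_id": gene_id}
            )
            break
        else:
            raise RuntimeError(f"could not place a {cls} circRNA; enlarge the annotation")

    df = pd.DataFrame(rows).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    df["circ_id"] = [f"novel_circ_{i + 1:06d}" for i in range(len(df))]

    # --- plant junction-spanning ORFs into intergenic circRNAs ------------
    editable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    orf_rows = []
    for _, row in df.iterrows():
        if row.origin_class != "intergenic" or rng.random() >= orf_rate:
            continue
        L = row.end - row.start + 1
        n_codons = int(rng.integers(*orf_codon_range, endpoint=True))
        orf_len = 3 * n_codons
        if orf_len + 6 > L:
            continue
        codons = ["ATG"]
        while len(codons) < n_codons - 1:
            c = _random_seq(rng, 3)
            if c not in STOP_CODONS:
                codons.append(c)
        codons.append(STOP_CODONS[int(rng.integers(3))])
        orf_seq = "".join(codons)
        overhang = int(rng.integers(3, orf_len - 3))  # nt of the ORF before the junction
        offset = L - overhang
        circ_seq = list(_random_seq(rng, L))
        for i, base in enumerate(orf_seq):
            circ_seq[(offset + i) % L] = base
        # avoid an accidental upstream in-frame ATG shadowing the planted start
        circ_str = "".join(circ_seq)
        segment = circ_str if row.strand == "+" else revcomp(circ_str)
        editable[row.chrom][row.start - 1 : row.end] = segment.encode("ascii")
        orf_rows.append(
            {"circ_id": row.circ_id, "offset": offset, "length_nt": orf_len,
             "spans_junction": True}
        )
    genome = {c: b.decode("ascii") for c, b in editable.items()}

    df["sequence"] = [
        extract_sequence(genome, annotation, r.chrom, r.start, r.end, r.strand,
                         r.origin_class, r.parent_gene_id)
        for r in df.itertuples()
    ]
    planted_orfs = pd.DataFrame(orf_rows, columns=["circ_id", "offset", "length_nt", "spans_junction"])
    return SyntheticTruth(
        circ_truth=df, annotation=annotation, genome=genome,
        planted_orfs=planted_orfs, seed=seed,
    )


def _resolve_class(pattern: str, cls: str) -> str:
    """Reconcile a drawn heterosis class with the parental pattern's structural
    zeros (some combinations are definitionally impossible)."""
    if pattern == "SFE":
        return "AHP"  # expressed only in F1 => significantly above MPV=0
    if pattern == "SPE_F" and cls == "BLP":
        return "LP"  # F1 cannot fall below the absent male parent
    if pattern == "SPE_M" and cls == "LP":
        return "BLP"  # F1 cannot stay above MPV/2 yet >= the male parent
    if pattern == "SPE_M" and cls == "HP":
        return "AHP"  # HP requires the male parent to be absent
    if pattern == "CoPE" and cls == "HP":
        return "AHP"  # HP needs mu_MP ~ 0, incompatible with co-expression
    return cls


def generate_expression(
    truth: SyntheticTruth,
    design: SampleDesign,
    class_mix: dict[str, float] = None,
    pattern_mix: dict[str, float] = None,
    effect_fold: float = 4.0,
    dispersion: float = 0.1,
    base_rpm: tuple[float, float] = (8.0, 400.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Plant per-genotype RPM means and draw NB back-spliced read counts.

    Fills ``truth.class_labels``, ``truth.parental_pattern`` and
    ``truth.rpm_means`` and returns the circRNA x sample count matrix.
    SPE/SFE absences are exact structural zeros. The planted heterosis class
    is shared by all F1 genotypes of a circRNA.
    """
    class_mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    pattern_mix = dict(DEFAULT_PATTERN_MIX if pattern_mix is None else pattern_mix)
    for name, mix in [("class_mix", class_mix), ("pattern_mix", pattern_mix)]:
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")
    if effect_fold <= 1:
        raise ValueError("effect_fold must be > 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    circ_ids = truth.circ_ids
    f1_gts = design.f1_genotypes
    fp_gt, mp_gt = design.genotype_of_role("FP"), design.genotype_of_role("MP")
    genotypes = [fp_gt, mp_gt] + f1_gts

    patterns = rng.choice(list(pattern_mix), size=len(circ_ids), p=list(pattern_mix.values()))
    classes = rng.choice(list(class_mix), size=len(circ_ids), p=list(class_mix.values()))

    # log-uniform base expression, floored so detection is never noise-limited
    lo, hi = np.log(base_rpm[0]), np.log(base_rpm[1])
    base = np.exp(rng.uniform(lo, hi, size=len(circ_ids)))

    means = pd.DataFrame(0.0, index=circ_ids, columns=genotypes)
    label_rows = []
    for i, cid in enumerate(circ_ids):
        pat = patterns[i]
        cls = _resolve_class(pat, classes[i])
        b = base[i]
        if pat == "CoPE":
            if cls == "LP":
                # LP needs parents skewed enough that F1 can sit `effect_fold`
                # below MPV while staying at or above the male parent
                mu_fp, mu_mp = 2.0 * effect_fold * b, b
            else:
                skew = rng.uniform(0.7, 1.4)
                mu_fp, mu_mp = b * skew, b / skew
        elif pat == "SPE_F":
            mu_fp, mu_mp = 2.0 * b, 0.0
        elif pat == "SPE_M":
            mu_fp, mu_mp = 0.0, 2.0 * b
        else:  # SFE
            mu_fp, mu_mp = 0.0, 0.0
        mpv = (mu_fp + mu_mp) / 2.0
        if pat == "SFE":
            mu_f1 = max(b, 10.0)
        elif cls == "additive":
            mu_f1 = mpv
        elif cls == "AHP":
            mu_f1 = effect_fold * max(mpv, mu_fp, 10.0 if mpv == 0 else 0.0)
        elif cls == "HP":
            mu_f1 = mu_fp  # exactly 2x MPV: the HP boundary (see methods note)
        elif cls == "LP":
            mu_f1 = max(mpv / effect_fold, mu_mp)
        else:  # BLP
            mu_f1 = min(mpv / effect_fold, mu_mp / 2.0)
        means.loc[cid, fp_gt] = mu_fp
        means.loc[cid, mp_gt] = mu_mp
        for gt in f1_gts:
            means.loc[cid, gt] = mu_f1
            label_rows.append({"circ_id": cid, "f1_genotype": gt, "heterosis_class": cls})

    # NB draws: mean in counts = RPM * depth / 1e6; var = m + dispersion * m^2
    counts = pd.DataFrame(0, index=circ_ids, columns=design.sample_ids, dtype=int)
    for gt in genotypes:
        mu_rpm = means[gt].to_numpy()
        for s in design.samples_of(gt):
            m = mu_rpm * design.mapped_reads[s] / 1e6
            lam = m.copy()
            positive = m > 0
            if dispersion > 0:
                shape = 1.0 / dispersion
                lam[positive] = rng.gamma(shape, m[positive] * dispersion)
            draws = np.zeros_like(m, dtype=int)
            draws[positive] = rng.poisson(lam[positive])
            counts[s] = draws

    truth.class_labels = pd.DataFrame(label_rows)
    truth.parental_pattern = pd.Series(patterns, index=circ_ids, name="parental_pattern")
    truth.rpm_means = means
    return counts


def generate_caller_calls(
    truth: SyntheticTruth,
    counts: pd.DataFrame,
    design: SampleDesign,
    jitter_sd: float = 2.0,
    fn_rate: float = 0.05,
    count_noise: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate two back-splice callers: per-caller coordinate jitter (truncated
    to +/-5 nt per end so every planted pair stays within the 10-nt merge
    window), per-caller dropout, and relative count noise around the common
    support value."""
    if not (0 <= fn_rate < 1):
        raise ValueError("fn_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    tables = {"A": [], "B": []}
    for row in truth.circ_truth.itertuples():
        per_circ = counts.loc[row.circ_id]
        for caller in ("A", "B"):
            dropped = rng.random() < fn_rate
            if jitter_sd > 0:
                js = int(np.clip(round(rng.normal(0, jitter_sd)), -5, 5))
                je = int(np.clip(round(rng.normal(0, jitter_sd)), -5, 5))
            else:
                js = je = 0
            if dropped:
                continue
            for sample_id, n in per_circ.items():
                if n <= 0:
                    continue
                if count_noise > 0:
                    n_obs = max(1, int(round(n * (1.0 + rng.normal(0, count_noise)))))
                else:
                    n_obs = int(n)
                tables[caller].append(
                    {"chrom": row.chrom, "start": row.start + js, "end": row.end + je,
                     "strand": row.strand, "n_reads": n_obs, "sample_id": sample_id}
                )
    cols = ["chrom", "start", "end", "strand", "n_reads", "sample_id"]
    return (pd.DataFrame(tables["A"], columns=cols),
            pd.DataFrame(tables["B"], columns=cols))


def generate_mirnas(
    truth: SyntheticTruth,
    n_mirnas: int = 30,
    planted_site_rate: float = 0.4,
    mirna_length: int = 21,
    seed: int = 0,
) -> dict[str, str]:
    """miRNA set with planted perfect target sites.

    A planted miRNA is the exact reverse complement of a circular window of a
    chosen circRNA (junction-spanning windows allowed), so the Allen-rule
    penalty at the recorded offset is exactly 0; the rest are random
    background. Fills ``truth.planted_targets``.
    """
    if not 20 <= mirna_length <= 22:
        raise ValueError("miRNA length must be 20-22 nt")
    rng = np.random.default_rng(seed)
    seqs = truth.sequences
    eligible = [cid for cid, s in seqs.items() if len(s) >= mirna_length]
    mirnas, target_rows = {}, []
    for i in range(n_mirnas):
        mid = f"mir_{i + 1:03d}"
        if eligible and rng.random() < planted_site_rate:
            cid = eligible[int(rng.integers(len(eligible)))]
            circ = seqs[cid]
            L = len(circ)
            offset = int(rng.integers(0, L))
            window = (circ + circ)[offset : offset + mirna_length]
            mirnas[mid] = revcomp(window)
            target_rows.append({"circ_id": cid, "mirna_id": mid, "offset": offset})
        else:
            mirnas[mid] = _random_seq(rng, mirna_length)
    truth.planted_targets = pd.DataFrame(
        target_rows, columns=["circ_id", "mirna_id", "offset"]
    )
    return mirnas


def generate_gene_expression(
    truth: SyntheticTruth,
    circ_rpm: pd.DataFrame,
    design: SampleDesign,
    coupling: float = 0.35,
    noise_sd: float = 0.05,
    base_fpkm: tuple[float, float] = (5.0, 100.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level FPKM matrix with planted circRNA/parent-gene coupling.

    Parent genes of SPE-M circRNAs co-vary negatively with their circRNA,
    all other parent genes positively; genes without a circRNA are
    independent log-uniform noise.
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.annotation.genes["gene_id"])
    samples = design.sample_ids
    lo, hi = np.log(base_fpkm[0]), np.log(base_fpkm[1])
    fpkm = pd.DataFrame(
        np.exp(rng.uniform(lo, hi, size=(len(genes), 1)))
        * np.exp(rng.normal(0, noise_sd, size=(len(genes), len(samples)))),
        index=genes, columns=samples,
    )
    parent_map = truth.circ_truth.dropna(subset=["parent_gene_id"])
    for gid, sub in parent_map.groupby("parent_gene_id"):
        cid = sub.iloc[0]["circ_id"]
        if cid not in circ_rpm.index:
            continue
        v = circ_rpm.loc[cid, samples].to_numpy(dtype=float)
        if v.std() == 0:
            continue
        z = (v - v.mean()) / v.std()
        sign = -1.0 if truth.parental_pattern is not None and truth.parental_pattern.get(cid) == "SPE_M" else 1.0
        base = fpkm.loc[gid].mean()
        fpkm.loc[gid] = np.maximum(
            base * (1.0 + sign * coupling * z) * np.exp(rng.normal(0, noise_sd, len(samples))),
            0.01,
        )
    return fpkm


def generate_module_matrix(
    n_blocks: int = 3,
    block_size: int = 30,
    n_samples: int = 21,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Block-structured feature x sample matrix for module-recovery checks."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b in range(n_blocks):
        latent = rng.normal(0, 1, size=n_samples)
        for i in range(block_size):
            rows.append(latent + rng.normal(0, noise_sd, size=n_samples))
            labels.append(b)
    idx = [f"feat_{i + 1:04d}" for i in range(len(rows))]
    df = pd.DataFrame(rows, index=idx, columns=[f"s{j + 1}" for j in range(n_samples)])
    return df, pd.Series(labels, index=idx, name="block")


def write_run_manifest(path, params: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def simulate_study(
    seed: int = 0,
    n_genes: int = 60,
    n_circ: int = 300,
    n_mirnas: int = 30,
    origin_mix: tuple[float, float, float, float] = DEFAULT_ORIGIN_MIX,
    class_mix: dict[str, float] | None = None,
    pattern_mix: dict[str, float] | None = None,
    effect_fold: float = 4.0,
    dispersion: float = 0.1,
    jitter_sd: float = 2.0,
    fn_rate: float = 0.05,
    count_noise: float = 0.1,
) -> dict:
    """One-call convenience wrapper producing every input the pipeline consumes."""
    ss = np.random.SeedSequence(seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    # enough genes (hence intergenic gaps) to place the requested catalog
    n_genes = max(n_genes, int(n_circ * 0.8) + 5)
    ann, genome = generate_annotation(sub[0], n_genes=n_genes)
    truth = generate_circ_truth(ann, genome, n_circ=n_circ, origin_mix=origin_mix, seed=sub[1])
    design = default_design(seed=np.random.default_rng(sub[2]))
    counts = generate_expression(
        truth, design, class_mix=class_mix, pattern_mix=pattern_mix,
        effect_fold=effect_fold, dispersion=dispersion, seed=sub[3],
    )
    calls_a, calls_b = generate_caller_calls(
        truth, counts, design, jitter_sd=jitter_sd, fn_rate=fn_rate,
        count_noise=count_noise, seed=sub[4],
    )
    mirnas = generate_mirnas(truth, n_mirnas=n_mirnas, seed=sub[5])
    return {
        "truth": truth, "design": design, "counts": counts,
        "calls_a": calls_a, "calls_b": calls_b, "mirnas": mirnas,
    }


def write_study(study: dict, outdir) -> None:
    """Serialize a simulated study as plain-text files (GFF3/FASTA/TSV)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    truth: SyntheticTruth = study["truth"]
    truth.annotation.write_gff3(os.path.join(outdir, "annotation.gff3"))
    write_fasta(truth.genome, os.path.join(outdir, "genome.fa"))
    write_fasta(truth.sequences, os.path.join(outdir, "circ_sequences.fa"))
    write_fasta(study["mirnas"], os.path.join(outdir, "mirnas.fa"))
    study["design"].to_tsv(os.path.join(outdir, "design.tsv"))
    study["counts"].rename_axis("circ_id").to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    study["calls_a"].to_csv(os.path.join(outdir, "calls_A.tsv"), sep="\t", index=False)
    study["calls_b"].to_csv(os.path.join(outdir, "calls_B.tsv"), sep="\t", index=False)
    truth.circ_truth.drop(columns=["sequence"]).to_csv(
        os.path.join(outdir, "circ_truth.tsv"), sep="\t", index=False
    )
    if truth.class_labels is not None:
        truth.class_labels.to_csv(os.path.join(outdir, "class_labels.tsv"), sep="\t", index=False)
    if truth.parental_pattern is not None:
        truth.parental_pattern.rename_axis("circ_id").to_csv(
            os.path.join(outdir, "parental_pattern.tsv"), sep="\t"
        )
    if truth.planted_targets is not None:
        truth.planted_targets.to_csv(os.path.join(outdir, "planted_targets.tsv"), sep="\t", index=False)
    truth.planted_orfs.to_csv(os.path.join(outdir, "planted_orfs.tsv"), sep="\t", index=False)
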