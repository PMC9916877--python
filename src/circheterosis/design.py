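"""Sample design: which sample belongs to which genotype, role and replicate.

The study layout this package targets is a heterosis trial: a female parent
(FP), a male parent (MP) and several F1 hybrids split into a high- and a
low-growth-potential group, each genotype with a small number of biological
replicates. Per-sample mapped-read totals are carried alongside because
circRNA expression is normalised to reads-per-million (RPM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("FP", "MP", "F1_high", "F1_low")


@dataclass
class SampleDesign:
    """Sample -> genotype/role/replicate map plus per-sample mapped-read totals.

    Attributes
    ----------
    samples
        DataFrame with columns ``sample_id``, ``genotype``, ``role``,
        ``replicate`` (1-based replicate index).
    mapped_reads
        Total clean mapped reads per sample, indexed by ``sample_id``.
    """

    samples: pd.DataFrame
    mapped_reads: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        required = {"sample_id", "genotype", "role", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        bad = set(self.samples["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}; expected {ROLES}")
        for role in ("FP", "MP"):
            gts = self.samples.loc[self.samples["role"] == role, "genotype"].unique()
            if len(gts) > 1:
                raise ValueError(f"role {role} maps to several genotypes: {list(gts)}")
        roles_per_gt = self.samples.groupby("genotype")["role"].nunique()
        if (roles_per_gt > 1).any():
            raise ValueError("each genotype must have exactly one role")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.mapped_reads is not None:
            self.mapped_reads = pd.Series(self.mapped_reads, dtype=float)
            missing_ids = set(self.samples["sample_id"]) - set(self.mapped_reads.index)
            if missing_ids:
                raise ValueError(f"mapped_reads missing samples: {sorted(missing_ids)}")

    # -- lookups -----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.samples["genotype"]))

    def genotype_of_role(self, role: str) -> str:
        gts = self.samples.loc[self.samples["role"] == role, "genotype"].unique()
        if len(gts) != 1:
            raise ValueError(f"role {role} does not map to exactly one genotype")
        return gts[0]

    def samples_of(self, genotype: str) -> list[str]:
        sel = self.samples.loc[self.samples["genotype"] == genotype, "sample_id"]
        if sel.empty:
            raise KeyError(f"unknown genotype {genotype!r}")
        return list(sel)

    def genotypes_of_role(self, role: str) -> list[str]:
        return list(
            dict.fromkeys(self.samples.loc[self.samples["role"] == role, "genotype"])
        )

    def role_of(self, genotype: str) -> str:
        sel = self.samples.loc[self.samples["genotype"] == genotype, "role"].unique()
        if len(sel) != 1:
            raise KeyError(f"unknown genotype {genotype!r}")
        return sel[0]

    @property
    def f1_genotypes(self) -> list[str]:
        return self.genotypes_of_role("F1_high") + self.genotypes_of_role("F1_low")

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.samples.copy()
        if self.mapped_reads is not None:
            out["mapped_reads"] = self.mapped_reads.reindex(out["sample_id"]).values
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t")
        mapped = None
        if "mapped_reads" in df.columns:
            mapped = pd.Series(df["mapped_reads"].values, index=df["sample_id"].values)
            df = df.drop(columns=["mapped_reads"])
        return cls(df, mapped)


def default_design(
    n_reps: int = 3,
    mapped_read_range: tuple[float, float] = (4e6, 6e6),
    seed: int | np.random.Generator = 0,
) -> SampleDesign:
    """The 7-genotype trial: FP, MP, three high-growth and two low-growth F1s.

    Mapped-read totals are drawn uniformly in ``mapped_read_range``. The
    default (4-6 million at toy scale) mirrors the near-equal sequencing
    depths of the emulated study: samples there differ by only a few percent,
    and near-equal depths keep the pooled mid-parent pseudo-library rate an
    unbiased stand-in for the mean-RPM MPV while still exercising RPM
    normalisation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genotypes = [
        ("Y3FP", "FP"),
        ("Y3MP", "MP"),
        ("Y3H1", "F1_high"),
        ("Y3H2", "F1_high"),
        ("Y3H3", "F1_high"),
        ("Y3L3", "F1_low"),
        ("Y3L4", "F1_low"),
    ]
    rows = []
    for gt, role in genotypes:
        for rep in range(1, n_reps + 1):
            rows.append({"sample_id": f"{gt}_r{rep}", "genotype": gt, "role": role, "replicate": rep})
    samples = pd.DataFrame(rows)
    lo, hi = mapped_read_range
    mapped = pd.Series(
        np.round(rng.uniform(lo, hi, size=len(samples))),
        index=samples["sample_id"].values,
    )
    return SampleDesign(samples, mapped)
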