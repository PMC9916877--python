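"""RPM normalisation, expression binning, genotype means, MPV, presence calls."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SampleDesign

PRESENCE_RULES = ("any_replicate", "mean_positive", "majority")


def rpm_normalize(counts: pd.DataFrame, mapped_reads: pd.Series) -> pd.DataFrame:
    """Back-spliced reads per million mapped reads:
    RPM[i, s] = counts[i, s] * 1e6 / mapped_reads[s]."""
    mapped = pd.Series(mapped_reads, dtype=float).reindex(counts.columns)
    if mapped.isna().any():
        raise ValueError(f"mapped_reads missing samples: {list(counts.columns[mapped.isna()])}")
    if (mapped <= 0).any():
        raise ValueError("all mapped-read totals must be > 0")
    return counts * 1e6 / mapped


def bin_expression(rpm):
    """<100 RPM -> low; 100-500 RPM (inclusive) -> moderate; >500 RPM -> high."""
    values = np.asarray(rpm, dtype=float)
    if (values < 0).any():
        raise ValueError("RPM values must be non-negative")
    out = np.where(values < 100, "low", np.where(values <= 500, "moderate", "high"))
    if np.isscalar(rpm) or np.ndim(rpm) == 0:
        return out.item()
    if isinstance(rpm, pd.Series):
        return pd.Series(out, index=rpm.index)
    return out


def genotype_means(expr: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Arithmetic mean of replicate expression per genotype (features x genotypes)."""
    cols = {}
    for gt in design.genotypes:
        cols[gt] = expr[design.samples_of(gt)].mean(axis=1)
    return pd.DataFrame(cols)


def mid_parent_value(means: pd.DataFrame, design: SampleDesign) -> pd.Series:
    """MPV = (mean_FP + mean_MP) / 2 per feature."""
    fp = design.genotype_of_role("FP")
    mp = design.genotype_of_role("MP")
    for role, gt in (("FP", fp), ("MP", mp)):
        if gt not in means.columns:
            raise ValueError(f"genotype means lack the {role} parent column {gt!r}")
    return ((means[fp] + means[mp]) / 2.0).rename("MPV")


def genotype_means_and_mpv(
    expr: pd.DataFrame, design: SampleDesign
) -> tuple[pd.DataFrame, pd.Series]:
    means = genotype_means(expr, design)
    return means, mid_parent_value(means, design)


def detect_expressed(
    expr: pd.DataFrame,
    design: SampleDesign,
    rule: str = "any_replicate",
) -> tuple[pd.DataFrame, pd.Series, pd.Index]:
    """Presence per (feature, genotype) plus per-genotype expressed counts and
    the co-expressed feature set (present in every genotype).

    Rules: ``any_replicate`` — any replicate > 0; ``mean_positive`` — replicate
    mean > 0 (equivalent for non-negative data, kept for symmetry);
    ``majority`` — more than half the replicates > 0.
    """
    if rule not in PRESENCE_RULES:
        raise ValueError(f"unknown presence rule {rule!r}; use one of {PRESENCE_RULES}")
    presence = {}
    for gt in design.genotypes:
        sub = expr[design.samples_of(gt)]
        if rule == "any_replicate":
            presence[gt] = (sub > 0).any(axis=1)
        elif rule == "mean_positive":
            presence[gt] = sub.mean(axis=1) > 0
        else:
            presence[gt] = (sub > 0).sum(axis=1) > sub.shape[1] / 2
    pres = pd.DataFrame(presence)
    n_expressed = pres.sum(axis=0)
    co_expressed = pres.index[pres.all(axis=1)]
    return pres, n_expressed, co_expressed
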