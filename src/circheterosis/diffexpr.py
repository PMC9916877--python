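"""Count-based differential expression between two pooled libraries.

The test mirrors the two-library paradigm of DEGseq-style callers: replicate
counts are pooled within each group and the group comparison is an exact
conditional binomial test — conditional on the total count k_a + k_b, k_a is
Binomial(k_a + k_b, n_a / (n_a + n_b)) under the null of equal rates, where
n_a and n_b are the pooled library sizes. The two-sided p-value doubles the
smaller tail (capped at 1). Replicate variance is deliberately not modelled;
see the methods note.

log2 fold change uses a pseudo-rate eps = 0.5 / min(n_a, n_b) on both sides
so single-library zeros stay finite.

Differentially expressed calls (DECs) use the inclusive thresholds
|log2FC| >= 1 and BH-adjusted q <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import SampleDesign


def de_test(count_a, n_a, count_b, n_b):
    """Exact conditional binomial test of pooled counts.

    Parameters are scalars or arrays: pooled back-spliced read counts and
    pooled library sizes for the two groups. Returns ``(log2fc, p)``;
    features with both counts zero get NaN for both (p undefined).
    """
    ka = np.asarray(count_a, dtype=float)
    kb = np.asarray(count_b, dtype=float)
    na = np.asarray(n_a, dtype=float)
    nb = np.asarray(n_b, dtype=float)
    if (na <= 0).any() or (nb <= 0).any():
        raise ValueError("library sizes must be > 0")
    # merged dual-caller counts can be half-integers (caller averaging); the
    # exact binomial needs integer trials, so round for the p-value while the
    # fold change stays on the raw rates
    kr_a = np.rint(ka)
    n = kr_a + np.rint(kb)
    p0 = na / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = stats.binom.cdf(kr_a, n, p0)
        upper = stats.binom.sf(kr_a - 1, n, p0)
        p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
        eps = 0.5 / np.minimum(na, nb)
        log2fc = np.log2((ka / na + eps) / (kb / nb + eps))
    undefined = (ka + kb) == 0
    p = np.where(undefined, np.nan, p)
    log2fc = np.where(undefined, np.nan, log2fc)
    if np.ndim(count_a) == 0 and np.ndim(count_b) == 0:
        return float(log2fc), float(p)
    return log2fc, p


def adjust_bh(p_values):
    """Benjamini-Hochberg step-up q-values; NaNs pass through untouched."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index)
    return q


def pooled_counts(
    counts: pd.DataFrame, design: SampleDesign, genotypes: str | list[str]
) -> tuple[pd.Series, float]:
    """Sum counts and mapped-read totals over all replicates of the genotype(s)."""
    if isinstance(genotypes, str):
        genotypes = [genotypes]
    samples = [s for gt in genotypes for s in design.samples_of(gt)]
    pooled = counts[samples].sum(axis=1)
    size = float(design.mapped_reads[samples].sum())
    return pooled, size


def _resolve_group(design: SampleDesign, label: str) -> list[str]:
    """A comparison side is a genotype name or the pseudo-group 'MPV'
    (both parents pooled)."""
    if label == "MPV":
        return [design.genotype_of_role("FP"), design.genotype_of_role("MP")]
    return [label]


def de_table(
    counts: pd.DataFrame,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Full DE result table for one comparison (group_a over group_b)."""
    ka, na = pooled_counts(counts, design, _resolve_group(design, group_a))
    kb, nb = pooled_counts(counts, design, _resolve_group(design, group_b))
    log2fc, p = de_test(ka.to_numpy(), na, kb.to_numpy(), nb)
    df = pd.DataFrame(
        {
            "group_a": group_a, "group_b": group_b,
            "count_a": ka, "count_b": kb, "n_a": na, "n_b": nb,
            "log2fc": log2fc, "p": p,
        },
        index=counts.index,
    )
    df["q"] = adjust_bh(df["p"])
    return call_dec(df, lfc_min=lfc_min, q_max=q_max)


def call_dec(results: pd.DataFrame, lfc_min: float = 1.0, q_max: float = 0.05) -> pd.DataFrame:
    """Direction calls at inclusive thresholds: up iff log2fc >= lfc_min and
    q <= q_max; down iff log2fc <= -lfc_min and q <= q_max; NaN p -> 'na'."""
    out = results.copy()
    sig = out["q"] <= q_max
    out["direction"] = np.select(
        [out["p"].isna(), sig & (out["log2fc"] >= lfc_min), sig & (out["log2fc"] <= -lfc_min)],
        ["na", "up", "down"],
        default="ns",
    )
    return out


def mpv_test(
    counts: pd.DataFrame,
    design: SampleDesign,
    f1_genotype: str,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """F1 vs mid-parent test: the MPV pseudo-group pools both parents' counts
    and library sizes, so its rate estimate is (k_FP + k_MP) / (n_FP + n_MP)."""
    for role in ("FP", "MP"):
        design.genotype_of_role(role)  # raises if absent
    return de_table(counts, design, f1_genotype, "MPV", lfc_min=lfc_min, q_max=q_max)


def dec_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/down/total DEC counts per comparison."""
    rows = []
    for name, tbl in tables.items():
        up = int((tbl["direction"] == "up").sum())
        down = int((tbl["direction"] == "down").sum())
        rows.append({"comparison": name, "up": up, "down": down, "total": up + down})
    return pd.DataFrame(rows)
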