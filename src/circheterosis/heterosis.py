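"""Heterosis expression taxonomy.

Per F1 genotype, each circRNA expressed in the F1 or with MPV > 0 is
classified additive (no significant F1-vs-MPV difference) or non-additive,
and non-additive circRNAs receive a Stupar subtype: significantly above MPV
-> AHP (above the high parent) or HP; significantly below -> BLP (below the
low parent) or LP. Following the study design this implements, the "high
parent" is the female parent and the "low parent" the male parent by growth
potential, independent of which parent expresses more; ``by_expression=True``
restores the conventional higher-expressing-parent definition.

Independently of the F1 tests, presence/absence in the parents defines the
parental pattern: SPE_F (female only), SPE_M (male only), CoPE (both), and
the SFE flag for circRNAs expressed in at least one F1 but neither parent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SampleDesign
from .diffexpr import mpv_test
from .expression import detect_expressed, genotype_means_and_mpv, rpm_normalize

STUPAR_CLASSES = ("AHP", "HP", "LP", "BLP")


def classify_additivity(mpv_result: pd.DataFrame, mpv: pd.Series, f1_present: pd.Series) -> pd.Series:
    """additive / non_additive per feature; features neither expressed in the
    F1 nor with MPV > 0 are excluded (NaN)."""
    tested = f1_present | (mpv > 0)
    out = pd.Series(np.nan, index=mpv_result.index, dtype=object)
    direction = mpv_result["direction"]
    out[tested & direction.isin(["up", "down"])] = "non_additive"
    out[tested & (direction == "ns")] = "additive"
    return out


def classify_stupar(
    f1_mean: float, fp_mean: float, mp_mean: float, mpv_direction: str,
    by_expression: bool = False,
) -> str:
    """Stupar subtype of one non-additive circRNA."""
    if mpv_direction not in ("up", "down"):
        raise ValueError("classify_stupar requires a non-additive (up/down) feature")
    if by_expression:
        high, low = max(fp_mean, mp_mean), min(fp_mean, mp_mean)
    else:
        high, low = fp_mean, mp_mean
    if mpv_direction == "up":
        return "AHP" if f1_mean > high else "HP"
    return "BLP" if f1_mean < low else "LP"


def classify_parental_pattern(
    presence: pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """SPE_F / SPE_M / CoPE / none per feature plus the SFE flag.

    SPE_F: present in FP, absent in MP. SPE_M: the reverse. CoPE: both
    present. SFE: both parents absent and at least one F1 genotype present.
    """
    fp = design.genotype_of_role("FP")
    mp = design.genotype_of_role("MP")
    f1 = design.f1_genotypes
    in_fp, in_mp = presence[fp], presence[mp]
    in_f1 = presence[f1].any(axis=1)
    pattern = pd.Series("none", index=presence.index, dtype=object)
    pattern[in_fp & ~in_mp] = "SPE_F"
    pattern[~in_fp & in_mp] = "SPE_M"
    pattern[in_fp & in_mp] = "CoPE"
    sfe = ~in_fp & ~in_mp & in_f1
    return pd.DataFrame({"parental_pattern": pattern, "sfe": sfe, "f1_expressed": in_f1})


def heterosis_calls(
    counts: pd.DataFrame,
    design: SampleDesign,
    presence_rule: str = "any_replicate",
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    by_expression: bool = False,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Full per-(circRNA, F1 genotype) classification.

    Returns ``(calls, mpv_tables)`` where ``calls`` has columns circ_id,
    f1_genotype, additivity, stupar, parental_pattern, sfe and ``mpv_tables``
    the underlying F1-vs-MPV DE tables.
    """
    rpm = rpm_normalize(counts, design.mapped_reads)
    means, mpv = genotype_means_and_mpv(rpm, design)
    presence, _, _ = detect_expressed(rpm, design, rule=presence_rule)
    patterns = classify_parental_pattern(presence, design)
    fp = design.genotype_of_role("FP")
    mp = design.genotype_of_role("MP")

    rows, mpv_tables = [], {}
    for gt in design.f1_genotypes:
        table = mpv_test(counts, design, gt, lfc_min=lfc_min, q_max=q_max)
        mpv_tables[gt] = table
        additivity = classify_additivity(table, mpv, presence[gt])
        for cid in counts.index:
            add = additivity[cid]
            if pd.isna(add):
                continue
            stupar = "none"
            if add == "non_additive":
                stupar = classify_stupar(
                    means.loc[cid, gt], means.loc[cid, fp], means.loc[cid, mp],
                    table.loc[cid, "direction"], by_expression=by_expression,
                )
            rows.append(
                {"circ_id": cid, "f1_genotype": gt, "additivity": add,
                 "stupar": stupar,
                 "parental_pattern": patterns.loc[cid, "parental_pattern"],
                 "sfe": bool(patterns.loc[cid, "sfe"])}
            )
    return pd.DataFrame(rows), mpv_tables


# ---------------------------------------------------------------------------
# summary bookkeeping
# ---------------------------------------------------------------------------

def spe_totals(parental_pattern: pd.Series) -> dict[str, int]:
    """SPE split and total; the two sets are disjoint by construction."""
    spe_f = int((parental_pattern == "SPE_F").sum())
    spe_m = int((parental_pattern == "SPE_M").sum())
    return {"SPE_F": spe_f, "SPE_M": spe_m, "total": spe_f + spe_m}


def spe_in_dec(parental_pattern: pd.Series, dec_features) -> dict[str, int]:
    """SPE counts restricted to a DEC feature set (e.g. the MP-vs-FP DECs)."""
    sub = parental_pattern.loc[parental_pattern.index.intersection(pd.Index(dec_features))]
    return spe_totals(sub)


def codec_decomposition(direction_table: pd.DataFrame) -> dict:
    """Intersection of several comparisons' DEC sets with direction concordance.

    ``direction_table``: features x comparisons frame of 'up'/'down'/'ns'/'na'.
    A co-DEC is a feature called up or down in every comparison; it is
    all-up / all-down when directions agree everywhere, otherwise mixed.
    """
    is_dec = direction_table.isin(["up", "down"]).all(axis=1)
    codec = direction_table.loc[is_dec]
    all_up = int((codec == "up").all(axis=1).sum())
    all_down = int((codec == "down").all(axis=1).sum())
    return {
        "n_codec": int(is_dec.sum()),
        "all_up": all_up,
        "all_down": all_down,
        "mixed": int(is_dec.sum()) - all_up - all_down,
        "codec_features": list(codec.index),
    }


def common_features(sets: list[set], k: int = 2) -> set:
    """Features present in at least k of the given sets (the 'common to at
    least two F1 hybrids' rule)."""
    counts: dict = {}
    for s in sets:
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    return {f for f, c in counts.items() if c >= k}


def class_count_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-F1-genotype counts of additive/non-additive and Stupar subtypes."""
    rows = []
    for gt, sub in calls.groupby("f1_genotype"):
        row = {"f1_genotype": gt,
               "additive": int((sub["additivity"] == "additive").sum()),
               "non_additive": int((sub["additivity"] == "non_additive").sum())}
        for cls in STUPAR_CLASSES:
            row[cls] = int((sub["stupar"] == cls).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_patterns(
    calls: pd.DataFrame,
    parental_pattern: pd.Series,
    parental_dec_features=None,
    f1_contrast_directions: pd.DataFrame | None = None,
) -> dict:
    """Summary tables: class counts per genotype, SPE split, SPE inside the
    parental DEC set, and the co-DEC decomposition across F1 contrasts."""
    out = {"class_counts": class_count_table(calls), "spe": spe_totals(parental_pattern)}
    if parental_dec_features is not None:
        out["spe_in_parental_dec"] = spe_in_dec(parental_pattern, parental_dec_features)
    if f1_contrast_directions is not None:
        out["codec"] = codec_decomposition(f1_contrast_directions)
    return out
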