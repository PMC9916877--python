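"""End-to-end orchestration: simulate -> identify -> quantify -> de ->
heterosis -> targets/orfs -> correlate -> modules -> report.

Every stage output is a TSV under one run directory; a YAML manifest records
parameters and seeds, and the report aggregates the summary tables. All
stage outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import json
import os

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import coexpression, correlation, diffexpr, expression, function, heterosis, identify, synthetic


class RunConfig(BaseModel):
    """Validated pipeline configuration. Defaults equal the published
    thresholds where stated: merge tolerance 10 nt, |log2FC| >= 1,
    q <= 0.05, correlation/enrichment p <= 0.05, RPM bins 100/500,
    minimum ORF 63 nt."""

    seed: int = 0
    n_genes: int = Field(60, ge=1)
    n_circ: int = Field(300, ge=1)
    n_mirnas: int = Field(30, ge=0)
    effect_fold: float = Field(4.0, gt=1.0)
    dispersion: float = Field(0.1, ge=0.0)
    jitter_sd: float = Field(2.0, ge=0.0)
    fn_rate: float = Field(0.05, ge=0.0, lt=1.0)
    count_noise: float = Field(0.1, ge=0.0)
    tolerance: int = Field(10, ge=0)
    presence_rule: str = "any_replicate"
    lfc_min: float = 1.0
    q_max: float = 0.05
    target_cutoff: float = 4.0
    min_orf_nt: int = 63
    max_wraps: int = 4
    beta: int | None = None
    min_module_size: int = 5
    cut_height: float = 0.99
    hub_k: int = 25

    @model_validator(mode="after")
    def _check_rule(self):
        if self.presence_rule not in expression.PRESENCE_RULES:
            raise ValueError(f"presence_rule must be one of {expression.PRESENCE_RULES}")
        return self


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Run every stage on a simulated study and write the report bundle."""
    os.makedirs(outdir, exist_ok=True)
    stage = "simulate"
    try:
        study = synthetic.simulate_study(
            seed=config.seed, n_genes=config.n_genes, n_circ=config.n_circ,
            n_mirnas=config.n_mirnas, effect_fold=config.effect_fold,
            dispersion=config.dispersion, jitter_sd=config.jitter_sd,
            fn_rate=config.fn_rate, count_noise=config.count_noise,
        )
        synthetic.write_study(study, os.path.join(outdir, "inputs"))
        truth, design = study["truth"], study["design"]

        stage = "identify"
        catalog, counts = identify.merge_calls(
            study["calls_a"], study["calls_b"], tolerance=config.tolerance
        )
        classified = identify.classify_catalog(catalog, truth.annotation)
        mapping, per_gene, gene_summary = identify.assign_parent_genes(classified)
        classified.to_csv(os.path.join(outdir, "catalog.tsv"), sep="\t", index=False)
        counts.rename_axis("circ_id").to_csv(os.path.join(outdir, "merged_counts.tsv"), sep="\t")
        gene_summary.to_csv(os.path.join(outdir, "parent_gene_summary.tsv"), sep="\t", index=False)

        stage = "quantify"
        rpm = expression.rpm_normalize(counts, design.mapped_reads)
        presence, n_expr, co_expr = expression.detect_expressed(
            rpm, design, rule=config.presence_rule
        )
        rpm.rename_axis("circ_id").to_csv(os.path.join(outdir, "rpm.tsv"), sep="\t")
        presence.rename_axis("circ_id").to_csv(os.path.join(outdir, "presence.tsv"), sep="\t")

        stage = "de"
        fp = design.genotype_of_role("FP")
        mp = design.genotype_of_role("MP")
        comparisons = [(mp, fp)]
        for gt in design.f1_genotypes:
            comparisons += [(gt, fp), (gt, mp)]
        high = design.genotypes_of_role("F1_high")[:2]
        low = design.genotypes_of_role("F1_low")[:2]
        f1_contrasts = [(lo, hi) for lo in low for hi in high]
        comparisons += f1_contrasts
        dec_tables = {}
        for a, b in comparisons:
            name = f"{a}_vs_{b}"
            tbl = diffexpr.de_table(counts, design, a, b, lfc_min=config.lfc_min, q_max=config.q_max)
            tbl.rename_axis("circ_id").to_csv(os.path.join(outdir, f"de_{name}.tsv"), sep="\t")
            dec_tables[name] = tbl
        dec_summary = diffexpr.dec_summary(dec_tables)
        dec_summary.to_csv(os.path.join(outdir, "dec_summary.tsv"), sep="\t", index=False)

        stage = "heterosis"
        calls, mpv_tables = heterosis.heterosis_calls(
            counts, design, presence_rule=config.presence_rule,
            lfc_min=config.lfc_min, q_max=config.q_max,
        )
        patterns = heterosis.classify_parental_pattern(presence, design)
        parental_dec = dec_tables[f"{mp}_vs_{fp}"]
        dec_features = parental_dec.index[parental_dec["direction"].isin(["up", "down"])]
        contrast_dirs = pd.DataFrame(
            {f"{a}_vs_{b}": dec_tables[f"{a}_vs_{b}"]["direction"] for a, b in f1_contrasts}
        )
        het_summary = heterosis.summarize_patterns(
            calls, patterns["parental_pattern"], dec_features, contrast_dirs
        )
        calls.to_csv(os.path.join(outdir, "heterosis_calls.tsv"), sep="\t", index=False)

        stage = "function"
        # catalog entries inherit the truth sequences via coordinates; at toy
        # scale we scan the generated circRNA sequences directly
        seqs = truth.sequences
        hits = function.find_targets(seqs, study["mirnas"], cutoff=config.target_cutoff)
        orfs = function.orf_table(seqs, min_orf_nt=config.min_orf_nt, max_wraps=config.max_wraps)
        potential = function.coding_potential(orfs, list(seqs))
        hits.to_csv(os.path.join(outdir, "target_hits.tsv"), sep="\t", index=False)
        orfs.to_csv(os.path.join(outdir, "orfs.tsv"), sep="\t", index=False)
        target_bins = function.summarize_target_bins(hits)

        stage = "correlate"
        truth_map = truth.circ_truth.dropna(subset=["parent_gene_id"])[
            ["circ_id", "parent_gene_id"]
        ].rename(columns={"parent_gene_id": "gene_id"})
        fpkm = synthetic.generate_gene_expression(
            truth, expression.rpm_normalize(study["counts"], design.mapped_reads),
            design, seed=config.seed + 101,
        )
        truth_rpm = expression.rpm_normalize(study["counts"], design.mapped_reads)
        records = correlation.pair_correlation(truth_rpm, fpkm, truth_map)
        spe_f = set(truth.parental_pattern.index[truth.parental_pattern == "SPE_F"])
        spe_m = set(truth.parental_pattern.index[truth.parental_pattern == "SPE_M"])
        corr_summary = correlation.summarize_correlation(
            records, {"SPE_F": spe_f, "SPE_M": spe_m}
        )
        records.to_csv(os.path.join(outdir, "correlation.tsv"), sep="\t", index=False)
        corr_summary.to_csv(os.path.join(outdir, "correlation_summary.tsv"), sep="\t", index=False)

        stage = "modules"
        dec_any = sorted(
            set().union(*[
                set(t.index[t["direction"].isin(["up", "down"])]) for t in dec_tables.values()
            ])
        )
        combined = pd.concat([truth_rpm.loc[dec_any], fpkm.loc[fpkm.std(axis=1) > 0]])
        combined = combined.loc[combined.std(axis=1) > 0]
        beta = config.beta or coexpression.pick_beta(combined)
        tom = coexpression.build_tom(combined, beta)
        assignments = coexpression.detect_modules(
            tom, min_module_size=config.min_module_size, cut_height=config.cut_height
        )
        eigengenes = coexpression.module_eigengenes(combined, assignments)
        module_summary = coexpression.module_size_summary(assignments)
        assignments.rename_axis("feature").to_csv(os.path.join(outdir, "modules.tsv"), sep="\t")
        if len(eigengenes):
            eigengenes.rename_axis("module").to_csv(os.path.join(outdir, "eigengenes.tsv"), sep="\t")
            mt_r, mt_p = coexpression.module_trait(eigengenes, design)
            mt_r.rename_axis("module").to_csv(os.path.join(outdir, "module_trait_r.tsv"), sep="\t")

        stage = "report"
        origin_props = (
            classified["origin_class"].value_counts(normalize=True).to_dict()
        )
        report = {
            "catalog_size": int(len(catalog)),
            "origin_proportions": origin_props,
            "expressed_per_genotype": {k: int(v) for k, v in n_expr.items()},
            "n_coexpressed": int(len(co_expr)),
            "dec_summary": dec_summary.to_dict(orient="records"),
            "class_counts": het_summary["class_counts"].to_dict(orient="records"),
            "spe": het_summary["spe"],
            "spe_in_parental_dec": het_summary["spe_in_parental_dec"],
            "codec": {k: v for k, v in het_summary["codec"].items() if k != "codec_features"},
            "target_bins": target_bins,
            "n_orf_circ": int(orfs["circ_id"].nunique()) if len(orfs) else 0,
            "coding_fraction": float(potential.mean()),
            "correlation_summary": corr_summary.to_dict(orient="records"),
            "module_summary": module_summary,
            "beta": int(beta),
        }
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        synthetic.write_run_manifest(
            os.path.join(outdir, "manifest.yaml"),
            {"config": config.model_dump(), "stages": "completed"},
        )
        return report
    except Exception as err:  # pragma: no cover - failure path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
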