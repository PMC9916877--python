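"""The synthetic generator must plant exactly the structure the pipeline assumes."""

import io

import numpy as np
import pandas as pd
import pytest

from circheterosis import identify, synthetic
from circheterosis.annotation import revcomp
from circheterosis.design import default_design


class TestGenerateAnnotation:
    def test_structure_and_bounds(self):
        ann, genome = synthetic.generate_annotation(seed=1, n_chroms=2, n_genes=50)
        assert len(ann.genes) == 50
        exons = ann.exons.merge(ann.genes, on="gene_id", suffixes=("", "_gene"))
        assert (exons["start"] >= exons["start_gene"]).all()
        assert (exons["end"] <= exons["end_gene"]).all()
        for _, g in ann.genes.iterrows():
            assert g.end <= len(genome[g.chrom])
        # genes do not overlap on a chromosome
        for _, sub in ann.genes.groupby("chrom"):
            ordered = sub.sort_values("start")
            assert (ordered["start"].values[1:] > ordered["end"].values[:-1]).all()

    def test_deterministic_for_fixed_seed(self, tmp_path):
        outputs = []
        for _ in range(2):
            ann, genome = synthetic.generate_annotation(seed=9, n_chroms=2, n_genes=20)
            gff = tmp_path / "a.gff3"
            ann.write_gff3(gff)
            outputs.append((gff.read_text(), genome))
        assert outputs[0] == outputs[1]

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0},
        {"exon_length_range": (0, 10)},
        {"intron_length_range": (50, 10)},
    ])
    def test_bad_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.generate_annotation(seed=1, **kwargs)


class TestGenerateCircTruth:
    def test_planted_origin_classes_reclassify_exactly(self, annotation_and_genome):
        """The identify module is the oracle: re-classifying planted
        coordinates must reproduce every planted origin label."""
        ann, genome = annotation_and_genome
        truth = synthetic.generate_circ_truth(
            ann, genome, n_circ=150, origin_mix=(0.40, 0.40, 0.08, 0.12), seed=7
        )
        for row in truth.circ_truth.itertuples():
            cls, parents, _ = identify.classify_origin(
                row.chrom, row.start, row.end, row.strand, truth.annotation
            )
            assert cls == row.origin_class
            if row.origin_class == "intergenic":
                assert parents == []
            else:
                assert row.parent_gene_id in parents

    def test_all_intergenic_mix_overlaps_no_gene(self, annotation_and_genome):
        ann, genome = annotation_and_genome
        truth = synthetic.generate_circ_truth(ann, genome, n_circ=40, origin_mix=(1, 0, 0, 0), seed=3)
        assert (truth.circ_truth["origin_class"] == "intergenic").all()
        for row in truth.circ_truth.itertuples():
            assert ann.genes_overlapping(row.chrom, row.start, row.end) == []

    def test_sequences_match_genome(self, annotation_and_genome):
        """Every sequence equals the genomic (or spliced-exonic) subsequence,
        reverse-complemented on the minus strand."""
        ann, genome = annotation_and_genome
        truth = synthetic.generate_circ_truth(
            ann, genome, n_circ=100, origin_mix=(0.5, 0.3, 0.1, 0.1), seed=13
        )
        saw_minus = False
        for row in truth.circ_truth.itertuples():
            if row.origin_class != "exonic":
                plus = truth.genome[row.chrom][row.start - 1 : row.end]
                expected = revcomp(plus) if row.strand == "-" else plus
                assert row.sequence == expected
                saw_minus = saw_minus or row.strand == "-"
        assert saw_minus

    def test_planted_orf_lengths_are_codon_multiples(self, annotation_and_genome):
        ann, genome = annotation_and_genome
        truth = synthetic.generate_circ_truth(
            ann, genome, n_circ=80, origin_mix=(1, 0, 0, 0), orf_rate=0.5, seed=21
        )
        orfs = truth.planted_orfs
        assert len(orfs) > 0
        assert (orfs["length_nt"] % 3 == 0).all()
        assert (orfs["length_nt"] >= 63).all()
        assert orfs["spans_junction"].all()

    def test_origin_mix_validation(self, annotation_and_genome):
        ann, genome = annotation_and_genome
        with pytest.raises(ValueError):
            synthetic.generate_circ_truth(ann, genome, n_circ=10, origin_mix=(0.5, 0.5, 0.5, 0), seed=1)

    def test_intronic_without_introns_raises(self):
        ann, genome = synthetic.generate_annotation(seed=2, n_genes=10, exons_per_gene=(1, 1))
        with pytest.raises(ValueError, match="intron"):
            synthetic.generate_circ_truth(ann, genome, n_circ=10, origin_mix=(0.5, 0.4, 0.1, 0), seed=1)

    def test_class_proportions_converge(self):
        """Realized class mix converges to the request (3 sd multinomial at n=2000)."""
        ann, genome = synthetic.generate_annotation(seed=31, n_chroms=4, n_genes=1650)
        mix = dict(zip(synthetic.ORIGIN_CLASSES, synthetic.DEFAULT_ORIGIN_MIX))
        truth = synthetic.generate_circ_truth(ann, genome, n_circ=2000, seed=32)
        realized = truth.circ_truth["origin_class"].value_counts(normalize=True)
        for cls, p in mix.items():
            sd = np.sqrt(p * (1 - p) / 2000)
            assert abs(realized.get(cls, 0.0) - p) <= 3 * sd + 1e-12


class TestGenerateExpression:
    def test_structural_zeros_are_exact(self, noisy_study):
        truth, counts, design = (
            noisy_study["truth"], noisy_study["counts"], noisy_study["design"]
        )
        fp_samples = design.samples_of(design.genotype_of_role("FP"))
        mp_samples = design.samples_of(design.genotype_of_role("MP"))
        pat = truth.parental_pattern
        spe_f = pat.index[pat == "SPE_F"]
        sfe = pat.index[pat == "SFE"]
        assert len(spe_f) and len(sfe)
        assert (counts.loc[spe_f, mp_samples] == 0).all().all()
        assert (counts.loc[sfe, fp_samples + mp_samples] == 0).all().all()

    def test_planted_means_satisfy_class_definitions(self, noisy_study):
        truth, design = noisy_study["truth"], noisy_study["design"]
        means = truth.rpm_means
        fp = design.genotype_of_role("FP")
        mp = design.genotype_of_role("MP")
        mpv = (means[fp] + means[mp]) / 2
        for row in truth.class_labels.itertuples():
            f1 = means.loc[row.circ_id, row.f1_genotype]
            if row.heterosis_class == "additive":
                assert f1 == pytest.approx(mpv[row.circ_id])
            elif row.heterosis_class == "AHP":
                assert f1 > mpv[row.circ_id] and f1 > means.loc[row.circ_id, fp]
            elif row.heterosis_class == "BLP":
                assert f1 < mpv[row.circ_id] and f1 < means.loc[row.circ_id, mp]
            elif row.heterosis_class == "LP":
                assert f1 < mpv[row.circ_id] and f1 >= means.loc[row.circ_id, mp]

    def test_dispersion_zero_is_poisson(self):
        """With dispersion 0 the count variance matches the Poisson mean."""
        ann, genome = synthetic.generate_annotation(seed=41, n_genes=30)
        truth = synthetic.generate_circ_truth(ann, genome, n_circ=20, origin_mix=(1, 0, 0, 0), seed=42)
        # equal depths so replicate counts are iid Poisson; many reps for variance
        design = default_design(n_reps=40, mapped_read_range=(4e6, 4e6), seed=43)
        counts = synthetic.generate_expression(
            truth, design, pattern_mix={"CoPE": 1.0}, class_mix={"additive": 1.0},
            dispersion=0.0, seed=44,
        )
        gt = design.genotype_of_role("FP")
        samples = design.samples_of(gt)
        depth = design.mapped_reads[samples]
        # scale counts to a common depth so replicates are iid Poisson-like
        rates = counts[samples] / depth.values
        mean_rate = rates.mean(axis=1)
        var_ratio = (counts[samples].var(axis=1) / (counts[samples].mean(axis=1) + 1e-9))
        assert var_ratio.median() == pytest.approx(1.0, abs=0.5)
        assert mean_rate.notna().all()

    def test_mix_validation(self, noisy_study):
        truth, design = noisy_study["truth"], noisy_study["design"]
        with pytest.raises(ValueError):
            synthetic.generate_expression(truth, design, class_mix={"additive": 0.5}, seed=1)
        with pytest.raises(ValueError):
            synthetic.generate_expression(truth, design, effect_fold=1.0, seed=1)


class TestGenerateCallerCalls:
    def test_noise_free_round_trip(self, noise_free_study):
        a, b = noise_free_study["calls_a"], noise_free_study["calls_b"]
        truth = noise_free_study["truth"]
        pd.testing.assert_frame_equal(
            a.sort_values(["chrom", "start", "sample_id"]).reset_index(drop=True),
            b.sort_values(["chrom", "start", "sample_id"]).reset_index(drop=True),
        )
        catalog, _ = identify.merge_calls(a, b)
        assert len(catalog) == len(truth.circ_truth)

    def test_single_caller_degenerate(self, noise_free_study):
        """If one caller misses everything, the catalog equals the other caller's calls."""
        a = noise_free_study["calls_a"]
        empty = a.iloc[0:0]
        catalog, _ = identify.merge_calls(a, empty)
        expected = a[["chrom", "start", "end", "strand"]].drop_duplicates()
        assert len(catalog) == len(expected)

    def test_jitter_bounded_for_merge(self, annotation_and_genome):
        ann, genome = annotation_and_genome
        truth = synthetic.generate_circ_truth(ann, genome, n_circ=60, origin_mix=(1, 0, 0, 0), seed=51)
        design = default_design(seed=52)
        counts = synthetic.generate_expression(truth, design, seed=53)
        a, b = synthetic.generate_caller_calls(
            truth, counts, design, jitter_sd=5.0, fn_rate=0.0, count_noise=0.0, seed=54
        )
        catalog, _ = identify.merge_calls(a, b)
        assert len(catalog) == len(truth.circ_truth)

    def test_fn_rate_validation(self, noise_free_study):
        truth, counts, design = (
            noise_free_study["truth"], noise_free_study["counts"], noise_free_study["design"]
        )
        with pytest.raises(ValueError):
            synthetic.generate_caller_calls(truth, counts, design, fn_rate=1.0, seed=1)


class TestGenerateMirnas:
    def test_planted_site_is_perfect_complement(self, noisy_study):
        from circheterosis.function import score_target

        truth, mirnas = noisy_study["truth"], noisy_study["mirnas"]
        seqs = truth.sequences
        assert len(truth.planted_targets) > 0
        for row in truth.planted_targets.itertuples():
            circ = seqs[row.circ_id]
            m = len(mirnas[row.mirna_id])
            window = (circ + circ)[row.offset : row.offset + m]
            assert score_target(mirnas[row.mirna_id], window) == 0.0

    def test_no_mirnas_empty_truth(self, noisy_study):
        truth = noisy_study["truth"]
        mirnas = synthetic.generate_mirnas(truth, n_mirnas=0, seed=1)
        assert mirnas == {}
        assert truth.planted_targets.empty

    def test_mirna_length_validated(self, noisy_study):
        with pytest.raises(ValueError):
            synthetic.generate_mirnas(noisy_study["truth"], n_mirnas=5, mirna_length=25, seed=1)


def test_simulate_study_deterministic(tmp_path):
    """Identical seeds and parameters produce byte-identical serialized outputs."""
    texts = []
    for d in ("a", "b"):
        study = synthetic.simulate_study(seed=99, n_circ=40, n_genes=40)
        out = tmp_path / d
        synthetic.write_study(study, out)
        texts.append({f.name: f.read_text() for f in sorted(out.iterdir())})
    assert texts[0] == texts[1]
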