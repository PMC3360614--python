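"""Synthetic-data generators: determinism, self-checks, truth scoring."""

import numpy as np
import pytest

from mirest.fold import fold_single_hairpin
from mirest.homology import PrecursorWindow, scan_est
from mirest.io import ESTRecord, MatureMiRNA
from mirest.precursor import PrecursorCandidate, evaluate_candidate
from mirest.synthetic import (
    SyntheticTruth,
    generate_est_dataset,
    generate_intensity_table,
    generate_utr_set,
    plant_precursor,
    score_recovery,
)

MIR33B = MatureMiRNA("sli-miR-33b", "GUGCAUUUGUAGUUGCAUUGCA")
MIR279B = MatureMiRNA("sli-miR-279b", "UGACGAGAUGCACUCAU")


class TestPlantPrecursor:
    @pytest.mark.parametrize("mature", [MIR33B, MIR279B])
    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_unmutated_construct_passes_filters(self, mature, arm, model):
        seq, offset, _ = plant_precursor(mature, 3, arm=arm, model=model)
        win = PrecursorWindow("s", 0, len(seq), "+", seq, offset,
                              mature.length, arm)
        cand = evaluate_candidate(
            PrecursorCandidate(win, fold_single_hairpin(seq, model)),
            model=model,
        )
        assert cand.verdict, cand.fail_reasons
        assert seq[offset:offset + mature.length] == mature.sequence

    def test_six_mutations_escape_the_scan(self, model):
        seq, offset, _ = plant_precursor(MIR33B, 3, mutations=6, model=model)
        est = ESTRecord("e1", seq.replace("U", "T"))
        hits = scan_est(est, [MIR33B], max_mm=5)
        # the mutated mature copy itself is beyond the mismatch bound (the
        # star arm on the minus strand may still be homologous, as it is
        # in a genuine hairpin)
        assert not any(
            h.strand == "+" and h.start == offset for h in hits
        )

    def test_same_seed_same_construct(self, model):
        a = plant_precursor(MIR33B, 42, model=model)
        b = plant_precursor(MIR33B, 42, model=model)
        assert a == b


class TestGenerateEstDataset:
    def test_bookkeeping(self, catalogue):
        ests, truth = generate_est_dataset(
            catalogue, n_planted=5, n_decoys=20, seed=7
        )
        assert len(ests) == 25
        assert len(truth.planted_precursors) == 5
        assert truth.n_decoys == 20
        ids = {e.id for e in ests}
        for p in truth.planted_precursors:
            assert p.est_id in ids
            est = next(e for e in ests if e.id == p.est_id)
            assert 0 <= p.start < p.end <= est.length
            assert p.start <= p.mature_start < p.mature_end <= p.end
            planted = est.sequence[p.mature_start:p.mature_end]
            assert planted.replace("T", "U") == next(
                m for m in catalogue if m.name == p.mature_name
            ).sequence

    def test_seed_determinism_byte_identical(self, catalogue):
        a, ta = generate_est_dataset(catalogue, 3, 10, seed=5)
        b, tb = generate_est_dataset(catalogue, 3, 10, seed=5)
        assert a == b
        assert ta.to_json() == tb.to_json()

    def test_different_seed_differs(self, catalogue):
        a, _ = generate_est_dataset(catalogue, 3, 10, seed=5)
        b, _ = generate_est_dataset(catalogue, 3, 10, seed=6)
        assert a != b

    def test_negative_counts_rejected(self, catalogue):
        with pytest.raises(ValueError):
            generate_est_dataset(catalogue, -1, 0, seed=1)


class TestGenerateUtrSet:
    def test_truth_site_count(self, catalogue):
        mirnas = catalogue[:11]
        utrs, truth = generate_utr_set(mirnas, 11, sites_per_mirna=1, seed=3)
        assert len(utrs) == 11
        assert len(truth.planted_sites) == 11
        by_gene = {u.gene_id: u for u in utrs}
        from mirest.seq import revcomp_rna

        for s in truth.planted_sites:
            seq = by_gene[s.gene_id].sequence[s.start:s.end]
            m = next(x for x in mirnas if x.name == s.mirna_name)
            assert seq == revcomp_rna(m.sequence)

    def test_seed_determinism(self, catalogue):
        a, _ = generate_utr_set(catalogue[:3], 3, seed=9)
        b, _ = generate_utr_set(catalogue[:3], 3, seed=9)
        assert a == b


class TestGenerateIntensityTable:
    def test_noiseless_classes_exact(self):
        from mirest.expression import count_classes, relative_expression

        spec = {f"hi{i}": "high" for i in range(11)}
        spec.update({f"mid{i}": "moderate" for i in range(45)})
        spec.update({f"lo{i}": "very_low" for i in range(2)})
        df, _ = generate_intensity_table(spec, noise_cv=0.0, seed=0)
        mat = relative_expression(df)
        assert count_classes(mat, "high") == 11
        assert count_classes(mat, "moderate") == 45
        assert count_classes(mat, "very_low") == 2

    def test_noise_keeps_class_agreement_high(self):
        from mirest.expression import relative_expression

        spec = {"a": "high", "b": "moderate", "c": "very_low",
                "d": "moderate", "e": "high"}
        agree = total = 0
        for seed in range(100):
            df, truth = generate_intensity_table(spec, noise_cv=0.1,
                                                 seed=seed)
            classes = relative_expression(df).classes
            for name, intended in truth.intensity_classes.items():
                agree += classes[name] == intended
                total += 1
        assert agree / total >= 0.9

    def test_seed_determinism(self):
        spec = {"a": "high", "b": "moderate"}
        a, _ = generate_intensity_table(spec, noise_cv=0.3, seed=4)
        b, _ = generate_intensity_table(spec, noise_cv=0.3, seed=4)
        assert a.equals(b)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            generate_intensity_table({"a": "stellar"})


class TestTruthAndScoring:
    def test_truth_round_trips_through_json(self, catalogue):
        _, truth = generate_est_dataset(catalogue, 3, 5, seed=2)
        back = SyntheticTruth.from_json(truth.to_json())
        assert back == truth

    def test_perfect_output_scores_one(self, catalogue):
        from mirest.pipeline import AcceptedPrecursor

        _, truth = generate_est_dataset(catalogue, 3, 5, seed=2)
        accepted = [
            AcceptedPrecursor(
                name=p.mature_name, est_id=p.est_id, ref_name=p.mature_name,
                strand="+", win_start=p.start, win_end=p.end,
                mature_start=p.mature_start, mature_end=p.mature_end,
                mismatches=0, dg=-30.0, sequence="", dot_bracket="",
                mature_seq="",
            )
            for p in truth.planted_precursors
        ]
        sc = score_recovery(accepted, truth)
        assert (sc.sensitivity, sc.precision, sc.decoy_false_accept) \
            == (1.0, 1.0, 0.0)

    def test_empty_output_scores_zero_sensitivity(self, catalogue):
        _, truth = generate_est_dataset(catalogue, 3, 5, seed=2)
        sc = score_recovery([], truth)
        assert sc.sensitivity == 0.0

    def test_unknown_est_id_rejected(self, catalogue):
        from mirest.pipeline import AcceptedPrecursor

        _, truth = generate_est_dataset(catalogue, 1, 1, seed=2)
        ghost = AcceptedPrecursor(
            name="x", est_id="nope", ref_name="x", strand="+",
            win_start=0, win_end=10, mature_start=0, mature_end=5,
            mismatches=0, dg=-30.0, sequence="", dot_bracket="",
            mature_seq="",
        )
        with pytest.raises(ValueError):
            score_recovery([ghost], truth)
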