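import math

import numpy as np
import pandas as pd
import pytest

from clonemap.seqselect import (DEFAULT_MAX_EDIT_DISTANCE, classify_read,
                                classify_reads, estimate_error_rate,
                                fold_improvement, quality_group_analysis,
                                select_targets, trim_adapters)
from clonemap.simulate import (DesignPool, PyroErrorModel, SynthesisErrorModel,
                               gen_pool, populate_plate, sample_abundances,
                               simulate_reads, synthesize_molecules)

ADAPTOR_A = "GCCTCCCTCGCGCCATCAGCTTGCAA"  # 26-mer, arbitrary fixture
ADAPTOR_B = "GCCTTGCCAGCCCGCTCAGACGTACT"


class TestTrim:
    def test_exact_adaptors_are_stripped(self):
        insert = "ACGTACGTACGTACGT"
        tr = trim_adapters(ADAPTOR_A + insert + ADAPTOR_B,
                           [ADAPTOR_A, ADAPTOR_B])
        assert tr.insert == insert
        assert tr.trimmed_prefix and tr.trimmed_suffix and tr.usable

    def test_no_adaptor_passes_through_flagged(self):
        tr = trim_adapters("ACGTACGTACGT", [ADAPTOR_A])
        assert tr.insert == "ACGTACGTACGT"
        assert not tr.trimmed_prefix and not tr.trimmed_suffix

    def test_one_mismatch_still_trims(self):
        mutated = "T" + ADAPTOR_A[1:]
        tr = trim_adapters(mutated + "ACGTACGT", [ADAPTOR_A])
        assert tr.insert == "ACGTACGT"
        assert tr.trimmed_prefix

    def test_fully_trimmed_read_is_unusable(self):
        tr = trim_adapters(ADAPTOR_A, [ADAPTOR_A])
        assert not tr.usable


@pytest.fixture(scope="module")
def toy_pool():
    return DesignPool(ids=("D0", "D1"),
                      sequences=("ACGTACGTAAAAATTTGCGC", "TTGCACGGCCAATGCGGCAT"))


class TestClassify:
    def test_exact_match_is_perfect(self, toy_pool):
        rc = classify_read("ACGTACGTAAAAATTTGCGC", toy_pool)
        assert rc.design_id == "D0"
        assert rc.cls == "perfect"
        assert (rc.n_sub, rc.n_ins, rc.n_del) == (0, 0, 0)

    def test_single_substitution(self, toy_pool):
        rc = classify_read("ACGTACGTAAAAATTTGCGG", toy_pool)
        assert rc.cls == "sub_only"
        assert (rc.n_sub, rc.n_ins, rc.n_del) == (1, 0, 0)

    def test_homopolymer_deletion(self, toy_pool):
        # one A dropped from the AAAAA run of D0
        rc = classify_read("ACGTACGTAAAATTTGCGC", toy_pool)
        assert rc.cls == "has_indel"
        assert (rc.n_sub, rc.n_ins, rc.n_del) == (0, 0, 1)

    def test_distance_beyond_limit_is_unmatched(self, toy_pool):
        rc = classify_read("G" * 20, toy_pool, max_edit_distance=5)
        assert rc.cls == "unmatched"
        assert rc.design_id is None

    def test_tie_broken_toward_smaller_design_id(self):
        # read is edit distance 2 from both designs; D0 must win the tie
        pool = DesignPool(ids=("D0", "D1"), sequences=("AAAATTTT", "AAAACCCC"))
        rc = classify_read("AAAATTCC", pool, max_edit_distance=5)
        assert rc.distance == 2
        assert rc.design_id == "D0"
        # same designs listed in the other order: the answer must not change
        pool_r = DesignPool(ids=("D1", "D0"), sequences=("AAAACCCC", "AAAATTTT"))
        rc_r = classify_read("AAAATTCC", pool_r, max_edit_distance=5)
        assert rc_r.design_id == "D0"

    def test_empty_pool_and_empty_insert_rejected(self, toy_pool):
        with pytest.raises(ValueError):
            classify_read("", toy_pool)

    def test_truth_counts_recovered_on_simulated_molecules(self, small_pool):
        # the aligner must reproduce the injected edit decomposition for
        # virtually all reads (alignment-ambiguous cases may differ in
        # decomposition but never in total distance)
        profile = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, profile, SynthesisErrorModel(),
                                    800, seed=21)
        reads = mols.rename(columns={"mol_id": "read_id"})[
            ["read_id", "sequence"]]
        cls = classify_reads(reads, small_pool)
        merged = cls.merge(mols, left_on="read_id", right_on="mol_id",
                           suffixes=("", "_true"))
        assert (merged["design_id"] == merged["design_id_true"]).all()
        exact = ((merged["n_sub"] == merged["n_sub_true"])
                 & (merged["n_ins"] == merged["n_ins_true"])
                 & (merged["n_del"] == merged["n_del_true"])).mean()
        assert exact >= 0.99
        total_pred = merged[["n_sub", "n_ins", "n_del"]].sum(axis=1)
        total_true = merged[["n_sub_true", "n_ins_true", "n_del_true"]].sum(axis=1)
        assert (total_pred <= total_true).all()


class TestSelect:
    @pytest.fixture()
    def mapping_and_classes(self):
        mapping = pd.DataFrame({
            "read_id": ["r1", "r2", "r3", "r4", "r5"],
            "well_id": ["R0C0", "R0C1", "R0C2", "R0C3", "R0C4"],
            "residual_px": [0.5, 0.1, 0.9, 0.2, 0.3],
            "flag": ["ok", "ok", "ok", "ok", "over_threshold"],
        })
        cls = pd.DataFrame({
            "read_id": ["r1", "r2", "r3", "r4", "r5"],
            "design_id": ["D0", "D0", "D1", "D2", "D2"],
            "n_sub": [0, 0, 0, 1, 0],
            "n_ins": [0, 0, 0, 0, 0],
            "n_del": [0, 0, 0, 0, 0],
            "distance": [0, 0, 0, 1, 0],
            "cls": ["perfect", "perfect", "perfect", "sub_only", "perfect"],
            "mean_quality": [30.0] * 5,
        })
        return mapping, cls

    def test_one_well_per_design_at_k1(self, mapping_and_classes):
        mapping, cls = mapping_and_classes
        sel = select_targets(mapping, cls, k=1, design_ids=["D0", "D1", "D2"])
        assert len(sel.frame) == 2  # D0 (best residual r2) and D1
        d0 = sel.frame[sel.frame["design_id"] == "D0"]
        assert d0["read_id"].tolist() == ["r2"]  # ascending residual
        assert sel.missing == ("D2",)  # r4 imperfect, r5 not ok-mapped

    def test_under_replicated_design_is_kept_and_flagged(self, mapping_and_classes):
        mapping, cls = mapping_and_classes
        sel = select_targets(mapping, cls, k=2, design_ids=["D0", "D1"])
        d1 = sel.frame[sel.frame["design_id"] == "D1"]
        assert d1["flag"].tolist() == ["under_replicated"]
        d0 = sel.frame[sel.frame["design_id"] == "D0"]
        assert d0["flag"].tolist() == ["ok", "ok"]
        assert d0["read_id"].tolist() == ["r2", "r1"]


class TestQualityGroups:
    def test_all_perfect_reads_are_fully_red_and_blue(self):
        cls = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(9)],
            "design_id": ["D0"] * 9,
            "n_sub": 0, "n_ins": 0, "n_del": 0, "distance": 0,
            "cls": "perfect",
            "mean_quality": np.linspace(10, 40, 9),
        })
        qa = quality_group_analysis(cls, 3)
        assert (qa["red_fraction"] == 1.0).all()
        assert (qa["blue_fraction"] == 1.0).all()

    def test_blue_never_exceeds_red(self):
        rng = np.random.default_rng(0)
        n = 300
        cls = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(n)],
            "design_id": ["D0"] * n,
            "n_sub": rng.poisson(0.5, n),
            "n_ins": rng.poisson(0.3, n),
            "n_del": rng.poisson(0.3, n),
            "distance": 1,
            "cls": "sub_only",
            "mean_quality": rng.uniform(10, 40, n),
        })
        qa = quality_group_analysis(cls, 3)
        assert (qa["blue_fraction"] <= qa["red_fraction"]).all()

    def test_too_few_reads_rejected(self):
        cls = pd.DataFrame({"read_id": ["a"], "design_id": ["D0"], "n_sub": [0],
                            "n_ins": [0], "n_del": [0], "distance": [0],
                            "cls": ["perfect"], "mean_quality": [30.0]})
        with pytest.raises(ValueError):
            quality_group_analysis(cls, 3)


class TestErrorRate:
    def _cls(self, n_err, n_reads=10):
        return pd.DataFrame({
            "read_id": [f"r{i}" for i in range(n_reads)],
            "design_id": ["D0"] * n_reads,
            "n_sub": [n_err] + [0] * (n_reads - 1),
            "n_ins": 0, "n_del": 0, "distance": 0,
            "cls": ["sub_only"] + ["perfect"] * (n_reads - 1),
            "mean_quality": 30.0,
        })

    def test_renders_one_in_x_bp(self):
        est = estimate_error_rate(self._cls(10), total_bases=23_670)
        assert est.text == "1 in 2,367 bp"
        assert est.rate == pytest.approx(10 / 23_670)

    def test_zero_errors_renders_specially(self):
        est = estimate_error_rate(self._cls(0), total_bases=1000)
        assert est.text == "0 errors in 1,000 bp"
        assert est.rate == 0.0

    def test_fold_improvement_examples(self):
        assert fold_improvement(1 / 70, 1 / 2367) == pytest.approx(2367 / 70)
        assert round(fold_improvement(1 / 70, 1 / 2367)) == 34
        assert fold_improvement(0.1, 0.1) == 1.0
        assert fold_improvement(1 / 10, 1 / 100) == pytest.approx(10.0)
        assert math.isinf(fold_improvement(0.1, 0.0))
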