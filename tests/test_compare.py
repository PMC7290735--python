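import numpy as np
import pandas as pd
import pytest

from pasflow import (
    RegulationCall,
    TimepointSummary,
    aggregate_unique_counts,
    classify_timepoint,
    correlation_matrix,
    dendrogram_newick,
    hierarchical_clustering,
    pas_profile,
    pca_projection,
    strong_inverse_set,
)
from pasflow.compare import CATEGORIES
from pasflow.datasets import reference_inverse_calls, reference_timepoint_summaries

from conftest import make_study


def profile_pair(small_db, pas_n, pas_e):
    """Build two PAS profiles over small_db whose group PAS are as given."""
    import dataclasses
    from pasflow.pas import PASProfile, PASConfig

    def mk(values):
        ids = small_db.pathway_ids
        s = pd.Series([values[p] for p in ids], index=ids)
        frame = pd.DataFrame({"x1": s, "x2": s})
        ones = pd.Series(1.0, index=ids)
        return PASProfile(
            sample_pas=frame, control_pas=frame, group_pas=s,
            p_sample=frame * 0 + 1, p_group=ones, fdr=ones,
            coverage=pd.Series(1.0, index=ids), config=PASConfig(),
        )

    return mk(pas_n), mk(pas_e)


class TestClassifyTimepoint:
    @pytest.mark.parametrize(
        "pn, pe, category, strong",
        [
            (0.2, 0.3, "common_activated", False),
            (-0.2, -0.3, "common_silenced", False),
            (0.26, -0.14, "inverse", True),
            (0.05, -0.05, "inverse", False),
            (0.2, 0.0, "unique_nHx_activated", False),
            (0.0, -0.2, "unique_eHx_silenced", False),
            (0.0, 0.0, "neutral", False),
        ],
    )
    def test_categories(self, small_db, pn, pe, category, strong):
        profs = profile_pair(small_db, {"P1": pn, "P2": 0.0}, {"P1": pe, "P2": 0.0})
        calls, _ = classify_timepoint(*profs, time_h=8)
        call = {c.pathway_id: c for c in calls}["P1"]
        assert call.category == category
        assert call.strong_inverse is strong

    def test_counts_partition_pathways(self, planted_study):
        db, study, _, _ = planted_study
        prof_n = pas_profile(study, db, study.select(arm="nHx", time_h=32),
                             study.select(arm="sham", time_h=32))
        prof_e = pas_profile(study, db, study.select(arm="eHx", time_h=32),
                             study.select(arm="sham", time_h=32))
        calls, summary = classify_timepoint(prof_n, prof_e, 32)
        assert len(calls) == len(db)
        assert sum(summary.counts.values()) == len(db)
        recount = {c: 0 for c in CATEGORIES}
        for call in calls:
            recount[call.category] += 1
        assert {k: v for k, v in recount.items() if v or k == "neutral"} == summary.counts

    def test_arm_swap_symmetry(self, planted_study):
        db, study, _, _ = planted_study
        prof_n = pas_profile(study, db, study.select(arm="nHx", time_h=32),
                             study.select(arm="sham", time_h=32))
        prof_e = pas_profile(study, db, study.select(arm="eHx", time_h=32),
                             study.select(arm="sham", time_h=32))
        calls, _ = classify_timepoint(prof_n, prof_e, 32)
        swapped, _ = classify_timepoint(prof_e, prof_n, 32)
        rename = {"unique_nHx_activated": "unique_eHx_activated",
                  "unique_eHx_activated": "unique_nHx_activated",
                  "unique_nHx_silenced": "unique_eHx_silenced",
                  "unique_eHx_silenced": "unique_nHx_silenced"}
        for a, b in zip(calls, swapped):
            assert b.category == rename.get(a.category, a.category)
            assert b.strong_inverse == a.strong_inverse

    def test_fdr_gate_is_stricter(self, planted_study):
        db, study, _, _ = planted_study
        prof_n = pas_profile(study, db, study.select(arm="nHx", time_h=32),
                             study.select(arm="sham", time_h=32))
        prof_e = pas_profile(study, db, study.select(arm="eHx", time_h=32),
                             study.select(arm="sham", time_h=32))
        _, by_sign = classify_timepoint(prof_n, prof_e, 32, gate="sign")
        _, by_fdr = classify_timepoint(prof_n, prof_e, 32, gate="fdr")
        assert by_fdr.counts.get("neutral", 0) >= by_sign.counts.get("neutral", 0)


class TestAggregateUniqueCounts:
    def test_reference_study_totals(self):
        summaries = reference_timepoint_summaries()
        assert aggregate_unique_counts(summaries, "nHx", "activated") == 68
        assert aggregate_unique_counts(summaries, "nHx", "silenced") == 53
        assert aggregate_unique_counts(summaries, "eHx", "activated") == 70
        assert aggregate_unique_counts(summaries, "eHx", "silenced") == 30

    def test_all_zero(self):
        summaries = [TimepointSummary.from_counts(t, 10) for t in (1, 8)]
        assert aggregate_unique_counts(summaries, "nHx", "activated") == 0

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(7)
        summaries, expected = [], 0
        for t in (1, 8, 16, 32, 48):
            k = int(rng.integers(0, 20))
            expected += k
            summaries.append(TimepointSummary.from_counts(t, 100, unique_eHx_silenced=k))
        assert aggregate_unique_counts(summaries, "eHx", "silenced") == expected

    def test_duplicate_time_point_rejected(self):
        s = TimepointSummary.from_counts(8, 10)
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_unique_counts([s, s], "nHx", "activated")


class TestStrongInverse:
    def test_reference_inverse_pathways(self):
        calls = reference_inverse_calls()
        assert len(calls) == 33
        strong = strong_inverse_set(calls, threshold=0.1)
        assert len(strong) == 14

    def test_empty_input(self):
        assert strong_inverse_set([]) == []

    def test_subthreshold_pair_excluded(self):
        call = RegulationCall("P", 8, 0.09, -0.09, "activated", "silenced", "inverse", False)
        assert strong_inverse_set([call], threshold=0.1) == []

    def test_monotone_in_threshold(self):
        calls = reference_inverse_calls()
        sizes = [len(strong_inverse_set(calls, threshold=t))
                 for t in (0.0, 0.05, 0.1, 0.2, 0.5, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_difference_criterion(self):
        call = RegulationCall("P", 8, 0.06, -0.06, "activated", "silenced", "inverse", False)
        assert strong_inverse_set([call], 0.1, criterion="difference") == [call]
        assert strong_inverse_set([call], 0.1, criterion="per_arm_magnitude") == []


def pas_matrix(cols: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"P{i}" for i in range(len(next(iter(cols.values()))))])


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        m = pas_matrix({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        z, order = hierarchical_clustering(m, distance="euclidean")
        assert z[0, 2] == 0.0
        assert set(order) == {"a", "b"}

    def test_duplicates_merge_first(self):
        m = pas_matrix({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                        "far": [9.0, 1.0, -5.0]})
        z, _ = hierarchical_clustering(m, distance="euclidean")
        assert sorted(z[0, :2]) == [0, 1]  # the two duplicates
        assert z[0, 2] == 0.0

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(8)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = list(np.array([5.0, 5, 5, -5, -5]) + rng.normal(0, 0.3, 5))
        for i in range(3):
            cols[f"b{i}"] = list(np.array([-5.0, -5, -5, 5, 5]) + rng.normal(0, 0.3, 5))
        z, order = hierarchical_clustering(pas_matrix(cols), distance="pearson")
        # top split separates the planted groups: leaf order is contiguous
        groups = ["a" if s.startswith("a") else "b" for s in order]
        assert groups == sorted(groups) or groups == sorted(groups, reverse=True)

    def test_constant_column_under_pearson_rejected(self):
        m = pas_matrix({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="a"):
            hierarchical_clustering(m, distance="pearson")

    def test_newick_contains_all_leaves(self):
        m = pas_matrix({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.5, 3.0], "c": [9.0, 0.0, 1.0]})
        z, _ = hierarchical_clustering(m, distance="euclidean")
        nwk = dendrogram_newick(z, sorted(m.columns))
        assert nwk.endswith(";")
        for leaf in "abc":
            assert leaf in nwk


class TestPCA:
    def test_rank_one_matrix(self):
        base = np.array([1.0, 2.0, 3.0])
        m = pas_matrix({"a": list(base), "b": list(2 * base), "c": list(3 * base)})
        coords, explained = pca_projection(m, k=1)
        assert explained[0] == pytest.approx(1.0)

    def test_duplicated_sample_same_coordinates(self):
        m = pas_matrix({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0], "c": [0.0, -3.0, 8.0]})
        coords, _ = pca_projection(m, k=1)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_k_exceeding_rank_rejected(self):
        m = pas_matrix({"a": [1.0, 2.0], "b": [2.0, 4.0], "c": [3.0, 6.0]})
        with pytest.raises(ValueError, match="rank"):
            pca_projection(m, k=3)

    def test_explained_variance_non_increasing(self, planted_study):
        db, study, _, _ = planted_study
        prof = pas_profile(study, db, study.select(arm="eHx", time_h=32),
                           study.select(arm="sham", time_h=32))
        joint = prof.sample_pas
        coords, explained = pca_projection(joint, k=2)
        assert explained[0] >= explained[1] >= 0

    def test_planted_groups_linearly_separable_on_pc1(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            cols = {f"a{i}": list(rng.normal(+4, 1, 6)) for i in range(3)}
            cols |= {f"b{i}": list(rng.normal(-4, 1, 6)) for i in range(3)}
            coords, _ = pca_projection(pas_matrix(cols), k=1)
            a = coords.loc[[f"a{i}" for i in range(3)], "PC1"]
            b = coords.loc[[f"b{i}" for i in range(3)], "PC1"]
            if a.max() < b.min() or b.max() < a.min():
                hits += 1
        assert hits / 40 >= 0.95


class TestCorrelationMatrix:
    def test_oracle_and_structure(self):
        rng = np.random.default_rng(10)
        m = pas_matrix({f"s{i}": list(rng.normal(0, 1, 8)) for i in range(5)})
        cm = correlation_matrix(m)
        assert np.allclose(np.diag(cm.to_numpy()), 1.0)
        assert np.allclose(cm.to_numpy(), cm.to_numpy().T)
        assert cm.to_numpy().min() >= -1 and cm.to_numpy().max() <= 1
        for a in cm.index:
            for b in cm.columns:
                expected = np.corrcoef(m[a], m[b])[0, 1]
                assert cm.loc[a, b] == pytest.approx(expected, abs=1e-12)
        _, order = hierarchical_clustering(m, distance="pearson")
        assert list(cm.index) == order

    def test_negated_sample_anticorrelated(self):
        m = pas_matrix({"a": [1.0, 2.0, 3.0], "b": [-1.0, -2.0, -3.0]})
        cm = correlation_matrix(m)
        assert cm.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_sample_rejected(self):
        m = pas_matrix({"a": [1.0, 1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(m)
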