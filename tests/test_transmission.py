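import itertools

import numpy as np
import pandas as pd
import pytest

import seedtrans as st
from seedtrans.io import DataError
from seedtrans.transmission import overlap_summary


def _seed_study(patterns, counts_per_group=(5, 5, 5)):
    """Build a toy seed-only study from per-group presence patterns."""
    otus = [f"o{i}" for i in range(len(patterns))]
    cols, rows = {}, []
    groups = {"g1": [], "g2": [], "g3": []}
    for g_idx, (gname, n) in enumerate(zip(groups, counts_per_group)):
        for r in range(n):
            sid = f"{gname}_r{r}"
            col = np.zeros(len(otus), dtype=int)
            for i, pat in enumerate(patterns):
                if pat[g_idx]:
                    col[i] = 10
            col[0] = max(col[0], 1)  # nonzero column guard
            cols[sid] = col
            groups[gname].append(sid)
            rows.append({"sample_id": sid, "compartment": "Se", "age_days": g_idx * 10,
                         "year": 2018, "site": "SW", "bio_rep": r + 1, "tech_rep": 1})
    table = st.CountTable(pd.DataFrame(cols, index=otus))
    meta = st.SampleMeta(pd.DataFrame(rows))
    return table, meta, groups


class TestDetectTransmitted:
    def test_toy_presence_patterns(self):
        patterns = [(1, 1, 1), (1, 0, 1), (1, 1, 0), (0, 1, 1), (1, 1, 1)]
        table, meta, groups = _seed_study(patterns)
        res = st.detect_transmitted(table, meta, groups)
        assert sorted(res.transmitted) == ["o0", "o4"]
        assert len(res.transient) == 3
        # partition property: statuses cover every seed OTU exactly once
        assert len(res.transmitted) + len(res.transient) == 5

    def test_detection_rule_boundary(self):
        # one OTU with a single positive replicate in group 2
        table, meta, groups = _seed_study([(1, 1, 1), (1, 1, 1)])
        counts = table.counts.copy()
        counts.loc["o1", groups["g2"]] = 0
        counts.loc["o1", groups["g2"][0]] = 3  # mean 0.6 > 0 but < 5
        table = st.CountTable(counts)
        res_mean = st.detect_transmitted(table, meta, groups, detection="mean_gt_zero")
        assert res_mean.status["o1"] == "transmitted"
        res_min = st.detect_transmitted(table, meta, groups, detection="min_count", min_count=5)
        assert res_min.status["o1"] == "transient"

    def test_empty_group_rejected(self):
        table, meta, groups = _seed_study([(1, 1, 1)])
        groups["g3"] = []
        with pytest.raises(DataError, match="empty"):
            st.detect_transmitted(table, meta, groups)

    def test_overlapping_groups_rejected(self):
        table, meta, groups = _seed_study([(1, 1, 1)])
        groups["g2"] = groups["g2"][:-1] + [groups["g1"][0]]
        with pytest.raises(DataError, match="overlap"):
            st.detect_transmitted(table, meta, groups)

    def test_full_study_recovers_planted_set_exactly(self, full_study):
        table, meta, _, truth = full_study
        res = st.detect_transmitted(table, meta, truth.generation_groups)
        assert set(res.transmitted) == truth.transmitted_otus
        # every planted transient OTU is called transient
        called = set(res.transient)
        assert set(truth.transient_otus) <= called


class TestClassifySuccession:
    def _meta(self, ages, reps):
        rows = [{"sample_id": f"a{a}r{r}", "compartment": "Se", "age_days": a,
                 "year": 2018, "site": "SW", "bio_rep": r, "tech_rep": 1}
                for a in ages for r in range(1, reps + 1)]
        return st.SampleMeta(pd.DataFrame(rows))

    def test_linear_increase_is_late_and_constant_is_no_trend(self):
        ages = [10, 20, 30, 40, 50]
        meta = self._meta(ages, reps=3)
        sids = list(meta.table["sample_id"])
        age_of = {s: int(meta.lookup(s)["age_days"]) for s in sids}
        rising = np.array([0.001 * age_of[s] for s in sids])
        flat = np.full(len(sids), 0.2)
        rest = 1.0 - rising - flat
        values = pd.DataFrame([rising, flat, rest], index=["up", "flat", "rest"], columns=sids)
        res = st.classify_succession(
            st.NormalizedTable(values, "relative_abundance"), meta)
        assert res.table.loc["up", "mode"] == "Late"
        assert res.table.loc["flat", "mode"] == "MidNoTrend"

    def test_absent_otu_flagged_degenerate(self):
        ages = [10, 20, 30]
        meta = self._meta(ages, reps=2)
        sids = list(meta.table["sample_id"])
        values = pd.DataFrame([np.zeros(len(sids)), np.ones(len(sids))],
                              index=["gone", "all"], columns=sids)
        res = st.classify_succession(st.NormalizedTable(values, "relative_abundance"), meta)
        assert res.table.loc["gone", "mode"] == "MidNoTrend"
        assert res.table.loc["gone", "p_value"] == 1.0
        assert bool(res.table.loc["gone", "degenerate"])

    def test_every_otu_gets_exactly_one_mode(self, seed_subset):
        sub, meta_sub, _ = seed_subset
        ra = st.transform(sub, "relative_abundance")
        res = st.classify_succession(ra, meta_sub)
        assert set(res.table["mode"]) <= {"Early", "Late", "MidNoTrend"}
        assert len(res.table) == len(sub.otu_ids)

    def test_planted_late_otus_recovered(self, seed_subset):
        sub, meta_sub, truth = seed_subset
        ra = st.transform(sub, "relative_abundance")
        res = st.classify_succession(ra, meta_sub)
        modes = res.table.loc[sorted(truth.transmitted_otus), "mode"]
        assert (modes == "Late").mean() >= 0.95


class TestConvergenceTrajectory:
    def test_progeny_identical_to_parent_has_zero_distance(self):
        otus = ["o0", "o1"]
        cols, rows = {}, []
        profile = np.array([6, 4])
        # parent (age 0) and one progeny age with identical composition
        for i, (age, rep) in enumerate([(0, 1), (0, 2), (60, 1), (60, 2)]):
            cols[f"s{i}"] = profile
            rows.append({"sample_id": f"s{i}", "compartment": "Se", "age_days": age,
                         "year": 2018, "site": "SW", "bio_rep": rep, "tech_rep": 1})
        table = st.CountTable(pd.DataFrame(cols, index=otus))
        meta = st.SampleMeta(pd.DataFrame(rows))
        res = st.convergence_trajectory(table, meta, run_test=False)
        assert np.allclose(res.distances["distance"], 0.0)

    def test_interpolating_progeny_monotone_decreasing(self):
        rng = np.random.default_rng(0)
        parent = rng.dirichlet(np.ones(30))
        start = rng.dirichlet(np.ones(30))
        otus = [f"o{i}" for i in range(30)]
        cols, rows = {}, []
        for rep in (1, 2, 3):
            cols[f"p{rep}"] = np.round(parent * 10000).astype(int) + 1
            rows.append({"sample_id": f"p{rep}", "compartment": "Se", "age_days": 0,
                         "year": 2018, "site": "SW", "bio_rep": rep, "tech_rep": 1})
        ages = [20, 40, 60, 80]
        for age in ages:
            lam = age / 100
            mix = (1 - lam) * start + lam * parent
            for rep in (1, 2, 3):
                cols[f"a{age}r{rep}"] = np.round(mix * 10000).astype(int) + 1
                rows.append({"sample_id": f"a{age}r{rep}", "compartment": "Se",
                             "age_days": age, "year": 2018, "site": "SW",
                             "bio_rep": rep, "tech_rep": 1})
        table = st.CountTable(pd.DataFrame(cols, index=otus))
        meta = st.SampleMeta(pd.DataFrame(rows))
        res = st.convergence_trajectory(table, meta, run_test=False)
        med = res.distances.groupby("age_days")["distance"].median()
        assert np.all(np.diff(med.to_numpy()) < 0)

    def test_restriction_to_full_set_is_identity(self, full_study):
        table, meta, _, _ = full_study
        free = st.convergence_trajectory(table, meta, run_test=False)
        restricted = st.convergence_trajectory(
            table, meta, restrict_to=set(table.otu_ids), run_test=False)
        pd.testing.assert_frame_equal(free.distances, restricted.distances)


class TestCoreOtus:
    def _study(self, hits, total=10):
        otus = ["core8", "core7", "bg"]
        cols, rows = {}, []
        for i in range(total):
            col = np.array([1 if i < hits[0] else 0, 1 if i < hits[1] else 0, 1])
            cols[f"s{i}"] = col
            rows.append({"sample_id": f"s{i}", "compartment": "Se", "age_days": i,
                         "year": 2018, "site": "SW", "bio_rep": 1, "tech_rep": 1})
        return (st.CountTable(pd.DataFrame(cols, index=otus)),
                st.SampleMeta(pd.DataFrame(rows)))

    def test_prevalence_boundary_inclusive(self):
        table, meta = self._study(hits=(8, 7))
        cores = st.core_otus(table, meta, prevalence=0.8)
        assert "core8" in cores.sets["Se"]
        assert "core7" not in cores.sets["Se"]

    def test_prevalence_one_requires_zero_absences(self):
        table, meta = self._study(hits=(10, 9))
        cores = st.core_otus(table, meta, prevalence=1.0)
        assert cores.sets["Se"] == {"core8", "bg"}

    def test_raising_threshold_never_adds_otus(self, full_study):
        table, meta, _, _ = full_study
        lo = st.core_otus(table, meta, prevalence=0.5)
        hi = st.core_otus(table, meta, prevalence=0.9)
        for comp in hi.sets:
            assert hi.sets[comp] <= lo.sets[comp]


class TestOverlapSummary:
    def test_disjoint_sets_have_empty_intersections(self):
        out = overlap_summary({"A": {1, 2}, "B": {3, 4}})
        both = out[out["sets"] == "A&B"]["count"].iloc[0]
        assert both == 0

    def test_subset_relation_empties_exclusive_region(self):
        out = overlap_summary({"trans": {1, 2}, "core": {1, 2, 3}})
        only_trans = out[out["sets"] == "trans"]["count"].iloc[0]
        assert only_trans == 0

    def test_three_set_regions_match_brute_force(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6, 7}}
        out = overlap_summary(sets)
        universe = set().union(*sets.values())
        for r in out.itertuples():
            inside = r.sets.split("&")
            outside = [n for n in sets if n not in inside]
            region = set.intersection(*(sets[n] for n in inside)) - set().union(
                *(sets[n] for n in outside)) if outside else set.intersection(
                *(sets[n] for n in inside))
            assert r.count == len(region)
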