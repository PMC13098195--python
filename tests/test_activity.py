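import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modkit.activity import (
    ReplicateNull,
    classify_phase,
    cluster_profiles,
    dima_test,
    fit_replicate_null,
    phase_templates,
)
from modkit.compendium import SampleTable

GRID = [0.0, 1.5, 3.5, 7.5, 15.0, 30.0]


def meta_for(groups):
    """SampleTable with duplicate groups named g1..gN (condition == group)."""
    rows = []
    for gname, size in groups:
        for r in range(size):
            rows.append((f"{gname}_r{r + 1}", "p", gname, 0.0, f"r{r + 1}", False))
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "project", "condition", "time_min",
                                    "replicate_id", "is_reference"])
    )


class TestReplicateNull:
    def test_constant_pair_differences_degenerate(self):
        meta = meta_for([(f"g{i}", 2) for i in range(20)])
        vals = []
        for i in range(20):
            vals += [float(i), float(i) + 1.0]  # every pair differs by exactly 1
        a = pd.DataFrame([vals], index=["IC_1"], columns=meta.sample_ids)
        null = fit_replicate_null(a, meta)[0]
        assert abs(null.mu) < 1e-9 and null.sigma < 1e-6
        assert null.degenerate and null.sf(10.0) == 1.0

    def test_lognormal_parameters_recovered(self):
        rng = np.random.default_rng(0)
        n_pairs = 500
        meta = meta_for([(f"g{i}", 2) for i in range(n_pairs)])
        d = rng.lognormal(mean=1.0, sigma=0.5, size=n_pairs)
        vals = []
        for i in range(n_pairs):
            vals += [0.0, d[i]]
        a = pd.DataFrame([vals], index=["IC_1"], columns=meta.sample_ids)
        null = fit_replicate_null(a, meta)[0]
        assert null.mu == pytest.approx(1.0, abs=0.1)
        assert null.sigma == pytest.approx(0.5, abs=0.1)
        assert null.n_pairs == n_pairs

    def test_triplicate_group_contributes_three_pairs(self):
        meta = meta_for([("g1", 3)])
        a = pd.DataFrame([[0.0, 1.0, 3.0]], index=["IC_1"], columns=meta.sample_ids)
        null = fit_replicate_null(a, meta)[0]
        assert null.n_pairs == 3

    def test_no_replicates_rejected(self):
        meta = meta_for([("g1", 1), ("g2", 1)])
        a = pd.DataFrame([[0.0, 1.0]], index=["IC_1"], columns=meta.sample_ids)
        with pytest.raises(ValueError, match="replicate"):
            fit_replicate_null(a, meta)


class TestDimaTest:
    def _setup(self, mean_b, sigma=1.0, mu=0.0):
        meta = meta_for([("cond_a", 2), ("cond_b", 2)])
        a = pd.DataFrame(
            [[0.0, 0.0, mean_b, mean_b]], index=["IC_1"], columns=meta.sample_ids
        )
        nulls = [ReplicateNull("IC_1", mu=mu, sigma=sigma, n_pairs=10)]
        return a, meta, nulls

    def test_zero_difference_gives_p_one(self):
        a, meta, nulls = self._setup(0.0)
        rec = dima_test(a, meta, "cond_a", "cond_b", nulls)[0]
        assert rec.p_value == 1.0 and not rec.significant

    def test_p_at_lognormal_median_is_half(self):
        # null with mu=0, sigma=1 has median exp(0)=1
        a, meta, nulls = self._setup(1.0)
        rec = dima_test(a, meta, "cond_a", "cond_b", nulls)[0]
        assert rec.abs_diff == pytest.approx(1.0)
        assert rec.p_value == pytest.approx(0.5, abs=1e-12)

    def test_small_shift_fails_five_unit_rule_despite_tiny_q(self):
        a, meta, nulls = self._setup(4.9, sigma=0.1, mu=-3.0)
        rec = dima_test(a, meta, "cond_a", "cond_b", nulls)[0]
        assert rec.q_value < 0.001
        assert rec.abs_diff == pytest.approx(4.9)
        assert not rec.significant

    def test_missing_condition_rejected(self):
        a, meta, nulls = self._setup(1.0)
        with pytest.raises(ValueError, match="nope"):
            dima_test(a, meta, "cond_a", "nope", nulls)

    def test_missing_null_named(self):
        a, meta, _ = self._setup(1.0)
        with pytest.raises(ValueError, match="IC_1"):
            dima_test(a, meta, "cond_a", "cond_b", [])

    @settings(derandomize=True, max_examples=50)
    @given(
        d1=st.floats(0.01, 50.0),
        d2=st.floats(0.01, 50.0),
        sigma=st.floats(0.1, 2.0),
        mu=st.floats(-2.0, 2.0),
    )
    def test_p_monotone_decreasing_in_difference(self, d1, d2, sigma, mu):
        null = ReplicateNull("IC", mu=mu, sigma=sigma, n_pairs=5)
        lo, hi = sorted([d1, d2])
        assert null.sf(hi) <= null.sf(lo)

    def test_bh_qvalues_invariant_to_component_order(self):
        rng = np.random.default_rng(0)
        n = 40
        meta = meta_for([("cond_a", 2), ("cond_b", 2)])
        vals = np.column_stack(
            [rng.normal(0, 1, n), rng.normal(0, 1, n),
             rng.normal(3, 1, n), rng.normal(3, 1, n)]
        )
        ids = [f"IC_{i}" for i in range(n)]
        a = pd.DataFrame(vals, index=ids, columns=meta.sample_ids)
        nulls = [ReplicateNull(i, mu=0.0, sigma=1.0, n_pairs=5) for i in ids]
        rec = dima_test(a, meta, "cond_a", "cond_b", nulls)
        perm = list(rng.permutation(ids))
        rec_p = dima_test(a.loc[perm], meta, "cond_a", "cond_b", nulls)
        q1 = {r.component_id: r.q_value for r in rec}
        q2 = {r.component_id: r.q_value for r in rec_p}
        assert q1 == pytest.approx(q2)


def timeseries_meta(n_components_unused=None, conditions=("c1",), reps=2):
    rows = []
    for cond in conditions:
        for t in GRID:
            for r in range(reps):
                rows.append((f"{cond}_t{t:g}_r{r + 1}", "p", cond, t, f"r{r + 1}", False))
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "project", "condition", "time_min",
                                    "replicate_id", "is_reference"])
    )


class TestProfileClustering:
    def _activities(self, profiles, meta):
        rows = []
        for prof in profiles:
            by_time = dict(zip(GRID, prof))
            rows.append([by_time[t] for t in meta.data["time_min"]])
        return pd.DataFrame(rows, index=[f"IC_{i}" for i in range(len(profiles))],
                            columns=meta.sample_ids)

    def test_identical_profiles_share_cluster(self):
        meta = timeseries_meta()
        a = self._activities([[0, 1, 2, 3, 4, 5]] * 2, meta)
        labels = cluster_profiles(a, meta, corr_threshold=0.7)
        assert labels["IC_0"] == labels["IC_1"]

    def test_anticorrelated_profiles_split(self):
        meta = timeseries_meta()
        prof = [0, 1, 2, 3, 4, 5]
        a = self._activities([prof, [-v for v in prof]], meta)
        labels = cluster_profiles(a, meta, corr_threshold=0.7)
        assert labels["IC_0"] != labels["IC_1"]

    def test_template_generated_profiles_recover_grouping(self):
        from sklearn.metrics import rand_score

        rng = np.random.default_rng(0)
        meta = timeseries_meta()
        templates = phase_templates(GRID)
        true_labels, profiles = [], []
        for i, phase in enumerate(["primary", "secondary", "tertiary"] * 10):
            profiles.append(templates[phase] + rng.normal(0, 0.1, len(GRID)))
            true_labels.append(phase)
        a = self._activities(profiles, meta)
        labels = cluster_profiles(a, meta, corr_threshold=0.7)
        pred = [labels[f"IC_{i}"] for i in range(30)]
        assert rand_score(true_labels, pred) > 0.9

    def test_single_time_point_rejected(self):
        rows = [("s1", "p", "c", 0.0, "r1", False), ("s2", "p", "c", 0.0, "r2", False)]
        meta = SampleTable(pd.DataFrame(
            rows, columns=["sample_id", "project", "condition", "time_min",
                           "replicate_id", "is_reference"]))
        a = pd.DataFrame([[1.0, 2.0]], index=["IC_0"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="time point"):
            cluster_profiles(a, meta)


class TestPhaseClassification:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((0, 8, 8, 8, 8, 8), "primary"),
            ((0, 0, 1, 6, 10, 2), "secondary"),
            ((0, 0, 0, 2, 5, 9), "tertiary"),
        ],
    )
    def test_canonical_profiles(self, profile, expected):
        pa = classify_phase(pd.Series(profile, index=GRID))
        assert pa.phase == expected
        assert pa.template_correlation >= 0.7

    def test_repressed_profile_classifies_like_activated(self):
        up = classify_phase(pd.Series((0, 8, 8, 8, 8, 8), index=GRID))
        down = classify_phase(pd.Series((0, -8, -8, -8, -8, -8), index=GRID))
        assert up.phase == down.phase == "primary"

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_to_positive_scaling(self, scale):
        prof = pd.Series((0, 0, 1, 6, 10, 2), index=GRID)
        assert classify_phase(prof * scale).phase == classify_phase(prof).phase

    def test_constant_profile_unclassified(self):
        pa = classify_phase(pd.Series([2.0] * 6, index=GRID))
        assert pa.phase == "unclassified" and pa.template_correlation == 0.0

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError, match="4 time points"):
            classify_phase(pd.Series([0, 1, 2], index=[0.0, 5.0, 10.0]))

    def test_noisy_templates_classified_accurately(self):
        import modkit as mk

        profs = mk.simulate_phase_profiles(n_per_phase=50, noise_sd=0.1, seed=2)
        acc = np.mean([classify_phase(p).phase == phase for phase, p in profs])
        assert acc >= 0.9
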