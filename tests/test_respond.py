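"""Responsive-neuron classification, taxonomy and group comparisons."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from fearsemble import align, respond, synthdata
from fearsemble.io import Event, EventSchedule, EventType, TraceMatrix
from fearsemble.respond import Label

from conftest import make_traces


def brute_force_label(z, threshold=3.0, n_consec=2):
    """Independent consecutive-pair scan used as the classification oracle."""
    plus = [
        (i, np.mean(np.abs(z[i : i + n_consec])))
        for i in range(len(z) - n_consec + 1)
        if all(v > threshold for v in z[i : i + n_consec])
    ]
    minus = [
        (i, np.mean(np.abs(z[i : i + n_consec])))
        for i in range(len(z) - n_consec + 1)
        if all(v < -threshold for v in z[i : i + n_consec])
    ]
    if not plus and not minus:
        return Label.NONE
    if plus and not minus:
        return Label.PLUS
    if minus and not plus:
        return Label.MINUS
    return (
        Label.PLUS
        if max(p[1] for p in plus) >= max(m[1] for m in minus)
        else Label.MINUS
    )


class TestClassifyResponse:
    def test_flat_trace_none(self):
        assert respond.classify_response(np.zeros(15)).label is Label.NONE

    def test_consecutive_pair_plus(self):
        z = np.array([0.0, 3.5, 3.2] + [0.0] * 12)
        lab = respond.classify_response(z)
        assert lab.label is Label.PLUS
        assert lab.trigger_bin == 1

    def test_isolated_crossings_none(self):
        z = np.array([3.5, 0.0, 3.5] + [0.0] * 12)
        assert respond.classify_response(z).label is Label.NONE

    def test_minus_pair(self):
        z = np.array([0.0, -4.0, -3.1] + [0.0] * 12)
        lab = respond.classify_response(z)
        assert lab.label is Label.MINUS

    def test_both_patterns_tie_break_by_mean_abs(self):
        z = np.array([3.5, 3.5, 0.0, -4.0, -4.0] + [0.0] * 10)
        assert respond.classify_response(z).label is Label.MINUS

    def test_exact_threshold_not_responsive(self):
        z = np.array([3.0, 3.0] + [0.0] * 13)  # strict inequality
        assert respond.classify_response(z).label is Label.NONE

    def test_too_few_bins_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            respond.classify_response(np.array([5.0]))

    def test_random_walk_oracle_equality(self, rng):
        z = np.cumsum(rng.standard_normal((2000, 15)) * 1.5, axis=1)
        for zi in z:
            got = respond.classify_response(zi).label
            assert got is brute_force_label(zi)

    def test_monotonicity_raising_trace_never_loses_plus(self, rng):
        for zi in rng.standard_normal((200, 15)) * 2.5:
            before = respond.classify_response(zi).label
            after = respond.classify_response(zi + 1.0).label
            if before is Label.PLUS:
                assert after is Label.PLUS


class TestTaxonomy:
    def test_nine_types_enumerated(self):
        assert len(respond.ALL_TYPE_CODES) == 9
        assert len(set(respond.ALL_TYPE_CODES)) == 9
        pairs = {tuple(code.split("/")) for code in respond.ALL_TYPE_CODES}
        assert pairs == set(itertools.product(["PLUS", "MINUS", "NONE"], repeat=2))

    def test_all_none_neurons(self):
        labs = [respond.ResponseLabel(Label.NONE)] * 4
        props = respond.taxonomy_proportions(respond.response_taxonomy(labs, labs))
        assert props["proportions"]["NONE/NONE"] == 1.0
        assert props["dual_proportion"] == 0.0

    def test_dual_aggregate(self):
        nt = [respond.ResponseLabel(Label.PLUS), respond.ResponseLabel(Label.PLUS)]
        cs = [respond.ResponseLabel(Label.NONE), respond.ResponseLabel(Label.PLUS)]
        props = respond.taxonomy_proportions(respond.response_taxonomy(nt, cs))
        assert props["dual_proportion"] == 0.5

    def test_partition_sums_to_one(self, rng):
        n = 50
        labels = [respond.ResponseLabel(l) for l in Label]
        nt = [labels[i] for i in rng.integers(0, 3, n)]
        cs = [labels[i] for i in rng.integers(0, 3, n)]
        props = respond.taxonomy_proportions(respond.response_taxonomy(nt, cs))
        assert sum(props["proportions"].values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(props["counts"].values()) == n

    def test_mismatched_label_sets_error(self):
        with pytest.raises(ValueError, match="identical neurons"):
            respond.response_taxonomy(
                [respond.ResponseLabel(Label.NONE)],
                [respond.ResponseLabel(Label.NONE)] * 2,
            )


class TestFisher:
    @staticmethod
    def props(k, n):
        counts = {c: 0 for c in respond.ALL_TYPE_CODES}
        counts["PLUS/PLUS"] = k
        counts["NONE/NONE"] = n - k
        return {"n": n, "counts": counts}

    def test_symmetric_table_or_one(self):
        res = respond.compare_type_proportions(
            self.props(10, 100), self.props(10, 100), "PLUS/PLUS"
        )
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        # table [[1, 9], [9, 1]]: enumerate all tables with fixed margins
        res = respond.compare_type_proportions(
            self.props(1, 10), self.props(9, 10), "PLUS/PLUS"
        )
        m, n_total, k_margin = 10, 20, 10
        probs = [hypergeom.pmf(x, n_total, m, k_margin) for x in range(11)]
        p_obs = probs[1]
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert res["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_empty_type_p_one(self):
        res = respond.compare_type_proportions(
            self.props(0, 10), self.props(0, 10), "PLUS/PLUS"
        )
        assert res["p_value"] == pytest.approx(1.0)

    def test_group_swap_symmetry(self, rng):
        a, b = self.props(7, 40), self.props(19, 55)
        r1 = respond.compare_type_proportions(a, b, "PLUS/PLUS")
        r2 = respond.compare_type_proportions(b, a, "PLUS/PLUS")
        assert r1["p_value"] == pytest.approx(r2["p_value"], rel=1e-12)
        assert 0 < r1["p_value"] <= 1

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="empty"):
            respond.compare_type_proportions(
                self.props(1, 10), {"n": 0, "counts": {c: 0 for c in respond.ALL_TYPE_CODES}},
                "PLUS/PLUS",
            )


class TestStability:
    @staticmethod
    def tensor_from_tone_z(tone_z):
        """Wrap per-trial tone z (neurons x trials x bins) with a flat baseline."""
        n, t, b = tone_z.shape
        z = np.concatenate([np.zeros((n, t, 15)), tone_z], axis=2)
        from fearsemble.io import AlignedZTensor

        return AlignedZTensor(z=z, baseline_bins=15, tone_bins=b, block_size=1)

    def test_adjacent_responses_counted(self):
        tone_z = np.zeros((2, 3, 15))
        tone_z[0, 0, :2] = 5.0  # trials 0 and 1 -> counted
        tone_z[0, 1, :2] = 5.0
        tone_z[1, 0, :2] = 5.0  # trials 0 and 2 only -> not counted
        tone_z[1, 2, :2] = 5.0
        res = respond.consecutive_tone_stability(self.tensor_from_tone_z(tone_z))
        assert res["stable_mask"].tolist() == [True, False]
        assert res["proportion"] == 0.5

    def test_single_presentation_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            respond.consecutive_tone_stability(
                self.tensor_from_tone_z(np.zeros((1, 1, 15)))
            )

    def test_planted_stable_vs_alternating_matches_brute_force(self, rng):
        # stable neurons respond every trial; unstable on alternating trials
        n_trials = 4
        tone_z = rng.standard_normal((20, n_trials, 15)) * 0.5
        for i in range(10):
            tone_z[i, :, 3:5] += 8.0
        for i in range(10, 20):
            tone_z[i, ::2, 3:5] += 8.0
        res = respond.consecutive_tone_stability(self.tensor_from_tone_z(tone_z))
        # brute force: label each trial independently, scan adjacency
        expected = []
        for i in range(20):
            labs = [brute_force_label(tone_z[i, t]) for t in range(n_trials)]
            expected.append(
                any(
                    a is not Label.NONE and b is not Label.NONE
                    for a, b in zip(labs, labs[1:])
                )
            )
        assert res["stable_mask"].tolist() == expected
        assert all(res["stable_mask"][:10])
        assert not any(res["stable_mask"][10:])


class TestSpontaneousRate:
    def test_flat_trace_zero_rate(self):
        tm = make_traces(np.zeros(3000))
        sched = EventSchedule([])
        rates = respond.spontaneous_event_rate(tm, sched, (0.0, 300.0))
        assert rates[0] == 0.0

    def test_one_transient_in_five_minutes(self, rng):
        values = rng.standard_normal(3000) * 0.5
        values[1000:1030] += 20.0  # one clear 3-s excursion
        tm = make_traces(values)
        rates = respond.spontaneous_event_rate(tm, EventSchedule([]), (0.0, 300.0))
        assert rates[0] == pytest.approx(0.2)

    def test_window_overlapping_event_rejected(self):
        tm = make_traces(np.zeros(3000))
        sched = EventSchedule([Event(EventType.NT, 100.0, 15.0)])
        with pytest.raises(ValueError, match="overlaps"):
            respond.spontaneous_event_rate(tm, sched, (0.0, 300.0))

    def test_poisson_planted_rate_recovered(self):
        # planted events at 1/min over 10 min, 50 seeds: mean estimate within 2 SE
        lam = 1.0
        est = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            values = r.standard_normal(6000) * 0.5
            n_ev = r.poisson(lam * 10)
            # onsets on a 5-s grid so excursions never merge
            slots = np.arange(0, 595, 5)
            onsets = np.sort(r.choice(slots, size=n_ev, replace=False)) * 10
            for o in onsets:
                values[o : o + 30] += 15.0
            tm = make_traces(values)
            est.append(
                respond.spontaneous_event_rate(tm, EventSchedule([]), (0.0, 600.0))[0]
            )
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - lam) < 2 * se + 0.05


class TestPlantedRecovery:
    def test_taxonomy_recovers_planted_fractions(self, mixed_population, small_session):
        traces, sched, truth = synthdata.generate_session(
            mixed_population, small_session
        )
        t_nt = align.peri_tone_tensor(traces, sched, EventType.NT)
        t_cs = align.peri_tone_tensor(traces, sched, EventType.CS_PLUS)
        tax = respond.response_taxonomy(
            respond.classify_tensor(t_nt),
            respond.classify_tensor(t_cs),
            traces.neuron_ids,
        )
        merged = tax.merge(truth, on="neuron_id")
        dual = (merged["type_code"] == "PLUS/PLUS").mean()
        cs_only = (merged["type_code"] == "NONE/PLUS").mean()
        assert dual == pytest.approx(0.2, abs=0.08)  # n=60, binomial slack
        assert cs_only == pytest.approx(0.3, abs=0.10)
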