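"""Log-rank statistic, maxstat cutpoint scan, MASA calling and association."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy import stats

from cismeth import association_test, call_masa, logrank_test, maxstat_cutoff
from cismeth.survival import survival_scan


def tabulated_logrank(time, event, group):
    """Independent per-event-time O-E/V tabulation (the textbook recipe)."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    group = np.asarray(group, bool)
    u = v = 0.0
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n, n1 = at.sum(), (at & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u, v


class TestLogrank:
    time = np.array([1, 2, 3, 4, 5, 1.5, 2.5, 3.5, 4.5, 6.0])
    event = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1])
    group = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)

    def test_matches_hand_tabulation_exactly(self):
        res = logrank_test(self.time, self.event, self.group)
        # frozen from the explicit O-E/V tabulation: O-E = 37/126,
        # V = 1.4640337616528094
        assert res.statistic == pytest.approx(0.058899453598933005, abs=1e-10)
        u, v = tabulated_logrank(self.time, self.event, self.group)
        assert res.statistic == pytest.approx(u * u / v, abs=1e-10)
        assert res.p == pytest.approx(stats.chi2.sf(u * u / v, 1), abs=1e-10)

    def test_agrees_with_lifelines_on_random_data(self, rng):
        for _ in range(10):
            n = 40
            time = rng.exponential(10, n).round(1) + 0.1
            event = rng.random(n) < 0.7
            group = rng.random(n) < 0.5
            if not group.any() or group.all():
                continue
            ours = logrank_test(time, event.astype(int), group)
            ref = lifelines_logrank(
                time[group], time[~group], event[group], event[~group]
            )
            assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert ours.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_identical_groups_give_null_result(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        group = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        res = logrank_test(time, event, group)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        a = logrank_test(self.time, self.event, self.group)
        b = logrank_test(self.time, self.event, ~self.group)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p == pytest.approx(b.p)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test([1.0, 2.0], [1, 1], [True, True])

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = logrank_test([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0], [1, 1, 0, 0])
        assert res.p == 1.0


class TestMaxstat:
    @staticmethod
    def changepoint_data(rng, n=60, cut=0.0):
        x = np.sort(rng.normal(size=n))
        low = x <= cut
        time = np.where(low, rng.exponential(2.0, n), rng.exponential(20.0, n))
        event = np.ones(n, dtype=int)
        return x, time + 0.01, event

    def test_recovers_planted_changepoint(self, rng):
        x, time, event = self.changepoint_data(rng)
        res = maxstat_cutoff(x, time, event)
        gaps = np.diff(np.sort(np.unique(x)))
        assert abs(res.cutoff - 0.0) <= gaps.max() + 1e-9

    def test_equals_exhaustive_cutpoint_scan(self, rng):
        x = rng.normal(size=50)
        time = rng.exponential(5, 50) + 0.1
        event = (rng.random(50) < 0.8).astype(int)
        res = maxstat_cutoff(x, time, event, minprop=0.1)
        uniq = np.unique(x)
        cands = (uniq[:-1] + uniq[1:]) / 2
        best = -np.inf
        best_cut = None
        for c in cands:
            g = x <= c
            if min(g.sum(), (~g).sum()) < np.ceil(0.1 * len(x)):
                continue
            z = abs(logrank_test(time, event, g).z)
            if z > best:
                best, best_cut = z, c
        assert res.cutoff == pytest.approx(best_cut)
        assert abs(res.z) == pytest.approx(best, abs=1e-10)

    def test_constant_expression_rejected(self, rng):
        time = rng.exponential(5, 40) + 0.1
        with pytest.raises(ValueError, match="constant"):
            maxstat_cutoff(np.ones(40), time, np.ones(40, int))

    def test_minprop_excludes_edge_cutpoints(self, rng):
        x, time, event = self.changepoint_data(rng, n=40)
        res = maxstat_cutoff(x, time, event, minprop=0.25)
        n_low = (x <= res.cutoff).sum()
        assert 10 <= n_low <= 30

    def test_too_few_events_rejected(self, rng):
        x = rng.normal(size=30)
        time = rng.exponential(5, 30)
        event = np.zeros(30, int)
        event[:5] = 1
        with pytest.raises(ValueError, match="events"):
            maxstat_cutoff(x, time, event)


class TestCallMasa:
    @staticmethod
    def run(r2, p):
        fits = pd.DataFrame({"gene_id": ["g"], "r2": [r2]})
        scan = pd.DataFrame(
            {"gene_id": ["g"], "cutoff": [1.0], "logrank_p": [p], "logrank_q": [p]}
        )
        return call_masa(fits, scan).iloc[0]

    @pytest.mark.parametrize(
        "r2,p,expected",
        [
            (0.31, 0.04, True),   # both thresholds cleared
            (0.30, 0.01, False),  # R2 boundary is strict
            (0.50, 0.05, True),   # p boundary is inclusive
            (0.50, 0.051, False),
            (0.29, 0.04, False),
        ],
    )
    def test_boundary_semantics(self, r2, p, expected):
        row = self.run(r2, p)
        assert bool(row.masa) is expected
        assert row.masa == (row.methylation_affected and row.survival_associated)

    def test_genes_missing_from_either_input_are_excluded(self):
        fits = pd.DataFrame({"gene_id": ["g1", "g2"], "r2": [0.5, 0.6]})
        scan = pd.DataFrame(
            {"gene_id": ["g2", "g3"], "cutoff": [1, 1],
             "logrank_p": [0.01, 0.01], "logrank_q": [0.01, 0.01]}
        )
        out = call_masa(fits, scan)
        assert out["gene_id"].tolist() == ["g2"]


class TestAssociation:
    @staticmethod
    def masa_frame(a, b, c, d):
        return pd.DataFrame(
            {
                "methylation_affected": [True] * (a + b) + [False] * (c + d),
                "survival_associated": [True] * a + [False] * b + [True] * c + [False] * d,
            }
        )

    def test_or_four_and_woolf_ci_hand_arithmetic(self):
        out = association_test(self.masa_frame(20, 10, 10, 20))
        assert out["odds_ratio"] == pytest.approx(4.0)
        se = np.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        assert out["ci_low"] == pytest.approx(4.0 * np.exp(-1.96 * se))
        assert out["ci_high"] == pytest.approx(4.0 * np.exp(1.96 * se))
        # Pearson chi-square without continuity correction, by hand:
        # 60 * (20*20 - 10*10)^2 / (30*30*30*30)
        assert out["chi2"] == pytest.approx(60 * 300**2 / 810_000)

    def test_independence_table(self):
        out = association_test(self.masa_frame(30, 70, 30, 70))
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_for_or_only(self):
        out = association_test(self.masa_frame(20, 10, 0, 20))
        assert out["haldane_corrected"]
        assert out["odds_ratio"] == pytest.approx(
            (20.5 * 20.5) / (10.5 * 0.5)
        )

    def test_empty_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            association_test(self.masa_frame(10, 10, 0, 0))


class TestSurvivalScan:
    def test_scan_reports_failures_without_crashing(self, rng):
        n = 60
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(
            {s: [rng.normal(), 1.0] for s in samples}, index=["ok", "flat"]
        )
        clinical = pd.DataFrame(
            {"sample": samples, "time": rng.exponential(5, n) + 0.1,
             "event": np.ones(n, int)}
        )
        scan = survival_scan(expr, clinical)
        ok = scan.set_index("gene_id")
        assert np.isfinite(ok.loc["ok", "logrank_p"])
        assert np.isnan(ok.loc["flat", "logrank_p"])
        assert "constant" in ok.loc["flat", "note"]
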