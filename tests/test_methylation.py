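"""DMR pipeline: oracle equivalence, merging, CBS, clustering, finalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcomics import methylation as M
from pcomics.simulate import SimConfig, gen_methylation_cohort


def brute_force_dml(table, groups, p_thr=0.01, d_thr=0.1):
    """Independent per-CpG Welch-t loop with hand-coded test statistic."""
    pe = [s for s, g in groups.items() if g == "PE"]
    non = [s for s, g in groups.items() if g == "nonPE"]
    rows = []
    for _, r in table.iterrows():
        a = r[pe].astype(float).dropna().to_numpy()
        b = r[non].astype(float).dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        va, vb = a.var(ddof=1), b.var(ddof=1)
        d = a.mean() - b.mean()
        se2 = va / len(a) + vb / len(b)
        if se2 == 0:
            p = 1.0 if d == 0 else 0.0
        else:
            t = d / np.sqrt(se2)
            df = se2**2 / (
                (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
            )
            p = 2 * stats.t.sf(abs(t), df)
        if p < p_thr and abs(d) > d_thr:
            rows.append((r["chrom"], r["pos"], d, p))
    return pd.DataFrame(rows, columns=["chrom", "pos", "delta_beta", "p_value"])


class TestCallDml:
    def test_identical_groups_empty(self):
        rng = np.random.default_rng(0)
        v = rng.beta(5, 5, size=(50, 3))
        data = {"chrom": "chr1", "pos": np.arange(100, 150)}
        groups = {}
        for grp in ("PE", "nonPE"):
            for i in range(3):
                data[f"{grp}_{i}"] = v[:, i]  # identical beta vectors per index
                groups[f"{grp}_{i}"] = grp
        out = M.call_dml(pd.DataFrame(data), groups)
        assert len(out) == 0

    def test_threshold_rules(self):
        # one CpG failing the delta rule, one failing the p rule
        def row(pe_vals, non_vals, pos):
            d = {"chrom": "chr1", "pos": pos}
            d.update({f"PE_{i}": v for i, v in enumerate(pe_vals)})
            d.update({f"nonPE_{i}": v for i, v in enumerate(non_vals)})
            return d

        table = pd.DataFrame(
            [
                # delta 0.05, tiny variance -> significant p but fails |d|>0.1
                row([0.55, 0.551, 0.549, 0.55], [0.5, 0.501, 0.499, 0.5], 100),
                # delta 0.3 but huge spread -> p > 0.01
                row([0.9, 0.1, 0.8, 0.2], [0.5, 0.0, 0.4, 0.1], 200),
                # delta 0.3, tight -> passes both
                row([0.8, 0.81, 0.79, 0.8], [0.5, 0.51, 0.49, 0.5], 300),
            ]
        )
        groups = {f"PE_{i}": "PE" for i in range(4)} | {f"nonPE_{i}": "nonPE" for i in range(4)}
        out = M.call_dml(table, groups)
        assert list(out["pos"]) == [300]

    def test_matches_brute_force_oracle(self, small_beta_table):
        table, groups = small_beta_table
        ours = M.call_dml(table, groups)
        oracle = brute_force_dml(table, groups)
        cast = {"pos": np.int64, "delta_beta": float, "p_value": float}
        pd.testing.assert_frame_equal(
            ours.reset_index(drop=True).astype(cast),
            oracle.reset_index(drop=True).astype(cast),
            check_exact=False,
            rtol=1e-10,
        )


class TestMergeDml:
    def test_hand_merge(self):
        dmls = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 150, 500], "delta_beta": 0.2, "p_value": 1e-3}
        )
        out = M.merge_dml(dmls, gap_bp=100)
        assert out[["start", "end"]].values.tolist() == [[99, 150], [499, 500]]
        assert list(out["n_dml"]) == [2, 1]

    def test_empty_and_zero_gap(self):
        assert len(M.merge_dml(pd.DataFrame(columns=["chrom", "pos"]))) == 0
        dmls = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30]})
        out = M.merge_dml(dmls, gap_bp=0)
        assert len(out) == 3  # every DML its own candidate


class TestSeedDmr:
    def _table(self, deltas, noise=0.01, n=4, seed=0):
        rng = np.random.default_rng(seed)
        pos = 100 + 10 * np.arange(len(deltas))
        data = {"chrom": "chr1", "pos": pos}
        groups = {}
        for i in range(n):
            data[f"nonPE_{i}"] = 0.5 + rng.normal(0, noise, len(deltas))
            groups[f"nonPE_{i}"] = "nonPE"
        for i in range(n):
            data[f"PE_{i}"] = 0.5 + np.asarray(deltas) + rng.normal(0, noise, len(deltas))
            groups[f"PE_{i}"] = "PE"
        return pd.DataFrame(data), groups

    def test_consistent_effect_retained(self):
        table, groups = self._table([0.3] * 5)
        cand = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [141]})
        out = M.seed_dmr(cand, table, groups)
        assert len(out) == 1 and out.loc[0, "mean_delta_beta"] == pytest.approx(0.3, abs=0.05)

    def test_cancellation_rejected(self):
        table, groups = self._table([0.3, -0.3, 0.3, -0.3, 0.3, -0.3])
        cand = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [151]})
        assert len(M.seed_dmr(cand, table, groups)) == 0

    def test_singleton_candidate_equals_dml_p(self):
        table, groups = self._table([0.3])
        cand = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [100]})
        out = M.seed_dmr(cand, table, groups)
        dml = M.call_dml(table, groups)
        assert out.loc[0, "p_value"] == pytest.approx(dml.loc[0, "p_value"], rel=1e-12)


def _delta_table(deltas, seed=0, noise=0.0, chrom="chr1"):
    """Table whose per-CpG group mean difference equals deltas (+ noise)."""
    rng = np.random.default_rng(seed)
    deltas = np.asarray(deltas, dtype=float) + rng.normal(0, noise, len(deltas))
    pos = 100 + 10 * np.arange(len(deltas))
    data = {"chrom": chrom, "pos": pos}
    groups = {}
    for i in range(2):
        data[f"nonPE_{i}"] = np.full(len(deltas), 0.5) - deltas / 2
        groups[f"nonPE_{i}"] = "nonPE"
        data[f"PE_{i}"] = np.full(len(deltas), 0.5) + deltas / 2
        groups[f"PE_{i}"] = "PE"
    return pd.DataFrame(data), groups


class TestSegmentDelta:
    def test_constant_track_single_segment(self):
        table, groups = _delta_table(np.zeros(100))
        segs = M.segment_delta(table, groups, seed=1)
        assert len(segs) == 1 and segs[0].n_cpg == 100

    def test_step_track_changepoint_matches_exhaustive_oracle(self):
        deltas = np.concatenate([np.zeros(100), np.full(100, 0.4)])
        table, groups = _delta_table(deltas, seed=2, noise=0.05)
        segs = M.segment_delta(table, groups, nperm=500, seed=3)
        assert len(segs) >= 2
        # exhaustive single linear split maximizing |mean diff| * sqrt(k(n-k)/n)
        pe = [s for s, g in groups.items() if g == "PE"]
        non = [s for s, g in groups.items() if g == "nonPE"]
        d = (table[pe].mean(axis=1) - table[non].mean(axis=1)).to_numpy()
        n = len(d)
        best, best_k = -1, None
        for k in range(1, n):
            s = abs(d[:k].mean() - d[k:].mean()) * np.sqrt(k * (n - k) / n)
            if s > best:
                best, best_k = s, k
        assert abs(best_k - 100) <= 3
        # the called boundary (first segment's CpG count) matches within 3 CpGs
        boundaries = np.cumsum([s.n_cpg for s in segs])[:-1]
        assert any(abs(b - best_k) <= 3 for b in boundaries)

    def test_determinism(self):
        deltas = np.concatenate([np.zeros(50), np.full(50, 0.3)])
        table, groups = _delta_table(deltas, seed=4, noise=0.05)
        s1 = M.segment_delta(table, groups, nperm=200, seed=7)
        s2 = M.segment_delta(table, groups, nperm=200, seed=7)
        assert [(s.start, s.end, s.n_cpg) for s in s1] == [(s.start, s.end, s.n_cpg) for s in s2]

    def test_short_chromosome_single_segment(self):
        table, groups = _delta_table([0.0, 0.4, 0.4])
        segs = M.segment_delta(table, groups, seed=1)
        assert len(segs) == 1


class TestClusterSegments:
    @staticmethod
    def _segs(values):
        return [
            M.Segment(chrom="chr1", start=10 * i, end=10 * i + 5, mean_delta_beta=v, n_cpg=1)
            for i, v in enumerate(values)
        ]

    def test_three_pure_clusters(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(-0.3, 0.01, 10), rng.normal(0, 0.01, 10), rng.normal(0.3, 0.01, 10)]
        )
        out = M.cluster_segments(self._segs(values), k=3)
        labels = np.array([s.cluster_id for s in out])
        assert (labels[:10] == 0).all() and (labels[10:20] == 1).all() and (labels[20:] == 2).all()

    def test_k1_and_k_too_large(self):
        segs = self._segs([0.1, 0.2, 0.3])
        assert {s.cluster_id for s in M.cluster_segments(segs, k=1)} == {0}
        with pytest.raises(ValueError):
            M.cluster_segments(segs, k=4)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 0.2, 30)
        segs = self._segs(values)
        out1 = {(s.start): s.cluster_id for s in M.cluster_segments(segs, k=4)}
        perm = [segs[i] for i in rng.permutation(30)]
        out2 = {(s.start): s.cluster_id for s in M.cluster_segments(perm, k=4)}
        assert out1 == out2

    def test_dp_is_optimal_vs_exhaustive(self):
        """DP 1-D k-means cost equals brute-force over all sorted partitions."""
        from itertools import combinations

        rng = np.random.default_rng(2)
        x = np.sort(rng.normal(0, 1, 9))
        k = 3

        def cost(partition):
            return sum(((x[a:b] - x[a:b].mean()) ** 2).sum() for a, b in partition)

        best = min(
            cost(list(zip([0] + list(c), list(c) + [len(x)])))
            for c in combinations(range(1, len(x)), k - 1)
        )
        labels = M._kmeans_1d(x, k)
        got = sum(((x[labels == c] - x[labels == c].mean()) ** 2).sum() for c in range(k))
        assert got == pytest.approx(best, rel=1e-12)


class TestFinalizeDmr:
    def test_single_segment_spanning_seed(self):
        segs = [M.Segment("chr1", 0, 1000, 0.3, 50, cluster_id=0)]
        seeds = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        dmrs = M.finalize_dmr(segs, seeds)
        assert len(dmrs) == 1 and dmrs[0].direction == "hyper"

    def test_straddling_seed_yields_no_dmr(self):
        segs = [
            M.Segment("chr1", 0, 150, 0.3, 10, cluster_id=0),
            M.Segment("chr1", 150, 1000, 0.3, 10, cluster_id=0),
        ]
        seeds = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        assert M.finalize_dmr(segs, seeds) == []

    def test_hypo_direction_and_effect_guard(self):
        segs = [
            M.Segment("chr1", 0, 1000, -0.3, 50, cluster_id=0),
            M.Segment("chr2", 0, 1000, 0.02, 50, cluster_id=1),
        ]
        seeds = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [100, 100], "end": [200, 200]}
        )
        dmrs = M.finalize_dmr(segs, seeds)
        assert len(dmrs) == 1 and dmrs[0].direction == "hypo"


def test_conversion_qc_threshold():
    out = M.conversion_qc(pd.Series({"a": 0.995, "b": 0.99, "c": 0.5, "d": np.nan}))
    assert out.loc["a", "pass"] and not out.loc["b", "pass"]  # strict >
    assert not out.loc["c", "pass"]
    assert not out.loc["d", "pass"] and out.loc["d", "reason"] == "missing CHH fraction"


def test_recovery_monotone_in_effect_size():
    """Raising the planted |delta| never decreases recovery probability."""
    rates = []
    for delta in (0.15, 0.25, 0.35):
        hit = 0
        reps = 30
        for rep in range(reps):
            cfg = SimConfig(seed=5000 + rep)
            mc = cfg.methylation
            mc.n_cpg, mc.n_chroms, mc.n_samples_per_group = 300, 1, 5
            mc.n_planted, mc.width_cpg, mc.planted_delta = 1, 40, delta
            table, groups, truth = gen_methylation_cohort(cfg)
            res = M.call_dmrs(table, groups, k=3, nperm=200, seed=rep)
            called = pd.DataFrame(
                [{"chrom": d.chrom, "start": d.start, "end": d.end} for d in res["dmrs"]]
            )
            if M.interval_recall(truth, called) >= 0.5:
                hit += 1
        rates.append(hit / reps)
    # non-strict monotonicity with a one-hit Monte-Carlo slack
    assert rates[1] >= rates[0] - 1 / 30 and rates[2] >= rates[1] - 1 / 30
    assert rates[2] >= 0.9
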