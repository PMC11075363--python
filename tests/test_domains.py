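"""Domain merging, RPKM, the differential rule, and overlap enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pcomics import domains as D
from pcomics.intervals import merge_intervals, overlaps_any
from pcomics.simulate import SimConfig, gen_histone_coverage


def regions(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestMergeDomains:
    def test_gap_boundary_inclusive(self):
        merged = D.merge_domains(regions([("chr1", 100, 200), ("chr1", 5200, 5300)]))
        assert len(merged) == 1 and merged.loc[0, "end"] == 5300  # gap 5000 merges

    def test_gap_just_over(self):
        merged = D.merge_domains(regions([("chr1", 100, 200), ("chr1", 5201, 5300)]))
        assert len(merged) == 2

    def test_idempotent(self):
        peaks = regions([("chr1", 0, 10), ("chr1", 4000, 4100), ("chr2", 0, 5)])
        once = D.merge_domains(peaks)
        twice = D.merge_domains(once)
        pd.testing.assert_frame_equal(once, twice)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1000), st.integers(1, 50)), min_size=1, max_size=20))
    def test_order_invariant_and_coverage_never_shrinks(self, items):
        peaks = regions([("chr1", s, s + w) for s, w in items])
        shuffled = peaks.sample(frac=1, random_state=0)
        m1 = D.merge_domains(peaks, gap_bp=10)
        m2 = D.merge_domains(shuffled, gap_bp=10)
        pd.testing.assert_frame_equal(m1, m2)
        merged_bp = (m1["end"] - m1["start"]).sum()
        raw = merge_intervals(peaks, gap_bp=-1)  # union without gap joining
        assert merged_bp >= (raw["end"] - raw["start"]).sum()


class TestDomainRpkm:
    def _counts(self, values, lengths, libs):
        df = pd.DataFrame(values)
        df["length"] = lengths
        df.attrs["library_size"] = libs
        return df

    def test_unit_case(self):
        c = self._counts({"s1": [100]}, [1000], {"s1": 1_000_000})
        assert D.domain_rpkm(c).loc[0, "s1"] == pytest.approx(100.0)

    def test_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        n = 50
        counts = {f"s{i}": rng.integers(0, 5000, n) for i in range(4)}
        lengths = rng.integers(500, 50_000, n)
        libs = {f"s{i}": int(rng.integers(5e6, 5e7)) for i in range(4)}
        out = D.domain_rpkm(self._counts(counts, lengths, libs))
        for s in counts:
            for j in range(n):
                expect = counts[s][j] / (lengths[j] / 1e3) / (libs[s] / 1e6)
                assert out.loc[j, s] == pytest.approx(expect, rel=1e-12)


class TestDifferentialDomains:
    GROUPS = {"pe1": "PE", "pe2": "PE", "c1": "control", "c2": "control"}

    def test_printed_rule_s3(self):
        rpkm = pd.DataFrame({"pe1": [9.0], "pe2": [11.0], "c1": [3.0], "c2": [5.0]})
        # means 10 vs 4, sds sqrt(2) each -> s = 6 / (2 sqrt2) = 2.12 > 2
        out = D.differential_domains(rpkm, self.GROUPS)
        s = abs(10 - 4) / (np.std([9, 11], ddof=1) + np.std([3, 5], ddof=1))
        assert out.loc[0, "statistic"] == pytest.approx(s)
        assert out.loc[0, "label"] == "PE_gain"

    def test_equal_means_unchanged(self):
        rpkm = pd.DataFrame({"pe1": [5.0], "pe2": [7.0], "c1": [5.0], "c2": [7.0]})
        out = D.differential_domains(rpkm, self.GROUPS)
        assert out.loc[0, "statistic"] == pytest.approx(0.0)
        assert out.loc[0, "label"] == "unchanged"

    def test_zero_sd_flagged(self):
        rpkm = pd.DataFrame({"pe1": [5.0], "pe2": [5.0], "c1": [3.0], "c2": [3.0]})
        out = D.differential_domains(rpkm, self.GROUPS)
        assert np.isinf(out.loc[0, "statistic"]) and out.loc[0, "degenerate"]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        rpkm = pd.DataFrame(
            {s: rng.uniform(1, 50, 30) for s in self.GROUPS}
        )
        l1 = D.differential_domains(rpkm, self.GROUPS)["label"]
        l2 = D.differential_domains(rpkm * 7.3, self.GROUPS)["label"]
        assert (l1 == l2).all()

    def test_planted_shift_recall(self):
        """3x(sd sum) planted shifts at n=3v3 recovered with recall >= 0.9."""
        hits = total = 0
        for seed in range(200):
            cfg = SimConfig(seed=seed)
            cfg.histone.n_domains = 20
            _, counts, truth = gen_histone_coverage(cfg)
            labels = D.differential_domains(
                D.domain_rpkm(counts), counts.attrs["groups"]
            )["label"]
            changed = (truth != "unchanged").to_numpy()
            hits += (labels.to_numpy()[changed] != "unchanged").sum()
            total += changed.sum()
        assert hits / total >= 0.9


class TestFisherEnrichment:
    def test_perfect_association(self):
        universe = regions([("chr1", i * 100, i * 100 + 50) for i in range(20)])
        target = regions([("chr1", i * 100, i * 100 + 10) for i in range(10)])
        query = universe.iloc[:10]  # exactly the target-overlapping half
        res = D.fisher_region_enrichment(query, target, universe)
        assert np.isinf(res["odds_ratio"])
        assert res["p_value"] == pytest.approx(1 / 92378, rel=1e-6)  # 1/C(20,10) * 2... minimal

    def test_balanced_table(self):
        universe = regions([("chr1", i * 100, i * 100 + 50) for i in range(40)])
        target = regions([("chr1", i * 100, i * 100 + 10) for i in range(0, 40, 2)])
        # query: half of overlapping + half of non-overlapping
        query = universe.iloc[[0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 1, 3, 5, 7, 9, 11, 13, 15, 17, 19]]
        res = D.fisher_region_enrichment(query, target, universe)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(2)
        universe = regions([("chr1", i * 1000, i * 1000 + 500) for i in range(60)])
        target = regions(
            [("chr1", i * 1000, i * 1000 + 100) for i in sorted(rng.choice(60, 25, replace=False))]
        )
        query = universe.iloc[sorted(rng.choice(60, 20, replace=False))]
        res = D.fisher_region_enrichment(query, target, universe)

        # brute-force table + two-sided Fisher from the hypergeometric pmf
        q_keys = set(map(tuple, query.to_numpy()))
        a = b = c = d = 0
        for _, u in universe.iterrows():
            hit = any(
                u["start"] < t["end"] and t["start"] < u["end"]
                for _, t in target.iterrows()
            )
            inq = (u["chrom"], u["start"], u["end"]) in q_keys
            a += inq and hit
            b += inq and not hit
            c += (not inq) and hit
            d += (not inq) and not hit
        assert res["table"].tolist() == [[a, b], [c, d]]
        M, n, N = a + b + c + d, a + c, a + b
        pmf = stats.hypergeom.pmf(np.arange(0, n + 1), M, n, N)
        p_two = pmf[pmf <= pmf[a] * (1 + 1e-9)].sum()
        assert res["p_value"] == pytest.approx(min(1.0, p_two), rel=1e-8)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            D.fisher_region_enrichment(
                regions([]), regions([("chr1", 0, 1)]), regions([])
            )


class TestPermutationOverlap:
    SPACE = pd.DataFrame({"chrom": ["chr1", "chr2"], "length": [5_000_000, 3_000_000]})

    def test_query_equals_target_large_z(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 4_900_000, 40)
        q = regions([("chr1", s, s + 1000) for s in starts])
        res = D.permutation_overlap_z(q, q, self.SPACE, n_perm=500, seed=1)
        assert res["observed"] == 40
        assert res["z"] > 3

    def test_null_calibration(self):
        # query drawn by the same uniform-relocation scheme the permutation
        # uses, so z should be standard normal; 300 reps keep the Monte-Carlo
        # error of the mean (~0.06) well inside the 0.15 tolerance
        zs = []
        for rep in range(300):
            rng = np.random.default_rng(500 + rep)
            lens_q = rng.integers(500, 3000, 30)
            qs = (rng.random(30) * (5_000_000 - lens_q + 1)).astype(int)
            ts = rng.integers(0, 4_900_000, 60)
            q = regions([("chr1", s, s + l) for s, l in zip(qs, lens_q)])
            t = regions([("chr1", s, s + rng.integers(1000, 8000)) for s in ts])
            zs.append(D.permutation_overlap_z(q, t, self.SPACE, n_perm=300, seed=rep)["z"])
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.15
        assert 0.8 <= zs.std(ddof=1) <= 1.2

    def test_planted_enrichment(self):
        rng = np.random.default_rng(42)
        t_starts = rng.integers(0, 4_000_000, 30)
        target = regions([("chr1", s, s + 20_000) for s in t_starts])
        # query drawn preferentially inside target intervals
        q_rows = []
        for i in range(50):
            if rng.random() < 0.8:
                base = t_starts[rng.integers(0, 30)]
                s = base + rng.integers(0, 18_000)
            else:
                s = rng.integers(0, 4_990_000)
            q_rows.append(("chr1", s, s + 1000))
        res = D.permutation_overlap_z(regions(q_rows), target, self.SPACE, n_perm=500, seed=42)
        assert res["z"] > 3
        assert res["p_empirical"] < 0.01

    def test_zero_sd_reports_empirical_only(self):
        # target covers the whole space: every permutation overlaps everything
        q = regions([("chr1", 0, 1000)])
        t = regions([("chr1", 0, 5_000_000)])
        res = D.permutation_overlap_z(q, t, self.SPACE, n_perm=50, seed=0)
        assert np.isnan(res["z"]) and res["p_empirical"] <= 1.0


def test_overlaps_any_spanning_and_disjoint():
    q = regions([("chr1", 10, 20), ("chr1", 100, 200), ("chr2", 0, 5)])
    t = regions([("chr1", 0, 11), ("chr1", 150, 160)])
    assert overlaps_any(q, t).tolist() == [True, True, False]
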