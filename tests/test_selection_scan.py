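"""Windowed Fst / theta-pi scan: per-site estimators, windowing, outlier
selection and region merging, each against an independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    MISSING,
    PopulationMap,
    Window,
    make_windows,
    merge_regions,
    select_outliers,
    site_fst_components,
    site_pi,
    windowed_stats,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent oracles (scalar transcriptions, no shared code with sweepscan)
# ---------------------------------------------------------------------------

def wc84_oracle(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) two-population a, b, c, written straight from
    the published expressions with r = 2."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - 1 / (nbar - 1)
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def windowed_fst_oracle(dosage, cols1, cols2, lo, hi, positions):
    """Sum(a)/Sum(a+b+c) by per-site Python loops over a window."""
    sum_a = sum_abc = 0.0
    for i, pos in enumerate(positions):
        if not (lo <= pos <= hi):
            continue
        g1 = [d for d in dosage[i, cols1] if d != MISSING]
        g2 = [d for d in dosage[i, cols2] if d != MISSING]
        if not g1 or not g2:
            continue
        n1, n2 = len(g1), len(g2)
        p1, p2 = sum(g1) / (2 * n1), sum(g2) / (2 * n2)
        h1 = sum(1 for d in g1 if d == 1) / n1
        h2 = sum(1 for d in g2 if d == 1) / n2
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        if pbar in (0.0, 1.0) or (n1 + n2) / 2 <= 1:
            continue
        a, b, c = wc84_oracle(n1, p1, h1, n2, p2, h2)
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def pairwise_pi_oracle(alt_count, n_alleles):
    """Count differing allele pairs over all pairs, by enumeration."""
    alleles = [1] * alt_count + [0] * (n_alleles - alt_count)
    pairs = list(itertools.combinations(alleles, 2))
    return sum(1 for x, y in pairs if x != y) / len(pairs)


# ---------------------------------------------------------------------------
# make_windows
# ---------------------------------------------------------------------------

class TestMakeWindows:
    def test_150kb_chromosome(self):
        w = make_windows({"1": 150_000})
        assert len(w) == (150_000 - 1) // 10_000 + 1 == 15
        assert (w[0].start, w[0].end) == (1, 100_000)
        assert (w[5].start, w[5].end) == (50_001, 150_000)
        assert (w[-1].start, w[-1].end) == (140_001, 150_000)

    def test_exact_window_length(self):
        w = make_windows({"1": 100_000})
        assert (w[0].start, w[0].end) == (1, 100_000)

    def test_chromosome_shorter_than_window(self):
        w = make_windows({"1": 5_000})
        assert all(win.end == 5_000 for win in w)
        assert [win.start for win in w] == [1]

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"1": 0})

    def test_count_matches_enumeration_oracle(self):
        for length, step in [(123_456, 10_000), (99_999, 7_000), (10, 3)]:
            w = make_windows({"1": length}, size=max(step, 50_000), step=step)
            starts = [s for s in range(1, length + 1, step)]
            assert [win.start for win in w] == starts


# ---------------------------------------------------------------------------
# Per-site estimators
# ---------------------------------------------------------------------------

class TestSiteFst:
    def test_fixed_difference(self):
        c = site_fst_components(25, 1.0, 0.0, 25, 0.0, 0.0)
        assert (c.a, c.b, c.c) == (0.5, 0.0, 0.0)
        assert c.a / (c.a + c.b + c.c) == 1.0

    def test_identical_hwe_populations(self):
        c = site_fst_components(10, 0.5, 0.5, 10, 0.5, 0.5)
        assert c.a == pytest.approx(-0.013889, abs=1e-6)
        assert c.b == pytest.approx(0.013889, abs=1e-6)
        assert c.c == pytest.approx(0.25)
        assert c.a / (c.a + c.b + c.c) == pytest.approx(-0.0556, abs=1e-4)

    def test_monomorphic_site_contributes_nothing(self):
        c = site_fst_components(10, 0.0, 0.0, 10, 0.0, 0.0)
        assert (c.a, c.b, c.c) == (0.0, 0.0, 0.0)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n1, n2 = rng.integers(2, 40, size=2)
            p1, p2 = rng.random(2)
            h1 = rng.random() * 2 * min(p1, 1 - p1)
            h2 = rng.random() * 2 * min(p2, 1 - p2)
            c = site_fst_components(n1, p1, h1, n2, p2, h2)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            if pbar in (0.0, 1.0):
                continue
            a, b, cc = wc84_oracle(n1, p1, h1, n2, p2, h2)
            assert c.a == pytest.approx(a, abs=1e-12)
            assert c.b == pytest.approx(b, abs=1e-12)
            assert c.c == pytest.approx(cc, abs=1e-12)


class TestSitePi:
    def test_examples(self):
        assert site_pi(2, 4) == pytest.approx(2 / 3)
        assert site_pi(0, 10) == 0.0
        assert site_pi(1, 2) == 1.0

    def test_exhaustive_pairwise_oracle_n_up_to_12(self):
        for n in range(2, 13):
            for alt in range(n + 1):
                assert site_pi(alt, n) == pytest.approx(
                    pairwise_pi_oracle(alt, n), abs=1e-12)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def _two_pop(n=10):
    names = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    popmap = PopulationMap({s: s[0] for s in names})
    return names, popmap


class TestWindowedStats:
    def test_sparse_window_discarded(self):
        names, popmap = _two_pop()
        dosage = np.tile([2] * 10 + [0] * 10, (9, 1))  # 9 SNPs only
        m = make_matrix(dosage, samples=names)
        st = windowed_stats(m, popmap, "A", "B", [Window("1", 1, 1000)])
        assert st.empty

    def test_fixed_difference_window_fst_1(self):
        names, popmap = _two_pop()
        dosage = np.tile([2] * 10 + [0] * 10, (10, 1))
        m = make_matrix(dosage, samples=names)
        st = windowed_stats(m, popmap, "A", "B", [Window("1", 1, 1000)])
        assert st["fst"].iloc[0] == 1.0
        # target diversity zero => infinite ratio, window retained
        assert st["pi_target"].iloc[0] == 0.0
        assert math.isinf(st["theta_pi_ratio"].iloc[0])

    def test_identical_populations_fst_near_zero(self):
        rng = np.random.default_rng(9)
        names, popmap = _two_pop(25)
        half = rng.integers(0, 3, size=(10, 25))
        dosage = np.hstack([half, half])  # identical genotype columns
        m = make_matrix(dosage, samples=names)
        st = windowed_stats(m, popmap, "A", "B", [Window("1", 1, 1000)])
        assert st["fst"].iloc[0] <= 0.0  # estimator's negative bias

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(4)
        names, popmap = _two_pop(12)
        dosage = rng.choice([0, 1, 2, MISSING], size=(60, 24),
                            p=[0.4, 0.2, 0.3, 0.1])
        positions = np.sort(rng.choice(np.arange(1, 5000), 60, replace=False))
        m = make_matrix(dosage, samples=names, positions=positions)
        st = windowed_stats(m, popmap, "A", "B", [Window("1", 1, 5000)], min_snps=1)
        expect = windowed_fst_oracle(dosage, range(12), range(12, 24), 1, 5000,
                                     positions)
        assert st["fst"].iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_pi_invariant_to_monomorphic_sites_and_sample_order(self):
        rng = np.random.default_rng(6)
        names, popmap = _two_pop(8)
        dosage = rng.integers(0, 3, size=(20, 16))
        positions = np.arange(1, 21) * 10
        m = make_matrix(dosage, samples=names, positions=positions)
        base = windowed_stats(m, popmap, "A", "B", [Window("1", 1, 1000)], min_snps=1)
        # add monomorphic reference-only sites
        extra = np.vstack([dosage, np.zeros((5, 16), dtype=np.int8)])
        pos2 = np.concatenate([positions, np.arange(500, 505)])
        order = np.argsort(pos2)
        m2 = make_matrix(extra[order], samples=names, positions=pos2[order])
        with_mono = windowed_stats(m2, popmap, "A", "B", [Window("1", 1, 1000)],
                                   min_snps=1)
        assert with_mono["pi_target"].iloc[0] == base["pi_target"].iloc[0]
        # permute samples
        perm = rng.permutation(16)
        m3 = make_matrix(dosage[:, perm], samples=[names[i] for i in perm],
                         positions=positions)
        shuffled = windowed_stats(m3, popmap, "A", "B", [Window("1", 1, 1000)],
                                  min_snps=1)
        assert shuffled["pi_target"].iloc[0] == pytest.approx(
            base["pi_target"].iloc[0])

    def test_ratio_reciprocity(self, small_cohort):
        _, matrix, popmap, _ = small_cohort
        windows = make_windows({"1": 5_000_000})
        fwd = windowed_stats(matrix, popmap, "XP", "TT", windows)
        rev = windowed_stats(matrix, popmap, "TT", "XP", windows)
        both = fwd.merge(rev, on=["chrom", "start", "end"], suffixes=("_f", "_r"))
        finite = both[np.isfinite(both["theta_pi_ratio_f"])
                      & np.isfinite(both["theta_pi_ratio_r"])
                      & (both["theta_pi_ratio_f"] > 0)]
        assert len(finite) > 100
        np.testing.assert_allclose(
            finite["theta_pi_ratio_f"], 1.0 / finite["theta_pi_ratio_r"])

    def test_deterministic_tsv(self, small_cohort, tmp_path):
        _, matrix, popmap, _ = small_cohort
        windows = make_windows({"1": 5_000_000})
        paths = []
        for i in range(2):
            st = windowed_stats(matrix, popmap, "XP", "TT", windows)
            p = tmp_path / f"stats{i}.tsv"
            st.to_csv(p, sep="\t", index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


# ---------------------------------------------------------------------------
# Outlier selection + merging
# ---------------------------------------------------------------------------

def _stats_frame(fst, ratio):
    n = len(fst)
    return pd.DataFrame({
        "chrom": ["1"] * n,
        "start": np.arange(n) * 10_000 + 1,
        "end": np.arange(n) * 10_000 + 100_000,
        "n_snps": 50,
        "fst": fst,
        "pi_target": 0.001,
        "pi_control": 0.001,
        "theta_pi_ratio": ratio,
    })


class TestSelectOutliers:
    def test_single_top_window(self):
        vals = list(range(1, 21))
        out, thr = select_outliers(_stats_frame(vals, vals), q=0.95)
        assert len(out) == 1
        assert out["fst"].iloc[0] == 20
        assert thr == {"fst": 20.0, "theta_pi_ratio": 20.0}

    def test_reversed_orders_give_empty_intersection(self):
        out, _ = select_outliers(
            _stats_frame(list(range(1, 21)), list(range(20, 0, -1))), q=0.95)
        assert out.empty

    def test_boundary_ties_all_included(self):
        fst = list(range(1, 39)) + [100, 100]  # 40 values, top-2 tie at 100
        ratio = list(range(1, 41))
        out, thr = select_outliers(_stats_frame(fst, ratio), q=0.95)
        # k = ceil(0.05*40) = 2; both tied fst values enter the fst set
        assert thr["fst"] == 100.0
        assert (out["fst"] == 100).all()

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(12)
        fst = rng.random(200)
        ratio = rng.random(200)
        out, _ = select_outliers(_stats_frame(fst, ratio), q=0.95)
        k = math.ceil(0.05 * 200)
        top_f = set(np.argsort(fst)[::-1][:k])
        top_r = set(np.argsort(ratio)[::-1][:k])
        expect = sorted(top_f & top_r)
        assert sorted((out["start"] - 1) // 10_000) == expect

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="quantile"):
            select_outliers(_stats_frame(range(10), range(10)))


class TestMergeRegions:
    def _frame(self, spans):
        return _stats_frame([1.0] * len(spans), [2.0] * len(spans)).assign(
            start=[s for s, _ in spans], end=[e for _, e in spans])

    def test_overlap_merges(self):
        r = merge_regions(self._frame([(1, 100_000), (10_001, 110_000)]))
        assert [(x.start, x.end) for x in r] == [(1, 110_000)]
        assert r[0].n_windows == 2

    def test_disjoint_stay_separate(self):
        r = merge_regions(self._frame([(1, 100_000), (200_001, 300_000)]))
        assert len(r) == 2

    def test_bookended_merge(self):
        """end+1 == next start merges, matching bedtools-merge defaults."""
        r = merge_regions(self._frame([(1, 100_000), (100_001, 200_000)]))
        assert [(x.start, x.end) for x in r] == [(1, 200_000)]

    def test_max_statistics_carried(self):
        df = self._frame([(1, 100_000), (50_001, 150_000)])
        df.loc[1, "fst"] = 9.0
        r = merge_regions(df)
        assert r[0].max_fst == 9.0
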