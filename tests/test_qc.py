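import itertools

import numpy as np
import pandas as pd
import pytest

from geotrace import (
    FilterConfig,
    build_site_table,
    deduplicate,
    filter_individuals,
    filter_sites,
    king_kinship,
    ld_prune,
    partition_neutral,
    tajimas_d,
)
from geotrace.containers import MISSING

from conftest import make_matrix


# ---------------------------------------------------------------- site filters

def toy_ten_site_fixture():
    """10 sites, exactly 4 planted failures: 1 indel, 1 low depth,
    1 over-missing, 1 low MAC."""
    rng = np.random.default_rng(0)
    n = 20
    dosage = rng.integers(0, 3, size=(n, 10)).astype(np.int8)
    # guarantee MAC >= 3 everywhere, then plant failures
    dosage[:6, :] = 1
    dosage[:, 7] = 0
    dosage[:3, 7] = 1  # MAC = 3: must be retained under MAC >= 3
    dosage[:, 3] = 0
    dosage[0, 3] = 1  # MAC = 2 -> fails min_mac
    dosage[: int(0.4 * n), 5] = MISSING  # 40% missing -> fails max_site_missing
    gm = make_matrix(dosage)
    depth = np.full(10, 30.0)
    depth[2] = 6.0  # fails min_mean_depth (8x)
    indel = np.zeros(10, bool)
    indel[0] = True
    sites = build_site_table(gm, mean_depth=depth, is_indel=indel)
    return gm, sites


class TestFilterSites:
    def test_planted_failures_counted(self):
        gm, sites = toy_ten_site_fixture()
        out, kept_sites, report = filter_sites(gm, sites, FilterConfig())
        assert out.n_sites == 6
        counts = dict(zip(report["rule"], report["sites_removed"]))
        assert counts["indel"] == 1
        assert counts["min_mean_depth"] == 1
        assert counts["max_site_missing"] == 1
        assert counts["min_mac"] == 1
        assert counts["any_rule"] == 4

    def test_mac_exactly_three_retained(self):
        gm, sites = toy_ten_site_fixture()
        out, kept_sites, _ = filter_sites(gm, sites, FilterConfig())
        assert 8 * 10 in out.positions  # site index 7 (MAC exactly 3) retained

    def test_non_binding_thresholds_identity(self):
        gm, sites = toy_ten_site_fixture()
        cfg = FilterConfig(min_mean_depth=0, max_mean_depth=1e9, max_site_missing=1.0,
                           min_quality=0, min_mac=0, biallelic_only=False)
        cfg2 = FilterConfig(**{**cfg.__dict__})
        out, _, report = filter_sites(gm, sites, cfg2)
        # the indel rule is structural and still fires; relax it via the table
        assert out.n_sites == 9

    def test_order_insensitive_retained_set(self):
        # conjunction of rules: permuting rule order cannot change the kept set
        gm, sites = toy_ten_site_fixture()
        out, kept, _ = filter_sites(gm, sites, FilterConfig())
        passing = np.ones(10, bool)
        checks = [
            ~sites["is_indel"].to_numpy(),
            sites["mean_depth"].to_numpy() >= 8,
            sites["missing_fraction"].to_numpy() <= 0.30,
            sites["minor_allele_count"].to_numpy() >= 3,
        ]
        for order in itertools.permutations(range(4)):
            acc = np.ones(10, bool)
            for k in order:
                acc &= checks[k]
            passing &= acc
        assert np.array_equal(np.nonzero(passing)[0], np.searchsorted(gm.positions, out.positions))


class TestFilterIndividuals:
    def test_threshold_is_strict(self):
        dosage = np.zeros((2, 4), dtype=np.int8)
        dosage[0, :3] = MISSING  # exactly 75% missing: retained
        dosage[1, :] = MISSING  # 100%: removed
        out = filter_individuals(make_matrix(dosage), 0.75)
        assert out.sample_ids == ["S0"]

    def test_no_missing_identity(self):
        gm = make_matrix(np.ones((3, 5), dtype=np.int8))
        assert filter_individuals(gm).n_samples == 3


# ---------------------------------------------------------------- Tajima's D

def tajimas_d_oracle(window):
    """Brute-force Tajima's D: explicit enumeration of pairwise differences
    between chromosomes, per site (complete data only)."""
    g = np.asarray(window)
    n, L = g.shape
    m = 2 * n
    pi = 0.0
    S = 0
    for j in range(L):
        alleles = []
        for i in range(n):
            alleles += [1] * int(g[i, j]) + [0] * (2 - int(g[i, j]))
        diffs = sum(a != b for a, b in itertools.combinations(alleles, 2))
        if 0 < sum(alleles) < m:
            S += 1
        pi += diffs / (m * (m - 1) / 2)
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3 * (m - 1))
    b2 = 2 * (m * m + m + 3) / (9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(50):
            n = rng.integers(3, 20)
            L = rng.integers(1, 10)
            g = rng.binomial(2, rng.uniform(0.05, 0.95, L), size=(n, L))
            expected = tajimas_d_oracle(g)
            got = tajimas_d(g.astype(np.int8))
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)
                checked += 1
        assert checked >= 30

    def test_monomorphic_undefined(self):
        assert np.isnan(tajimas_d(np.full((5, 4), 2, dtype=np.int8)))

    def test_all_singletons_negative(self):
        g = np.zeros((10, 6), dtype=np.int8)
        for j in range(6):
            g[j, j] = 1  # each site a singleton in a different sample
        assert tajimas_d(g) < 0


class TestPartitionNeutral:
    def test_boundary_and_exhaustive(self):
        # three contigs engineered: one balanced (D>0 small), one monomorphic
        rng = np.random.default_rng(1)
        d1 = rng.binomial(2, 0.5, size=(12, 10)).astype(np.int8)
        d2 = np.full((12, 10), 1, dtype=np.int8)
        d2[0] = 0  # low-variation contig
        dosage = np.hstack([d1, d2])
        from geotrace import GenotypeMatrix
        gm = GenotypeMatrix(
            dosage, [f"S{i}" for i in range(12)],
            np.array(["c1"] * 10 + ["c2"] * 10), np.tile(np.arange(1, 11) * 5, 2),
        )
        sites = build_site_table(gm)
        neutral, nonneutral, table = partition_neutral(gm, sites, (-2, 2))
        assert len(neutral) + len(nonneutral) == 20
        assert len(np.intersect1d(neutral, nonneutral)) == 0
        # bounds are exclusive: |D| exactly 2 stays neutral
        d = table["tajima_d"].to_numpy()
        for i in np.nonzero((d <= 2) & (d >= -2))[0]:
            assert i in neutral

    def test_undefined_d_is_neutral(self):
        gm = make_matrix(np.full((5, 3), 2, dtype=np.int8))
        sites = build_site_table(gm)
        neutral, nonneutral, _ = partition_neutral(gm, sites)
        assert len(neutral) == 3 and len(nonneutral) == 0


# ---------------------------------------------------------------- LD pruning

def ld_prune_oracle(matrix, r2_max=0.2):
    """Windowless greedy rule: scan all ordered pairs, remove the higher-
    missingness member (tie: later site)."""
    from geotrace.qc import _pairwise_r2

    n = matrix.n_sites
    removed = np.zeros(n, bool)
    miss = matrix.site_missingness()
    for i in range(n):
        if removed[i]:
            continue
        for j in range(i + 1, n):
            if removed[i]:
                break
            if removed[j]:
                continue
            if _pairwise_r2(matrix.dosage[:, i], matrix.dosage[:, j]) > r2_max:
                if miss[i] > miss[j]:
                    removed[i] = True
                else:
                    removed[j] = True
    return np.nonzero(~removed)[0]


class TestLdPrune:
    def test_duplicate_columns_keep_earlier(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, size=(30, 1)).astype(np.int8)
        others = rng.integers(0, 3, size=(30, 3)).astype(np.int8)
        gm = make_matrix(np.hstack([base, others[:, :1], base, others[:, 1:]]))
        kept = ld_prune(gm, window=10, step=5)
        assert 0 in kept and 2 not in kept

    def test_orthogonal_sites_all_kept(self):
        # block-diagonal construction: site j varies only in block j
        dosage = np.zeros((40, 4), dtype=np.int8)
        for j in range(4):
            dosage[10 * j : 10 * j + 5, j] = 2
        gm = make_matrix(dosage)
        assert len(ld_prune(gm, window=4, step=2)) == 4

    def test_oracle_equivalence_window_spanning(self):
        # window >= n_sites: the windowed scan must equal the windowless rule
        for seed in range(20):
            rng = np.random.default_rng(seed)
            L = rng.integers(20, 101)
            dosage = rng.binomial(2, rng.uniform(0.1, 0.9, L), size=(50, L)).astype(np.int8)
            dosage[rng.random(dosage.shape) < 0.05] = MISSING
            gm = make_matrix(dosage)
            kept = ld_prune(gm, window=int(L), step=10)
            oracle = ld_prune_oracle(gm)
            assert np.array_equal(kept, oracle), f"seed {seed}"

    def test_windowed_invariants(self):
        from geotrace.qc import _pairwise_r2

        rng = np.random.default_rng(17)
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 80), size=(40, 80)).astype(np.int8)
        gm = make_matrix(dosage)
        window, step = 20, 5
        kept = ld_prune(gm, window=window, step=step, r2_max=0.2)
        assert set(kept) <= set(range(80))
        kept_set = list(kept)
        starts = range(0, 80, step)
        for a in range(len(kept_set)):
            for b in range(a + 1, len(kept_set)):
                i, j = kept_set[a], kept_set[b]
                shares_window = any(s <= i and j < s + window for s in starts)
                if shares_window:
                    assert _pairwise_r2(gm.dosage[:, i], gm.dosage[:, j]) <= 0.2

    def test_window_smaller_than_step_rejected(self):
        gm = make_matrix(np.zeros((5, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            ld_prune(gm, window=5, step=10)


# ---------------------------------------------------------------- kinship

class TestKingKinship:
    def test_duplicate_is_half(self):
        g = np.array([0, 1, 2, 1, 0, 1], dtype=np.int8)
        assert king_kinship(g, g) == pytest.approx(0.5)

    def test_worked_four_site_example(self):
        gi = np.array([0, 1, 2, 1], dtype=np.int8)
        gj = np.array([0, 1, 0, 2], dtype=np.int8)
        assert king_kinship(gi, gj) == pytest.approx(-1.0 / 3.0)

    def test_no_heterozygotes_undefined(self):
        assert np.isnan(king_kinship(np.array([0, 0]), np.array([2, 2])))

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            gi = rng.integers(0, 3, 50).astype(np.int8)
            gj = rng.integers(0, 3, 50).astype(np.int8)
            a, b = king_kinship(gi, gj), king_kinship(gj, gi)
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b)


class TestDeduplicate:
    def _dup_pair_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=300).astype(np.int8)
        others = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(3, 300)).astype(np.int8)
        a = base.copy()
        b = base.copy()
        a[rng.random(300) < 0.1] = MISSING
        b[rng.random(300) < 0.1] = MISSING
        return make_matrix(np.vstack([a, others, b]))

    def test_duplicate_pair_flagged_and_removed(self):
        gm = self._dup_pair_matrix()
        assert king_kinship(gm.dosage[0], gm.dosage[4]) > 0.354
        out, removed = deduplicate(gm)
        assert out.n_samples == 4
        assert len(removed) == 1
        assert {removed[0][0], removed[0][1]} == {"S0", "S4"}

    def test_unrelated_population_untouched(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.2, 0.8, 500)
        dosage = rng.binomial(2, p, size=(6, 500)).astype(np.int8)
        gm = make_matrix(dosage)
        out, removed = deduplicate(gm)
        assert out.n_samples == 6 and not removed
        from geotrace.qc import kinship_table
        assert kinship_table(gm)["phi"].abs().max() < 0.1

    def test_single_sample_identity(self):
        gm = make_matrix(np.array([[0, 1, 2]], dtype=np.int8))
        out, removed = deduplicate(gm)
        assert out.n_samples == 1 and not removed

    def test_idempotent(self):
        gm = self._dup_pair_matrix(seed=9)
        once, _ = deduplicate(gm)
        twice, removed = deduplicate(once)
        assert not removed
        assert twice.sample_ids == once.sample_ids
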