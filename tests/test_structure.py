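import numpy as np
import pandas as pd
import pytest

from helpers import brute_amova_components, random_table
from mitopop.distances import DistanceMatrix, haplotype_distance_matrix
from mitopop.diversity import mean_pairwise_differences
from mitopop.errors import MitopopError
from mitopop.haplotypes import HaplotypeTable, collapse_haplotypes
from mitopop.simulate import SimConfig, simulate_dataset
from mitopop.structure import amova, bonferroni_flags, pairwise_phist


def _table(counts, labels=None):
    P, m = np.asarray(counts).shape
    return HaplotypeTable(counts=pd.DataFrame(
        counts, index=labels or [f"P{i}" for i in range(P)],
        columns=[f"H{j+1}" for j in range(m)]))


def _unit_distance(m):
    d = np.ones((m, m)) - np.eye(m)
    return DistanceMatrix(labels=[f"H{j+1}" for j in range(m)], values=d)


class TestAmova:
    def test_fixed_difference_populations(self):
        tab = _table([[10, 0], [0, 10]])
        res = amova(tab, _unit_distance(2), n_perm=200, seed=1)
        assert res.pct_within == pytest.approx(0.0, abs=1e-9)
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 201, abs=0.02)

    def test_single_shared_haplotype(self):
        tab = _table([[6, 0], [4, 1]])
        # make the variation zero by using a single haplotype instead
        tab0 = _table([[6], [4]])
        d0 = DistanceMatrix(labels=["H1"], values=np.zeros((1, 1)))
        res = amova(tab0, d0, n_perm=0)
        assert res.ssd_total == 0.0 and res.phi_st == 0.0

    def test_components_match_expanded_enumeration(self, rng):
        for _ in range(10):
            tab, dm = random_table(rng, max_pops=3, max_haps=4, max_count=5)
            if tab.total_n < 3:
                continue
            res = amova(tab, dm, n_perm=0)
            brute = brute_amova_components(tab, dm.values)
            assert res.ssd_total == pytest.approx(brute["ssd_total"], abs=1e-9)
            assert res.ssd_within == pytest.approx(brute["ssd_within"], abs=1e-9)
            assert res.var_a == pytest.approx(brute["var_a"], abs=1e-9)
            assert res.var_b == pytest.approx(brute["var_b"], abs=1e-9)
            assert res.phi_st == pytest.approx(brute["phi"], abs=1e-9)

    def test_ssd_additivity_and_percentages(self, rng):
        tab, dm = random_table(rng)
        res = amova(tab, dm, n_perm=0)
        assert res.ssd_among + res.ssd_within == pytest.approx(
            res.ssd_total, abs=1e-9)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-6)

    def test_single_population_rejected(self):
        with pytest.raises(MitopopError):
            amova(_table([[3, 3]]), _unit_distance(2), n_perm=0)


class TestPairwisePhist:
    def test_two_population_amova_equals_pairwise_entry(self, rng):
        tab, dm = random_table(rng, max_pops=3)
        fst = pairwise_phist(tab, dm, n_perm=0)
        pops = tab.populations
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                pair = tab.counts.iloc[[i, j]]
                present = pair.sum(axis=0) > 0
                sub = HaplotypeTable(counts=pair.loc[:, present])
                idx = np.flatnonzero(present.values)
                sub_d = DistanceMatrix(
                    labels=[dm.labels[k] for k in idx],
                    values=dm.values[np.ix_(idx, idx)])
                res = amova(sub, sub_d, n_perm=0)
                assert fst.phi_st[i, j] == pytest.approx(res.phi_st, abs=1e-12)

    def test_identical_composition_pair_near_zero(self):
        tab = _table([[12, 6, 2], [12, 6, 2]])
        dm = _unit_distance(3)
        fst = pairwise_phist(tab, dm, n_perm=200, seed=5)
        assert fst.phi_st[0, 1] <= 0.0 + 1e-9
        assert fst.p_values[0, 1] > 0.05

    def test_fixed_difference_pair(self):
        tab = _table([[10, 0], [0, 10]])
        fst = pairwise_phist(tab, _unit_distance(2), n_perm=400, seed=7)
        assert fst.phi_st[0, 1] == pytest.approx(1.0)
        assert fst.p_values[0, 1] == pytest.approx(1 / 401, abs=1e-9)

    def test_null_pvalues_roughly_uniform(self, rng):
        # exchangeable null: both populations drawn from one pool
        hits = total = 0
        for _ in range(200):
            pool = rng.integers(0, 4, size=24)
            counts = np.zeros((2, 4), int)
            for idx, h in enumerate(pool):
                counts[idx % 2, h] += 1
            keep = counts.sum(axis=0) > 0
            tab = _table(counts[:, keep])
            m = int(keep.sum())
            if m < 2:
                continue
            dm = DistanceMatrix(
                labels=tab.haplotype_ids,
                values=np.ones((m, m)) - np.eye(m))
            res = amova(tab, dm, n_perm=99, seed=int(rng.integers(2**31)))
            total += 1
            if res.p_value < 0.05:
                hits += 1
        assert 0.01 <= hits / total <= 0.10

    def test_high_migration_island_phist_near_zero(self, rng):
        phis = []
        for rep in range(50):
            aln, _ = simulate_dataset(
                SimConfig(scenario="island", n_per_pop=(12, 12),
                          theta=2.0, M=100.0),
                seed=1000 + rep,
            )
            tab = collapse_haplotypes(aln)
            d = haplotype_distance_matrix(tab, "diff_count")
            res = amova(tab, d, n_perm=0)
            phis.append(res.phi_st)
        assert abs(np.mean(phis)) < 0.05


class TestBonferroni:
    def test_adjusted_threshold_55_tests(self):
        # 11 populations -> 55 comparisons; 0.05/55 = 9.09e-4
        labels = [f"P{i}" for i in range(11)]
        p = pd.DataFrame(1.0, index=labels, columns=labels)
        p.iloc[0, 1] = p.iloc[1, 0] = 0.0008
        flags = bonferroni_flags(p)
        assert flags.iloc[0, 1] == "*"
        assert flags.iloc[2, 3] == ""

    def test_two_tier_marking(self):
        labels = ["a", "b", "c"]  # m = 3: * below 0.0167, ** below 0.00333
        p = pd.DataFrame(1.0, index=labels, columns=labels)
        p.iloc[0, 1] = p.iloc[1, 0] = 0.001
        p.iloc[0, 2] = p.iloc[2, 0] = 0.01
        flags = bonferroni_flags(p)
        assert flags.iloc[0, 1] == "**"
        assert flags.iloc[0, 2] == "*"

    def test_single_test_reduces_to_raw_threshold(self):
        labels = ["a", "b"]
        p = pd.DataFrame(1.0, index=labels, columns=labels)
        p.iloc[0, 1] = p.iloc[1, 0] = 0.049
        assert bonferroni_flags(p).iloc[0, 1] == "*"
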