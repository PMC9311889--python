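import math

import numpy as np
import pandas as pd
import pytest

from mitopop.distances import (
    DistanceMatrix,
    haplotype_distance_matrix,
    k2p_distance,
    p_distance,
    pairwise_difference_count,
    population_distance_matrix,
)
from mitopop.errors import AlignmentError, SaturationError
from mitopop.haplotypes import HaplotypeTable, collapse_haplotypes
from mitopop.simulate import SimConfig, simulate_dataset


class TestDifferenceCount:
    def test_identical(self):
        assert pairwise_difference_count("ACGT", "ACGT") == 0

    def test_single_difference(self):
        assert pairwise_difference_count("ACGT", "ACGA") == 1

    def test_random_pair_matches_column_scan(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(rng.choice(list("ACGT"), size=300))
        want = sum(x != y for x, y in zip(a, b))
        assert pairwise_difference_count(a, b) == want

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            pairwise_difference_count("ACG", "ACGT")


class TestK2P:
    def test_identical_is_zero(self):
        assert k2p_distance("ACGT" * 5, "ACGT" * 5) == 0.0

    def test_closed_form_mixed(self):
        # L=20: 2 transitions + 1 transversion -> P=0.1, Q=0.05
        a = "A" * 20
        b = "G" * 2 + "C" + "A" * 17
        d = k2p_distance(a, b)
        want = -0.5 * math.log(1 - 0.2 - 0.05) - 0.25 * math.log(1 - 0.1)
        assert d == pytest.approx(want)
        assert round(d, 4) == 0.1702

    def test_closed_form_transitions_only(self):
        a = "A" * 20
        b = "G" * 2 + "A" * 18
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))
        assert round(k2p_distance(a, b), 4) == 0.1116

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("AC", "GT")  # P=0.5, Q=0.5 -> log(<=0)

    def test_k2p_dominates_p_distance(self, rng):
        for _ in range(30):
            L = 60
            a = list("ACGT" * (L // 4))
            b = list(a)
            for pos in rng.choice(L, size=int(rng.integers(1, 8)), replace=False):
                b[pos] = rng.choice([c for c in "ACGT" if c != b[pos]])
            a, b = "".join(a), "".join(b)
            assert k2p_distance(a, b) >= p_distance(a, b) - 1e-12


class TestPopulationDistances:
    def _two_pop_table(self, seq_a, seq_b, na=5, nb=5):
        counts = pd.DataFrame(
            [[na, 0], [0, nb]], index=["X", "Y"], columns=["H1", "H2"]
        )
        return HaplotypeTable(counts=counts,
                              sequences={"H1": seq_a, "H2": seq_b})

    def test_identical_fixation_gives_zero(self):
        counts = pd.DataFrame([[5], [4]], index=["X", "Y"], columns=["H1"])
        tab = HaplotypeTable(counts=counts, sequences={"H1": "ACGT" * 10})
        for kind in ("dxy", "da"):
            dm = population_distance_matrix(tab, model="p", kind=kind)
            assert dm.loc("X", "Y") == 0.0

    def test_fixed_single_step_p_distance(self):
        L = 647
        s1 = "A" * L
        s2 = "G" + "A" * (L - 1)
        tab = self._two_pop_table(s1, s2)
        dm = population_distance_matrix(tab, model="p", kind="dxy")
        assert dm.loc("X", "Y") == pytest.approx(1 / 647)

    def test_da_of_population_with_itself_is_zero(self):
        # diagonal of the da matrix is structurally zero
        tab = self._two_pop_table("AAAA", "AAAT")
        dm = population_distance_matrix(tab, model="p", kind="da")
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_dxy_matches_expanded_pair_mean(self, rng):
        aln, _ = simulate_dataset(
            SimConfig(scenario="island", n_per_pop=(8, 10), theta=2.0, M=2.0),
            seed=21,
        )
        tab = collapse_haplotypes(aln)
        dm = population_distance_matrix(tab, model="p", kind="dxy")
        pops = tab.populations
        seq_of = {sid: aln.seqs[i] for i, sid in enumerate(aln.ids)}
        xs = [s for s in aln.ids if aln.population_of[s] == pops[0]]
        ys = [s for s in aln.ids if aln.population_of[s] == pops[1]]
        brute = np.mean([
            p_distance(seq_of[x], seq_of[y]) for x in xs for y in ys
        ])
        assert dm.loc(pops[0], pops[1]) == pytest.approx(brute, abs=1e-12)

    def test_symmetry_and_relabel_invariance(self, rng):
        aln, _ = simulate_dataset(
            SimConfig(scenario="island", n_per_pop=(6, 6, 6), theta=2.0, M=3.0),
            seed=4,
        )
        tab = collapse_haplotypes(aln)
        dm = population_distance_matrix(tab, model="p")
        assert np.allclose(dm.values, dm.values.T)
        # shuffle haplotype columns: population distances must not move
        order = list(rng.permutation(tab.haplotype_ids))
        tab2 = HaplotypeTable(
            counts=tab.counts[order],
            sequences={h: tab.sequences[h] for h in order},
        )
        dm2 = population_distance_matrix(tab2, model="p")
        assert np.allclose(dm.values, dm2.values)


class TestDistanceMatrixContainer:
    def test_symmetry_enforced(self):
        with pytest.raises(Exception):
            DistanceMatrix(labels=["a", "b"],
                           values=np.array([[0, 1], [2, 0]], float))

    def test_phylip_export_shape(self):
        dm = DistanceMatrix(labels=["a", "b"],
                            values=np.array([[0.0, 1.5], [1.5, 0.0]]))
        text = dm.to_phylip()
        assert text.splitlines()[0].strip() == "2"
        assert "1.500000" in text
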