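"""LD machinery: decomposition round trips, geometric decay, allele probabilities.

The independent oracle here is a direct deterministic iteration of the
infinite-population recombination dynamics on the full haplotype
frequency table: each generation, a gamete copies parent 1 or 2 between
crossovers, with crossover pattern probabilities from the adjacent
recombination fractions.  No Bennett algebra is involved.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldlmap.genmap import haldane_recomb
from ldlmap.ldmodel import (
    LDParams,
    bennett_from_freqs,
    expected_freq_at_t,
    freq_from_bennett,
    general_partition_coefficient,
    qtl_prob_given_hap,
    rho_no_recomb,
    time0_freqs,
    window_qtl_probs,
)


def random_freq_table(n, rng):
    t = rng.dirichlet(np.ones(2 ** n)).reshape((2,) * n)
    return t


def recombine_once(table, positions):
    """One generation of random mating with free recombination pattern mixing."""
    n = table.ndim
    c = haldane_recomb(np.diff(np.asarray(positions, float)))
    new = np.zeros_like(table)
    haps = list(itertools.product((0, 1), repeat=n))
    for origins in itertools.product((0, 1), repeat=n):
        p = 0.5
        for k in range(n - 1):
            p *= c[k] if origins[k] != origins[k + 1] else 1.0 - c[k]
        for h1 in haps:
            f1 = table[h1]
            if f1 == 0.0:
                continue
            for h2 in haps:
                f2 = table[h2]
                if f2 == 0.0:
                    continue
                g = tuple(h1[k] if origins[k] == 0 else h2[k] for k in range(n))
                new[g] += p * f1 * f2
    return new


class TestRho:
    def test_singleton_is_one(self):
        assert rho_no_recomb([3.2]) == 1.0

    def test_two_loci_single_factor(self):
        d = 11.57
        assert rho_no_recomb([0.0, d]) == pytest.approx(1 - haldane_recomb(d), abs=1e-14)

    def test_three_equally_spaced_vs_enumeration(self):
        """(1-c)^2 equals the no-recombination probability summed over the
        4 crossover configurations of the two intervals."""
        d = 10.0
        c = haldane_recomb(d)
        total = 0.0
        for s1, s2 in itertools.product((0, 1), repeat=2):
            p = (c if s1 else 1 - c) * (c if s2 else 1 - c)
            if s1 == 0 and s2 == 0:
                total += p
        assert rho_no_recomb([0.0, d, 2 * d]) == pytest.approx(total, abs=1e-14)
        assert total == pytest.approx((1 - c) ** 2, abs=1e-14)


class TestBennettRoundTrip:
    def test_two_locus_worked_example(self):
        # Pi_11 = 0.5, both allele frequencies 0.5 -> D = 0.25
        table = np.array([[0.5, 0.0], [0.0, 0.5]])
        d = bennett_from_freqs(table, (1, 1))
        assert d[frozenset([0, 1])] == pytest.approx(0.25, abs=1e-15)

    def test_independent_loci_have_zero_d(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, size=3)
        table = np.einsum("i,j,k->ijk",
                          *[np.array([1 - pi, pi]) for pi in p])
        d = bennett_from_freqs(table, (1, 0, 1))
        for s, val in d.items():
            if len(s) >= 2:
                assert val == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_round_trip_random_tables(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(20):
            table = random_freq_table(n, rng)
            alleles = tuple(rng.integers(0, 2, n))
            d = bennett_from_freqs(table, alleles)
            idx = [slice(None)] * n
            for k, a in enumerate(alleles):
                idx[k] = a
            target = float(table[tuple(idx)])
            assert freq_from_bennett(d, range(n)) == pytest.approx(target, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        table = random_freq_table(n, rng)
        alleles = tuple(rng.integers(0, 2, n))
        d = bennett_from_freqs(table, alleles)
        idx = tuple(alleles)
        assert freq_from_bennett(d, range(n)) == pytest.approx(float(table[idx]), abs=1e-12)

    def test_three_locus_partition_count(self):
        """n = 3 has exactly 5 partitions in the decomposition family."""
        from ldlmap.ldmodel import _one_block_partitions
        parts = list(_one_block_partitions(3))
        assert len(parts) == 5  # 3 pairs + full triple + all-singletons

    def test_inconsistent_table_rejected(self):
        with pytest.raises(ValueError):
            bennett_from_freqs(np.full((2, 2), 0.5), (0, 0))

    def test_general_coefficients_unimplemented(self):
        with pytest.raises(NotImplementedError):
            general_partition_coefficient([(0, 3), (1, 2)], [0.0, 1.0, 2.0, 3.0])


class TestGeometricDecay:
    @pytest.mark.parametrize("t", [0, 1, 5])
    def test_three_locus_any_table_matches_recursion_oracle(self, t):
        """Closed-form t-generation frequencies equal direct iteration of the
        recombination dynamics, for arbitrary initial 3-locus LD."""
        rng = np.random.default_rng(7)
        positions = [0.0, 4.0, 10.0]
        table = random_freq_table(3, rng)
        evolved = table.copy()
        for _ in range(t):
            evolved = recombine_once(evolved, positions)
        for alleles in itertools.product((0, 1), repeat=3):
            d0 = bennett_from_freqs(table, alleles)
            pred = expected_freq_at_t(d0, positions, t, clip=False)
            assert pred == pytest.approx(float(evolved[alleles]), abs=1e-12)

    def test_two_locus_window_iteration(self):
        """D(t+1) = (1-c) D(t) plus constant allele frequencies, c at 10 cM."""
        positions = [0.0, 10.0]
        c = haldane_recomb(10.0)
        table = np.array([[0.4, 0.1], [0.05, 0.45]])
        d0 = bennett_from_freqs(table, (1, 1))
        d_t = d0[frozenset([0, 1])]
        pa = d0[frozenset([0])]
        pb = d0[frozenset([1])]
        for t in range(6):
            pred = expected_freq_at_t(d0, positions, t, clip=False)
            assert pred == pytest.approx(pa * pb + d_t, abs=1e-12)
            d_t *= 1 - c
    def test_five_locus_marker_equilibrium_matches_oracle(self):
        """With marker-only LD absent at time 0 the restricted decomposition is
        exact even for 5 loci (QTL + 4 markers)."""
        params = LDParams(hstar=(1, 0, 1, 1), pi_q0=0.04, t=0,
                          marker_freqs=(0.3, 0.6, 0.5, 0.7))
        table0 = time0_freqs(params)  # axes: 4 markers then QTL
        positions = [0.0, 1.0, 1.7, 2.4, 3.3]
        # move the QTL axis to its map slot (index 2)
        table0 = np.moveaxis(table0, -1, 2)
        t = 4
        evolved = table0.copy()
        for _ in range(t):
            evolved = recombine_once(evolved, positions)
        for alleles in itertools.product((0, 1), repeat=5):
            d0 = bennett_from_freqs(table0, alleles)
            pred = expected_freq_at_t(d0, positions, t, clip=False)
            assert pred == pytest.approx(float(evolved[alleles]), abs=1e-12)

    def test_complete_linkage_is_constant(self):
        params = LDParams(hstar=(1, 1), pi_q0=0.1, t=0, marker_freqs=(0.5, 0.5))
        table0 = np.moveaxis(time0_freqs(params), -1, 1)
        d0 = bennett_from_freqs(table0, (1, 1, 1))
        positions = [2.0, 2.0 + 1e-12, 2.0 + 2e-12]  # c ~ 0
        for t in (0, 3, 50):
            assert expected_freq_at_t(d0, positions, t) == pytest.approx(0.1, abs=1e-9)


class TestTime0Model:
    def test_beta_one_delta(self):
        params = LDParams(hstar=(1, 0), pi_q0=0.05, t=0, marker_freqs=(0.5, 0.5))
        tab = time0_freqs(params)
        assert tab[(1, 0, 1)] == pytest.approx(0.05)
        for h in [(0, 0), (0, 1), (1, 1)]:
            assert tab[h + (1,)] == 0.0

    def test_beta_zero_independence(self):
        params = LDParams(hstar=(1, 0), pi_q0=0.3, t=0,
                          marker_freqs=(0.4, 0.6), beta=0.0)
        tab = time0_freqs(params)
        for h in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            ph = (0.4 if h[0] else 0.6) * (0.6 if h[1] else 0.4)
            assert tab[h + (1,)] == pytest.approx(ph * 0.3, abs=1e-15)

    def test_pi_q0_exceeding_founder_freq_rejected(self):
        params = LDParams(hstar=(1, 1), pi_q0=0.9, t=0, marker_freqs=(0.5, 0.5))
        with pytest.raises(ValueError):
            time0_freqs(params)


class TestQtlProb:
    def test_certainty_at_time_zero(self):
        """beta=1, Pi_Q(0) = Pi_{h*}: every h* copy carries Q at t = 0."""
        params = LDParams(hstar=(1, 0), pi_q0=0.25, t=0, marker_freqs=(0.5, 0.5))
        p = qtl_prob_given_hap(params, (1, 0), 1, [3.0, 4.0], 3.5, t=0)
        assert p == pytest.approx(1.0, abs=1e-12)
        # and a different haplotype cannot carry Q yet
        assert qtl_prob_given_hap(params, (0, 1), 1, [3.0, 4.0], 3.5, t=0) == 0.0

    def test_additivity_q_and_not_q(self):
        params = LDParams(hstar=(1, 1), pi_q0=0.1, t=12, marker_freqs=(0.6, 0.4))
        for hap in [(0, 0), (1, 1), (1, 0)]:
            pq = qtl_prob_given_hap(params, hap, 1, [0.0, 1.0], 0.4, t=12)
            pnot = qtl_prob_given_hap(params, hap, 0, [0.0, 1.0], 0.4, t=12)
            assert pq + pnot == pytest.approx(1.0, abs=1e-12)

    def test_limit_full_decay(self):
        """As t -> infinity with c > 0, P(Q | h) -> Pi_Q(0) for every h."""
        params = LDParams(hstar=(1, 1), pi_q0=0.07, t=0, marker_freqs=(0.5, 0.5))
        probs = window_qtl_probs(params, [0.0, 10.0], 5.0, t=200000)
        assert np.allclose(probs, 0.07, atol=1e-9)

    def test_monotone_decay_for_hstar(self):
        params = LDParams(hstar=(1, 0), pi_q0=0.03, t=0, marker_freqs=(0.5, 0.5))
        code = 0b10
        vals = [window_qtl_probs(params, [0.0, 1.0], 0.5, t)[code]
                for t in range(0, 200, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)


class TestSimulatorCrossCheck:
    def test_qtl_marker_ld_decay_near_infinite_ne(self):
        """Sample LD between the QTL and a flanking marker decays like
        (1-c)^t D_0: joint check of the simulator and the decay model."""
        from ldlmap.simdesign import PopulationState, Scenario, evolve

        n_e, t, dist = 5000, 6, 8.0
        c = haldane_recomb(dist)
        scn = Scenario(n_e=n_e, n_generations=t, n_sires=2, n_progeny=5,
                       n_markers=2, density_cM=dist, qtl_position_cM=4.0,
                       founder_mode="equilibrium")
        rng = np.random.default_rng(23)
        ds = []
        for _ in range(80):
            haps = np.zeros((2 * n_e, 2), dtype=np.int8)
            haps[:n_e] = 1
            rng.shuffle(haps, axis=0)
            pop = PopulationState(haps, np.array([0.0, dist]), qtl_col=1)
            pop = evolve(pop, scn, rng, generations=t)
            a = pop.haplotypes[:, 0].astype(float)
            b = pop.haplotypes[:, 1].astype(float)
            ds.append(np.mean(a * b) - a.mean() * b.mean())
        expected = 0.25 * (1 - c) ** t
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert np.mean(ds) == pytest.approx(expected, abs=3 * se)
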