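"""Gene-dropping simulator of half-sib QTL mapping designs.

A founder population of ``Ne`` diploid individuals (``2 Ne`` haplotypes over
the markers plus one bi-allelic QTL) evolves for ``Ng`` discrete
Wright-Fisher generations: random mating with replacement, Haldane
crossovers between adjacent loci, optional per-meiosis marker mutation and
optional truncation selection on a simulated phenotype.  From the final
generation a half-sib design is drawn: ``Ns`` sires, each mated to
unrelated dams, one progeny per dam, and phenotypes from an additive
dose-response model at the QTL.

Replicates in which the QTL allele is lost or no sire is QTL-heterozygous
are discarded and redrawn, mirroring the conditioning used in the
simulation study this module reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap, haldane_recomb

__all__ = [
    "Scenario",
    "PopulationState",
    "HalfSibDesign",
    "init_founders",
    "evolve",
    "apply_truncation_selection",
    "sample_design",
    "simulate_phenotypes",
    "simulate_design",
]


@dataclass(frozen=True)
class Scenario:
    """Parameters of one simulation scenario.

    Defaults are the reference conditions of the simulation study: a 10 cM
    region of 40 markers at 0.25 cM spacing, a founder population of
    effective size 100 evolving 50 generations after the causal mutation,
    20 sires with 100 progeny each, a QTL substitution effect of 0.25
    phenotypic standard deviations at 3.35 cM and residual variance 1.
    """

    n_e: int = 100
    n_generations: int = 50
    n_sires: int = 20
    n_progeny: int = 100
    n_markers: int = 40
    density_cM: float = 0.25
    qtl_effect: float = 0.25
    qtl_position_cM: float = 3.35
    founder_mode: str = "complete_LD"
    selection_fraction: float = 1.0
    marker_mutation_rate: float = 0.0
    sigma2: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("n_e", "n_generations", "n_sires", "n_progeny", "n_markers"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                if name == "n_generations" and v == 0:
                    continue
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must be in (0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.founder_mode not in ("complete_LD", "equilibrium"):
            raise ValueError("founder_mode must be 'complete_LD' or 'equilibrium'")
        if not 0.0 <= self.marker_mutation_rate < 0.5:
            raise ValueError("marker_mutation_rate must be in [0, 0.5)")

    def genetic_map(self) -> GeneticMap:
        """Evenly spaced markers at ``density_cM``, QTL at ``qtl_position_cM``."""
        pos = self.density_cM * np.arange(1, self.n_markers + 1)
        return GeneticMap(pos, qtl_position=self.qtl_position_cM)


@dataclass
class PopulationState:
    """One Wright-Fisher generation: ``2 Ne`` haplotypes over markers + QTL.

    ``haplotypes`` has one column per locus in map order, the QTL inserted
    at its map position (column ``qtl_col``); rows ``2i`` and ``2i+1`` are
    the two chromosomes of individual ``i``.
    """

    haplotypes: np.ndarray  # (2*Ne, n_loci) int8, alleles {0, 1}
    loci_positions: np.ndarray  # (n_loci,) cM, strictly increasing
    qtl_col: int
    generation: int = 0

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even (2 per individual)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("allele codes must be 0 or 1")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def qtl_frequency(self) -> float:
        return float(self.haplotypes[:, self.qtl_col].mean())

    def marker_columns(self) -> np.ndarray:
        keep = np.ones(self.haplotypes.shape[1], dtype=bool)
        keep[self.qtl_col] = False
        return self.haplotypes[:, keep]


@dataclass
class HalfSibDesign:
    """A half-sib design as seen by the mapping methods, plus simulator truth.

    The methods use the marker data only: sire phased haplotype pairs, each
    progeny's paternally and maternally transmitted marker haplotypes, the
    sire assignment and the phenotypes.  The ``true_*`` fields carry the
    simulator's hidden QTL alleles and are never consulted by the scans.
    """

    gmap: GeneticMap
    sire_haps: np.ndarray  # (Ns, 2, M) int8
    sire_of: np.ndarray  # (n,) int, progeny -> sire index
    pat_haps: np.ndarray  # (n, M) int8, sire-transmitted
    mat_haps: np.ndarray  # (n, M) int8, dam-transmitted
    y: np.ndarray  # (n,) float
    true_sire_qtl: np.ndarray = None  # (Ns, 2) int8
    true_pat_qtl: np.ndarray = None  # (n,) int8
    true_mat_qtl: np.ndarray = None  # (n,) int8

    @property
    def n_progeny(self) -> int:
        return self.pat_haps.shape[0]

    @property
    def n_sires(self) -> int:
        return self.sire_haps.shape[0]

    def validate(self):
        n, m = self.pat_haps.shape
        if self.mat_haps.shape != (n, m) or self.y.shape != (n,):
            raise ValueError("inconsistent design array shapes")
        if self.gmap.n_markers != m:
            raise ValueError("haplotype length does not match the map")
        if self.sire_of.min() < 0 or self.sire_of.max() >= self.n_sires:
            raise ValueError("sire_of out of range")
        if not np.isfinite(self.y).all():
            raise ValueError("phenotypes must be finite")
        return self

    def window_codes(self, marker_idx: np.ndarray):
        """Encode window haplotypes as small integers.

        Returns ``(sire_codes (Ns, 2), pat_codes (n,), mat_codes (n,))``
        where each code is the binary number formed by the alleles at
        ``marker_idx`` (left marker = most significant bit).
        """
        w = np.asarray(marker_idx)
        pw = (1 << np.arange(w.size - 1, -1, -1)).astype(np.int64)
        sire = self.sire_haps[:, :, w].astype(np.int64) @ pw
        pat = self.pat_haps[:, w].astype(np.int64) @ pw
        mat = self.mat_haps[:, w].astype(np.int64) @ pw
        return sire, pat, mat


def _insert_qtl_locus(gmap: GeneticMap):
    """Map positions with the QTL inserted; returns (positions, qtl_col)."""
    if gmap.qtl_position is None:
        raise ValueError("map has no QTL position")
    x = float(gmap.qtl_position)
    if np.any(gmap.positions == x):
        raise ValueError("the simulated QTL must not sit exactly on a marker")
    col = int(np.searchsorted(gmap.positions, x))
    pos = np.insert(gmap.positions, col, x)
    return pos, col


def init_founders(scenario: Scenario, gmap: GeneticMap, rng: np.random.Generator) -> PopulationState:
    """Founder haplotypes at time 0.

    Marker alleles are i.i.d. Bernoulli(1/2) per haplotype per locus
    (linkage equilibrium between markers).  In ``complete_LD`` mode the
    favourable QTL allele is a new mutation carried by exactly one of the
    ``2 Ne`` haplotypes; in ``equilibrium`` mode the QTL is one more
    independent Bernoulli(1/2) locus.
    """
    pos, qtl_col = _insert_qtl_locus(gmap)
    n_hap = 2 * scenario.n_e
    haps = rng.integers(0, 2, size=(n_hap, pos.size), dtype=np.int8)
    if scenario.founder_mode == "complete_LD":
        haps[:, qtl_col] = 0
        haps[rng.integers(0, n_hap), qtl_col] = 1
    return PopulationState(haps, pos, qtl_col, generation=0)


def _meiosis(h1: np.ndarray, h2: np.ndarray, c_adj: np.ndarray, rng: np.random.Generator):
    """One gamete per row of ``(h1, h2)`` with Haldane crossovers.

    Returns ``(gametes, origins)``; ``origins[g, l]`` is 0 where the allele
    came from ``h1`` and 1 where it came from ``h2``.
    """
    n, n_loci = h1.shape
    start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
    switches = (rng.random((n, n_loci - 1)) < c_adj).astype(np.int8)
    origins = np.empty((n, n_loci), dtype=np.int8)
    origins[:, 0] = 0
    np.cumsum(switches, axis=1, out=origins[:, 1:], dtype=np.int8)
    origins = (origins + start) % 2
    return np.where(origins == 0, h1, h2), origins


def _phenotype_of_individuals(pop: PopulationState, scenario: Scenario, rng: np.random.Generator):
    q = pop.haplotypes[:, pop.qtl_col].reshape(-1, 2).sum(axis=1)
    return scenario.qtl_effect * q + rng.normal(0.0, math.sqrt(scenario.sigma2), size=pop.n_individuals)


def apply_truncation_selection(phenotypes: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the breeding pool: the top ``ceil(fraction * n)`` by phenotype."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = phenotypes.shape[0]
    if n == 0:
        raise ValueError("empty population")
    k = math.ceil(fraction * n)
    if fraction == 1.0:
        return np.arange(n)
    return np.argpartition(phenotypes, n - k)[n - k:]


def evolve(pop: PopulationState, scenario: Scenario, rng: np.random.Generator,
           generations: int | None = None) -> PopulationState:
    """Evolve the population ``generations`` Wright-Fisher generations.

    Each generation, ``2 Ne`` gametes are produced by parents drawn
    uniformly with replacement from the breeding pool (the whole
    population, or the truncation-selected top fraction by phenotype),
    with Haldane crossovers; marker alleles flip with probability
    ``marker_mutation_rate`` per meiosis, the QTL never mutates after
    time 0.
    """
    if generations is None:
        generations = scenario.n_generations
    if generations < 0:
        raise ValueError("generations must be non-negative")
    haps = pop.haplotypes
    n_e = pop.n_individuals
    c_adj = haldane_recomb(np.diff(pop.loci_positions))
    mu = scenario.marker_mutation_rate
    state = pop
    for _ in range(generations):
        if scenario.selection_fraction < 1.0:
            phen = _phenotype_of_individuals(state, scenario, rng)
            pool = apply_truncation_selection(phen, scenario.selection_fraction)
        else:
            pool = None
        if pool is None:
            parents = rng.integers(0, n_e, size=2 * n_e)
        else:
            parents = pool[rng.integers(0, pool.size, size=2 * n_e)]
        h1 = haps[2 * parents]
        h2 = haps[2 * parents + 1]
        gametes, _ = _meiosis(h1, h2, c_adj, rng)
        if mu > 0.0:
            flips = rng.random(gametes.shape) < mu
            flips[:, state.qtl_col] = False
            gametes = np.where(flips, 1 - gametes, gametes)
        haps = np.ascontiguousarray(gametes)
        state = PopulationState(haps, state.loci_positions, state.qtl_col,
                                generation=state.generation + 1)
    return state


def simulate_phenotypes(true_pat_qtl: np.ndarray, true_mat_qtl: np.ndarray,
                        scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    """Additive dose-response phenotypes: ``y = a * (#Q alleles) + N(0, sigma2)``."""
    dose = true_pat_qtl.astype(float) + true_mat_qtl.astype(float)
    return scenario.qtl_effect * dose + rng.normal(
        0.0, math.sqrt(scenario.sigma2), size=dose.shape[0])


def sample_design(pop: PopulationState, scenario: Scenario,
                  rng: np.random.Generator) -> HalfSibDesign | None:
    """Draw a half-sib design from the final generation, or ``None`` to discard.

    ``Ns`` sires are sampled without replacement from the ``Ne``
    individuals; each of the ``Ns * Np`` progeny receives a recombined
    paternal gamete from its sire and a maternal gamete from a dam drawn
    uniformly from the population (one progeny per dam).  The replicate is
    discarded (``None``) when the QTL allele is absent or no sampled sire
    is QTL-heterozygous.
    """
    n_s, n_p = scenario.n_sires, scenario.n_progeny
    if pop.n_individuals < n_s:
        raise ValueError("population smaller than the number of sires")
    qf = pop.qtl_frequency
    if qf == 0.0 or qf == 1.0:
        return None
    sires = rng.choice(pop.n_individuals, size=n_s, replace=False)
    hap_idx = np.stack([2 * sires, 2 * sires + 1], axis=1)  # (Ns, 2)
    sire_full = pop.haplotypes[hap_idx]  # (Ns, 2, n_loci)
    sire_qtl = sire_full[:, :, pop.qtl_col]
    if not np.any(sire_qtl[:, 0] != sire_qtl[:, 1]):
        return None

    n = n_s * n_p
    c_adj = haldane_recomb(np.diff(pop.loci_positions))
    sire_of = np.repeat(np.arange(n_s), n_p)
    pat, _ = _meiosis(sire_full[sire_of, 0], sire_full[sire_of, 1], c_adj, rng)
    dams = rng.integers(0, pop.n_individuals, size=n)
    mat, _ = _meiosis(pop.haplotypes[2 * dams], pop.haplotypes[2 * dams + 1], c_adj, rng)

    marker_cols = np.ones(pop.haplotypes.shape[1], dtype=bool)
    marker_cols[pop.qtl_col] = False
    gmap = GeneticMap(pop.loci_positions[marker_cols],
                      qtl_position=pop.loci_positions[pop.qtl_col])
    pat_qtl = pat[:, pop.qtl_col].copy()
    mat_qtl = mat[:, pop.qtl_col].copy()
    design = HalfSibDesign(
        gmap=gmap,
        sire_haps=np.ascontiguousarray(sire_full[:, :, marker_cols]),
        sire_of=sire_of,
        pat_haps=np.ascontiguousarray(pat[:, marker_cols]),
        mat_haps=np.ascontiguousarray(mat[:, marker_cols]),
        y=simulate_phenotypes(pat_qtl, mat_qtl, scenario, rng),
        true_sire_qtl=sire_qtl.copy(),
        true_pat_qtl=pat_qtl,
        true_mat_qtl=mat_qtl,
    )
    return design.validate()


def simulate_design(scenario: Scenario, rng: np.random.Generator | int | None = None,
                    max_tries: int = 10_000) -> HalfSibDesign:
    """Simulate one accepted replicate (discard-and-redraw on the QTL rules)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(scenario.seed if rng is None else rng)
    gmap = scenario.genetic_map()
    for _ in range(max_tries):
        pop = init_founders(scenario, gmap, rng)
        pop = evolve(pop, scenario, rng)
        design = sample_design(pop, scenario, rng)
        if design is not None:
            return design
    raise RuntimeError("no accepted replicate after max_tries population draws")
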