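"""Multilocus linkage-disequilibrium evolution under a Wright-Fisher model.

The central objects are the Bennett multilocus disequilibria ``D_n(A_n, t)``
of a set ``A_n`` of alleles at ``n`` loci.  They are the unique multilocus
LD coefficients that decay geometrically under random mating without
interference::

    D_n(A_n, t+1) = rho{A_n} * D_n(A_n, t),
    rho{A_n} = prod_i (1 - c_{i,i+1}),

where ``rho{A_n}`` is the probability of no recombination across the loci
of ``A_n`` (product over consecutive pairs, Haldane fractions).  Haplotype
frequencies decompose over partitions of ``A_n`` into blocks, each block
contributing its Bennett coefficient.

Scope: the mapping model assumes the markers are at linkage equilibrium
when the causal mutation appears, so every marker-only disequilibrium is
zero at time 0 and stays zero.  Under that assumption only partitions made
of one block plus singletons contribute, and all their combinatorial
coefficients equal one; the decomposition below is restricted to that
partition family (the general coefficients needed for 4+ linked loci with
marker LD are exposed as an unimplemented extension point).

The time-0 state ties the favourable QTL allele ``Q`` to a founder marker
haplotype ``h*``::

    Pi_{h,Q}(0) = (1 - beta) * Pi_h * Pi_Q(0) + beta * Pi_Q(0) * delta_{h = h*}

with ``beta`` the proportion of ``Q`` copies that are new at time 0
(``beta = 1``: a brand-new mutation, all copies on ``h*``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genmap import haldane_recomb

logger = logging.getLogger(__name__)

__all__ = [
    "LDParams",
    "rho_no_recomb",
    "bennett_from_freqs",
    "freq_from_bennett",
    "expected_freq_at_t",
    "time0_freqs",
    "qtl_prob_given_hap",
    "general_partition_coefficient",
]


@dataclass(frozen=True)
class LDParams:
    """Time-0 LD model state for one marker window.

    Parameters
    ----------
    hstar
        Founder marker haplotype (tuple of 0/1 alleles, map order) on which
        the QTL allele ``Q`` arose.
    pi_q0
        Frequency of ``Q`` at time 0, in ``(0, Pi_{h*}]``.
    t
        Generations elapsed since time 0 (sires; dam-transmitted
        haplotypes are one meiosis later, ``t + 1``).
    marker_freqs
        Frequency of allele 1 at each window marker (time-0 estimates).
    beta
        Proportion of ``Q`` copies that are new at time 0.
    """

    hstar: tuple
    pi_q0: float
    t: int
    marker_freqs: tuple
    beta: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.pi_q0 <= 1.0:
            raise ValueError("pi_q0 must be in (0, 1]")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if len(self.hstar) != len(self.marker_freqs):
            raise ValueError("hstar and marker_freqs length mismatch")


def rho_no_recomb(positions_cM) -> float:
    """Probability of no recombination across a map-ordered set of loci.

    Product of ``(1 - c)`` over consecutive pairs; 1 for a singleton
    (empty product).
    """
    pos = np.asarray(positions_cM, dtype=float)
    if pos.size <= 1:
        return 1.0
    if np.any(np.diff(pos) < 0):
        raise ValueError("loci must be map-ordered")
    return float(np.prod(1.0 - haldane_recomb(np.diff(pos))))


def general_partition_coefficient(partition, positions_cM):
    """Combinatorial coefficient of an arbitrary partition (n >= 4 with
    several linked multi-locus blocks).

    Not implemented: outside the model's scope (markers at time-0
    equilibrium), where every contributing partition is one block plus
    singletons and its coefficient is one.
    """
    raise NotImplementedError(
        "general Bennett partition coefficients (several linked multi-locus "
        "blocks) are outside the supported model scope")


def _one_block_partitions(n):
    """Partitions of range(n) into one block (size >= 2) plus singletons,
    together with the all-singleton partition (block = None)."""
    idx = range(n)
    for size in range(2, n + 1):
        for block in combinations(idx, size):
            yield block
    yield None


def _marginal_freq(table: np.ndarray, alleles, subset) -> float:
    """Marginal frequency of carrying ``alleles[k]`` at the loci in ``subset``."""
    idx = [slice(None)] * table.ndim
    for k in subset:
        idx[k] = alleles[k]
    sub = table[tuple(idx)]
    return float(np.sum(sub))


def bennett_from_freqs(freq_table: np.ndarray, alleles, atol: float = 1e-8) -> dict:
    """Bennett coefficients of an allele set from a full haplotype table.

    ``freq_table`` has shape ``(2,) * n`` over the ``n`` loci in map order;
    ``alleles`` picks one allele per locus.  Returns a dict mapping each
    non-empty locus subset (as a frozenset of indices) to its
    disequilibrium at time 0; singletons map to the allele frequency (the
    convention that makes the recursion well-founded).

    Computed bottom-up: ``D(S)`` is the haplotype frequency of ``S`` minus
    the contributions of every coarser one-block-plus-singletons partition.
    """
    table = np.asarray(freq_table, dtype=float)
    n = table.ndim
    if table.shape != (2,) * n:
        raise ValueError("freq_table must have shape (2,)*n")
    total = table.sum()
    if np.any(table < -atol) or abs(total - 1.0) > max(atol, 1e-6):
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    if len(alleles) != n:
        raise ValueError("alleles length mismatch")
    d = {}
    for k in range(n):
        d[frozenset([k])] = _marginal_freq(table, alleles, [k])
    for size in range(2, n + 1):
        for subset in combinations(range(n), size):
            pi_s = _marginal_freq(table, alleles, subset)
            acc = 0.0
            for block in _one_block_partitions(size):
                if block is None:
                    acc += float(np.prod([d[frozenset([subset[k]])] for k in range(size)]))
                elif len(block) < size:
                    db = d[frozenset(subset[k] for k in block)]
                    singles = [d[frozenset([subset[k]])] for k in range(size) if k not in block]
                    acc += db * float(np.prod(singles))
            d[frozenset(subset)] = pi_s - acc
    return d


def freq_from_bennett(bennett: dict, loci) -> float:
    """Haplotype frequency of an allele set from its Bennett coefficients.

    Sum over one-block-plus-singletons partitions (coefficient one) of the
    block coefficient times the singleton allele frequencies — the inverse
    of :func:`bennett_from_freqs`.
    """
    loci = tuple(loci)
    n = len(loci)
    if n == 1:
        return bennett[frozenset(loci)]
    acc = 0.0
    for block in _one_block_partitions(n):
        if block is None:
            acc += float(np.prod([bennett[frozenset([loci[k]])] for k in range(n)]))
        else:
            db = bennett[frozenset(loci[k] for k in block)]
            singles = [bennett[frozenset([loci[k]])] for k in range(n) if k not in block]
            acc += db * float(np.prod(singles))
    return acc


def expected_freq_at_t(bennett0: dict, positions_cM, t: int, clip: bool = True) -> float:
    """Expected haplotype frequency after ``t`` Wright-Fisher generations.

    Each block's coefficient decays as ``rho{block}^t``; singleton allele
    frequencies are drift-neutral in expectation.  Exact in the
    infinite-population limit; first-order accurate in ``1/(2 Ne)``
    otherwise.  Result clipped to ``[0, 1]``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    pos = np.asarray(positions_cM, dtype=float)
    n = pos.size
    loci = tuple(range(n))
    if n == 1:
        val = bennett0[frozenset(loci)]
        return float(np.clip(val, 0.0, 1.0)) if clip else float(val)
    acc = 0.0
    for block in _one_block_partitions(n):
        if block is None:
            acc += float(np.prod([bennett0[frozenset([k])] for k in loci]))
        else:
            rho = rho_no_recomb(pos[list(block)])
            db = bennett0[frozenset(block)]
            singles = [bennett0[frozenset([k])] for k in loci if k not in block]
            acc += (rho ** t) * db * float(np.prod(singles))
    return float(np.clip(acc, 0.0, 1.0)) if clip else float(acc)


def _marker_hap_freq(marker_freqs, hap) -> float:
    p = np.asarray(marker_freqs, dtype=float)
    h = np.asarray(hap)
    return float(np.prod(np.where(h == 1, p, 1.0 - p)))


def time0_freqs(params: LDParams) -> np.ndarray:
    """Time-0 extended haplotype frequencies ``Pi_{h, a}(0)``.

    Returns a table of shape ``(2,)*w + (2,)`` (window markers in map
    order, QTL axis last, allele 1 = ``Q``) built from the mutation model
    with marker haplotype frequencies taken as products of the marker
    allele frequencies (markers at equilibrium at time 0).
    """
    w = len(params.hstar)
    table = np.empty((2,) * w + (2,), dtype=float)
    pi_hstar = _marker_hap_freq(params.marker_freqs, params.hstar)
    if params.beta * params.pi_q0 > pi_hstar + 1e-12:
        raise ValueError(
            "pi_q0 exceeds the founder haplotype frequency: the time-0 "
            "model would give a negative (h*, q) frequency")
    for hap in np.ndindex(*(2,) * w):
        pi_h = _marker_hap_freq(params.marker_freqs, hap)
        delta = 1.0 if tuple(hap) == tuple(params.hstar) else 0.0
        pi_hq = (1.0 - params.beta) * pi_h * params.pi_q0 + params.beta * params.pi_q0 * delta
        table[hap + (1,)] = pi_hq
        table[hap + (0,)] = max(pi_h - pi_hq, 0.0)
    return table


def _window_order(marker_positions, qtl_position):
    """Sorted positions of markers + QTL; returns (positions, qtl_index)."""
    mpos = np.asarray(marker_positions, dtype=float)
    qi = int(np.searchsorted(mpos, qtl_position))
    pos = np.insert(mpos, qi, qtl_position)
    return pos, qi


def qtl_prob_given_hap(params: LDParams, hap, allele: int,
                       marker_positions, qtl_position: float,
                       t: int | None = None) -> float:
    """``P(QTL allele = a | marker window haplotype h)`` after ``t`` generations.

    The ratio ``min(1, E[Pi_{a,h}(t)] / E[Pi_h(t)])`` of expected
    extended-haplotype to marker-haplotype frequencies; the marker
    haplotype frequency is constant in time (markers at equilibrium).
    When ``h`` has expected frequency 0 under the model the marginal
    ``Pi_Q(0)`` is returned with a warning (keeps likelihoods finite).
    """
    if t is None:
        t = params.t
    if _marker_hap_freq(params.marker_freqs, hap) <= 0.0:
        logger.warning(
            "window haplotype %s has expected frequency 0; falling back to "
            "the marginal Pi_Q(0)", tuple(hap))
    probs = window_qtl_probs(params, marker_positions, qtl_position, t)
    code = int(np.asarray(hap) @ (1 << np.arange(len(hap) - 1, -1, -1)))
    p_q = probs[code]
    return p_q if allele == 1 else 1.0 - p_q


def window_qtl_probs(params: LDParams, marker_positions, qtl_position: float,
                     t: int) -> np.ndarray:
    """``P(Q | h)`` for every window marker haplotype ``h`` (binary codes).

    Vector of length ``2^w`` indexed by the haplotype's binary code (left
    marker = most significant bit).
    """
    slopes = window_qtl_prob_slopes(params, marker_positions, qtl_position, t)
    return np.clip(params.pi_q0 * slopes, 0.0, 1.0)


def window_qtl_prob_slopes(params: LDParams, marker_positions,
                           qtl_position: float, t: int) -> np.ndarray:
    """``P(Q | h) / Pi_Q(0)`` before capping, per window haplotype code.

    Under the time-0 mutation model every extended-haplotype frequency is
    linear in ``Pi_Q(0)`` (zero at ``Pi_Q(0) = 0``), so the conditional
    probability is ``min(1, Pi_Q(0) * slope_h)``; the slopes depend only
    on (``h*``, ``beta``, marker frequencies, map, ``t``).  Haplotypes
    with expected frequency 0 get slope 1 (fall back to the marginal
    ``Pi_Q(0)``, with a warning).
    """
    w = len(params.hstar)
    table0 = time0_freqs(params)
    pos_all, qi = _window_order(marker_positions, qtl_position)
    out = np.empty(2 ** w)
    for code, hap in enumerate(np.ndindex(*(2,) * w)):
        pi_h = _marker_hap_freq(params.marker_freqs, hap)
        if pi_h <= 0.0:
            # haplotype absent from the model (monomorphic window marker):
            # fall back to the marginal, slope 1 => P(Q|h) = Pi_Q(0)
            logger.debug("window haplotype %s has expected frequency 0; "
                         "using the marginal Pi_Q(0)", hap)
            out[code] = 1.0
            continue
        # reorder alleles so the QTL sits at its map position
        alleles = list(hap)
        alleles.insert(qi, 1)  # allele Q
        table = np.moveaxis(table0, -1, qi)
        d0 = bennett_from_freqs(table, alleles)
        num = expected_freq_at_t(d0, pos_all, t, clip=False)
        out[code] = max(num, 0.0) / pi_h / params.pi_q0
    return out
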