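"""Sire-to-progeny transmission probabilities at a tested position.

For a progeny's paternally transmitted haplotype, the grand-parental
origin (sire chromosome 1 or 2) is observed wherever the sire is
marker-heterozygous.  Between the nearest informative markers flanking a
tested position ``x``, the origin probability follows exactly from the
crossover pattern probabilities under Haldane (no interference)::

    p(origin k at x) ∝ P(no/one crossover on each side matching the
                         flanking origins)

using the recombination fractions between ``x`` and the two flanks.  With
an informative marker on one side only, the single flank is used; with no
informative marker, both origins are equally likely.
"""

from __future__ import annotations

import numpy as np

from .genmap import GeneticMap, haldane_recomb

__all__ = ["transmission_prob", "transmission_probs_batch"]


def transmission_prob(sire_haps: np.ndarray, pat_hap: np.ndarray,
                      x: float, gmap: GeneticMap) -> tuple:
    """``(p1, p2)``: probability the allele at ``x`` came from each sire chromosome.

    ``sire_haps`` is the sire's phased pair ``(2, M)``; ``pat_hap`` the
    progeny's paternally transmitted haplotype ``(M,)``.  ``p1 + p2 = 1``.
    Raises on a pedigree inconsistency (paternal allele matching neither
    sire chromosome at an informative marker).
    """
    sire_haps = np.asarray(sire_haps)
    pat = np.asarray(pat_hap)
    if sire_haps.shape != (2, gmap.n_markers) or pat.shape != (gmap.n_markers,):
        raise ValueError("haplotype length does not match the map")
    p1 = _batch_p1(sire_haps, pat[None, :], x, gmap)[0]
    return float(p1), float(1.0 - p1)


def _batch_p1(sire_haps: np.ndarray, pat: np.ndarray, x: float,
              gmap: GeneticMap) -> np.ndarray:
    """P(origin = sire chromosome 1) at ``x`` for many progeny of one sire."""
    info = sire_haps[0] != sire_haps[1]
    n = pat.shape[0]
    if not info.any():
        return np.full(n, 0.5)
    idx = np.flatnonzero(info)
    match1 = pat[:, idx] == sire_haps[0, idx]
    match2 = pat[:, idx] == sire_haps[1, idx]
    if not (match1 | match2).all():
        raise ValueError("paternal haplotype incompatible with both sire "
                         "chromosomes at an informative marker")
    origins = np.where(match1, 0, 1)  # (n, n_info)
    pos = gmap.positions[idx]

    on = np.flatnonzero(np.isclose(pos, x))
    if on.size:  # x exactly on an informative marker: origin is observed
        return np.where(origins[:, on[0]] == 0, 1.0, 0.0)

    left = np.flatnonzero(pos < x)
    right = np.flatnonzero(pos > x)
    if left.size and right.size:
        il, ir = left[-1], right[0]
        c_l = haldane_recomb(x - pos[il])
        c_r = haldane_recomb(pos[ir] - x)
        o_l, o_r = origins[:, il], origins[:, ir]
        # weight of each origin at x given the flank origins
        w1 = np.where(o_l == 0, 1.0 - c_l, c_l) * np.where(o_r == 0, 1.0 - c_r, c_r)
        w2 = np.where(o_l == 1, 1.0 - c_l, c_l) * np.where(o_r == 1, 1.0 - c_r, c_r)
        return w1 / (w1 + w2)
    if left.size:
        il = left[-1]
        c = haldane_recomb(x - pos[il])
        return np.where(origins[:, il] == 0, 1.0 - c, c)
    ir = right[0]
    c = haldane_recomb(pos[ir] - x)
    return np.where(origins[:, ir] == 0, 1.0 - c, c)


def transmission_probs_batch(design, x: float) -> np.ndarray:
    """P(allele at ``x`` came from sire chromosome 1) for every progeny."""
    p1 = np.empty(design.n_progeny)
    for i in range(design.n_sires):
        rows = design.sire_of == i
        p1[rows] = _batch_p1(design.sire_haps[i], design.pat_haps[rows], x, design.gmap)
    return p1
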