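"""Genetic maps of bi-allelic SNP markers with positions in centimorgans.

A :class:`GeneticMap` orders markers along one chromosome segment and
converts map distances into recombination fractions with Haldane's map
function (no crossover interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def haldane_recomb(distance_cM):
    """Recombination fraction between two loci separated by ``distance_cM``.

    Haldane's map function, ``c = (1 - exp(-2 d)) / 2`` with ``d`` in
    Morgans, assumes crossovers occur as a Poisson process with no
    interference.  ``c`` is in ``[0, 0.5)``.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    c = 0.5 * (1.0 - np.exp(-0.02 * d))
    if np.ndim(distance_cM) == 0:
        return float(c)
    return c


@dataclass(frozen=True)
class GeneticMap:
    """Ordered bi-allelic marker loci on one chromosome.

    Parameters
    ----------
    positions
        Marker positions in cM, strictly increasing.
    marker_ids
        One label per marker; generated as ``M1..Mn`` when omitted.
    qtl_position
        Optional position (cM) of a causal locus; it need not (and in the
        simulated designs does not) coincide with a marker.
    """

    positions: np.ndarray
    marker_ids: tuple = field(default=None)
    qtl_position: float = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("a map needs at least two markers")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        ids = self.marker_ids
        if ids is None:
            ids = tuple(f"M{i + 1}" for i in range(pos.size))
        else:
            ids = tuple(str(m) for m in ids)
            if len(ids) != pos.size:
                raise ValueError("marker_ids and positions length mismatch")
            if len(set(ids)) != len(ids):
                raise ValueError("duplicated marker ids")
        object.__setattr__(self, "marker_ids", ids)

    @property
    def n_markers(self) -> int:
        return self.positions.size

    @property
    def n_intervals(self) -> int:
        return self.n_markers - 1

    def interval_midpoints(self) -> np.ndarray:
        """Midpoint (cM) of each adjacent-marker interval."""
        return 0.5 * (self.positions[:-1] + self.positions[1:])

    def recomb_fraction(self, pos_a: float, pos_b: float) -> float:
        return haldane_recomb(abs(pos_b - pos_a))

    def adjacent_recomb(self) -> np.ndarray:
        """Recombination fraction between each pair of adjacent markers."""
        return haldane_recomb(np.diff(self.positions))

    def window_markers(self, interval: int, n_flanking: int = 2) -> np.ndarray:
        """Marker indices of the ``n_flanking``-marker window around an interval.

        ``n_flanking=2`` gives the interval's two bounding markers,
        ``n_flanking=4`` adds one more on each side.  The window is
        truncated at chromosome ends.
        """
        if n_flanking not in (2, 4):
            raise ValueError("n_flanking must be 2 or 4")
        if not 0 <= interval < self.n_intervals:
            raise ValueError("interval index out of range")
        half = n_flanking // 2
        lo = max(0, interval - half + 1)
        hi = min(self.n_markers, interval + half + 1)
        return np.arange(lo, hi)

    def with_qtl(self, qtl_position: float) -> "GeneticMap":
        return GeneticMap(self.positions, self.marker_ids, float(qtl_position))
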