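"""HaploMax: haplotype-dose association scan for half-sib designs.

In each marker interval, every observed flanking-marker haplotype ``h`` is
tested in turn against all the others with the linear model::

    y_ij = sire_i + gamma * dose_h(ij) + e_ij

where ``dose_h`` counts the copies of ``h`` (0, 1 or 2) among the
progeny's two window haplotypes.  The interval statistic is the maximum
over haplotypes of the 1-df F test of ``gamma`` (sire effects absorbed as
fixed categorical nuisance); the estimated QTL position is the midpoint of
the interval with the largest statistic.  Complete and constant QTL-marker
linkage is implicit: no LD-evolution model enters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanResult", "haplotype_dose", "haplomax_scan"]


@dataclass
class ScanResult:
    """Per-interval scan statistics and the estimated QTL position."""

    method: str
    positions: np.ndarray  # tested positions (interval midpoints, cM)
    statistics: np.ndarray  # per-position statistic (F or LRT)
    s_hat: float  # estimated QTL position (cM)
    max_statistic: float
    best_haplotype: np.ndarray = None  # per-position winning window haplotype code
    extras: dict = field(default_factory=dict)

    @property
    def argmax_interval(self) -> int:
        return int(np.argmax(self.statistics))


def haplotype_dose(pat_codes: np.ndarray, mat_codes: np.ndarray, h: int) -> np.ndarray:
    """Copies (0/1/2) of window haplotype ``h`` carried by each progeny."""
    return (pat_codes == h).astype(np.int64) + (mat_codes == h)


def _family_center(v: np.ndarray, sire_of: np.ndarray, n_sires: int) -> np.ndarray:
    """Subtract the sire-family mean (absorbs fixed sire effects)."""
    sums = np.bincount(sire_of, weights=v, minlength=n_sires)
    counts = np.bincount(sire_of, minlength=n_sires)
    return v - (sums / counts)[sire_of]


def interval_structures(design, n_flanking: int = 2):
    """Pre-computed per-interval dose design pieces for fast F statistics.

    For each interval: the window haplotype codes tested and the
    family-centered dose matrix with its column sums of squares.  Columns
    whose centered dose is (numerically) zero — haplotype absent,
    universal, or confounded with sire families — are dropped, matching
    the rule that such haplotypes are skipped.
    """
    gmap = design.gmap
    sire_of = design.sire_of
    n_s = design.n_sires
    out = []
    for j in range(gmap.n_intervals):
        w = gmap.window_markers(j, n_flanking)
        _, pat, mat = design.window_codes(w)
        haps = np.unique(np.concatenate([pat, mat]))
        cols, kept = [], []
        for h in haps:
            dose = haplotype_dose(pat, mat, h).astype(float)
            dc = _family_center(dose, sire_of, n_s)
            if dc @ dc > 1e-10:
                cols.append(dc)
                kept.append(h)
        if cols:
            dmat = np.column_stack(cols)
            sxx = np.einsum("ij,ij->j", dmat, dmat)
        else:
            dmat = np.empty((design.n_progeny, 0))
            sxx = np.empty(0)
        out.append((np.asarray(kept), dmat, sxx))
    return out


def max_f_statistics(structures, ycent: np.ndarray, df_den: int):
    """Max-over-haplotypes F per interval for (batches of) centered phenotypes.

    ``ycent`` is family-centered, shape ``(n,)`` or ``(B, n)``.  Returns
    ``(F, best)`` with ``F`` of shape ``(n_intervals,)`` or
    ``(B, n_intervals)``; ``best`` (single-phenotype case only) holds the
    winning haplotype code per interval, -1 where no haplotype was testable.
    """
    y2 = np.atleast_2d(ycent)
    ss0 = np.einsum("bi,bi->b", y2, y2)
    n_int = len(structures)
    f = np.zeros((y2.shape[0], n_int))
    best = np.full(n_int, -1, dtype=np.int64)
    for j, (haps, dmat, sxx) in enumerate(structures):
        if haps.size == 0:
            continue
        sxy = y2 @ dmat  # (B, k)
        ssr = sxy * sxy / sxx
        fj = ssr / ((ss0[:, None] - ssr) / df_den)
        k = np.argmax(fj, axis=1)
        f[:, j] = fj[np.arange(y2.shape[0]), k]
        if ycent.ndim == 1:
            best[j] = haps[k[0]]
    if ycent.ndim == 1:
        return f[0], best
    return f, None


def haplomax_scan(design, n_flanking: int = 2) -> ScanResult:
    """Run the HaploMax scan; see the module docstring for the model.

    Ties across intervals are broken towards the smallest interval index;
    the estimated position is the argmax interval's midpoint.
    """
    if design.n_sires < 2:
        raise ValueError("the sire-effect model needs at least 2 sires")
    n = design.n_progeny
    df_den = n - design.n_sires - 1
    if df_den < 1:
        raise ValueError("not enough progeny for the residual degrees of freedom")
    structures = interval_structures(design, n_flanking)
    ycent = _family_center(design.y, design.sire_of, design.n_sires)
    f, best = max_f_statistics(structures, ycent, df_den)
    mid = design.gmap.interval_midpoints()
    j = int(np.argmax(f))
    return ScanResult(
        method=f"haplomax{n_flanking}",
        positions=mid,
        statistics=f,
        s_hat=float(mid[j]),
        max_statistic=float(f[j]),
        best_haplotype=best,
        extras={"n_flanking": n_flanking, "df_den": df_den},
    )
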