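"""HAPimLDL: linkage + LD-evolution likelihood scan for half-sib designs.

At a tested position ``x`` the phenotype of progeny ``ij`` follows a
Gaussian mixture over the unobserved QTL states::

    Lambda_ij(x) = sum_z P(Z_i = z | h_i) sum_a P(Q^d_ij = a | h^d_ij)
                   * [ phi(y; mu_i + alpha_{Q a}, sigma^2) * P(sire transmits Q)
                     + phi(y; mu_i + alpha_{q a}, sigma^2) * P(sire transmits q) ]

where ``z`` runs over the four ordered sire diplotypes (QQ, qq, Qq, qQ),
``a`` over the dam-transmitted allele, and the sire-transmission terms
combine the chromosome-of-origin probabilities at ``x`` (linkage, from the
flanking-marker origins) with the 0/1 indicators of the allele carried by
each sire chromosome under ``z``.  Diplotype and dam-allele probabilities
condition on the flanking-marker haplotypes through the Wright-Fisher LD
model (sires at generation ``t``, dam gametes at ``t + 1``), assuming
Hardy-Weinberg so the diplotype probability is the product over the two
chromosomes.

Diplotype effects satisfy ``alpha_QQ + alpha_qq = 0`` and
``alpha_Qq = alpha_qQ = 0`` (additive model, one free effect).  The scan
maximizes the total log-likelihood at each interval midpoint over the
sire means, the effect, the residual variance and the LD nuisance
parameters (founder haplotype ``h*`` profiled over observed window
haplotypes, ``Pi_Q(0)`` over a bounded range), and reports the
likelihood-ratio statistic against the no-QTL-effect null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .haplomax import ScanResult
from .ldmodel import LDParams, window_qtl_prob_slopes, window_qtl_probs
from .transmission import transmission_prob, transmission_probs_batch

__all__ = [
    "QTLModelParams",
    "sire_diplotype_probs",
    "individual_likelihood",
    "ldl_loglik",
    "ldl_scan",
]

_LOG2PI = math.log(2.0 * math.pi)
_DIPLOTYPES = ("QQ", "qq", "Qq", "qQ")
# allele (1 = Q) carried by sire chromosome (1, 2) under each diplotype
_DIPLO_ALLELES = {"QQ": (1, 1), "qq": (0, 0), "Qq": (1, 0), "qQ": (0, 1)}


@dataclass
class QTLModelParams:
    """Parameters of the mixture at one tested position.

    ``alpha`` is the single free diplotype effect ``alpha_QQ``
    (``alpha_qq = -alpha``, heterozygote effects 0: additive model);
    ``mu`` holds one phenotype mean per sire family; ``ld`` the time-0 LD
    model state (founder haplotype, ``Pi_Q(0)``, elapsed generations).
    """

    mu: np.ndarray
    alpha: float
    sigma2: float
    ld: LDParams

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def alphas(self) -> dict:
        """Diplotype effects keyed by (sire-transmitted, dam-transmitted) allele."""
        return {"QQ": self.alpha, "qq": -self.alpha, "Qq": 0.0, "qQ": 0.0}


def sire_diplotype_probs(p_q1: float, p_q2: float) -> np.ndarray:
    """Ordered diplotype distribution (QQ, qq, Qq, qQ) for one sire.

    Hardy-Weinberg product of the per-chromosome QTL-allele probabilities;
    renormalized in case clipping upstream perturbed additivity.
    """
    p = np.array([
        p_q1 * p_q2,
        (1.0 - p_q1) * (1.0 - p_q2),
        p_q1 * (1.0 - p_q2),
        (1.0 - p_q1) * p_q2,
    ])
    s = p.sum()
    if s <= 0:
        raise ValueError("degenerate diplotype distribution")
    return p / s


class _PositionContext:
    """Everything at one tested position that does not depend on (h*, Pi_Q(0))."""

    def __init__(self, design, interval: int, n_flanking: int):
        gmap = design.gmap
        self.x = float(gmap.interval_midpoints()[interval])
        self.window = gmap.window_markers(interval, n_flanking)
        self.wpos = gmap.positions[self.window]
        self.sire_codes, self.pat_codes, self.mat_codes = design.window_codes(self.window)
        self.p1 = transmission_probs_batch(design, self.x)
        self.sire_of = design.sire_of


def _class_weights(ctx: _PositionContext, ld: LDParams):
    """Mixture weights of the three effect classes (+alpha, 0, -alpha).

    Exact collapse of the (diplotype, dam allele, origin) sum under the
    additive model: the effect depends only on the sire-transmitted and
    dam-transmitted alleles, whose probabilities factorize.
    """
    probs_t = window_qtl_probs(ld, ctx.wpos, ctx.x, ld.t)
    probs_t1 = window_qtl_probs(ld, ctx.wpos, ctx.x, ld.t + 1)
    pq_sire = probs_t[ctx.sire_codes]  # (Ns, 2)
    ws = ctx.p1 * pq_sire[ctx.sire_of, 0] + (1.0 - ctx.p1) * pq_sire[ctx.sire_of, 1]
    wd = probs_t1[ctx.mat_codes]
    w_plus = ws * wd
    w_minus = (1.0 - ws) * (1.0 - wd)
    w_zero = 1.0 - w_plus - w_minus
    return w_plus, w_zero, w_minus


def individual_likelihood(design, j: int, x: float, params: QTLModelParams,
                          n_flanking: int = 2) -> float:
    """``Lambda_ij(x)`` by direct enumeration of (diplotype, dam allele, origin).

    The faithful mixture sum, used as the reference form; the scan
    evaluates an algebraically collapsed, vectorized version of the same
    sum (their equality is a tested invariant).
    """
    y = design.y[j]
    if not np.isfinite(y):
        raise ValueError("non-finite phenotype")
    gmap = design.gmap
    interval = int(np.clip(np.searchsorted(gmap.positions, x) - 1, 0, gmap.n_intervals - 1))
    w = gmap.window_markers(interval, n_flanking)
    wpos = gmap.positions[w]
    sire_codes, pat_codes, mat_codes = design.window_codes(w)
    i = int(design.sire_of[j])
    ld = params.ld

    probs_t = window_qtl_probs(ld, wpos, x, ld.t)
    probs_t1 = window_qtl_probs(ld, wpos, x, ld.t + 1)
    p_q1, p_q2 = probs_t[sire_codes[i, 0]], probs_t[sire_codes[i, 1]]
    diplo = sire_diplotype_probs(p_q1, p_q2)
    p_dam_q = probs_t1[mat_codes[j]]

    p1, p2 = transmission_prob(design.sire_haps[i], design.pat_haps[j], x, gmap)

    alphas = params.alphas
    mu_i = params.mu[i]
    sd = math.sqrt(params.sigma2)
    lam = 0.0
    for z, pz in zip(_DIPLOTYPES, diplo):
        a1, a2 = _DIPLO_ALLELES[z]
        for a, pa in (("Q", p_dam_q), ("q", 1.0 - p_dam_q)):
            # sire transmits Q with the origin-weighted 0/1 indicators
            p_trans_q = p1 * (a1 == 1) + p2 * (a2 == 1)
            p_trans_p = p1 * (a1 == 0) + p2 * (a2 == 0)
            lam += pz * pa * (
                norm.pdf(y, mu_i + alphas["Q" + ("Q" if a == "Q" else "q")], sd) * p_trans_q
                + norm.pdf(y, mu_i + alphas["q" + ("Q" if a == "Q" else "q")], sd) * p_trans_p
            )
    return lam


def _mixture_loglik(y, mu_of, alpha, sigma2, w_plus, w_zero, w_minus):
    inv = -0.5 / sigma2
    lam = (w_plus * np.exp(inv * (y - mu_of - alpha) ** 2)
           + w_zero * np.exp(inv * (y - mu_of) ** 2)
           + w_minus * np.exp(inv * (y - mu_of + alpha) ** 2))
    norm_c = math.sqrt(2.0 * math.pi * sigma2)
    lam = np.maximum(lam / norm_c, 1e-300)  # floor guards log(0)
    return float(np.log(lam).sum())


def ldl_loglik(design, x: float, params: QTLModelParams, n_flanking: int = 2) -> float:
    """Total log-likelihood ``sum_ij log Lambda_ij(x)`` (independent families)."""
    gmap = design.gmap
    interval = int(np.clip(np.searchsorted(gmap.positions, x) - 1, 0, gmap.n_intervals - 1))
    ctx = _PositionContext(design, interval, n_flanking)
    ctx.x = float(x)
    ctx.p1 = transmission_probs_batch(design, float(x))
    w_plus, w_zero, w_minus = _class_weights(ctx, params.ld)
    mu_of = params.mu[design.sire_of]
    return _mixture_loglik(design.y, mu_of, params.alpha, params.sigma2,
                           w_plus, w_zero, w_minus)


def _em_loglik(y, sire_of, w_plus, w_zero, w_minus, mu, alpha, sigma2):
    """Observed-data log-likelihood and the pieces the E-step reuses."""
    mu_of = mu[sire_of]
    inv = -0.5 / sigma2
    d_p = np.exp(inv * (y - mu_of - alpha) ** 2)
    d_0 = np.exp(inv * (y - mu_of) ** 2)
    d_m = np.exp(inv * (y - mu_of + alpha) ** 2)
    lam = np.maximum(w_plus * d_p + w_zero * d_0 + w_minus * d_m, 1e-300)
    n = y.shape[0]
    ll = float(np.log(lam).sum()) - 0.5 * n * (_LOG2PI + math.log(sigma2))
    return ll, lam, d_p, d_m


def _em_step(y, sire_of, n_sires, counts, w_plus, w_zero, w_minus,
             mu, alpha, sigma2, s2_floor):
    """One EM iteration (E-step responsibilities, closed-form M-step)."""
    ll, lam, d_p, d_m = _em_loglik(y, sire_of, w_plus, w_zero, w_minus,
                                   mu, alpha, sigma2)
    r_p = w_plus * d_p / lam
    r_m = w_minus * d_m / lam
    g = r_p - r_m
    v = r_p + r_m
    ybar = np.bincount(sire_of, weights=y, minlength=n_sires) / counts
    gbar = np.bincount(sire_of, weights=g, minlength=n_sires) / counts
    yc = y - ybar[sire_of]
    denom = v.sum() - float(counts @ (gbar * gbar))
    alpha_new = float(yc @ g) / denom if denom > 1e-12 else 0.0
    mu_new = ybar - alpha_new * gbar
    resid0 = y - mu_new[sire_of]
    s2_new = float(np.mean(resid0 * resid0 - 2.0 * alpha_new * resid0 * g
                           + alpha_new * alpha_new * v))
    return ll, mu_new, alpha_new, max(s2_new, s2_floor)


def _em_fit(y, sire_of, n_sires, w_plus, w_zero, w_minus,
            mu, alpha, sigma2, tol=1e-8, max_iter=200, s2_floor=1e-6):
    """Maximize the 3-class mixture over (mu, alpha, sigma2).

    EM with closed-form M-steps (the per-family means and the shared
    effect solve a 2-level weighted least squares), accelerated by squared
    extrapolation of consecutive EM steps (SQUAREM); the extrapolated
    point is kept only when it improves the log-likelihood, so the ascent
    stays monotone.  ``sigma2`` is extrapolated on the log scale to stay
    positive, with a hard floor.
    """
    counts = np.bincount(sire_of, minlength=n_sires).astype(float)

    def pack(mu, alpha, s2):
        return np.concatenate([mu, [alpha, math.log(s2)]])

    def unpack(theta):
        return theta[:-2], float(theta[-2]), max(math.exp(theta[-1]), s2_floor)

    theta0 = pack(np.asarray(mu, dtype=float), alpha, sigma2)
    ll_prev = -np.inf
    ll = ll_prev
    iters = 0
    while iters < max_iter:
        ll, mu1, a1, s21 = _em_step(y, sire_of, n_sires, counts,
                                    w_plus, w_zero, w_minus, *unpack(theta0),
                                    s2_floor)
        if ll - ll_prev < tol and ll_prev > -np.inf:
            theta0 = pack(mu1, a1, s21)
            break
        ll_prev = ll
        ll2, mu2, a2, s22 = _em_step(y, sire_of, n_sires, counts,
                                     w_plus, w_zero, w_minus, mu1, a1, s21,
                                     s2_floor)
        iters += 2
        theta1 = pack(mu1, a1, s21)
        theta2 = pack(mu2, a2, s22)
        r = theta1 - theta0
        v = theta2 - theta1 - r
        vnorm = float(v @ v)
        if vnorm < 1e-24:
            theta0 = theta2
            continue
        step = -max(1.0, math.sqrt(float(r @ r) / vnorm))
        cand = theta0 - 2.0 * step * r + step * step * v
        mu_c, a_c, s2_c = unpack(cand)
        ll_c, _, _, _ = _em_loglik(y, sire_of, w_plus, w_zero, w_minus,
                                   mu_c, a_c, s2_c)
        ll2_obs, _, _, _ = _em_loglik(y, sire_of, w_plus, w_zero, w_minus,
                                      mu2, a2, s22)
        iters += 1
        theta0 = cand if (np.isfinite(ll_c) and ll_c > ll2_obs) else theta2
    mu_f, a_f, s2_f = unpack(theta0)
    ll, _, _, _ = _em_loglik(y, sire_of, w_plus, w_zero, w_minus,
                             mu_f, a_f, s2_f)
    return ll, mu_f, a_f, s2_f


def null_fit(design):
    """Null model (no QTL effect): per-sire means and ML residual variance."""
    counts = np.bincount(design.sire_of, minlength=design.n_sires).astype(float)
    mu0 = np.bincount(design.sire_of, weights=design.y, minlength=design.n_sires) / counts
    resid = design.y - mu0[design.sire_of]
    s20 = float(np.mean(resid * resid))
    n = design.n_progeny
    ll0 = -0.5 * n * (_LOG2PI + math.log(s20) + 1.0)
    return ll0, mu0, s20


def _code_to_hap(code: int, width: int) -> tuple:
    return tuple((code >> (width - 1 - k)) & 1 for k in range(width))


def estimate_marker_freqs(design) -> np.ndarray:
    """Allele-1 frequency per marker from the observed parental haplotypes.

    Sire chromosomes and dam-transmitted haplotypes; drift is
    frequency-neutral in expectation, so the sample estimates stand in for
    the time-0 frequencies.
    """
    m = design.gmap.n_markers
    pool = np.vstack([design.sire_haps.reshape(-1, m), design.mat_haps])
    return pool.mean(axis=0)


def ldl_scan(design, n_flanking: int = 2, t: int = 50,
             pi_q0_min: float = 1e-4, n_grid: int = 4,
             em_tol: float = 1e-8, em_max_iter: int = 200,
             beta: float = 1.0, intervals=None) -> ScanResult:
    """Likelihood-ratio scan over interval midpoints.

    ``t`` is the number of generations since the founding mutation (an
    input, known in simulations, not estimated).  ``intervals`` restricts
    the tested positions to a subset of interval indices (default: all).
    At each midpoint the
    founder haplotype ``h*`` is profiled over the observed window
    haplotypes and ``Pi_Q(0)`` over ``(pi_q0_min, Pi_{h*}]`` (coarse
    geometric grid, then bounded refinement); (mu, alpha, sigma2) are
    maximized by EM warm-started from the null fit.
    """
    gmap = design.gmap
    freqs = estimate_marker_freqs(design)
    ll0, mu0, s20 = null_fit(design)
    n_int = gmap.n_intervals
    mid = gmap.interval_midpoints()
    lrt = np.zeros(n_int)
    alpha_hat = np.zeros(n_int)
    hstar_hat = np.full(n_int, -1, dtype=np.int64)
    piq0_hat = np.full(n_int, np.nan)
    y, sire_of, n_s = design.y, design.sire_of, design.n_sires
    tested = range(n_int) if intervals is None else list(intervals)

    for j in tested:
        ctx = _PositionContext(design, j, n_flanking)
        wfreqs = tuple(float(freqs[k]) for k in ctx.window)
        width = ctx.window.size
        observed = np.unique(np.concatenate(
            [ctx.sire_codes.ravel(), ctx.pat_codes, ctx.mat_codes]))
        best = (ll0, 0.0, mu0, s20, -1, np.nan)

        s1 = ctx.sire_codes[ctx.sire_of, 0]
        s2_idx = ctx.sire_codes[ctx.sire_of, 1]

        for code in observed:
            hstar = _code_to_hap(int(code), width)
            pi_h = float(np.prod([p if a == 1 else 1.0 - p
                                  for a, p in zip(hstar, wfreqs)]))
            hi = min(pi_h, 1.0)
            if hi <= pi_q0_min:
                continue
            # P(Q | h) is linear in Pi_Q(0) before capping: slopes computed
            # once per (position, h*), reused across the whole profile
            ld_ref = LDParams(hstar=hstar, pi_q0=hi, t=t,
                              marker_freqs=wfreqs, beta=beta)
            slopes_t = window_qtl_prob_slopes(ld_ref, ctx.wpos, ctx.x, t)
            slopes_t1 = window_qtl_prob_slopes(ld_ref, ctx.wpos, ctx.x, t + 1)
            state = {"mu": mu0, "alpha": 0.0, "s2": s20, "ll": -np.inf,
                     "pi": np.nan}

            def objective(pi_q0, _state=state):
                pt = np.clip(pi_q0 * slopes_t, 0.0, 1.0)
                pt1 = np.clip(pi_q0 * slopes_t1, 0.0, 1.0)
                ws = ctx.p1 * pt[s1] + (1.0 - ctx.p1) * pt[s2_idx]
                wd = pt1[ctx.mat_codes]
                wp = ws * wd
                wm = (1.0 - ws) * (1.0 - wd)
                ll, mu, a, s2 = _em_fit(y, sire_of, n_s, wp, 1.0 - wp - wm, wm,
                                        _state["mu"], _state["alpha"],
                                        _state["s2"], tol=em_tol,
                                        max_iter=em_max_iter)
                if ll > _state["ll"]:
                    _state.update(mu=mu, alpha=a, s2=s2, ll=ll,
                                  pi=float(pi_q0))
                return -ll

            grid = np.geomspace(pi_q0_min * 10, hi, n_grid)
            vals = [objective(p) for p in grid]
            k = int(np.argmin(vals))
            if state["ll"] > best[0] - 2.0:  # refine only competitive h*
                lo_b = grid[k - 1] if k > 0 else pi_q0_min
                hi_b = grid[k + 1] if k < n_grid - 1 else hi
                try:
                    minimize_scalar(objective, bounds=(lo_b, hi_b),
                                    method="bounded",
                                    options={"maxiter": 10,
                                             "xatol": max(1e-4, 0.02 * hi)})
                except Exception:  # a failed refinement leaves the grid optimum
                    pass
            if state["ll"] > best[0]:
                best = (state["ll"], state["alpha"], state["mu"], state["s2"],
                        int(code), state["pi"])

        lrt[j] = max(0.0, 2.0 * (best[0] - ll0))
        alpha_hat[j] = best[1]
        hstar_hat[j] = best[4]
        piq0_hat[j] = best[5]

    tested = list(tested)
    jmax = int(tested[int(np.argmax(lrt[tested]))])
    return ScanResult(
        method=f"hapimldl{n_flanking}",
        positions=mid,
        statistics=lrt,
        s_hat=float(mid[jmax]),
        max_statistic=float(lrt[jmax]),
        best_haplotype=hstar_hat,
        extras={"alpha_hat": alpha_hat, "pi_q0_hat": piq0_hat, "t": t,
                "n_flanking": n_flanking, "loglik_null": ll0},
    )
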