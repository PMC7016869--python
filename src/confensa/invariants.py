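"""Model-free invariants of a scattering curve.

Three classical analyses:

* Guinier fit — at low q, ln I(q) = ln I(0) - q^2 Rg^2 / 3; a weighted
  linear fit over a self-consistent window q*Rg <= limit yields the radius
  of gyration and forward scattering.
* Indirect Fourier transform — the pair-distance distribution P(r) is
  recovered from I(q) = 4*pi * int_0^Dmax P(r) sin(qr)/(qr) dr by
  Tikhonov-regularized least squares with the endpoints pinned to zero;
  P(r) is NOT constrained to be positive by default.
* Molecular weight — from calibrated I(0), from the Porod invariant
  (Q = int q^2 I dq, Vp = 2 pi^2 I(0)/Q, MW ~ Vp/1.6), and from the
  concentration-independent volume of correlation (Vc = I(0)/int q I dq,
  QR = Vc^2/Rg, MW = QR/0.1231 for proteins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curves import ScatteringCurve

__all__ = ["GuinierResult", "PairDistribution", "MWEstimates",
           "guinier_fit", "ift_pr", "estimate_mw"]

PORAD_VOLUME_TO_DA = 1.6     # Vp [A^3] per Da, apparent (hydrated) protein
VC_PROTEIN_CONSTANT = 0.1231  # QR -> MW(Da) divisor for proteins


@dataclass
class GuinierResult:
    rg: float
    rg_err: float
    i0: float
    i0_err: float
    q_range_used: tuple
    qrg_max: float
    fit_r2: float


@dataclass
class PairDistribution:
    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg_real: float
    i0_real: float
    alpha: float
    positivity: bool
    chi2: float = np.nan


@dataclass
class MWEstimates:
    mw_i0: float | None       # kDa; None without intensity calibration
    mw_porod: float
    mw_vc: float
    oligomer_n: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)


def _weighted_linfit(x, y, w):
    """Weighted least squares y = a + b x; returns a, b, var_a, var_b, r2."""
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * y).sum() / W
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    b = sxy / sxx
    a = ym - b * xm
    var_b = 1.0 / sxx
    var_a = 1.0 / W + xm ** 2 / sxx
    ss_tot = (w * (y - ym) ** 2).sum()
    ss_res = (w * (y - a - b * x) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, b, var_a, var_b, r2


def guinier_fit(
    curve: ScatteringCurve,
    qrg_limit: float = 1.3,
    auto_range: bool = True,
) -> GuinierResult:
    """Self-consistent Guinier fit of the low-q region.

    Iterates the window upper bound so that qmax * Rg <= qrg_limit.  With
    ``auto_range`` a low-q upturn (aggregation signature: a leading run of
    positive residuals) is trimmed.  Errors come from the fit covariance.
    """
    pos = curve.intensity > 0
    q = curve.q[pos]
    inten = curve.intensity[pos]
    sig = curve.sigma[pos]
    if len(q) < 10:
        raise ValueError("fewer than 10 positive-intensity points")

    y = np.log(inten)
    w = (inten / sig) ** 2          # var(ln I) = (sigma/I)^2
    x = q ** 2

    i_lo = 0
    i_hi = max(10, len(q) // 10)    # exclusive; start low-q, grow outward
    rg = None
    for _ in range(100):
        a, b, va, vb, r2 = _weighted_linfit(x[i_lo:i_hi], y[i_lo:i_hi],
                                            w[i_lo:i_hi])
        if b >= 0:
            raise ValueError("Guinier fit has non-negative slope (Rg^2 < 0)")
        rg_new = float(np.sqrt(-3.0 * b))
        new_hi = int(np.searchsorted(q, qrg_limit / rg_new, side="right"))
        new_hi = max(new_hi, i_lo + 10)
        new_lo = i_lo
        if auto_range:
            resid = y[i_lo:new_hi] - (a + b * x[i_lo:new_hi])
            k = 0
            while k < len(resid) - 10 and resid[k] > 0:
                k += 1
            new_lo = i_lo + (k if k >= 3 else 0)   # only trim a real run
        if new_hi == i_hi and new_lo == i_lo and rg is not None \
                and abs(rg_new - rg) < 1e-9 * rg_new:
            rg = rg_new
            break
        rg = rg_new
        converged = (new_hi == i_hi and new_lo == i_lo)
        i_hi, i_lo = new_hi, new_lo
        if converged:
            break

    if auto_range:
        # shrink the window while the residuals show significant curvature
        # (the Guinier expansion breaking down before q*Rg hits the limit)
        while i_hi - i_lo > 12:
            xs, ys, ws = x[i_lo:i_hi], y[i_lo:i_hi], w[i_lo:i_hi]
            X = np.column_stack([np.ones_like(xs), xs, xs ** 2])
            WX = X * ws[:, None]
            cov = np.linalg.inv(X.T @ WX)
            coef = cov @ (WX.T @ ys)
            if abs(coef[2]) <= 3.0 * np.sqrt(cov[2, 2]):
                break
            i_hi -= max(1, (i_hi - i_lo) // 10)

    a, b, va, vb, r2 = _weighted_linfit(x[i_lo:i_hi], y[i_lo:i_hi], w[i_lo:i_hi])
    if b >= 0:
        raise ValueError("Guinier fit has non-negative slope (Rg^2 < 0)")
    rg = float(np.sqrt(-3.0 * b))
    if q[i_hi - 1] * rg > qrg_limit * 1.5:
        raise ValueError("no q-window with >= 10 points satisfies the "
                         f"q*Rg <= {qrg_limit} limit")
    rg_err = float(1.5 * np.sqrt(vb) / rg)
    i0 = float(np.exp(a))
    return GuinierResult(rg, rg_err, i0, float(i0 * np.sqrt(va)),
                         (float(q[i_lo]), float(q[i_hi - 1])),
                         float(q[i_hi - 1] * rg), float(r2))


def _ift_design(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Design matrix A with I(q) = A @ P(r) (trapezoid quadrature)."""
    dr = r[1] - r[0]
    wq = np.full(len(r), dr)
    wq[0] = wq[-1] = dr / 2
    x = np.outer(q, r)
    return 4.0 * np.pi * np.sinc(x / np.pi) * wq


def _ift_solve(curve, dmax, alpha, n_r, positivity):
    r = np.linspace(0.0, dmax, n_r)
    A = _ift_design(curve.q, r)
    # pin P(0) = P(dmax) = 0 by dropping the end columns
    Ai = A[:, 1:-1] / curve.sigma[:, None]
    yi = curve.intensity / curve.sigma
    m = n_r - 2
    D = np.zeros((m, m))           # second differences on the interior,
    for j in range(m):             # with the pinned zeros as boundary values
        D[j, j] = -2.0
        if j > 0:
            D[j, j - 1] = 1.0
        if j + 1 < m:
            D[j, j + 1] = 1.0
    scale = np.linalg.norm(Ai) / max(np.linalg.norm(D), 1e-300)
    stacked = np.vstack([Ai, np.sqrt(alpha) * scale * D])
    rhs = np.concatenate([yi, np.zeros(m)])
    sol, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
    if positivity:
        from scipy.optimize import nnls
        sol, _ = nnls(stacked, rhs)
    p = np.concatenate([[0.0], sol, [0.0]])
    resid = Ai @ sol - yi
    chi2 = float((resid ** 2).sum() / max(len(yi) - 1, 1))
    rough = float(np.sqrt((np.diff(p, 2) ** 2).sum() /
                          max((p ** 2).sum(), 1e-300)))
    return r, p, chi2, rough


def _lcurve_alpha(curve, dmax, n_r, positivity) -> float:
    """Pick alpha at the L-curve corner (max curvature in log-log)."""
    alphas = np.logspace(-8, 2, 21)
    logr, logn = [], []
    for al in alphas:
        r, p, chi2, _ = _ift_solve(curve, dmax, al, n_r, positivity)
        seminorm = np.sqrt((np.diff(p, 2) ** 2).sum())
        logr.append(np.log10(max(chi2, 1e-300)))
        logn.append(np.log10(max(seminorm, 1e-300)))
    logr, logn = np.array(logr), np.array(logn)
    # discrete curvature of the parametric curve (logr, logn)
    best, best_k = -np.inf, len(alphas) // 2
    for k in range(1, len(alphas) - 1):
        v1 = np.array([logr[k] - logr[k - 1], logn[k] - logn[k - 1]])
        v2 = np.array([logr[k + 1] - logr[k], logn[k + 1] - logn[k]])
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        curvature = cross / (n1 * n2 * (n1 + n2) / 2)
        if curvature > best:
            best, best_k = curvature, k
    return float(alphas[best_k])


def ift_pr(
    curve: ScatteringCurve,
    dmax: float | None = None,
    alpha: float | None = None,
    positivity: bool = False,
    n_r: int = 201,
) -> PairDistribution:
    """Indirect Fourier transform of I(q) to the pair distribution P(r).

    When ``dmax`` is omitted it is scanned over a grid anchored at the
    Guinier Rg and the value minimizing (reduced chi2 + roughness penalty)
    is chosen; a boundary optimum triggers a warning.  ``alpha`` defaults to
    the L-curve corner.  Real-space invariants come from the P(r) moments:
    I(0) = 4*pi*int P dr and Rg^2 = int r^2 P dr / (2 int P dr).
    """
    if dmax is not None and dmax <= 0:
        raise ValueError("dmax must be positive")

    if dmax is None:
        g = guinier_fit(curve)
        grid = np.linspace(2.0 * g.rg, 4.5 * g.rg, 26)
        scan_alpha = alpha if alpha is not None else 1e-6
        chi2s = []
        for dm in grid:
            _, _, chi2, _ = _ift_solve(curve, dm, scan_alpha, 101, positivity)
            chi2s.append(chi2)
        chi2s_arr = np.array(chi2s)
        cmin = chi2s_arr.min()
        # parsimony: the smallest Dmax that already fits (near-minimal chi2);
        # larger Dmax only adds unconstrained oscillation room
        ok = chi2s_arr <= max(1.1 * cmin, cmin + 0.05)
        k = int(np.argmax(ok))
        if k in (0, len(grid) - 1):
            warnings.warn("Dmax scan optimum at the grid boundary; the "
                          "returned Dmax may be unreliable")
        dmax = float(grid[k])

    if alpha is None:
        alpha = _lcurve_alpha(curve, dmax, n_r, positivity)
    r, p, chi2, _ = _ift_solve(curve, dmax, alpha, n_r, positivity)

    dr = r[1] - r[0]
    total = np.trapezoid(p, dx=dr)
    if total <= 0:
        raise RuntimeError("ill-conditioned P(r): non-positive integral")
    i0_real = float(4.0 * np.pi * total)
    rg2 = np.trapezoid(r ** 2 * p, dx=dr) / (2.0 * total)
    rg_real = float(np.sqrt(max(rg2, 0.0)))
    return PairDistribution(r, p, float(dmax), rg_real, i0_real,
                            float(alpha), positivity, chi2)


def _porod_invariant(curve, guinier, q_cutoff):
    """Porod invariant Q = int q^2 I dq with background correction and
    low-q Guinier completion below the measured qmin."""
    m = curve.q <= q_cutoff
    q, inten = curve.q[m], curve.intensity[m]
    sig = curve.sigma[m]
    # noise-robust smoothed intensity (inverse-variance moving average)
    w = 1.0 / sig ** 2
    kern = np.ones(11)
    smooth = np.convolve(w * inten, kern, mode="same") / \
        np.convolve(w, kern, mode="same")
    # flat background from a K/q^4 + B fit over the upper third of the range
    tail = q >= q[int(2 * len(q) / 3)]
    X = np.column_stack([q[tail] ** -4, np.ones(tail.sum())])
    coef, *_ = np.linalg.lstsq(X, smooth[tail], rcond=None)
    B = float(min(max(coef[1], 0.0), smooth.min())) if smooth.min() > 0 else 0.0
    corr = np.clip(inten - B, 0.0, None)
    Q = np.trapezoid(q ** 2 * corr, q)
    # analytic Guinier extension over [0, qmin]
    qq = np.linspace(0, q[0], 50)
    Q += np.trapezoid(qq ** 2 * guinier.i0 * np.exp(-qq ** 2 * guinier.rg ** 2 / 3),
                      qq)
    # Porod continuation beyond the cutoff: assume I ~ K'/q^4 pinned at the
    # (smoothed) measured level near q_cutoff, so the remainder integral
    # int_{qc}^inf q^2 K'/q^4 dq equals I(qc) * qc^3
    i_cut = max(float(smooth[-3:].mean() - B), 0.0)
    Q += i_cut * q[-1] ** 3
    return float(Q), B


def estimate_mw(
    curve: ScatteringCurve,
    guinier: GuinierResult,
    concentration: float | None = None,
    q_cutoff_porod: float = 0.25,
    reference_monomer_mw: float | None = None,
    porod_ratio: float = PORAD_VOLUME_TO_DA,
    vc_constant: float = VC_PROTEIN_CONSTANT,
    q_cutoff_vc: float = 0.30,
) -> MWEstimates:
    """Three molecular-weight estimates (kDa) from one curve.

    ``mw_i0`` requires the intensity-calibration metadata (I(0) in Da);
    otherwise it is None with a notice.  ``oligomer_n`` divides each
    estimate by ``reference_monomer_mw`` when given.
    """
    if curve.q[-1] < q_cutoff_porod:
        warnings.warn("curve ends before the Porod cutoff; the invariant "
                      "integral may be truncated")

    if curve.meta.get("calibrated"):
        mw_i0 = guinier.i0 / 1e3
    else:
        mw_i0 = None

    Q, background = _porod_invariant(curve, guinier, q_cutoff_porod)
    vp = 2.0 * np.pi ** 2 * guinier.i0 / Q
    mw_porod = vp / porod_ratio / 1e3

    m = curve.q <= q_cutoff_vc
    integral = np.trapezoid(curve.q[m] * curve.intensity[m], curve.q[m])
    qq = np.linspace(0, curve.q[0], 50)
    integral += np.trapezoid(
        qq * guinier.i0 * np.exp(-qq ** 2 * guinier.rg ** 2 / 3), qq)
    vc = guinier.i0 / integral
    qr = vc ** 2 / guinier.rg
    mw_vc = qr / vc_constant / 1e3

    olig = {}
    if reference_monomer_mw is not None:
        for name, mw in (("i0", mw_i0), ("porod", mw_porod), ("vc", mw_vc)):
            if mw is not None:
                olig[name] = mw / reference_monomer_mw
    return MWEstimates(
        mw_i0, float(mw_porod), float(mw_vc), olig,
        {"porod_ratio": porod_ratio, "vc_constant": vc_constant,
         "porod_background": background, "porod_q_cutoff": q_cutoff_porod,
         "vc_q_cutoff": q_cutoff_vc})
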