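"""Genetic-algorithm ensemble selection and state-population analysis.

A flexible or polydisperse protein in solution produces a scattering curve
that is the population-weighted average over its conformational ensemble.
Ensemble-optimization selects, from large pools of candidate conformers, a
small sub-ensemble (repeats allowed) whose average theoretical curve best
fits the measured one; the radius-of-gyration histogram of the selected
members, compared with the pool's, then reveals which regions of
conformational space are actually occupied.  Overlapping Rg peaks are
quantified by Gaussian decomposition — single Gaussians for simple peaks,
an equal-height double Gaussian for flat-topped ones — reporting each
state's center, full width at half maximum and percent area.

The GA operates on multisets of pool members: fitness is the reduced chi2
of the mass-scaled average curve against the experiment; elite individuals
carry over unchanged (so best-so-far fitness is monotone), the rest arise
by uniform crossover plus random member-swap mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .curves import ScatteringCurve
from .debye import fit_scale
from .conformers import ConformerPool

__all__ = ["EnsembleFit", "RgDistribution", "PeakDecomposition",
           "select_ensemble", "rg_distribution", "decompose_peaks"]


@dataclass
class EnsembleFit:
    member_refs: list          # (pool_index, member_index) pairs, repeats ok
    chi2: float
    scale: float
    constant: float
    generations_run: int
    seed: int
    pool_ids: list
    pool_weights: np.ndarray   # fraction of slots drawn from each pool
    mixture: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        n = len(self.member_refs)
        return np.full(n, 1.0 / n)


@dataclass
class RgDistribution:
    bin_centers: np.ndarray
    selected_freq: np.ndarray
    pool_freq: np.ndarray
    bin_width: float
    n_selected: int | None = None   # members behind selected_freq


@dataclass
class PeakDecomposition:
    peaks: list                # dicts: center, fwhm, area_fraction, shape
    residual_rms: float
    n_gaussians: int


def _pool_curve_matrix(pools, mass_scales):
    """Stacked normalized member curves (I(0) -> mass scale) + bookkeeping."""
    q = pools[0].q_grid
    if q is None:
        raise ValueError("pools must have precomputed curves "
                         "(call pool.compute_curves(q_grid))")
    for p in pools[1:]:
        if p.q_grid is None or len(p.q_grid) != len(q) or \
                not np.allclose(p.q_grid, q, rtol=1e-9, atol=0):
            raise ValueError("pools do not share a q grid")
    mats, owner, local = [], [], []
    for k, p in enumerate(pools):
        m = p.curves / p.curves[:, :1]
        if mass_scales is not None:
            m = m * mass_scales[k]
        mats.append(m)
        owner.append(np.full(len(p), k))
        local.append(np.arange(len(p)))
    return np.vstack(mats), np.concatenate(owner), np.concatenate(local), q


def select_ensemble(
    pools: list,
    experiment: ScatteringCurve,
    ensemble_size: int = 20,
    population: int = 50,
    generations: int = 500,
    elitism_fraction: float = 0.1,
    mutation_rate: float = 0.1,
    mass_scales=None,
    seed: int = 0,
) -> EnsembleFit:
    """Select a best-fitting sub-ensemble from one or more conformer pools.

    With multiple pools and ``mass_scales`` (per-pool relative molecular
    weight), member curves follow the calibrated-I0 convention: each is
    normalized to I(0) = mass, so a dimer pool contributes twice the
    forward scattering per selected slot.
    """
    if not pools or any(len(p) == 0 for p in pools):
        raise ValueError("empty pools")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    curves, owner, local, q = _pool_curve_matrix(pools, mass_scales)
    n_total = len(curves)

    # interpolate experiment onto the pool grid once
    exp = experiment
    lo, hi = max(q[0], exp.q[0]), min(q[-1], exp.q[-1])
    msk = (exp.q >= lo) & (exp.q <= hi)
    qe, ie, se = exp.q[msk], exp.intensity[msk], exp.sigma[msk]
    curves_e = np.empty((n_total, len(qe)))
    for i in range(n_total):
        curves_e[i] = np.interp(qe, q, curves[i])

    w = 1.0 / se ** 2
    sw = w.sum()

    def fitness(idx):
        mix = curves_e[idx].mean(axis=0)
        # closed-form scale+constant weighted LS
        a11 = np.sum(w * mix * mix)
        a12 = np.sum(w * mix)
        rhs1 = np.sum(w * mix * ie)
        rhs2 = np.sum(w * ie)
        det = a11 * sw - a12 * a12
        c = (rhs1 * sw - a12 * rhs2) / det
        b = (a11 * rhs2 - a12 * rhs1) / det
        resid = (c * mix + b - ie) / se
        return float((resid ** 2).sum() / (len(ie) - 2)), c, b

    pop = rng.integers(0, n_total, size=(population, ensemble_size))
    fits = np.array([fitness(ind)[0] for ind in pop])
    n_elite = max(1, int(round(elitism_fraction * population)))
    gens = 0
    for gens in range(1, generations + 1):
        order = np.argsort(fits)
        pop = pop[order]
        fits = fits[order]
        new = [pop[i].copy() for i in range(n_elite)]
        while len(new) < population:
            # tournament parent selection
            cands = rng.integers(0, population, 4)
            p1 = pop[min(cands[:2], key=lambda i: fits[i])]
            p2 = pop[min(cands[2:], key=lambda i: fits[i])]
            mask = rng.random(ensemble_size) < 0.5
            child = np.where(mask, p1, p2)
            mut = rng.random(ensemble_size) < mutation_rate
            child[mut] = rng.integers(0, n_total, mut.sum())
            new.append(child)
        pop = np.array(new)
        fits = np.concatenate([fits[:n_elite],
                               [fitness(ind)[0] for ind in pop[n_elite:]]])
    best = pop[np.argmin(fits)]
    chi2, c, b = fitness(best)
    refs = [(int(owner[i]), int(local[i])) for i in best]
    pw = np.array([(owner[best] == k).mean() for k in range(len(pools))])
    return EnsembleFit(refs, chi2, float(c), float(b), gens, seed,
                       [p.template_id for p in pools], pw,
                       mixture=curves_e[best].mean(axis=0),
                       params={"ensemble_size": ensemble_size,
                               "population": population,
                               "generations": generations,
                               "elitism_fraction": elitism_fraction,
                               "mutation_rate": mutation_rate,
                               "mass_scales": None if mass_scales is None
                               else list(mass_scales)})


def rg_distribution(
    fit: EnsembleFit,
    pools: list,
    bin_width: float = 0.25,
) -> RgDistribution:
    """Selected-ensemble and pool Rg histograms on a common grid."""
    all_rg = np.concatenate([p.rg_values for p in pools])
    sel_rg = np.array([pools[k].rg_values[i] for k, i in fit.member_refs])
    lo = np.floor(all_rg.min() / bin_width) * bin_width
    hi = np.ceil(all_rg.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    sel_h, _ = np.histogram(sel_rg, bins=edges)
    pool_h, _ = np.histogram(all_rg, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RgDistribution(centers, sel_h / sel_h.sum(),
                          pool_h / pool_h.sum(), bin_width,
                          n_selected=len(sel_rg))


def _gauss(x, a, mu, s):
    return a * np.exp(-0.5 * ((x - mu) / s) ** 2)


def _multi_gauss(x, *p):
    out = np.zeros_like(x)
    for j in range(len(p) // 3):
        out += _gauss(x, p[3 * j], p[3 * j + 1], p[3 * j + 2])
    return out


def _bic(y, model, k_params, sigma=None):
    n = len(y)
    if sigma is None:
        rss = float(((y - model) ** 2).sum())
        return n * np.log(max(rss / n, 1e-300)) + k_params * np.log(n)
    chi2 = float((((y - model) / sigma) ** 2).sum())
    return chi2 + k_params * np.log(n)


def _freq_sigma(y, n_selected):
    """Multinomial standard error of histogram proportions (Poisson-ish);
    makes small but many-sigma peaks statistically visible."""
    return np.sqrt(np.maximum(y, 0.5 / n_selected) / n_selected)


def _fit_k_gaussians(x, y, k, dx, sigma=None):
    """curve_fit k Gaussians initialized at the k most prominent maxima."""
    from scipy.signal import find_peaks

    # smooth lightly so single-bin spikes do not dominate peak picking
    kern = np.array([0.25, 0.5, 0.25])
    ys = np.convolve(y, kern, mode="same")
    locs, props = find_peaks(ys, prominence=0.0)
    order = np.argsort(props["prominences"])[::-1]
    centers = [x[locs[i]] for i in order[:k]]
    heights = [y[locs[i]] for i in order[:k]]
    # supplement by residual subtraction if too few maxima
    resid = y.copy()
    for c, h in zip(centers, heights):
        resid = np.clip(resid - _gauss(x, h, c, 4 * dx), 0, None)
    while len(centers) < k:
        j = int(np.argmax(resid))
        centers.append(x[j])
        heights.append(max(resid[j], 1e-9))
        resid = np.clip(resid - _gauss(x, heights[-1], centers[-1], 4 * dx),
                        0, None)
    p0 = []
    for c, h in zip(centers, heights):
        p0 += [max(h, 1e-9), c, 4 * dx]
    lo = [0, x[0] - 5 * dx, dx / 2] * k
    hi = [np.inf, x[-1] + 5 * dx, (x[-1] - x[0])] * k
    popt, _ = curve_fit(_multi_gauss, x, y, p0=p0, bounds=(lo, hi),
                        sigma=sigma, maxfev=20000)
    return popt


def _fwhm_numeric(x_dense, y_dense):
    ymax = y_dense.max()
    above = np.flatnonzero(y_dense >= ymax / 2)
    return float(x_dense[above[-1]] - x_dense[above[0]])


def decompose_peaks(
    dist: RgDistribution,
    max_peaks: int = 3,
) -> PeakDecomposition:
    """Decompose a selected-ensemble Rg distribution into Gaussian states.

    The number of Gaussians (1..max_peaks) is chosen by BIC.  Each retained
    peak is then re-tested as a flat-top: an equal-height, split-center
    double Gaussian replaces it if that lowers the BIC, and its FWHM is
    measured at half maximum of the summed pair.  Areas are integrated
    analytically and reported as percent fractions.
    """
    x = dist.bin_centers
    y = dist.selected_freq
    if (y > 0).sum() < 5:
        raise ValueError("need at least 5 occupied bins")
    dx = dist.bin_width
    # multinomial standard errors when the histogram's member count is
    # known: a small far-away peak is then many sigma above zero and BIC
    # can justify it even though its RSS contribution is tiny
    sigma = None if dist.n_selected is None else \
        _freq_sigma(y, dist.n_selected)

    best = None
    for k in range(1, max_peaks + 1):
        try:
            popt = _fit_k_gaussians(x, y, k, dx, sigma=sigma)
        except (RuntimeError, ValueError):
            continue
        # reject degenerate fits: two components piled on the same center
        # describe one peak and are pure overfitting
        cs = [(popt[3 * j + 1], popt[3 * j + 2]) for j in range(k)]
        degenerate = any(abs(cs[i][0] - cs[j][0]) < 2.0 * min(cs[i][1], cs[j][1])
                         for i in range(k) for j in range(i + 1, k))
        if k > 1 and degenerate:
            continue
        bic = _bic(y, _multi_gauss(x, *popt), 3 * k, sigma=sigma)
        if best is None or bic < best[0]:
            best = (bic, k, popt)
    if best is None:
        # moment fallback
        mu = float((x * y).sum() / y.sum())
        var = float(((x - mu) ** 2 * y).sum() / y.sum())
        import warnings
        warnings.warn("Gaussian fit failed; falling back to moments")
        return PeakDecomposition(
            [{"center": mu, "fwhm": 2.355 * np.sqrt(var),
              "area_fraction": 100.0, "shape": "gaussian"}],
            float(np.sqrt(((y - y.mean()) ** 2).mean())), 1)
    bic0, k, popt = best
    comps = [(popt[3 * j], popt[3 * j + 1], popt[3 * j + 2]) for j in range(k)]

    # flat-top refinement per peak: equal heights, split centers, common sigma
    peaks = []
    areas = []
    model_total = _multi_gauss(x, *popt)
    for a, mu, s in comps:
        others = model_total - _gauss(x, a, mu, s)
        resid_y = y - others

        def dbl(xx, aa, c1, c2, ss):
            return _gauss(xx, aa, c1, ss) + _gauss(xx, aa, c2, ss)

        try:
            p0 = [a / 2,
                  float(np.clip(mu - s, x[0], x[-1])),
                  float(np.clip(mu + s, x[0], x[-1])),
                  float(np.clip(s, dx / 2, x[-1] - x[0]))]
            popt2, _ = curve_fit(
                dbl, x, resid_y, p0=p0,
                bounds=([0, x[0], x[0], dx / 2],
                        [np.inf, x[-1], x[-1], x[-1] - x[0]]),
                sigma=sigma, maxfev=20000)
            bic_single = _bic(resid_y, _gauss(x, a, mu, s), 3, sigma=sigma)
            bic_double = _bic(resid_y, dbl(x, *popt2), 4, sigma=sigma)
            # positive evidence required, and the split must be real (a
            # coincident pair is just a single Gaussian re-parameterized)
            is_flat = (bic_double < bic_single - 2.0
                       and abs(popt2[2] - popt2[1]) > popt2[3])
        except (RuntimeError, ValueError):
            is_flat = False
        if is_flat:
            aa, c1, c2, ss = popt2
            xd = np.linspace(min(c1, c2) - 5 * ss, max(c1, c2) + 5 * ss, 2000)
            fwhm = _fwhm_numeric(xd, dbl(xd, aa, c1, c2, ss))
            area = 2 * aa * ss * np.sqrt(2 * np.pi)
            peaks.append({"center": float((c1 + c2) / 2), "fwhm": fwhm,
                          "shape": "double_gaussian"})
        else:
            area = a * s * np.sqrt(2 * np.pi)
            peaks.append({"center": float(mu),
                          "fwhm": float(2.0 * np.sqrt(2 * np.log(2)) * s),
                          "shape": "gaussian"})
        areas.append(area)

    total = sum(areas)
    for pk, ar in zip(peaks, areas):
        pk["area_fraction"] = float(100.0 * ar / total)
    # absorb insignificant (< 3%) peaks into their nearest neighbour:
    # only significant ensemble members are reported
    while len(peaks) > 1 and min(p["area_fraction"] for p in peaks) < 3.0:
        j = min(range(len(peaks)), key=lambda i: peaks[i]["area_fraction"])
        small = peaks.pop(j)
        near = min(range(len(peaks)),
                   key=lambda i: abs(peaks[i]["center"] - small["center"]))
        peaks[near]["area_fraction"] += small["area_fraction"]
    peaks.sort(key=lambda p: p["center"])
    resid_rms = float(np.sqrt(((y - model_total) ** 2).mean()))
    return PeakDecomposition(peaks, resid_rms, k)
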