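"""1-D SAXS curve container and reduction operations.

A solution-scattering experiment yields a rotationally averaged intensity
profile I(q) with statistical uncertainties sigma(q), where
q = 4*pi*sin(theta)/lambda is the momentum transfer in inverse angstroms.
This module handles the text-file exchange format used by data banks such
as SASBDB (3 whitespace-separated columns: q, I, sigma), frame averaging
with outlier rejection, buffer subtraction with a differential-transmission
correction, and absolute-scale calibration that makes the extrapolated
forward scattering I(0) read out as a molecular weight in daltons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScatteringCurve",
    "CurveFormatError",
    "InsufficientDataError",
    "read_curve",
    "write_curve",
    "average_frames",
    "subtract_buffer",
    "calibrate_intensity",
]


class CurveFormatError(ValueError):
    """Raised when a curve file cannot be parsed."""


class InsufficientDataError(ValueError):
    """Raised when fewer than the minimum usable data rows are present."""


@dataclass
class ScatteringCurve:
    """A 1-D scattering profile I(q) with 1-sigma uncertainties.

    Parameters
    ----------
    q : array
        Momentum transfer grid in inverse angstroms; strictly increasing,
        all positive.
    intensity : array
        Scattered intensity, arbitrary units (or daltons once calibrated).
    sigma : array
        1-sigma uncertainty of ``intensity``, same units; all positive.
    meta : dict
        Free-form metadata (concentration in mg/mL, exposure hours, label,
        calibration record, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ValueError("q, intensity and sigma must have equal length")
        if len(self.q) == 0:
            raise ValueError("empty curve")
        if np.any(self.q <= 0):
            raise ValueError("all q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be positive")

    def __len__(self) -> int:
        return len(self.q)

    def crop(self, qmin: float = -np.inf, qmax: float = np.inf) -> "ScatteringCurve":
        """Return the sub-curve with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        if not m.any():
            raise ValueError(f"no points in q-window [{qmin}, {qmax}]")
        return ScatteringCurve(self.q[m], self.intensity[m], self.sigma[m],
                               dict(self.meta))

    def copy(self) -> "ScatteringCurve":
        return ScatteringCurve(self.q.copy(), self.intensity.copy(),
                               self.sigma.copy(), dict(self.meta))


def read_curve(path, format: str = "dat3col") -> ScatteringCurve:
    """Read a 3-column (q, I, sigma) text file.

    Comment lines start with '#' and are kept in ``meta['header']``.  Rows
    with non-positive q or sigma are dropped; the count is recorded in
    ``meta['n_dropped']``.

    Raises
    ------
    CurveFormatError
        If a non-comment line does not contain 3 numeric columns.
    InsufficientDataError
        If fewer than 5 valid rows remain.
    """
    if format != "dat3col":
        raise ValueError(f"unknown format {format!r}")
    header: list[str] = []
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                header.append(s.lstrip("# ").rstrip())
                continue
            parts = s.split()
            if len(parts) < 3:
                raise CurveFormatError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                vals = tuple(float(p) for p in parts[:3])
            except ValueError as exc:
                raise CurveFormatError(
                    f"{path}: line {lineno}: non-numeric value") from exc
            rows.append(vals)
    arr = np.array(rows, dtype=float).reshape(-1, 3)
    good = (arr[:, 0] > 0) & (arr[:, 2] > 0)
    n_dropped = int((~good).sum())
    arr = arr[good]
    if len(arr) < 5:
        raise InsufficientDataError(
            f"{path}: only {len(arr)} valid rows (need >= 5)")
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    meta = {"header": header, "n_dropped": n_dropped, "source": str(path)}
    # recover simple key: value pairs from the header
    for h in header:
        if ":" in h:
            key, _, val = h.partition(":")
            key = key.strip().lower().replace(" ", "_")
            val = val.strip()
            try:
                meta[key] = float(val)
            except ValueError:
                if val:
                    meta[key] = val
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], meta)


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write a curve as 3-column text with metadata in '#' header lines."""
    with open(path, "w") as fh:
        for key, val in curve.meta.items():
            if key in ("header", "n_dropped", "source"):
                continue
            fh.write(f"# {key}: {val}\n")
        fh.write("#         q      intensity          sigma\n")
        for qi, ii, si in zip(curve.q, curve.intensity, curve.sigma):
            fh.write(f"{qi:.6e} {ii:.6e} {si:.6e}\n")


def _check_common_grid(frames: Sequence[ScatteringCurve]) -> None:
    q0 = frames[0].q
    for f in frames[1:]:
        if len(f.q) != len(q0) or not np.allclose(f.q, q0, rtol=1e-9, atol=0):
            raise ValueError("frames are not on a common q grid")


def average_frames(
    frames: Sequence[ScatteringCurve],
    similarity_alpha: float = 0.01,
) -> tuple[ScatteringCurve, dict]:
    """Average repeated exposures of the same sample, rejecting outliers.

    Each frame is compared against the error-weighted mean of the *other*
    frames by reduced chi-squared; frames exceeding the upper
    ``1 - similarity_alpha`` quantile of the chi-squared distribution are
    rejected (radiation damage / instability screening).  Survivors are
    combined by inverse-variance weighting.

    Returns the averaged curve and a report dict with ``rejected`` (indices)
    and ``chi2`` (per-frame reduced chi2 against the rest).
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    _check_common_grid(frames)
    if len(frames) == 1:
        return frames[0].copy(), {"rejected": [], "chi2": [0.0]}

    I = np.stack([f.intensity for f in frames])
    V = np.stack([f.sigma for f in frames]) ** 2
    W = 1.0 / V
    n = len(frames)
    npts = I.shape[1]
    threshold = stats.chi2.ppf(1.0 - similarity_alpha, df=npts) / npts

    # reference = elementwise median curve: robust against a strong
    # outlier frame dragging a mean reference toward itself (masking)
    median = np.median(I, axis=0)
    var_med = np.median(V, axis=0) * (np.pi / 2) / n
    chi2s = []
    for i in range(n):
        chi2 = np.mean((I[i] - median) ** 2 / (V[i] + var_med))
        chi2s.append(float(chi2))
    chi2s_arr = np.array(chi2s)
    keep = chi2s_arr <= threshold
    if not keep.any():
        raise ValueError("all frames rejected by the similarity test")
    rejected = [int(i) for i in np.flatnonzero(~keep)]

    w = W[keep]
    avg = (w * I[keep]).sum(axis=0) / w.sum(axis=0)
    sig = np.sqrt(1.0 / w.sum(axis=0))
    meta = dict(frames[0].meta)
    meta["n_frames_averaged"] = int(keep.sum())
    meta["n_frames_rejected"] = len(rejected)
    out = ScatteringCurve(frames[0].q.copy(), avg, sig, meta)
    return out, {"rejected": rejected, "chi2": chi2s}


def subtract_buffer(
    sample: ScatteringCurve,
    buffer: ScatteringCurve,
    q_window: tuple[float, float] = (0.1, 0.7),
    transmission: float | None = None,
) -> tuple[ScatteringCurve, float]:
    """Subtract buffer scattering with a differential-transmission correction.

    For a dilute macromolecule the net signal I/sigma falls below 1 sigma in
    the high-q part of the accessible range, so the subtracted intensity
    should average to zero there.  The buffer is interpolated onto the
    sample grid (linear, no extrapolation — points outside the buffer range
    are trimmed) and a scalar transmission factor ``t`` is solved so that
    the error-weighted mean of ``I_s - t*I_b`` over ``q_window`` vanishes.
    A mismatch |t - 1| > 0.1 triggers a warning, as does a window with
    fewer than 20 points (then t falls back to 1).

    Pass ``transmission`` to fix t externally instead of fitting it.

    Returns (subtracted curve, t).
    """
    lo, hi = buffer.q[0], buffer.q[-1]
    samp = sample.crop(lo, hi) if (sample.q[0] < lo or sample.q[-1] > hi) else sample
    ib = np.interp(samp.q, buffer.q, buffer.intensity)
    sb = np.interp(samp.q, buffer.q, buffer.sigma)

    w0, w1 = q_window
    if w0 > samp.q[-1] or w1 < samp.q[0]:
        raise ValueError(f"q-window {q_window} outside data range "
                         f"({samp.q[0]:.4g}-{samp.q[-1]:.4g})")
    win = (samp.q >= w0) & (samp.q <= w1)

    if transmission is not None:
        t = float(transmission)
    elif win.sum() < 20:
        warnings.warn(f"only {int(win.sum())} points in the transmission "
                      "window; falling back to t = 1")
        t = 1.0
    else:
        # solve t so the weighted mean of I_s - t*I_b vanishes over the
        # window.  The premise is that the net macromolecular signal is
        # below noise there; where it clearly is not (a systematic positive
        # run of residuals at the low-q side of the window, detected on a
        # smoothed residual), the window start is trimmed upward.  Trimming
        # only ever removes a low-q prefix, so noise cannot be self-selected.
        idx = np.flatnonzero(win)
        lo_k = 0

        def _solve(k):
            sel = idx[k:]
            w = 1.0 / (samp.sigma[sel] ** 2 + sb[sel] ** 2)
            denom = np.sum(w * ib[sel])
            if denom <= 0:
                raise RuntimeError("transmission fit failed: non-positive "
                                   "buffer signal in window")
            return float(np.sum(w * samp.intensity[sel]) / denom)

        half = 5   # smoothing half-width (points) for the run test
        for _ in range(len(idx)):
            t = _solve(lo_k)
            sel = idx[lo_k:]
            if len(sel) <= 20:
                break
            z = (samp.intensity[sel] - t * ib[sel]) / \
                np.sqrt(samp.sigma[sel] ** 2 + (t * sb[sel]) ** 2)
            kern = np.ones(2 * half + 1)
            zs = np.convolve(z, kern, mode="same") / \
                np.convolve(np.ones_like(z), kern, mode="same")
            # standard error of the smoothed residual ~ 1/sqrt(#points)
            if zs[0] > 1.0 / np.sqrt(2 * half + 1):
                lo_k += 1
            else:
                break
        t = _solve(lo_k)
        if t < 0:
            raise RuntimeError(f"transmission fit failed: t = {t:.3g} < 0")
        if abs(t - 1.0) > 0.1:
            warnings.warn(f"transmission factor t = {t:.3f} differs from 1 "
                          "by more than 10%")

    sub_i = samp.intensity - t * ib
    sub_s = np.sqrt(samp.sigma ** 2 + (t * sb) ** 2)
    meta = dict(samp.meta)
    meta["transmission"] = t
    if win.sum() > 0:
        w = 1.0 / sub_s[win] ** 2
        mean_resid = np.sum(w * sub_i[win]) / np.sum(w)
        mean_sig = np.sqrt(1.0 / np.sum(w))
        meta["window_residual_ok"] = bool(abs(mean_resid) < mean_sig)
    return ScatteringCurve(samp.q.copy(), sub_i, sub_s, meta), t


def calibrate_intensity(
    curve: ScatteringCurve,
    concentration: float,
    calibration_constant: float,
) -> ScatteringCurve:
    """Put a curve on the molecular-weight scale.

    Multiplies intensity and sigma by ``calibration_constant/concentration``
    so that the extrapolated forward scattering I(0) equals the molecular
    weight in daltons.  The calibration constant (Da * mL/mg per intensity
    unit) comes from protein MW standards measured on the same camera.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if calibration_constant <= 0:
        raise ValueError("calibration constant must be positive")
    fac = calibration_constant / concentration
    meta = dict(curve.meta)
    meta["calibrated"] = True
    meta["concentration"] = concentration
    meta["calibration_constant"] = calibration_constant
    return ScatteringCurve(curve.q.copy(), curve.intensity * fac,
                           curve.sigma * fac, meta)
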