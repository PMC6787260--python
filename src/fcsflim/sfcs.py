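"""Scanning-FCS analysis: drift alignment, multi-tau autocorrelation, and
fits of the 2D membrane-diffusion and 3D point-FCS models.

The measurement this module analyses is a repeated line scan (``xt`` mode)
across the equator of a giant unilamellar vesicle.  Each pass across the
membrane yields one intensity sample; the autocorrelation of that per-line
trace decays with the diffusion time tau_D of the membrane-bound molecules
through the focus, and the diffusion coefficient follows from the calibrated
beam waist as ``D = w_o**2 / (4 * tau_D)``.

The 2D model fitted to membrane curves is

    G(tau) = (1/N) * (1 + tau/tau_D)**-1/2 * (1 + tau/(S**2 tau_D))**-1/2

with N the mean number of molecules in the focal area and S = z_o/w_o the
axial-to-radial aspect ratio of the confocal volume, fixed from a dye
calibration (the model is only weakly sensitive to S, so floating it on
membrane data would be degenerate).  Point measurements of a calibration dye
use the standard 3D model with an extra (1 + tau/tau_D)**-1/2 factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .errors import (
    EdgeClippingError,
    ImplausibleGeometryWarning,
    MembraneNotFoundError,
    NormalizationError,
)
from .tcspc import LineScanMatrix, PhotonStream


@dataclass
class MembraneTrace:
    """Per-line membrane photon counts after drift alignment."""

    intensity: np.ndarray  # photon counts per line within the aperture
    dt: float  # s, the line period
    center_trajectory: np.ndarray | None = None  # fractional pixel per line


@dataclass
class CorrelationCurve:
    """Normalised fluctuation autocorrelation with per-lag error bars."""

    lags: np.ndarray  # s, strictly increasing, first lag >= dt
    G: np.ndarray
    G_sd: np.ndarray  # standard error of the segment mean
    n_segments: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lag_s": self.lags, "G": self.G, "G_sd": self.G_sd})


@dataclass
class FocusCalibration:
    """Confocal detection-volume geometry from a reference-dye measurement."""

    beam_waist: float  # w_o, µm
    axial_waist: float  # z_o, µm
    reference_d: float | None = None  # µm²/s of the dye used

    @property
    def aspect(self) -> float:
        """S = z_o / w_o."""
        return self.axial_waist / self.beam_waist

    def to_json(self) -> str:
        import json

        return json.dumps(
            {"beam_waist_um": self.beam_waist, "axial_waist_um": self.axial_waist,
             "aspect": self.aspect, "reference_d_um2_s": self.reference_d},
            indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FocusCalibration":
        import json

        d = json.loads(text)
        return cls(beam_waist=d["beam_waist_um"], axial_waist=d["axial_waist_um"],
                   reference_d=d.get("reference_d_um2_s"))


@dataclass
class DiffusionFit:
    """Result of fitting the 2D (or 3D) diffusion model to a curve."""

    n: float  # mean molecules in the focal area
    tau_d: float  # s
    d: float  # µm²/s, = w_o**2 / (4 tau_d) given the calibration
    s: float  # aspect ratio used (fixed for 2D, fitted for 3D)
    n_err: float = np.nan
    tau_d_err: float = np.nan
    chi2red: float = np.nan
    converged: bool = True
    at_bound: bool = False
    model: str = "2d"

    @property
    def flagged(self) -> bool:
        """True when the fit must not be used silently."""
        return (not self.converged) or self.at_bound


def model_g2d(tau, n, tau_d, s):
    """2D membrane-diffusion autocorrelation (scanned focus).

    ``G(tau) = (1/n)(1 + tau/tau_d)^-1/2 (1 + tau/(s^2 tau_d))^-1/2``
    """
    n, tau_d, s = float(n), float(tau_d), float(s)
    if n <= 0 or tau_d <= 0 or s <= 0:
        raise ValueError("model_g2d requires n, tau_d, s > 0")
    tau = np.asarray(tau, dtype=float)
    return (1.0 / n) / np.sqrt((1.0 + tau / tau_d) * (1.0 + tau / (s * s * tau_d)))


def model_g3d(tau, n, tau_d, s):
    """Standard 3D free-diffusion autocorrelation for point FCS."""
    n, tau_d, s = float(n), float(tau_d), float(s)
    if n <= 0 or tau_d <= 0 or s <= 0:
        raise ValueError("model_g3d requires n, tau_d, s > 0")
    tau = np.asarray(tau, dtype=float)
    return (1.0 / n) / ((1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (s * s * tau_d)))


# ---------------------------------------------------------------------------
# correlator
# ---------------------------------------------------------------------------

def _multitau_segment(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Multi-tau autocorrelation of one segment.

    Lags 1..2m are computed on the raw trace; the trace is then binned by 2
    and lags m+1..2m (in binned units) added per octave.  Normalisation is
    the symmetric estimator G(k) = <F_i F_{i+k}> / (mean_left * mean_right) - 1,
    which is exactly zero for a constant trace and robust to slow trends.
    Returns (lags in samples, G).
    """
    lags: list[float] = []
    g: list[float] = []
    y = x.astype(float)
    scale = 1
    level = 0
    while True:
        kmin = 1 if level == 0 else m + 1
        for k in range(kmin, 2 * m + 1):
            nn = y.size - k
            if nn < 8:
                return np.asarray(lags), np.asarray(g)
            a = y[:nn]
            b = y[k:]
            ma = a.mean()
            mb = b.mean()
            denom = ma * mb
            g.append(float((a @ b) / nn / denom - 1.0) if denom > 0 else 0.0)
            lags.append(float(k * scale))
        n2 = (y.size // 2) * 2
        if n2 < 2 * (2 * m + 8):
            return np.asarray(lags), np.asarray(g)
        y = y[0:n2:2] + y[1:n2:2]
        scale *= 2
        level += 1


def autocorrelate(trace: MembraneTrace, m: int = 8, n_segments: int = 10) -> CorrelationCurve:
    """Segmented multi-tau autocorrelation of a photon-count trace.

    The trace is split into ``n_segments`` equal blocks; G is the mean over
    segments and G_sd the segment standard deviation / sqrt(n_segments).
    The first lag equals the sampling interval ``trace.dt`` (for sFCS, the
    inverse of the scanning frequency).
    """
    x = np.asarray(trace.intensity, dtype=float)
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if x.size < 8 * m:
        raise ValueError(f"trace too short for m={m} (need >= {8 * m} samples)")
    if x.mean() <= 0:
        raise NormalizationError("cannot normalise a zero-mean trace")
    seg_len = x.size // n_segments
    per_seg = []
    lags0 = None
    for s in range(n_segments):
        lags, g = _multitau_segment(x[s * seg_len:(s + 1) * seg_len], m)
        if lags0 is None or lags.size < lags0.size:
            lags0 = lags
        per_seg.append(g)
    nl = lags0.size
    gmat = np.vstack([g[:nl] for g in per_seg])
    return CorrelationCurve(
        lags=lags0 * trace.dt,
        G=gmat.mean(axis=0),
        G_sd=gmat.std(axis=0, ddof=1) / np.sqrt(n_segments),
        n_segments=n_segments,
    )


def direct_autocorrelation(x: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force direct-sum correlator (oracle-grade, O(n*max_lag)).

    Same symmetric normalisation as the multi-tau estimator; returns lags in
    samples and G, for lags 1..max_lag.
    """
    import math

    x = np.asarray(x, dtype=float)
    lags = np.arange(1, max_lag + 1)
    g = np.empty(lags.size)
    for j, k in enumerate(lags):
        nn = x.size - k
        acc = math.fsum(x[i] * x[i + k] for i in range(nn))
        ma = math.fsum(x[:nn]) / nn
        mb = math.fsum(x[k:]) / nn
        g[j] = acc / nn / (ma * mb) - 1.0
    return lags.astype(float), g


# ---------------------------------------------------------------------------
# drift alignment
# ---------------------------------------------------------------------------

def _gaussian_profile(x, amp, center, sigma, offset):
    return offset + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _fit_gaussian_blocks(profiles: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Gaussian peak centres of many line profiles at once.

    Damped Gauss-Newton on (amp, center, sigma, offset) per block, with all
    blocks advanced simultaneously; equivalent to per-profile least-squares
    Gaussian fits but vectorised.  Returns the fitted centres (pixels).
    """
    n_blocks, n_pixels = profiles.shape
    x = np.arange(n_pixels, dtype=float)

    def model_of(p):
        u = (x[None, :] - p[:, 1, None]) / p[:, 2, None]
        e = np.exp(-0.5 * u * u)
        return p[:, 3, None] + p[:, 0, None] * e, e, u

    def clipped(p):
        p = p.copy()
        p[:, 0] = np.maximum(p[:, 0], 1e-9)
        p[:, 1] = np.clip(p[:, 1], 0.0, n_pixels - 1.0)
        p[:, 2] = np.clip(p[:, 2], 0.3, n_pixels / 2.0)
        p[:, 3] = np.maximum(p[:, 3], 0.0)
        return p

    off = np.median(profiles, axis=1)
    params = np.column_stack([
        np.maximum(profiles.max(axis=1) - off, 1e-6),
        profiles.argmax(axis=1).astype(float),
        np.full(n_blocks, 2.0),
        off,
    ])
    lam = np.full(n_blocks, 1e-2)
    model, e, u = model_of(params)
    r = profiles - model
    resid = np.einsum("bp,bp->b", r, r)
    for _ in range(n_iter):
        amp, sig = params[:, 0, None], params[:, 2, None]
        jac = np.stack([e, amp * e * u / sig, amp * e * u * u / sig,
                        np.ones_like(e)], axis=2)  # [B, P, 4]
        jtj = np.einsum("bpi,bpj->bij", jac, jac)
        jtr = np.einsum("bpi,bp->bi", jac, r)
        diag = np.arange(4)
        jtj[:, diag, diag] *= 1.0 + lam[:, None]
        jtj[:, diag, diag] += 1e-12
        try:
            step = np.linalg.solve(jtj, jtr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        trial = clipped(params + step)
        t_model, t_e, t_u = model_of(trial)
        t_r = profiles - t_model
        t_resid = np.einsum("bp,bp->b", t_r, t_r)
        accept = t_resid <= resid
        params = np.where(accept[:, None], trial, params)
        lam = np.where(accept, lam * 0.3, lam * 5.0)
        e = np.where(accept[:, None], t_e, e)
        u = np.where(accept[:, None], t_u, u)
        r = np.where(accept[:, None], t_r, r)
        resid = np.where(accept, t_resid, resid)
        if np.max(np.where(accept, np.abs(step[:, 1]), 0.0)) < 1e-6 and accept.any():
            break
    return params[:, 1]


def align_membrane(xt: LineScanMatrix, smooth_lines: int = 70, aperture_px: int = 4) -> MembraneTrace:
    """Track the membrane across the scan and extract the aligned trace.

    The matrix is block-averaged over ``smooth_lines`` lines; each block's
    line profile is fitted with a Gaussian to locate the membrane centre,
    centres are linearly interpolated to a per-line trajectory, and the
    per-line intensity is the photon sum over a fixed-width window of
    ``aperture_px + 1`` pixels centred on the rounded fractional centre
    (nearest-pixel summation preserves integer photon counts).
    """
    counts = xt.counts
    n_lines, n_pixels = counts.shape
    profile = counts.mean(axis=0)
    bg = float(np.median(profile))
    peak = float(profile.max())
    # the peak must be a clear outlier against the profile's own scatter;
    # a MAD-based z > 5 separates any usable membrane from the ~3-sigma
    # extremes a featureless Poisson profile reaches across 64 pixels
    mad = float(np.median(np.abs(profile - bg)))
    noise = 1.4826 * mad + np.sqrt(bg / max(n_lines, 1) + 1e-12) * 1e-3 + 1e-9
    if (peak - bg) / noise < 5.0 or peak <= 0:
        raise MembraneNotFoundError("no membrane peak detectable above background")

    n_blocks = max(1, n_lines // smooth_lines)
    edges = np.linspace(0, n_lines, n_blocks + 1).astype(int)
    sums = np.add.reduceat(counts, edges[:-1], axis=0)
    widths = np.diff(edges)[:, None]
    centers = _fit_gaussian_blocks(sums / widths)
    # guard against stray block fits: smooth drift never jumps pixels
    if centers.size >= 5:
        from scipy.ndimage import median_filter

        smooth = median_filter(centers, size=9, mode="nearest")
        bad = np.abs(centers - smooth) > 3.0
        centers[bad] = smooth[bad]
    block_mid = 0.5 * (edges[:-1] + edges[1:] - 1)

    trajectory = np.interp(np.arange(n_lines, dtype=float), block_mid, centers)
    half = aperture_px // 2
    med = float(np.median(trajectory))
    if med - half < 0.5 or med + half > n_pixels - 1.5:
        raise EdgeClippingError(
            f"membrane at pixel {med:.1f} is within the aperture of the matrix edge")

    cols = np.rint(trajectory).astype(int)[:, None] + np.arange(-half, half + 1)[None, :]
    np.clip(cols, 0, n_pixels - 1, out=cols)
    intensity = counts[np.arange(n_lines)[:, None], cols].sum(axis=1)
    return MembraneTrace(intensity=intensity, dt=xt.line_period, center_trajectory=trajectory)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def _weights(curve: CorrelationCurve) -> np.ndarray:
    sd = np.asarray(curve.G_sd, dtype=float)
    if not np.any(sd > 0):
        return np.ones_like(sd)
    floor = sd[sd > 0].min()
    return 1.0 / np.maximum(sd, floor)


def _init_tau(curve: CorrelationCurve) -> float:
    """Lag where G first drops below half its first value (crude tau_D)."""
    g0 = curve.G[0]
    below = np.nonzero(curve.G < 0.5 * g0)[0]
    if g0 <= 0 or below.size == 0:
        return float(curve.lags[min(3, curve.lags.size - 1)])
    return float(curve.lags[below[0]])


def _fit_window(curve: CorrelationCurve, frac: float, floor: int = 12) -> CorrelationCurve:
    """Restrict a curve to lags where G is above ``frac`` of its first value.

    The informative part of an FCS curve ends once G has decayed to a few
    percent of its amplitude; beyond that the fat tail of the diffusion
    models carries almost no parameter information while real measurements
    (membrane undulations, residual drift) and finite simulations deviate
    from the ideal baseline.  At least ``floor`` lags are always kept.
    """
    g0 = curve.G[0]
    if g0 <= 0 or frac <= 0:
        return curve
    below = np.nonzero(curve.G < frac * g0)[0]
    hi = int(below[0]) if below.size else curve.lags.size
    hi = min(max(hi, floor), curve.lags.size)
    return CorrelationCurve(lags=curve.lags[:hi], G=curve.G[:hi],
                            G_sd=curve.G_sd[:hi], n_segments=curve.n_segments)


def fit_diffusion(curve: CorrelationCurve, calib: FocusCalibration,
                  m_model: str = "2d", fit_window_frac: float = 0.10,
                  fit_baseline: bool = False) -> DiffusionFit:
    """Weighted least-squares fit of the 2D model over (N, tau_D), S fixed.

    Weights are 1/G_sd (unit weights when G_sd is absent); the diffusion
    coefficient is ``D = w_o**2 / (4 tau_D)`` with w_o from the calibration.
    The fit window ends where G has decayed to ``fit_window_frac`` of its
    first-lag value (see :func:`_fit_window`).  ``fit_baseline`` frees a
    constant offset G_inf, the usual guard against residual long-time
    correlations.  Non-convergence or tau_D pinned at a parameter bound is
    flagged on the returned fit rather than silently reported.
    """
    if curve.lags.size < 10:
        raise ValueError("need >= 10 lags to fit the diffusion model")
    curve = _fit_window(curve, fit_window_frac)
    s_fixed = calib.aspect
    tau_lo, tau_hi = curve.lags[0] / 100.0, curve.lags[-1] * 10.0
    g0 = max(curve.G[0], 1e-6)
    params = lmfit.Parameters()
    params.add("n", value=1.0 / g0, min=1e-8)
    params.add("tau_d", value=min(max(_init_tau(curve), tau_lo * 2), tau_hi / 2),
               min=tau_lo, max=tau_hi)
    params.add("g_inf", value=0.0, min=-0.5, max=0.5, vary=fit_baseline)
    w = _weights(curve)
    model_fn = model_g2d if m_model == "2d" else model_g3d

    def resid(p):
        return (model_fn(curve.lags, p["n"].value, p["tau_d"].value, s_fixed)
                + p["g_inf"].value - curve.G) * w

    out = lmfit.minimize(resid, params, method="leastsq")
    tau_d = float(out.params["tau_d"].value)
    n = float(out.params["n"].value)
    at_bound = tau_d <= tau_lo * 1.01 or tau_d >= tau_hi * 0.99
    d = calib.beam_waist ** 2 / (4.0 * tau_d)
    nfree = max(curve.lags.size - 2, 1)
    return DiffusionFit(
        n=n, tau_d=tau_d, d=d, s=s_fixed,
        n_err=float(out.params["n"].stderr or np.nan),
        tau_d_err=float(out.params["tau_d"].stderr or np.nan),
        chi2red=float(np.sum(out.residual ** 2) / nfree),
        converged=bool(out.success), at_bound=at_bound, model=m_model)


def calibrate_focus(curve: CorrelationCurve, d_ref: float,
                    fit_window_frac: float = 0.05) -> FocusCalibration:
    """Determine w_o and z_o from a 3D point measurement of a reference dye.

    Fits the standard 3D model over (N, tau_D, S) and converts
    ``w_o = sqrt(4 * D_ref * tau_D)``, ``z_o = S * w_o``.  An aspect ratio
    below 1 triggers an implausible-geometry warning.
    """
    if curve.lags.size < 10:
        raise ValueError("need >= 10 lags to calibrate")
    curve = _fit_window(curve, fit_window_frac)
    g0 = max(curve.G[0], 1e-6)
    tau_lo, tau_hi = curve.lags[0] / 100.0, curve.lags[-1] * 10.0
    w = _weights(curve)

    def resid(p):
        return (model_g3d(curve.lags, p["n"].value, p["tau_d"].value, p["s"].value)
                - curve.G) * w

    out = None
    for s0 in (5.0, 1.0, 0.5):  # multi-start: S is prone to local minima
        params = lmfit.Parameters()
        params.add("n", value=1.0 / g0, min=1e-8)
        params.add("tau_d", value=min(max(_init_tau(curve), tau_lo * 2), tau_hi / 2),
                   min=tau_lo, max=tau_hi)
        params.add("s", value=s0, min=0.3, max=100.0)
        trial = lmfit.minimize(resid, params, method="leastsq")
        if out is None or np.sum(trial.residual ** 2) < np.sum(out.residual ** 2):
            out = trial
    if not out.success:
        warnings.warn("focal-volume calibration fit did not converge",
                      ImplausibleGeometryWarning)
    tau_d = float(out.params["tau_d"].value)
    s = float(out.params["s"].value)
    if s < 1.0:
        warnings.warn(f"fitted aspect ratio S={s:.2f} < 1 is implausible",
                      ImplausibleGeometryWarning)
    w_o = float(np.sqrt(4.0 * d_ref * tau_d))
    return FocusCalibration(beam_waist=w_o, axial_waist=s * w_o, reference_d=d_ref)


def bin_photon_stream(stream: PhotonStream, bin_width: float) -> MembraneTrace:
    """Bin a marker-less (point-measurement) stream into an intensity trace."""
    ticks = bin_width * stream.clock_hz
    duration_ticks = float(stream.metadata.get(
        "duration_ticks", stream.macro_times[-1] + 1 if stream.n_photons else ticks))
    n_bins = int(np.ceil(duration_ticks / ticks))
    idx = np.minimum((stream.macro_times / ticks).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return MembraneTrace(intensity=counts, dt=bin_width)
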