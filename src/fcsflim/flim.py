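"""TCSPC decay fitting and dimerisation quantification.

FRET shortens the donor fluorescence lifetime, so the per-pixel (or
per-cell) decay of a donor in a partly dimerised population is a mixture of
a donor-only exponential (lifetime tau_D) and a FRET-quenched exponential
(tau_DA), both convolved with the instrument response.  The amplitude
fraction of the quenched component is the effective fraction of donors
undergoing FRET, f_D^eff.

The dimerisation efficiency E_D normalises f_D^eff for donor/acceptor
abundance.  Under random pairing of protomers, a donor sits in a dimer with
probability p (the dimerised protomer fraction) and its partner is an
acceptor with probability C_A/(C_D + C_A); hence
``f_D^eff = p * C_A / (C_D + C_A)`` and

    E_D = f_D^eff * (C_D + C_A) / C_A  =  p

which is independent of the donor:acceptor ratio — the property that makes
E_D comparable between cells.  This normalisation is a reconstruction: it is
the unique random-pairing correction with that invariance (see the methods
note).

Decay fits minimise the Poisson deviance (maximum likelihood for counting
data) rather than least squares, since low-count TCSPC bins violate
Gaussian assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy.optimize import minimize, nnls, curve_fit
from scipy.special import erfc

from .errors import (
    EmptyMapWarning,
    IllConditionedWarning,
    InsufficientDataError,
    UndefinedEfficiencyError,
)
from .tcspc import DecayHistogram, FlimImage

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = FWHM / (2 sqrt(2 ln 2))


@dataclass
class LifetimeModel:
    """Donor-only / FRET-quenched decay components and IRF description.

    Lifetimes in ns; ``background`` is counts per micro-time bin.  ``tau_da``
    may be None for a mono-exponential (donor-only) model.
    """

    tau_d: float  # ns, donor-only lifetime
    tau_da: float | None = None  # ns, FRET-quenched lifetime
    irf_fwhm: float = 0.3  # ns
    irf_t0: float = 2.0  # ns, IRF centre within the micro-time window
    background: float = 0.0  # counts per bin

    def __post_init__(self) -> None:
        if self.tau_d <= 0:
            raise ValueError("tau_d must be > 0")
        if self.tau_da is not None and not (0 < self.tau_da < self.tau_d):
            raise ValueError("need 0 < tau_da < tau_d")

    @property
    def irf_sigma(self) -> float:
        return self.irf_fwhm * _FWHM_TO_SIGMA


def decay_shape(t: np.ndarray, tau: float, irf_sigma: float, t0: float) -> np.ndarray:
    """Exponential decay convolved with a Gaussian IRF, analytic form.

    ``(1/2) exp(sigma^2/(2 tau^2) - (t-t0)/tau) erfc((sigma^2/tau - (t-t0)) / (sqrt2 sigma))``
    evaluated stably in log space; unit pre-exponential amplitude.
    """
    t = np.asarray(t, dtype=float)
    dt = t - t0
    if irf_sigma <= 0:
        return np.where(dt >= 0, np.exp(-dt / tau), 0.0)
    arg = (irf_sigma ** 2 / tau - dt) / (np.sqrt(2.0) * irf_sigma)
    log_pref = irf_sigma ** 2 / (2.0 * tau ** 2) - dt / tau
    # erfcx for numerical stability when arg is large positive
    from scipy.special import erfcx

    out = np.where(
        arg > 0,
        0.5 * np.exp(log_pref - arg ** 2) * erfcx(np.clip(arg, 0, None)),
        0.5 * np.exp(np.clip(log_pref, -700, 700)) * erfc(arg),
    )
    return out


def _poisson_deviance(counts: np.ndarray, model: np.ndarray) -> float:
    model = np.maximum(model, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / model), 0.0)
    return float(2.0 * np.sum(model - counts + term))


def _deviance_residuals(counts: np.ndarray, model: np.ndarray) -> np.ndarray:
    """Signed square-root deviance residuals (sum of squares = deviance)."""
    model = np.maximum(model, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / model), 0.0)
    dev = 2.0 * (model - counts + term)
    return np.sign(counts - model) * np.sqrt(np.maximum(dev, 0.0))


@dataclass
class MonoExpFit:
    tau: float  # ns
    amplitude: float
    background: float
    tau_stderr: float = np.nan
    converged: bool = True


def fit_monoexp(decay: DecayHistogram, model: LifetimeModel) -> MonoExpFit:
    """Poisson-MLE fit of ``background + A exp(-t/tau)`` (x) Gaussian IRF.

    ``model`` supplies the IRF description and an initial guess for tau
    (its ``tau_d``); tau, amplitude and background are free.
    """
    counts = np.asarray(decay.counts, dtype=float)
    if counts.sum() < 1e3:
        raise InsufficientDataError(
            f"mono-exponential fit needs >= 1000 photons, got {int(counts.sum())}")
    t = decay.times
    sig, t0 = model.irf_sigma, model.irf_t0

    params = lmfit.Parameters()
    params.add("tau", value=model.tau_d, min=0.05, max=50.0)
    peak = counts.max()
    params.add("amp", value=max(peak, 1.0), min=1e-9)
    params.add("bg", value=max(counts[: max(int(t0 / decay.bin_width) - 4, 1)].mean()
                               if t0 > 0 else 0.0, 0.0), min=0.0)

    def resid(p):
        m = p["bg"].value + p["amp"].value * decay_shape(t, p["tau"].value, sig, t0)
        return _deviance_residuals(counts, m)

    out = lmfit.minimize(resid, params, method="leastsq")
    return MonoExpFit(
        tau=float(out.params["tau"].value),
        amplitude=float(out.params["amp"].value),
        background=float(out.params["bg"].value),
        tau_stderr=float(out.params["tau"].stderr or np.nan),
        converged=bool(out.success),
    )


def fit_fret_fraction(decay: DecayHistogram, model: LifetimeModel,
                      min_photons: int = 100) -> float:
    """Amplitude-fraction of the FRET-quenched component, f_D in [0, 1].

    Both lifetimes are frozen (tau_D from a donor-only control, tau_DA fixed
    or pre-fitted on a pooled high-FRET decay), so the model is linear in
    the two pre-exponential amplitudes and the background; the Poisson
    deviance is minimised over those three non-negative coefficients and
    ``f_D = a_DA / (a_DA + a_D)``.
    """
    if model.tau_da is None:
        raise ValueError("fit_fret_fraction requires tau_da in the model")
    counts = np.asarray(decay.counts, dtype=float)
    if counts.sum() < min_photons:
        raise InsufficientDataError(
            f"FRET-fraction fit needs >= {min_photons} photons, got {int(counts.sum())}")
    t = decay.times
    s1 = decay_shape(t, model.tau_da, model.irf_sigma, model.irf_t0)
    s2 = decay_shape(t, model.tau_d, model.irf_sigma, model.irf_t0)
    basis = np.column_stack([s1, s2, np.ones_like(t)])

    coef0, _ = nnls(basis, counts)
    coef0 = np.maximum(coef0, 1e-9)

    def negll_and_grad(c):
        m = np.maximum(basis @ c, 1e-12)
        nll = np.sum(m - counts * np.log(m))
        grad = basis.T @ (1.0 - counts / m)
        return nll, grad

    res = minimize(negll_and_grad, coef0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * 3)
    a_da, a_d = res.x[0], res.x[1]
    if a_da + a_d <= 0:
        return 0.0
    return float(np.clip(a_da / (a_da + a_d), 0.0, 1.0))


@dataclass
class FretMap:
    """Per-pixel donor-FRET fraction map with a photon-count validity mask."""

    f_d: np.ndarray  # NaN outside valid_mask
    photon_count: np.ndarray
    valid_mask: np.ndarray


def fret_map(img: FlimImage, model: LifetimeModel, min_photons: int = 300) -> FretMap:
    """Per-pixel :func:`fit_fret_fraction` on pixels above ``min_photons``."""
    intensity = img.intensity
    valid = intensity >= min_photons
    f = np.full(intensity.shape, np.nan)
    if not valid.any():
        warnings.warn("no pixel exceeds the photon threshold; empty map",
                      EmptyMapWarning)
        return FretMap(f_d=f, photon_count=intensity, valid_mask=valid)
    t = (np.arange(img.decay.shape[-1]) + 0.5) * img.bin_width
    s1 = decay_shape(t, model.tau_da, model.irf_sigma, model.irf_t0)
    s2 = decay_shape(t, model.tau_d, model.irf_sigma, model.irf_t0)
    basis = np.column_stack([s1, s2, np.ones_like(t)])
    ys, xs = np.nonzero(valid)
    for y, x in zip(ys, xs):
        counts = img.decay[y, x].astype(float)
        coef0, _ = nnls(basis, counts)
        coef0 = np.maximum(coef0, 1e-9)

        def negll_and_grad(c, counts=counts):
            m = np.maximum(basis @ c, 1e-12)
            return (np.sum(m - counts * np.log(m)),
                    basis.T @ (1.0 - counts / m))

        res = minimize(negll_and_grad, coef0, jac=True, method="L-BFGS-B",
                       bounds=[(0.0, None)] * 3)
        a_da, a_d = res.x[0], res.x[1]
        f[y, x] = np.clip(a_da / (a_da + a_d), 0.0, 1.0) if a_da + a_d > 0 else 0.0
    return FretMap(f_d=f, photon_count=intensity, valid_mask=valid)


def cell_fret_fraction(img: FlimImage, model: LifetimeModel,
                       mask: np.ndarray | None = None) -> float:
    """Cell-level f_D^eff from the photon-weighted sum decay over the mask.

    Pooling the decay maximises photon statistics; per-pixel maps are for
    localisation only.
    """
    return fit_fret_fraction(img.pooled_decay(mask), model)


# ---------------------------------------------------------------------------
# dimerisation efficiency and mass-action equilibrium
# ---------------------------------------------------------------------------

def dimerisation_efficiency(f_d_eff: float, i_d: float, i_a: float,
                            brightness_d: float = 1.0, brightness_a: float = 1.0) -> float:
    """E_D = f_D^eff (C_D + C_A)/C_A, clipped to [0, 1].

    Intensities must be background-subtracted; concentrations are
    ``C = I / brightness`` (brightness factors default to 1, leaving
    concentrations in intensity units).
    """
    if brightness_d <= 0 or brightness_a <= 0:
        raise ValueError("brightness factors must be > 0")
    if i_d < 0 or i_a < 0:
        raise ValueError("intensities must be background-subtracted and >= 0")
    c_d = i_d / brightness_d
    c_a = i_a / brightness_a
    if c_a <= 0:
        raise UndefinedEfficiencyError("E_D undefined when C_A = 0")
    return float(np.clip(f_d_eff * (c_d + c_a) / c_a, 0.0, 1.0))


def mass_action_monomer(c_t, kd):
    """Equilibrium monomer concentration of 2M = M2 at total protomer C_T."""
    c_t = np.asarray(c_t, dtype=float)
    return (-kd + np.sqrt(kd * kd + 8.0 * kd * c_t)) / 4.0


def dimer_protomer_fraction(c_t, kd):
    """Fraction of protomers in dimers, p = (C_T - m)/C_T."""
    c_t = np.asarray(c_t, dtype=float)
    return (c_t - mass_action_monomer(c_t, kd)) / c_t


@dataclass
class KdFit:
    """Effective dissociation constant fitted to a cell population."""

    kd_eff: float  # µM
    kd_stderr: float
    residual_rms: float
    n_cells: int


@dataclass
class CellResult:
    """Per-cell quantification unit aggregated into population statistics."""

    cell_id: int
    f_d_eff: float
    e_d: float
    i_d: float
    i_a: float
    pm_cyt_intensity: float = np.nan
    pm_cyt_fdeff: float = np.nan


def estimate_kd_eff(cells, n_boot: int = 500, seed: int = 0) -> KdFit:
    """Fit the mass-action dimer fraction p(C_T; K) to per-cell E_D.

    ``cells`` is an iterable of mappings with keys ``C_D``, ``C_A`` and
    either ``E_D`` or ``f_D_eff_observed`` (converted via the random-pairing
    normalisation).  Uncertainty is a bootstrap over cells.
    """
    cells = list(cells)
    if len(cells) < 10:
        raise ValueError(f"need >= 10 cells to fit K_D^eff, got {len(cells)}")
    c_t = np.array([c["C_D"] + c["C_A"] for c in cells])
    e_d = np.array([
        c["E_D"] if "E_D" in c
        else np.clip(c["f_D_eff_observed"] * (c["C_D"] + c["C_A"]) / c["C_A"], 0.0, 1.0)
        for c in cells
    ])
    if c_t.max() / c_t.min() < 3.0:
        warnings.warn(
            "concentration range spans < 3x; K_D fit is ill-conditioned",
            IllConditionedWarning)

    def fit_once(ct, ed):
        popt, _ = curve_fit(dimer_protomer_fraction, ct, ed,
                            p0=[np.median(ct)], bounds=(1e-6, 1e9), maxfev=5000)
        return float(popt[0])

    kd = fit_once(c_t, e_d)
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(cells), len(cells))
        try:
            boot.append(fit_once(c_t[idx], e_d[idx]))
        except RuntimeError:
            continue
    stderr = float(np.std(boot, ddof=1)) if len(boot) > 1 else np.nan
    resid = e_d - dimer_protomer_fraction(c_t, kd)
    return KdFit(kd_eff=kd, kd_stderr=stderr,
                 residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                 n_cells=len(cells))
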