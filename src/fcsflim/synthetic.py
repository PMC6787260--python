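"""Photon-level simulators with known ground truth.

Four generators cover every input the analysis pipeline consumes:

* :func:`simulate_membrane_fcs` — a line scan across a GUV equator.  The
  membrane is modelled locally as a flat 2D plane spanned by the in-membrane
  lateral coordinate and the optical axis (the geometry under which the 2D
  diffusion model is exact); molecules perform Brownian motion in that plane
  and emit photons through a Gaussian confocal profile while slow vesicle
  drift moves the membrane crossing position along the scan axis.
* :func:`simulate_point_fcs` — a stationary-focus measurement of a dye in
  3D, used for focal-volume calibration.
* :func:`simulate_flim_cell` — a TCSPC FLIM image of a synthetic cell:
  per-pixel decay histograms that are Poisson counts of a donor-only /
  FRET-quenched bi-exponential convolved with a Gaussian instrument
  response, plus donor and acceptor intensity planes blurred by the PSF.
* :func:`simulate_dimer_population` — per-cell dimer fractions from the
  mass-action homodimerisation equilibrium at a configured K_D^eff.

All simulators are reproducible: identical seed and configuration give
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, DegenerateStreamError
from .flim import decay_shape, dimer_protomer_fraction
from .tcspc import (
    DEFAULT_CLOCK_HZ,
    MARKER_LINE,
    FlimImage,
    PhotonStream,
)

_CHUNK_LINES = 16384


@dataclass
class GroundTruth:
    """Generative parameters plus derived per-entity truths.

    Sufficient to score any estimator without re-simulation; arrays are kept
    in ``extras`` and summarised on JSON export.
    """

    params: dict[str, Any] = field(default_factory=dict)
    derived: dict[str, Any] = field(default_factory=dict)
    extras: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        def clean(d):
            out = {}
            for k, v in d.items():
                if isinstance(v, np.ndarray):
                    out[k] = v.tolist() if v.size <= 256 else {
                        "shape": list(v.shape), "mean": float(v.mean())}
                elif isinstance(v, (np.floating, np.integer)):
                    out[k] = v.item()
                elif callable(v):
                    out[k] = repr(v)
                else:
                    out[k] = v
            return out

        return json.dumps({"params": clean(self.params), "derived": clean(self.derived)},
                          indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass
class SfcsSimConfig:
    """Scanning-FCS acquisition emulation.

    Defaults follow the acquisition geometry of the study this package
    models: 1400 Hz line rate, 64 pixels of 260 nm (16.64 µm scan length),
    5-minute acquisitions.  Brightness and background are not stated for the
    original instrument; defaults (5 kHz per molecule at focus centre,
    200 Hz background) are typical for eGFP-tagged proteins on a confocal
    with avalanche photodiodes and make recovery feasible without being
    unrealistically bright.
    """

    diffusion_coeff: float = 8.3  # µm²/s
    beam_waist: float = 0.25  # w_o, µm
    axial_waist: float = 1.25  # z_o, µm
    particle_density: float = 1.5  # molecules/µm² in the membrane plane
    brightness: float = 5000.0  # photons/s per molecule at focus centre
    scan_freq: float = 1400.0  # Hz
    n_pixels: int = 64
    pixel_size: float = 0.26  # µm
    duration: float = 300.0  # s
    drift_profile: Callable[[np.ndarray], np.ndarray] | None = None  # t[s] -> µm
    background_rate: float = 200.0  # photons/s
    membrane_center_px: float | None = None  # default: middle of the scan
    patch_x_factor: float = 130.0  # patch extent along the membrane, units of w_o
    patch_z_factor: float = 10.0  # patch extent along the optical axis, units of z_o
    rng_seed: int = 0

    def validate(self) -> None:
        if self.diffusion_coeff < 0:
            raise ConfigurationError("diffusion_coeff must be >= 0")
        if self.scan_freq <= 0:
            raise ConfigurationError("scan_freq must be > 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.brightness < 0 or self.background_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.beam_waist <= 0 or self.axial_waist <= 0:
            raise ConfigurationError("waists must be > 0")
        if self.particle_density < 0:
            raise ConfigurationError("particle_density must be >= 0")

    @property
    def scan_length(self) -> float:
        return self.n_pixels * self.pixel_size


@dataclass
class FlimSimConfig:
    """FLIM acquisition emulation for a single synthetic cell.

    The cell is an ellipse (axis ratio 1.5 by default) with a membrane ring
    of configurable width; no nucleus is modelled.  Region concentration
    and FRET-fraction values are given per region ("membrane", "cytoplasm");
    the micro-time axis defaults to 256 bins over 12.5 ns (a typical
    Ti:Sapphire repetition period) and the instrument response is Gaussian
    with 0.3 ns FWHM.
    """

    image_size: tuple[int, int] = (64, 64)  # (ny, nx)
    pixel_size: float = 0.275  # µm
    cell_axes: tuple[float, float] = (6.0, 4.0)  # ellipse semi-axes, µm
    membrane_width: float = 0.4  # µm
    donor_lifetime: float = 2.4  # tau_D, ns
    fret_lifetime: float = 1.0  # tau_DA, ns
    fret_fraction: dict[str, float] | None = None  # per-region f_D
    donor_conc: dict[str, float] | None = None  # per-region, arbitrary units
    acceptor_conc: dict[str, float] | None = None
    irf_fwhm: float = 0.3  # ns
    irf_t0: float = 2.0  # ns
    n_microtime_bins: int = 256
    microtime_range: float = 12.5  # ns
    total_photon_budget: float = 2.0e6
    background_fraction: float = 0.005  # uniform counts, fraction of budget
    psf_fwhm: float = 0.25  # µm
    rng_seed: int = 0

    def validate(self) -> None:
        if self.total_photon_budget <= 0:
            raise ConfigurationError("total_photon_budget must be > 0")
        if not (0 < self.fret_lifetime < self.donor_lifetime):
            raise ConfigurationError("need 0 < fret_lifetime < donor_lifetime")
        for v in (self.fret_fraction or {}).values():
            if not 0 <= v <= 1:
                raise ConfigurationError("fret fractions must lie in [0, 1]")

    def region_defaults(self):
        f = {"cytoplasm": 0.0, "membrane": 0.0}
        f.update(self.fret_fraction or {})
        cd = {"cytoplasm": 1.0, "membrane": 1.0}
        cd.update(self.donor_conc or {})
        ca = {"cytoplasm": 1.0, "membrane": 1.0}
        ca.update(self.acceptor_conc or {})
        return f, cd, ca


@dataclass
class DimerPopulationConfig:
    """Cell population with mass-action homodimer fractions.

    Per cell the total protomer concentration is sampled log-uniformly from
    ``total_conc_range`` (so a decade of concentrations is evenly covered),
    the donor fraction uniformly from ``donor_fraction_range``, and the
    observed donor-FRET fraction is p * C_A/C_T plus Gaussian measurement
    noise clipped to [0, 1].
    """

    n_cells: int = 50
    kd_eff: float = 49.0  # µM
    total_conc_range: tuple[float, float] = (1.0, 100.0)  # µM
    donor_fraction_range: tuple[float, float] = (0.3, 0.7)
    measurement_noise_sd: float = 0.02  # absolute, on f_D^eff
    rng_seed: int = 0

    def validate(self) -> None:
        if self.kd_eff <= 0:
            raise ConfigurationError("kd_eff must be > 0")
        if self.total_conc_range[0] <= 0:
            raise ConfigurationError("concentrations must be > 0")
        if self.measurement_noise_sd < 0:
            raise ConfigurationError("measurement_noise_sd must be >= 0")
        lo, hi = self.donor_fraction_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("donor_fraction_range must lie inside (0, 1)")


# ---------------------------------------------------------------------------
# scanning FCS on a membrane
# ---------------------------------------------------------------------------

def simulate_membrane_fcs(cfg: SfcsSimConfig) -> tuple[PhotonStream, GroundTruth]:
    """Simulate a line scan across a membrane with diffusing fluorophores.

    Molecules perform 2D Brownian motion in the membrane plane (in-plane
    coordinate x, optical axis z) within a periodic patch of
    ``patch_x_factor * w_o`` by ``patch_z_factor * z_o`` (the default,
    ~32.5 x 12.5 µm, is comparable to the equatorial extent of a large GUV
    and keeps the ratio of focal to patch area below 0.3%, so the
    number-conservation artefacts of a periodic box are negligible).  Per
    line, each molecule contributes expected photons
    ``brightness * exp(-2x^2/w_o^2 - 2z^2/z_o^2) / scan_freq`` (emission is
    integrated once per scan period, matching the minimal lag of the
    analysis).  Detected photons are placed along the scan axis around the
    membrane crossing position — Gaussian with sd w_o/2, the beam profile —
    which itself follows ``drift_profile``; background photons land
    uniformly across the line.  The stream carries one line marker per scan
    period plus a terminal marker, so decoding returns exactly
    ``duration * scan_freq`` lines.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n_lines = int(round(cfg.duration * cfg.scan_freq))
    line_t = 1.0 / cfg.scan_freq
    w, zo = cfg.beam_waist, cfg.axial_waist
    patch_x, patch_z = cfg.patch_x_factor * w, cfg.patch_z_factor * zo
    n_mol = max(1, int(round(cfg.particle_density * patch_x * patch_z)))
    step_sd = np.sqrt(2.0 * cfg.diffusion_coeff * line_t)

    center0 = cfg.membrane_center_px if cfg.membrane_center_px is not None \
        else cfg.n_pixels / 2.0
    t_lines = np.arange(n_lines) * line_t
    if cfg.drift_profile is not None:
        crossing = center0 + np.asarray(cfg.drift_profile(t_lines)) / cfg.pixel_size
    else:
        crossing = np.full(n_lines, center0)

    x = rng.uniform(-patch_x / 2, patch_x / 2, n_mol).astype(np.float32)
    z = rng.uniform(-patch_z / 2, patch_z / 2, n_mol).astype(np.float32)

    ticks_per_line = DEFAULT_CLOCK_HZ * line_t
    all_times: list[np.ndarray] = []
    occ_sum = 0.0
    spread_px = (w / 2.0) / cfg.pixel_size
    # detection is negligible beyond 3 waists (exp(-18)); evaluate it only
    # near the focus so huge patches cost compares, not exps
    x_cut, z_cut = np.float32(3.0 * w), np.float32(3.0 * zo)

    for start in range(0, n_lines, _CHUNK_LINES):
        nc = min(_CHUNK_LINES, n_lines - start)
        if step_sd > 0:
            dx = rng.standard_normal((nc, n_mol), dtype=np.float32)
            dx *= np.float32(step_sd)
            np.cumsum(dx, axis=0, out=dx)
            xs = dx
            xs += x + np.float32(patch_x / 2)
            xs %= np.float32(patch_x)
            xs -= np.float32(patch_x / 2)
            dz = rng.standard_normal((nc, n_mol), dtype=np.float32)
            dz *= np.float32(step_sd)
            np.cumsum(dz, axis=0, out=dz)
            zs = dz
            zs += z + np.float32(patch_z / 2)
            zs %= np.float32(patch_z)
            zs -= np.float32(patch_z / 2)
            x, z = xs[-1].copy(), zs[-1].copy()
        else:
            xs = np.broadcast_to(x, (nc, n_mol))
            zs = np.broadcast_to(z, (nc, n_mol))
        near = (np.abs(xs) < x_cut) & (np.abs(zs) < z_cut)
        rows, cols = np.nonzero(near)
        xn = xs[rows, cols].astype(float) / w
        zn = zs[rows, cols].astype(float) / zo
        det = np.exp(-2.0 * xn ** 2 - 2.0 * zn ** 2)
        occ_sum += float((xn ** 2 + zn ** 2 <= 1.0).sum())
        lam_mem = np.zeros(nc)
        np.add.at(lam_mem, rows, det)
        lam_mem *= cfg.brightness * line_t
        n_mem = rng.poisson(lam_mem)
        n_bg = rng.poisson(cfg.background_rate * line_t, nc)

        lines_rep = np.repeat(np.arange(start, start + nc), n_mem)
        pos = rng.normal(crossing[lines_rep], spread_px)
        keep = (pos >= 0) & (pos < cfg.n_pixels)
        lines_rep, pos = lines_rep[keep], pos[keep]
        bg_lines = np.repeat(np.arange(start, start + nc), n_bg)
        bg_pos = rng.uniform(0, cfg.n_pixels, bg_lines.size)
        lr = np.concatenate([lines_rep, bg_lines])
        pp = np.concatenate([pos, bg_pos])
        times = ((lr + pp / cfg.n_pixels) * ticks_per_line).astype(np.int64)
        all_times.append(np.sort(times))

    macro = np.sort(np.concatenate(all_times)) if all_times else np.empty(0, np.int64)
    marker_times = np.round(np.arange(n_lines + 1) * ticks_per_line).astype(np.int64)
    stream = PhotonStream(
        macro_times=macro,
        marker_kinds=np.full(n_lines + 1, MARKER_LINE, dtype=np.int8),
        marker_times=marker_times,
        metadata={"kind": "sfcs_linescan", "n_pixels": cfg.n_pixels,
                  "pixel_size_um": cfg.pixel_size, "scan_freq_hz": cfg.scan_freq},
    )
    params = asdict(cfg)
    params["drift_profile"] = None if cfg.drift_profile is None else "callable"
    truth = GroundTruth(
        params=params,
        derived={
            "n_molecules": n_mol,
            "mean_occupancy_1e2_area": occ_sum / n_lines,
            "expected_focal_n": cfg.particle_density * np.pi * w * zo,
            "n_photons": int(macro.size),
            "tau_d_s": (w ** 2 / (4 * cfg.diffusion_coeff)
                        if cfg.diffusion_coeff > 0 else np.inf),
        },
        extras={"crossing_px": crossing},
    )
    return stream, truth


# ---------------------------------------------------------------------------
# point FCS (calibration dye)
# ---------------------------------------------------------------------------

def simulate_point_fcs(d: float, focus, n_molecules_mean: float, brightness: float,
                       duration: float, seed: int = 0, background_rate: float = 0.0,
                       sampling_dt: float = 5e-6) -> PhotonStream:
    """Simulate a stationary-focus FCS measurement of a freely diffusing dye.

    Molecules diffuse in 3D through a Gaussian ellipsoidal focus (waists
    ``focus.beam_waist`` and ``focus.axial_waist``) inside a periodic box;
    emission is integrated per ``sampling_dt``.  ``n_molecules_mean`` is the
    mean occupancy of the effective focal volume ``pi^{3/2} w_o^2 z_o``.
    The stream carries no line markers (point measurement); bin it with
    :func:`fcsflim.sfcs.bin_photon_stream` before correlating.
    """
    if d <= 0 or duration <= 0 or sampling_dt <= 0:
        raise ConfigurationError("d, duration and sampling_dt must be > 0")
    if brightness < 0 or background_rate < 0 or n_molecules_mean < 0:
        raise ConfigurationError("rates and occupancy must be >= 0")
    if n_molecules_mean == 0 and background_rate == 0:
        raise DegenerateStreamError("no molecules and no background: empty stream")
    w, zo = focus.beam_waist, focus.axial_waist
    # box kept large relative to the effective volume (ratio < 1%) so the
    # periodic boundary's number conservation does not distort G
    half = np.array([4.0 * w, 4.0 * w, 7.0 * zo], dtype=np.float32)
    box = 2.0 * half
    v_eff = np.pi ** 1.5 * w * w * zo
    conc = n_molecules_mean / v_eff
    n_mol = max(1, int(round(conc * float(box.prod())))) if n_molecules_mean > 0 else 0

    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / sampling_dt))
    step_sd = np.sqrt(2.0 * d * sampling_dt)
    pos = (rng.uniform(-half, half, (n_mol, 3)).astype(np.float32)
           if n_mol else np.zeros((0, 3), dtype=np.float32))
    cut = np.array([3.0 * w, 3.0 * w, 3.0 * zo], dtype=np.float32)

    chunk = max(1, int(12e6 // max(n_mol, 1)))
    all_times: list[np.ndarray] = []
    ticks_per_bin = DEFAULT_CLOCK_HZ * sampling_dt
    for start in range(0, n_steps, chunk):
        nc = min(chunk, n_steps - start)
        if n_mol:
            steps = rng.standard_normal((nc, n_mol, 3), dtype=np.float32)
            steps *= np.float32(step_sd)
            np.cumsum(steps, axis=0, out=steps)
            steps += pos + half
            steps %= box
            steps -= half
            traj = steps
            pos = traj[-1].copy()
            near = np.all(np.abs(traj) < cut, axis=2)
            rows, cols = np.nonzero(near)
            p = traj[rows, cols].astype(float)
            det = np.exp(-2.0 * (p[:, 0] ** 2 + p[:, 1] ** 2) / (w * w)
                         - 2.0 * p[:, 2] ** 2 / (zo * zo))
            lam = np.zeros(nc)
            np.add.at(lam, rows, det)
            lam *= brightness * sampling_dt
        else:
            lam = np.zeros(nc)
        lam = lam + background_rate * sampling_dt
        nph = rng.poisson(lam)
        bins_rep = np.repeat(np.arange(start, start + nc), nph)
        u = rng.uniform(0.0, 1.0, bins_rep.size)
        all_times.append(np.sort(((bins_rep + u) * ticks_per_bin).astype(np.int64)))

    macro = np.sort(np.concatenate(all_times)) if all_times else np.empty(0, np.int64)
    return PhotonStream(
        macro_times=macro,
        metadata={"kind": "point_fcs", "duration_ticks": n_steps * ticks_per_bin,
                  "sampling_dt_s": sampling_dt},
    )


# ---------------------------------------------------------------------------
# FLIM cell
# ---------------------------------------------------------------------------

def _cell_region_masks(cfg: FlimSimConfig):
    """Interior / membrane-band masks of the configured ellipse (pixel grid)."""
    ny, nx = cfg.image_size
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    a, b = cfg.cell_axes  # semi-axes in µm (x, y)
    px = cfg.pixel_size
    # normalised ellipse radius; the band within membrane_width of the edge
    # (measured along the local normal, approximated radially) is "membrane"
    r = np.sqrt(((xx - cx) * px / a) ** 2 + ((yy - cy) * px / b) ** 2)
    inside = r <= 1.0
    r_inner = 1.0 - cfg.membrane_width / min(a, b)
    membrane = inside & (r > r_inner)
    cytoplasm = inside & ~membrane
    return cytoplasm, membrane


def simulate_flim_cell(cfg: FlimSimConfig) -> tuple[FlimImage, GroundTruth]:
    """Simulate a FLIM image of one cell with region-wise FRET fractions.

    Each pixel's decay histogram is Poisson counts of
    ``B + A [f e^{-t/tau_DA} + (1-f) e^{-t/tau_D}]`` convolved with a
    Gaussian instrument response, where the amplitude A follows the
    PSF-blurred donor concentration map and f mixes region values in
    proportion to their blurred photon contributions.  Donor and acceptor
    intensity planes (blurred, Poisson-noised) are stored in the ground
    truth for segmentation and E_D work.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    f_reg, cd_reg, ca_reg = cfg.region_defaults()
    cyt, mem = _cell_region_masks(cfg)
    sigma_px = cfg.psf_fwhm / 2.3548 / cfg.pixel_size

    tcent = (np.arange(cfg.n_microtime_bins) + 0.5) * (
        cfg.microtime_range / cfg.n_microtime_bins)
    sigma_irf = cfg.irf_fwhm / 2.3548
    shape_da = decay_shape(tcent, cfg.fret_lifetime, sigma_irf, cfg.irf_t0)
    shape_d = decay_shape(tcent, cfg.donor_lifetime, sigma_irf, cfg.irf_t0)

    ny, nx = cfg.image_size
    expected = np.zeros((ny, nx, cfg.n_microtime_bins))
    donor_plane = np.zeros((ny, nx))
    acceptor_plane = np.zeros((ny, nx))
    f_weighted = np.zeros((ny, nx))
    for region, mask in (("cytoplasm", cyt), ("membrane", mem)):
        amp = gaussian_filter(mask.astype(float) * cd_reg[region], sigma_px)
        f = f_reg[region]
        shape = f * shape_da + (1.0 - f) * shape_d
        shape = shape / shape.sum()
        expected += amp[:, :, None] * shape[None, None, :]
        donor_plane += amp
        f_weighted += amp * f
        acceptor_plane += gaussian_filter(mask.astype(float) * ca_reg[region], sigma_px)

    total = expected.sum()
    if total <= 0:
        raise ConfigurationError("concentration maps produce no signal")
    scale = cfg.total_photon_budget * (1.0 - cfg.background_fraction) / total
    expected *= scale
    bg_per_bin = (cfg.total_photon_budget * cfg.background_fraction
                  / (ny * nx * cfg.n_microtime_bins))
    decay = rng.poisson(expected + bg_per_bin)

    with np.errstate(invalid="ignore"):
        f_true = np.where(donor_plane > 0, f_weighted / np.maximum(donor_plane, 1e-30), 0.0)
    donor_scale = cfg.total_photon_budget / max(donor_plane.sum(), 1e-30)
    donor_noisy = rng.poisson(donor_plane * donor_scale)
    acc_scale = cfg.total_photon_budget / max(acceptor_plane.sum(), 1e-30)
    acceptor_noisy = rng.poisson(acceptor_plane * acc_scale)

    img = FlimImage(
        decay=decay, pixel_size=cfg.pixel_size,
        bin_width=cfg.microtime_range / cfg.n_microtime_bins,
        metadata={"kind": "flim_cell"})
    params = asdict(cfg)
    truth = GroundTruth(
        params=params,
        derived={"n_photons": int(decay.sum()),
                 "mean_f_in_cell": float(f_true[cyt | mem].mean())},
        extras={"f_map": f_true, "cytoplasm_mask": cyt, "membrane_mask": mem,
                "donor_plane": donor_noisy.astype(float),
                "acceptor_plane": acceptor_noisy.astype(float)},
    )
    return img, truth


# ---------------------------------------------------------------------------
# dimerising cell population
# ---------------------------------------------------------------------------

def simulate_dimer_population(cfg: DimerPopulationConfig):
    """Simulate per-cell dimer observations at a known K_D^eff.

    Per cell: C_T log-uniform over the configured range, split into donor and
    acceptor protomers; the dimerised protomer fraction follows the closed
    form of the 2M = M2 equilibrium,
    ``m = (-K + sqrt(K^2 + 8 K C_T)) / 4``, ``p = (C_T - m)/C_T``; the
    observed donor-FRET fraction is ``p * C_A / C_T`` plus Gaussian noise,
    clipped to [0, 1].  Returns (list of per-cell records, GroundTruth).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    lo, hi = cfg.total_conc_range
    c_t = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_cells))
    x_d = rng.uniform(*cfg.donor_fraction_range, cfg.n_cells)
    c_d = x_d * c_t
    c_a = c_t - c_d
    p = dimer_protomer_fraction(c_t, cfg.kd_eff)
    f_true = p * c_a / c_t
    f_obs = np.clip(f_true + rng.normal(0.0, cfg.measurement_noise_sd, cfg.n_cells),
                    0.0, 1.0)
    cells = [
        {"cell_id": i, "C_D": float(c_d[i]), "C_A": float(c_a[i]),
         "p": float(p[i]), "f_D_eff_observed": float(f_obs[i])}
        for i in range(cfg.n_cells)
    ]
    truth = GroundTruth(
        params=asdict(cfg),
        derived={"mean_p": float(p.mean())},
        extras={"c_t": c_t, "p": p, "f_true": f_true},
    )
    return cells, truth
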