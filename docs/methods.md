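# Methods

This note documents the models, estimators and numerical choices behind
`fcsflim`, and what the synthetic-data generators do and do not emulate.

## Scanning FCS on a model membrane

A confocal focus is scanned repeatedly (1400 Hz by default) across the
equator of a giant unilamellar vesicle (GUV). Each pass crosses the
membrane once; summing the photons around the membrane crossing gives one
intensity sample per scan period, and the autocorrelation of that trace
reports the diffusion of membrane-bound molecules through the focus. The
membrane curve is fitted with the two-dimensional diffusion model

    G(tau) = (1/N) (1 + tau/tau_D)^(-1/2) (1 + tau/(S^2 tau_D))^(-1/2)

where `N` is the mean number of molecules in the focal area, `tau_D` the
diffusion time, and `S = z_o/w_o` the axial-to-radial aspect ratio of the
detection volume. The diffusion coefficient is `D = w_o^2 / (4 tau_D)`.
`S` is held fixed during membrane fits (default 5, or the value from a dye
calibration): the 2D model is only weakly sensitive to it, and floating it
on membrane data is degenerate. Point measurements of a calibration dye
(Alexa 488, D ≈ 430 µm²/s at 25 °C) use the standard 3D model with an extra
`(1 + tau/tau_D)^(-1/2)` factor, from which `w_o = sqrt(4 D_ref tau_D)` and
`z_o = S w_o`.

### Drift alignment

Vesicles drift slowly, moving the membrane crossing along the scan axis.
The line-scan matrix is block-averaged (70 lines ≈ 50 ms per block), each
block profile is fitted with a Gaussian (a damped Gauss–Newton fit run on
all blocks simultaneously; stray block fits are replaced from a running
median of the centre track), and the per-block centres are linearly
interpolated to a per-line trajectory. The per-line intensity is the
photon sum over a fixed window of `aperture_px + 1` pixels (default ±2 px ≈
±0.52 µm) centred on the rounded fractional centre. Nearest-pixel
summation is used deliberately: interpolating integer photon counts would
distort the shot-noise statistics the correlator relies on.

### Correlator

A multi-tau estimator: lags 1..2m at the raw line period, then the trace
is binned by two and lags m+1..2m added per octave (default m = 8). The
normalisation is symmetric, `G(k) = <F_i F_{i+k}> / (mean_left *
mean_right) - 1`, which is exactly zero for a constant trace and tolerant
of slow trends. The trace is split into `n_segments` (default 10) equal
segments; `G` is the segment mean and `G_sd` the segment scatter divided by
`sqrt(n_segments)`. The first lag equals the inverse scanning frequency.
A brute-force direct-sum correlator with the same normalisation serves as
an oracle in the test suite; the two agree to 1e-12 on first-octave lags.

### Fit window

Fits are restricted to lags where `G` is still above 10% (2D) or 5% (3D)
of its first-lag value, with a floor of 12 lags. The fat `t^(-1)` tail of
the 2D model carries almost no parameter information, while long lags are
the first casualty of everything unmodelled — membrane undulations and
residual drift in experiments, periodic-boundary artefacts in simulations.
With the window in place, end-to-end recovery on synthetic ground truth is
unbiased within the per-condition SEM (the end-to-end recovery tests in
the suite verify this at both study conditions). The 3D point-FCS fit additionally
frees a constant baseline `G_inf` when requested — the usual guard against
residual long-time correlation — which is used in the calibration
round-trip, where the aspect ratio is fixed at the known instrument value.

### Weighting

Weighted least squares with `1/G_sd` weights (floored at the smallest
positive per-lag error; unit weights when no errors are present).
Non-convergence or `tau_D` pinned at a bound is flagged on the returned
fit object, never silently reported.

## The membrane/point simulators

The GUV membrane is modelled locally as a flat 2D plane spanned by the
in-membrane coordinate and the optical axis — the geometry under which the
2D model is exact; the scan samples the membrane only near the crossing
point, so sphere curvature is irrelevant on the focal scale. Molecules
perform Brownian dynamics in a periodic patch; per scan period each
molecule contributes expected photons `brightness * exp(-2x²/w_o² -
2z²/z_o²) / scan_freq`, photons are drawn Poisson, placed along the scan
axis as a Gaussian of sd `w_o/2` around the membrane crossing position
(the beam profile), and stamped with within-line macro-times so the
decoder can reconstruct pixels. Background photons arrive uniformly.
Drift is injected only into the recorded crossing position, not into the
in-plane diffusion, so alignment must remove it without touching `D`.

Positions are advanced once per scan period. Because emission is
integrated once per line from a single molecular position, a Brownian path
sampled at the line period is statistically identical to a sub-stepped
one (Gaussian increments are exact at any step size), so finer stepping
would only add cost.

Patch size matters: a periodic box conserves molecule number, which
suppresses fluctuations by roughly the focal-to-patch area ratio and adds
a slow negative quasi-baseline — both distort `tau_D` if the ratio is more
than a few tenths of a percent. Defaults keep the ratio below 0.3%:
membrane patch `130 w_o x 10 z_o` (≈ 32.5 x 12.5 µm, comparable to the
equatorial extent of a large GUV) at 1.5 molecules/µm² (focal occupancy
N ≈ 1.5, the usual single-molecule sFCS regime), and a 3D box of
`8w x 8w x 14z_o` for the point simulator. Molecular brightness (5 kHz at
focus centre) and background (200 Hz) are not stated for the original
instrument; these values are typical for eGFP on an APD-equipped confocal
and give ~4–8 kHz traces in which recovery is feasible.

Not emulated: triplet blinking, photobleaching, detector afterpulsing,
full-sphere curvature, membrane undulations. Passing recovery tests
therefore shows the estimator chain is unbiased for pure 2D diffusion
plus drift — not that real GUV data are free of those other effects.

## FLIM-FRET and dimerisation

TCSPC decays are modelled as `B + A [f e^(-t/tau_DA) + (1-f) e^(-t/tau_D)]`
convolved with a Gaussian instrument response (analytic
exponentially-modified-Gaussian form, evaluated via `erfcx` for
stability). Defaults: `tau_D = 2.4 ns` (eGFP), `tau_DA = 1.0 ns`, IRF FWHM
0.3 ns centred 2 ns into a 12.5 ns window of 256 bins (a typical
Ti:Sapphire repetition period).

Decay fits minimise the Poisson deviance (maximum likelihood for counting
data) rather than least squares — low-count TCSPC bins are far from
Gaussian. `fit_monoexp` uses deviance residuals inside a
Levenberg–Marquardt loop; `fit_fret_fraction` exploits that with both
lifetimes frozen the model is linear in the two pre-exponential amplitudes
and the background, and minimises the deviance over those three
non-negative coefficients (NNLS start, bounded L-BFGS with analytic
gradient). The effective donor-FRET fraction is the amplitude share of
the quenched component, `f_D = a_DA / (a_DA + a_D)`.

Lifetimes are frozen before per-pixel or per-cell fits: `tau_D` from a
donor-only control, `tau_DA` fitted once on a pooled high-FRET decay —
freeing them per pixel invites amplitude–lifetime degeneracy at low
counts. Per-cell `f_D^eff` is fitted on the photon-weighted sum decay over
the cell mask (maximising photon statistics); per-pixel maps (pixels with
≥ 300 photons by default) are for localisation only.

### Dimerisation efficiency

`f_D^eff` depends on how much acceptor is present. Under random pairing
of protomers, a donor is in a dimer with probability `p` (the dimerised
protomer fraction) and its partner is an acceptor with probability
`C_A/(C_D + C_A)`, so `f_D^eff = p C_A/(C_D + C_A)` and

    E_D = f_D^eff (C_D + C_A) / C_A = p .

This normalisation is a reconstruction: the published definition lives in
a methods reference that is not reproduced here. It is the unique
random-pairing correction that makes the quantity equal the dimerised
fraction and hence independent of the donor:acceptor ratio — the defining
property the measurement relies on — and the simulators and estimators use
it consistently. Concentrations default to intensity units (brightness
factors 1) unless a calibration is supplied.

### K_D^eff estimation

For the homodimerisation equilibrium `2M ⇌ M₂` with effective constant
`K`, the monomer concentration at total protomer concentration `C_T` is
`m = (-K + sqrt(K² + 8K C_T))/4` and the dimerised fraction
`p = (C_T - m)/C_T`. `estimate_kd_eff` fits this closed form to per-cell
`E_D` by least squares, with a bootstrap over cells (default 500
resamples) for the uncertainty, and warns when the concentration range
spans less than 3x (the fit is then ill-conditioned). The population
simulator samples `C_T` log-uniformly so a decade of concentrations is
evenly covered, and adds Gaussian noise to `f_D^eff` (default sd 0.02,
clipped to [0, 1]).

## Segmentation and PM/Cyt ratios

Cells are segmented by Otsu threshold on a Gaussian-smoothed image,
largest connected component, hole filling. The raw contour of that mask
sits at the half-maximum of the PSF-blurred cell edge — exactly where a
cytosolic probe's signal has fallen to ~50% of its interior value. A
plasma-membrane ring centred there would score every cytoplasmic protein
at PM/Cyt ≈ 0.5, so the ring (width 0.55 µm by default) is centred
`edge_margin` = 0.4 µm (≈ PSF FWHM plus a pixelation allowance) inside
the contour; the cytoplasm mask is the interior eroded by `edge_margin +
ring_width`. With this geometry a synthetic cytosol-filled cell imaged at
68 nm pixels scores ≈ 0.99 and a membrane-anchored construct with a 5%
cytosolic pool scores well above 2, matching the reference construct
levels the ratio is calibrated against. The raw contour is kept as
`boundary`; masks are disjoint and contained in the cell mask by
construction. Background (the mode of the off-cell histogram) is
subtracted before all ratios. Coordinates are 0-based with pixel centres
on integers; masks export as 8-bit TIFF.

The coarse-pixel (275 nm) reference levels are reproduced only
qualitatively: partial-volume effects at the boundary depend on exact
contour placement at 2-pixel ring widths.

Ratiometric sensing divides a sensor channel by a co-expressed free
fluorophore channel per pixel (masking non-positive denominators, warning
above 5% masked), cancelling expression level; `relative_level_change`
reports the percent change of condition versus basal means with a
bootstrap CI.

## Population reporting

Populations are summarised as mean ± SEM with a `mean ± 2 SEM` box — read
as such because ±2 SEM is what yields the stated 95.4% confidence — and
whiskers at the 10th/90th percentiles (central 80% of the population,
linear interpolation). Group comparisons use the two-sided Mann–Whitney
test with mid-rank ties: exact by full enumeration of label assignments
for `n1 + n2 ≤ 12` (p = probability of a U at least as far from `n1 n2/2`
as observed), otherwise a normal approximation with tie correction and a
0.5 continuity correction toward the mean. Whether the original analyses
were exact or approximate, one- or two-sided, is not stated; two-sided is
assumed throughout. The exact cutoff of 12 balances runtime against
exactness.

## Problem sizes

End-to-end demonstrations use 8 vesicles x 5 min per lipid condition for
membrane recovery, 60 s x 10 seeds for the dye calibration, 50-cell
populations for K_D^eff, and 10-20 seeds for decay-fit recovery sweeps —
sizes at which the recovery targets sit comfortably inside their quoted
uncertainties on a single CPU.

## Known limitations

- The correlator's segment scatter underestimates `G_sd` when fewer than
  ~8 segments are used; fits fall back to unit weights without errors.
- Per-pixel FRET maps are bounded to [0, 1]; at very low counts the bound
  clipping biases pixel means slightly toward the interior of the range.
- The E_D normalisation assumes random donor/acceptor pairing and equal
  maturation/visibility of both labels; FRET-inactive dimer conformations
  fold into an effective (apparent) dimer fraction, as they do in the
  underlying measurement.
- The exact-test enumeration cost grows combinatorially; above the cutoff
  the normal approximation is used even when ties are heavy.
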