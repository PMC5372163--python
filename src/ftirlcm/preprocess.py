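"""Spectral preprocessing: quality control, Mie/resonance-Mie EMSC, smoothing.

The pipeline mirrors common practice for infrared microspectroscopy of tissue
thin-sections:

1. per-pixel quality control on signal-to-noise ratio and the amide I band
   integral (rejecting cracks, folds, blank substrate and saturated pixels);
2. extended multiplicative signal correction (EMSC) with a Mie-extinction
   basis, removing the baseline distortions that spherical cellular
   structures imprint on the spectra;
3. optional Savitzky-Golay smoothing / second derivatives for unsupervised
   exploration.  Classification consumes the EMSC-corrected absorbance
   directly, without smoothing or derivatives.

The amide I integral doubles as a relative protein-concentration proxy: by
the Lambert-Beer law absorbance is proportional to concentration times path
length, so at fixed section thickness the band integral tracks protein
content per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ParameterError, WindowError
from .hyperspec_io import SpectralImage, WavenumberAxis

__all__ = [
    "QCParams",
    "QCReport",
    "EMSCModel",
    "estimate_snr",
    "integrate_band",
    "quality_control",
    "mie_extinction",
    "build_mie_basis",
    "emsc_correct",
    "emsc_correct_image",
    "savitzky_golay",
]

# Default wavenumber windows (cm^-1).  2000-1800 is spectroscopically quiet
# in tissue; 1700-1600 brackets the amide I band at ~1654.
NOISE_WINDOW = (1800.0, 2000.0)
AMIDE_I_WINDOW = (1600.0, 1700.0)


@dataclass(frozen=True)
class QCParams:
    """Thresholds for per-pixel spectral quality control.

    ``amide_integral_*`` are absorbance*cm^-1; the defaults reject blank /
    crack pixels (low integral) and saturated pixels (high integral).
    """

    noise_window: tuple[float, float] = NOISE_WINDOW
    signal_window: tuple[float, float] = AMIDE_I_WINDOW
    amide_window: tuple[float, float] = AMIDE_I_WINDOW
    snr_min: float = 10.0
    amide_integral_min: float = 0.5
    amide_integral_max: float = 60.0

    def __post_init__(self) -> None:
        if self.snr_min <= 0:
            raise ParameterError("snr_min must be positive")
        if self.amide_integral_min >= self.amide_integral_max:
            raise ParameterError("amide_integral_min must be below amide_integral_max")


@dataclass
class QCReport:
    """Outcome counts and per-pixel failure codes of quality control."""

    n_total: int
    n_pass: int
    failure_counts: dict[str, int]
    failure_codes: np.ndarray  # rows x cols of '' / 'snr-low' / 'amide-low' / 'amide-high'

    @property
    def n_fail(self) -> int:
        return self.n_total - self.n_pass

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_pass": self.n_pass,
            "n_fail": self.n_fail,
            "failure_counts": dict(self.failure_counts),
        }


def _linear_detrend(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Residual after least-squares line fit along the last axis."""
    g = (grid - grid.mean()) / (grid.std() if grid.std() > 0 else 1.0)
    design = np.stack([np.ones_like(g), g], axis=-1)  # (n, 2)
    coef, *_ = np.linalg.lstsq(design, np.moveaxis(values, -1, 0).reshape(grid.size, -1), rcond=None)
    fit = design @ coef
    return values - np.moveaxis(fit.reshape((grid.size,) + values.shape[:-1]), 0, -1)


def estimate_snr(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    noise_window: tuple[float, float] = NOISE_WINDOW,
    signal_window: tuple[float, float] = AMIDE_I_WINDOW,
) -> np.ndarray | float:
    """Signal-to-noise ratio of one spectrum or a stack of spectra.

    Signal is the peak absorbance in ``signal_window`` above the linear
    baseline through the window endpoints; noise is the standard deviation of
    the linearly detrended absorbance in ``noise_window``.  Zero noise maps
    to ``inf`` (a perfectly clean spectrum passes).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    noise_idx = axis.window_indices(*noise_window)
    signal_idx = axis.window_indices(*signal_window)
    if noise_idx.size < 3:
        raise WindowError("noise window must contain >=3 axis points")

    noise_part = spectrum[..., noise_idx]
    resid = _linear_detrend(noise_part, axis.values[noise_idx])
    noise = resid.std(axis=-1)

    sig_part = spectrum[..., signal_idx]
    nu = axis.values[signal_idx]
    # linear baseline through window endpoints
    left, right = sig_part[..., 0], sig_part[..., -1]
    frac = (nu - nu[0]) / (nu[-1] - nu[0])
    baseline = left[..., None] + (right - left)[..., None] * frac
    signal = np.max(sig_part - baseline, axis=-1)
    signal = np.maximum(signal, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(noise > 0, signal / np.where(noise > 0, noise, 1.0), np.inf)
    # identically-zero spectra carry no signal at all: SNR 0, not 0/0 -> inf
    zero_spec = np.max(np.abs(sig_part), axis=-1) == 0
    ratio = np.where(zero_spec, 0.0, ratio)
    return float(ratio) if ratio.ndim == 0 else ratio


def integrate_band(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    window: tuple[float, float] = AMIDE_I_WINDOW,
    baseline: str = "none",
) -> np.ndarray | float:
    """Trapezoidal band integral (absorbance*cm^-1) over a wavenumber window.

    ``baseline='linear-endpoints'`` subtracts the straight line through the
    window endpoints first.  Linear in the spectrum for ``baseline='none'``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    idx = axis.window_indices(*window)
    if idx.size < 2:
        raise WindowError("integration window must span >=2 axis points")
    nu = axis.values[idx]
    part = spectrum[..., idx]
    if baseline == "linear-endpoints":
        left, right = part[..., 0], part[..., -1]
        frac = (nu - nu[0]) / (nu[-1] - nu[0])
        part = part - (left[..., None] + (right - left)[..., None] * frac)
    elif baseline != "none":
        raise ParameterError(f"unknown baseline mode '{baseline}'")
    order = np.argsort(nu)
    result = np.trapezoid(part[..., order], nu[order], axis=-1)
    return float(result) if np.ndim(result) == 0 else result


def quality_control(
    image: SpectralImage, params: QCParams | None = None
) -> tuple[np.ndarray, QCReport]:
    """Flag unusable pixels; returns (mask, report) and stores the mask.

    A pixel passes iff SNR >= ``snr_min`` and the amide I integral lies in
    ``[amide_integral_min, amide_integral_max]``.  Failure codes record the
    first violated criterion in the order amide-low, amide-high, snr-low.
    Idempotent: the decision depends only on the spectra, not on a prior mask.
    """
    params = params or QCParams()
    flat = image.cube.reshape(-1, image.cube.shape[2])
    snr = np.asarray(
        estimate_snr(flat, image.axis, params.noise_window, params.signal_window)
    )
    # endpoint baseline makes the criterion insensitive to smooth
    # Mie-scattering baselines, which QC precedes correction of
    integral = np.asarray(
        integrate_band(flat, image.axis, params.amide_window, baseline="linear-endpoints")
    )
    codes = np.full(flat.shape[0], "", dtype=object)
    codes[snr < params.snr_min] = "snr-low"
    codes[integral > params.amide_integral_max] = "amide-high"
    codes[integral < params.amide_integral_min] = "amide-low"
    mask = codes == ""

    shape = image.shape
    mask = mask.reshape(shape)
    codes = codes.reshape(shape)
    counts: dict[str, int] = {}
    for code in ("snr-low", "amide-low", "amide-high"):
        counts[code] = int(np.sum(codes == code))
    report = QCReport(
        n_total=int(mask.size),
        n_pass=int(mask.sum()),
        failure_counts=counts,
        failure_codes=codes,
    )
    image.qc_mask = mask
    return mask, report


# ---------------------------------------------------------------------------
# EMSC with Mie-extinction basis


def mie_extinction(
    wavenumbers: np.ndarray, radius_um: float, refractive_index: float
) -> np.ndarray:
    """van de Hulst approximate extinction efficiency of a dielectric sphere.

    Q(rho) = 2 - (4/rho) sin(rho) + (4/rho^2)(1 - cos(rho)) with the phase
    parameter rho = 4 pi r nu (n - 1); r in cm (converted from um), nu in
    cm^-1.  This is the non-resonant approximation; the complex-index
    resonant refinement is intentionally out of scope.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    rho = 4.0 * np.pi * (radius_um * 1e-4) * nu * (refractive_index - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 2.0 - (4.0 / rho) * np.sin(rho) + (4.0 / rho**2) * (1.0 - np.cos(rho))
    return np.where(np.abs(rho) < 1e-12, 0.0, q)


def build_mie_basis(
    axis: WavenumberAxis,
    fit_range: tuple[float, float] = (950.0, 2300.0),
    radius_range_um: tuple[float, float] = (2.0, 8.0),
    n_range: tuple[float, float] = (1.1, 1.5),
    grid_points: int = 10,
    k: int = 7,
) -> np.ndarray:
    """Top-k orthonormal principal components of simulated Mie curves.

    Extinction curves Q(nu; r, n) are generated on a ``grid_points x
    grid_points`` (radius, refractive index) grid, mean-centered and reduced
    by SVD over the fit-range wavenumber grid.  Returns (k, n_fit_points).
    """
    if radius_range_um[0] <= 0 or n_range[0] <= 1.0:
        raise ParameterError("radius must be positive and refractive index > 1")
    n_curves = grid_points * grid_points
    if k > n_curves:
        raise ParameterError(f"k={k} exceeds number of simulated curves ({n_curves})")
    idx = axis.window_indices(*fit_range)
    nu = axis.values[idx]
    radii = np.linspace(*radius_range_um, grid_points)
    indices = np.linspace(*n_range, grid_points)
    curves = np.array(
        [mie_extinction(nu, r, n) for r in radii for n in indices]
    )
    centered = curves - curves.mean(axis=0)
    # principal directions over the wavenumber grid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[:k]


@dataclass
class EMSCModel:
    """Extended multiplicative signal correction model.

    Decomposes a measured spectrum z(nu) over the fit range into
    ``c * m(nu) + sum_j b_j nu^j + sum_i g_i p_i(nu) + e(nu)`` where m is the
    reference chemical spectrum, the polynomial absorbs broad baselines and
    the p_i are Mie-extinction principal components.  The corrected spectrum
    is ``(z - baseline - mie) / c``.
    """

    reference: np.ndarray  # m(nu) over the fit-range grid
    axis: WavenumberAxis  # full axis the model was built on
    fit_range: tuple[float, float] = (950.0, 2300.0)
    mie_basis: np.ndarray | None = None  # (k, n_fit) or None
    baseline_order: int = 2
    n_iterations: int = 1
    c_min: float = 1e-3

    _fit_idx: np.ndarray = field(init=False, repr=False)
    _design: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        self._fit_idx = self.axis.window_indices(*self.fit_range)
        nu = self.axis.values[self._fit_idx]
        if self.reference.shape[-1] == len(self.axis):
            self.reference = np.asarray(self.reference, float)[self._fit_idx]
        elif self.reference.shape[-1] != self._fit_idx.size:
            raise ParameterError(
                "reference spectrum must cover the full axis or the fit range"
            )
        if self.mie_basis is not None and self.mie_basis.shape[1] != self._fit_idx.size:
            raise ParameterError("mie basis grid does not match the fit range")
        self._design = self._build_design(self.reference)

    @property
    def fit_wavenumbers(self) -> np.ndarray:
        return self.axis.values[self._fit_idx]

    def _build_design(self, reference: np.ndarray) -> np.ndarray:
        nu = self.fit_wavenumbers
        nu_scaled = (nu - nu.mean()) / (nu.max() - nu.min())  # conditioning
        cols = [reference]
        cols += [nu_scaled**j for j in range(self.baseline_order + 1)]
        if self.mie_basis is not None:
            cols += list(self.mie_basis)
        return np.column_stack(cols)

    @property
    def n_baseline(self) -> int:
        return self.baseline_order + 1

    @property
    def n_mie(self) -> int:
        return 0 if self.mie_basis is None else self.mie_basis.shape[0]


def _emsc_single_pass(
    spectra_fit: np.ndarray, design: np.ndarray, model: EMSCModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One EMSC least-squares pass; returns (corrected, coeffs, degenerate)."""
    coef, *_ = np.linalg.lstsq(design, spectra_fit.T, rcond=None)
    coef = coef.T  # (n_pixels, n_params)
    c = coef[:, 0]
    interference = coef[:, 1:] @ design[:, 1:].T
    degenerate = c <= model.c_min
    safe_c = np.where(degenerate, 1.0, c)
    corrected = (spectra_fit - interference) / safe_c[:, None]
    return corrected, coef, degenerate


def emsc_correct(
    spectra: np.ndarray, model: EMSCModel
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Apply EMSC to one spectrum or a stack (n, bands) over the fit range.

    Returns ``(corrected, info)`` where ``corrected`` has the fit-range band
    count and ``info`` carries ``c`` (multiplicative scale), ``baseline``
    and ``mie`` coefficients plus a ``degenerate`` flag for pixels whose
    fitted scale fell below ``c_min`` (these are returned uncorrected and
    should be excluded downstream).

    With ``n_iterations > 1`` the reference is replaced by the mean corrected
    spectrum and the fit repeated; on undistorted input the iteration is
    stationary after the first pass.
    """
    spectra = np.asarray(spectra, dtype=float)
    single = spectra.ndim == 1
    flat = np.atleast_2d(spectra)
    fit = flat[:, model._fit_idx] if flat.shape[1] == len(model.axis) else flat
    if fit.shape[1] != model._fit_idx.size:
        raise ParameterError("spectra do not cover the EMSC fit range")

    design = model._design
    corrected, coef, degenerate = _emsc_single_pass(fit, design, model)
    for _ in range(model.n_iterations - 1):
        good = ~degenerate
        if not good.any():
            break
        reference = corrected[good].mean(axis=0)
        design = model._build_design(reference)
        corrected, coef, degenerate = _emsc_single_pass(fit, design, model)
    corrected = np.where(degenerate[:, None], fit, corrected)

    info = {
        "c": coef[:, 0],
        "baseline": coef[:, 1 : 1 + model.n_baseline],
        "mie": coef[:, 1 + model.n_baseline :],
        "degenerate": degenerate,
    }
    if single:
        corrected = corrected[0]
        info = {key: val[0] for key, val in info.items()}
    return corrected, info


def emsc_correct_image(
    image: SpectralImage, model: EMSCModel
) -> tuple[SpectralImage, dict[str, np.ndarray]]:
    """EMSC-correct every QC-passing pixel of an image.

    Returns a new :class:`SpectralImage` cropped to the fit range, whose QC
    mask additionally excludes EMSC-degenerate pixels.  QC-failed pixels keep
    their raw (cropped) spectra but stay masked.
    """
    rows, cols, _ = image.cube.shape
    flat = image.cube.reshape(rows * cols, -1)
    mask_flat = image.qc_mask.reshape(-1)
    cropped = flat[:, model._fit_idx].copy()

    if mask_flat.any():
        corrected, info = emsc_correct(flat[mask_flat], model)
        cropped[mask_flat] = corrected
        degenerate = np.zeros(rows * cols, dtype=bool)
        degenerate[np.nonzero(mask_flat)[0][info["degenerate"]]] = True
    else:
        degenerate = np.zeros(rows * cols, dtype=bool)
        info = {}
    new_mask = mask_flat & ~degenerate

    sub_axis = WavenumberAxis(
        image.axis.values[model._fit_idx],
        nominal_resolution=image.axis.nominal_resolution,
    )
    out = SpectralImage(
        cube=cropped.reshape(rows, cols, -1),
        axis=sub_axis,
        pixel_size=image.pixel_size,
        stage_origin=image.stage_origin,
        qc_mask=new_mask.reshape(rows, cols),
    )
    return out, info


def savitzky_golay(
    spectra: np.ndarray,
    axis: WavenumberAxis,
    window_points: int = 9,
    poly_order: int = 4,
    deriv: int = 0,
) -> np.ndarray:
    """Savitzky-Golay smoothing or derivatives along the spectral axis.

    Output length equals input length; edges are handled by polynomial
    extrapolation of the terminal windows, which keeps the filter exact for
    polynomials up to ``poly_order`` over the whole support.  Derivatives
    are scaled by the actual wavenumber step, so ``deriv=2`` returns
    d^2 A / d nu^2 in absorbance * cm^2.  The default 9-point quartic is a
    standard choice for second-derivative band sharpening.  Used for
    unsupervised exploration only; the classifier consumes unsmoothed
    corrected spectra.
    """
    spectra = np.asarray(spectra, dtype=float)
    if window_points % 2 == 0:
        raise ParameterError("window_points must be odd")
    if poly_order >= window_points:
        raise ParameterError("poly_order must be smaller than window_points")
    if deriv > poly_order:
        raise ParameterError("deriv must not exceed poly_order")
    if spectra.shape[-1] < window_points:
        raise ParameterError("spectrum shorter than the filter window")
    # signed step so odd derivatives keep their orientation on descending axes
    delta = float(axis.values[1] - axis.values[0])
    return savgol_filter(
        spectra,
        window_length=window_points,
        polyorder=poly_order,
        deriv=deriv,
        delta=delta,
        axis=-1,
        mode="interp",
    )
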