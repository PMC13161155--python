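"""The four-step spectral preprocessing chain plus fingerprint cropping.

Order is fixed: Savitzky-Golay denoising → DWT-based glass-substrate removal
→ iterative spline fluorescence-baseline correction → min-max normalization,
followed by cropping to the 600–1800 cm⁻¹ fingerprint region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.optimize import nnls
from scipy.signal import savgol_filter
from scipy.ndimage import uniform_filter1d

from .errors import ParameterError, RamanError
from .io import SpectraSet, Spectrum, check_same_grid


@dataclass
class PreprocessConfig:
    """Tuning parameters; defaults are the pipeline's standard settings."""

    sg_window: int = 25
    sg_order: int = 3
    wavelet_name: str = "sym4"
    dwt_levels: int | None = None  # None = deepest level allowed, capped at 7
    spline_interval_init: int = 150
    spline_max_rounds: int = 20
    region: tuple[float, float] = (600.0, 1800.0)

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ParameterError(
                "sg_window must be odd and greater than sg_order "
                f"(got window={self.sg_window}, order={self.sg_order})"
            )
        if self.region[0] >= self.region[1]:
            raise ParameterError("region must satisfy lo < hi")


@dataclass
class PreprocessReport:
    """Per-sample QC surface: fitted glass scales, baselines, convergence."""

    glass_scales: np.ndarray
    baselines: np.ndarray
    baseline_converged: np.ndarray
    sample_ids: list[str] = field(default_factory=list)


def sg_denoise(spectrum: Spectrum, window: int = 25, order: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing; exact on polynomials of degree ≤ order.

    Edges are handled by polynomial fits within truncated windows
    (``mode='interp'``), so the polynomial-reproduction property holds on the
    full grid.
    """
    if window % 2 == 0 or window <= order:
        raise ParameterError(
            f"window must be odd and > order (got window={window}, order={order})"
        )
    if len(spectrum) < window:
        raise ParameterError(
            f"spectrum length {len(spectrum)} shorter than window {window}"
        )
    smoothed = savgol_filter(spectrum.intensities, window, order, mode="interp")
    return Spectrum(spectrum.wavenumbers, smoothed)


def select_sg_window(
    noisy: Spectrum,
    clean: Spectrum,
    candidates: list[int],
    order: int = 3,
) -> int:
    """Pick the candidate window minimizing RMSE to a clean reference.

    Ties break toward the smallest window.
    """
    if not candidates:
        raise ParameterError("candidates must be non-empty")
    check_same_grid(noisy.wavenumbers, clean.wavenumbers)
    best_w, best_rmse = None, np.inf
    for w in sorted(candidates):
        sm = sg_denoise(noisy, w, order)
        rmse = float(np.sqrt(np.mean((sm.intensities - clean.intensities) ** 2)))
        if rmse < best_rmse - 1e-15:
            best_w, best_rmse = w, rmse
    return best_w


def remove_glass_background(
    spectrum: Spectrum,
    glass_ref: Spectrum,
    wavelet_name: str = "sym4",
    dwt_levels: int | None = None,
) -> tuple[Spectrum, float]:
    """Fit and subtract the glass-substrate contribution via DWT scale separation.

    Both the cell spectrum and the glass reference are wavelet-decomposed;
    the cell's coarse approximation band is regressed onto the glass
    reference's coarse band, because the broad substrate hump lives in the
    approximation band while narrow Raman peaks concentrate in the detail
    bands and would bias a full-spectrum fit.  Densely packed lorentzian
    bands still leave a broad envelope in the coarse band, so the regression
    includes a quadratic nuisance polynomial that absorbs that envelope (and
    any fluorescence pedestal); the glass coefficient is constrained
    non-negative and ``scale × glass_ref`` is subtracted from the full
    spectrum.
    """
    check_same_grid(spectrum.wavenumbers, glass_ref.wavenumbers)
    wavelet = pywt.Wavelet(wavelet_name)
    max_level = pywt.dwt_max_level(len(spectrum), wavelet.dec_len)
    if dwt_levels is None:
        dwt_levels = max(1, min(7, max_level))
    if dwt_levels < 1 or dwt_levels > max_level:
        raise ParameterError(
            f"dwt_levels={dwt_levels} out of range [1, {max_level}] for "
            f"length {len(spectrum)} with {wavelet_name}"
        )
    ca_cell = pywt.wavedec(spectrum.intensities, wavelet, level=dwt_levels)[0]
    ca_glass = pywt.wavedec(glass_ref.intensities, wavelet, level=dwt_levels)[0]
    if float(ca_glass @ ca_glass) <= 0:
        return Spectrum(spectrum.wavenumbers, spectrum.intensities.copy()), 0.0
    t = np.linspace(-1.0, 1.0, ca_glass.size)
    # unbounded polynomial columns enter NNLS as +/- pairs so only the glass
    # coefficient is sign-constrained
    poly = [t**d for d in range(3)]
    A = np.column_stack([ca_glass] + [c for b in poly for c in (b, -b)])
    coef, _ = nnls(A, ca_cell)
    scale = float(coef[0])
    corrected = spectrum.intensities - scale * glass_ref.intensities
    return Spectrum(spectrum.wavenumbers, corrected), scale


def correct_baseline_spline(
    spectrum: Spectrum,
    interval_init: int = 150,
    max_rounds: int = 20,
) -> tuple[Spectrum, Spectrum, bool]:
    """Iterative equal-interval cubic-spline fluorescence-baseline estimate.

    The spectrum is first smoothed with a zero-order local fit (a moving
    average over the knot interval); each round, the local minimum of the
    working curve within each equal channel interval becomes a knot, a cubic
    spline through the knots is the candidate baseline, and points above the
    baseline are suppressed for the next round.  Stops when the baseline's
    relative change falls below 0.1% or ``max_rounds`` is reached.  Smoothing
    happens once, up front: re-smoothing the suppressed curve every round
    would compound the moving average's downward bias in concave regions and
    make the baseline creep below a genuinely smooth background.

    Returns ``(corrected, baseline, converged)`` with the corrected spectrum
    clipped at zero so downstream non-negativity constraints stay valid.
    """
    n = len(spectrum)
    if interval_init < 4:
        raise ParameterError("interval_init must be >= 4 channels")
    if interval_init > n:
        raise ParameterError(
            f"interval_init={interval_init} wider than spectrum length {n}"
        )
    w = spectrum.wavenumbers
    work = uniform_filter1d(spectrum.intensities, size=interval_init, mode="nearest")
    edges = np.arange(0, n, interval_init)
    if edges[-1] < n:
        edges = np.append(edges, n)
    prev_baseline = None
    converged = False
    baseline = np.zeros(n)
    for _ in range(max_rounds):
        knot_x, knot_y = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            j = lo + int(np.argmin(work[lo:hi]))
            knot_x.append(w[j])
            knot_y.append(work[j])
        if len(knot_x) < 2:
            raise ParameterError("too few spline knots; decrease interval_init")
        if len(knot_x) < 4:
            baseline = np.interp(w, knot_x, knot_y)
        else:
            baseline = CubicSpline(knot_x, knot_y, bc_type="natural")(w)
        work = np.minimum(work, baseline)
        if prev_baseline is not None:
            denom = float(np.linalg.norm(prev_baseline))
            change = float(np.linalg.norm(baseline - prev_baseline))
            if denom == 0.0 or change / denom < 1e-3:
                converged = True
                break
        prev_baseline = baseline
    corrected = np.clip(spectrum.intensities - baseline, 0.0, None)
    return Spectrum(w, corrected), Spectrum(w, baseline), converged


def minmax_normalize(spectrum: Spectrum) -> Spectrum:
    """Rescale intensities to [0, 1]; constant spectra are degenerate."""
    x = spectrum.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ParameterError("cannot min-max normalize a constant spectrum")
    return Spectrum(spectrum.wavenumbers, (x - lo) / (hi - lo))


def crop_region(dataset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Retain channels with lo ≤ wavenumber ≤ hi (closed interval)."""
    if lo >= hi:
        raise ParameterError("crop region must satisfy lo < hi")
    mask = (dataset.wavenumbers >= lo) & (dataset.wavenumbers <= hi)
    if mask.sum() < 2:
        raise ParameterError(
            f"crop region [{lo}, {hi}] has no overlap with the grid "
            f"[{dataset.wavenumbers[0]}, {dataset.wavenumbers[-1]}]"
        )
    return SpectraSet(dataset.wavenumbers[mask], dataset.matrix[:, mask], list(dataset.meta))


def preprocess_pipeline(
    dataset: SpectraSet,
    glass_ref: Spectrum,
    config: PreprocessConfig | None = None,
) -> tuple[SpectraSet, PreprocessReport]:
    """Run the fixed four-step chain on every row, then crop the fingerprint region."""
    config = config or PreprocessConfig()
    check_same_grid(dataset.wavenumbers, glass_ref.wavenumbers, "dataset and glass reference")
    out = np.empty_like(dataset.matrix)
    scales = np.empty(dataset.n_samples)
    baselines = np.empty_like(dataset.matrix)
    flags = np.empty(dataset.n_samples, dtype=bool)
    for i in range(dataset.n_samples):
        stage = "sg_denoise"
        try:
            sp = sg_denoise(dataset.spectrum(i), config.sg_window, config.sg_order)
            stage = "remove_glass_background"
            sp, scales[i] = remove_glass_background(
                sp, glass_ref, config.wavelet_name, config.dwt_levels
            )
            stage = "correct_baseline_spline"
            sp, base, flags[i] = correct_baseline_spline(
                sp, config.spline_interval_init, config.spline_max_rounds
            )
            baselines[i] = base.intensities
            stage = "minmax_normalize"
            sp = minmax_normalize(sp)
        except RamanError as exc:
            raise type(exc)(
                f"{stage} failed on sample {dataset.sample_ids[i]}: {exc}"
            ) from exc
        out[i] = sp.intensities
    processed = SpectraSet(dataset.wavenumbers.copy(), out, list(dataset.meta))
    processed = crop_region(processed, *config.region)
    report = PreprocessReport(scales, baselines, flags, list(dataset.sample_ids))
    return processed, report
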