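"""Group-level spectral descriptives and per-peak statistics.

Mean ± SD spectra per response group, the CR−NR difference spectrum,
characteristic-peak intensity extraction (windowed maximum, ±5 cm⁻¹
default), the normality/variance-driven choice between Student's t and the
Mann-Whitney U test, and per-peak ROC analysis — by default at patient level
to avoid pseudoreplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DataError, LabelError, ParameterError
from .io import SpectraSet, Spectrum, check_same_grid
from .chemometrics import ROCCurve, roc_auc

#: Characteristic-band list: (center cm⁻¹, assignment, molecule class).
DEFAULT_PEAKS: list[tuple[float, str, str]] = [
    (662, "glutathione", "protein"),
    (682, "G ring breathing (DNA bases)", "nucleic_acid"),
    (747, "T ring breathing (DNA/RNA)", "nucleic_acid"),
    (785, "U/T/C ring breathing, O-P-O backbone", "nucleic_acid"),
    (943, "skeletal modes (polysaccharides)", "carbohydrate"),
    (1003, "phenylalanine", "protein"),
    (1095, "PO2- phosphodioxy", "nucleic_acid"),
    (1175, "cytosine, guanine", "nucleic_acid"),
    (1235, "amide III", "protein"),
    (1298, "acyl chains / fatty acids", "lipid"),
    (1382, "CH3 band", "lipid"),
    (1441, "C-H deformation", "protein/lipid"),
    (1671, "amide I / cholesterol", "protein/lipid"),
]


@dataclass
class PeakRocResult:
    curve: ROCCurve
    positive_group: str  # group whose higher intensities drive AUC >= 0.5


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mean_sd_spectrum(dataset: SpectraSet, group: str) -> tuple[Spectrum, Spectrum]:
    """Channelwise mean and sample SD over one group's rows."""
    mask = dataset.groups == group
    if not mask.any():
        raise DataError(f"no samples in group {group!r}")
    sub = dataset.matrix[mask]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else np.zeros_like(mean)
    return Spectrum(dataset.wavenumbers, mean), Spectrum(dataset.wavenumbers, sd)


def difference_spectrum(mean_a: Spectrum, mean_b: Spectrum) -> Spectrum:
    """Signed channelwise difference mean_a − mean_b."""
    check_same_grid(mean_a.wavenumbers, mean_b.wavenumbers)
    return Spectrum(mean_a.wavenumbers, mean_a.intensities - mean_b.intensities)


def extract_peak_intensity(
    spectrum: Spectrum, center: float, halfwidth: float = 5.0
) -> float:
    """Maximum intensity within [center − halfwidth, center + halfwidth].

    A windowed maximum is robust to small wavenumber-calibration shifts.
    With halfwidth 0 the nearest channel's intensity is returned.
    """
    w = spectrum.wavenumbers
    if halfwidth == 0:
        if center < w[0] or center > w[-1]:
            raise ParameterError(f"peak center {center} outside grid span")
        return float(spectrum.intensities[int(np.argmin(np.abs(w - center)))])
    mask = (w >= center - halfwidth) & (w <= center + halfwidth)
    if not mask.any():
        raise ParameterError(
            f"window [{center - halfwidth}, {center + halfwidth}] has no overlap "
            f"with the grid [{w[0]}, {w[-1]}]"
        )
    return float(spectrum.intensities[mask].max())


def group_compare(values_a, values_b, alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided two-group comparison with the standard test-selection rule.

    Shapiro-Wilk normality on each group and an F-ratio variance-homogeneity
    check, each at α=0.05: if all pass, an unpaired Student's t-test; else a
    tie-corrected two-sided Mann-Whitney U.  Returns (p, test name).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DataError("each group needs at least 3 values")
    normal = True
    for v in (a, b):
        if np.ptp(v) == 0:  # Shapiro undefined for constant data
            normal = False
            break
        if stats.shapiro(v).pvalue <= alpha:
            normal = False
            break
    if normal:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va > 0 and vb > 0:
            f = max(va, vb) / min(va, vb)
            dfn = (a.size if va >= vb else b.size) - 1
            dfd = (b.size if va >= vb else a.size) - 1
            p_var = 2.0 * min(stats.f.sf(f, dfn, dfd), 0.5)
            if p_var <= alpha:
                normal = False
    if normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.pvalue), "t-test"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue), "mann-whitney"


def per_peak_roc(peak_values, labels) -> PeakRocResult:
    """ROC of one peak's intensities, oriented so AUC ≥ 0.5.

    The reported orientation names the group whose larger intensities carry
    the discrimination.
    """
    v = np.asarray(peak_values, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise LabelError(f"need exactly two groups, got {classes}")
    curve = roc_auc(v, y)
    # roc_auc treats NR (or the lexicographically last class) as positive
    from .chemometrics import POSITIVE_CLASS

    pos = POSITIVE_CLASS if POSITIVE_CLASS in classes else classes[-1]
    neg = next(c for c in classes if c != pos)
    if curve.auc >= 0.5:
        return PeakRocResult(curve, pos)
    flipped = roc_auc(-v, y)
    return PeakRocResult(flipped, neg)


def build_peak_table(
    dataset_patient_level: SpectraSet,
    peak_list: list[tuple[float, str, str]] | None = None,
    halfwidth: float = 5.0,
) -> pd.DataFrame:
    """Per-peak intensities, group stats, test p-value, stars and AUC.

    Expects one row per patient (see
    :func:`ramancell.chemometrics.patient_mean_spectra`); running on
    cell-level data inflates significance through pseudoreplication.
    """
    peak_list = peak_list if peak_list is not None else DEFAULT_PEAKS
    ds = dataset_patient_level
    groups = ds.groups
    present = sorted(set(groups.tolist()) - {"UNKNOWN"})
    if len(present) != 2:
        raise LabelError(f"need exactly two groups, got {present}")
    a, b = present
    rows = []
    for center, label, mclass in peak_list:
        vals = np.array(
            [extract_peak_intensity(ds.spectrum(i), center, halfwidth) for i in range(ds.n_samples)]
        )
        va, vb = vals[groups == a], vals[groups == b]
        p, test = group_compare(va, vb)
        roc = per_peak_roc(vals, groups)
        rows.append(
            {
                "center": center,
                "assignment": label,
                "class": mclass,
                f"mean_{a}": va.mean(),
                f"sd_{a}": va.std(ddof=1),
                f"mean_{b}": vb.mean(),
                f"sd_{b}": vb.std(ddof=1),
                "p_value": p,
                "test_used": test,
                "stars": significance_stars(p),
                "auc": roc.curve.auc,
                "higher_in": roc.positive_group,
            }
        )
    return pd.DataFrame(rows)
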