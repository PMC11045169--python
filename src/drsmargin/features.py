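"""Bespoke spectral shape features on fixed wavelength ranges.

For each of 16 wavelength ranges (and each of the five probe fibers), five
quantities are computed from the normalized spectrum:

1. ``slope`` — gradient of the chord through the spectrum's maxima in the
   first 25% and the last 25% of the range (by wavelength span);
2. ``max_diff`` — the maximum of chord_line(lambda) - spectrum(lambda)
   between the chord endpoints, i.e. the depth of the absorption dip below
   its chord;
3. ``lambda_max_diff`` — the wavelength of that maximum (first occurrence
   on ties, scanning ascending);
4./5. ``infl_left`` / ``infl_right`` — the wavelengths of the nearest
   inflection points (sign changes of the Savitzky-Golay-smoothed second
   derivative) left and right of ``lambda_max_diff``; the range edge is
   returned (and flagged) when no sign change exists on that side.

16 ranges x 5 operators = 80 features per fiber; with five fibers, 400 per
measurement.  The default range set covers the NIR absorption dips of fat,
water and collagen; it is configuration, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .preprocess import ANALYSIS_WAVELENGTHS, N_ANALYSIS_SAMPLES, AnalysisSpectrum

__all__ = [
    "FeatureRange",
    "RangeFeatures",
    "FeatureVector",
    "DEFAULT_RANGES",
    "OPERATORS",
    "chord_slope",
    "chord_deficit",
    "inflection_points",
    "extract_features",
    "range_feature_matrix",
    "feature_names",
]

OPERATORS = ("slope", "max_diff", "lambda_max_diff", "infl_left", "infl_right")

_GRID_LO = float(ANALYSIS_WAVELENGTHS[0])
_GRID_HI = float(ANALYSIS_WAVELENGTHS[-1])


@dataclass(frozen=True)
class FeatureRange:
    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (_GRID_LO <= self.lo < self.hi <= _GRID_HI):
            raise ValueError(f"range [{self.lo}, {self.hi}] outside analysis grid")
        if self.hi - self.lo < 7:
            raise ValueError("range must contain at least 8 grid samples")
        if not self.name:
            object.__setattr__(self, "name", f"{self.lo:.0f}-{self.hi:.0f}")


# The 16 distinct NIR ranges over which the shape features are computed.
_DEFAULT_RANGE_BOUNDS = [
    (1213, 1248), (931, 1195), (1224, 1331), (1142, 1225),
    (1021, 1102), (999, 1034), (1395, 1430), (1404, 1437),
    (1467, 1502), (1121, 1401), (932, 967), (1112, 1147),
    (1201, 1236), (1382, 1574), (883, 1149), (926, 1149),
]
DEFAULT_RANGES: tuple[FeatureRange, ...] = tuple(
    FeatureRange(float(max(lo, _GRID_LO)), float(hi)) for lo, hi in _DEFAULT_RANGE_BOUNDS
)


@dataclass(frozen=True)
class RangeFeatures:
    """The five shape features of one spectrum over one range."""

    slope: float
    max_diff: float
    lambda_max_diff: float
    lambda_infl_left: float
    lambda_infl_right: float
    clamped_left: bool
    clamped_right: bool


@dataclass(frozen=True)
class FeatureVector:
    """Named 400-feature vector for one measured location."""

    location_id: str
    patient_id: str
    context: str
    label: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != self.values.size:
            raise ValueError("names and values must align")


def _range_indices(rng: FeatureRange) -> tuple[int, int]:
    i_lo = int(np.searchsorted(ANALYSIS_WAVELENGTHS, rng.lo, side="left"))
    i_hi = int(np.searchsorted(ANALYSIS_WAVELENGTHS, rng.hi, side="right")) - 1
    return i_lo, i_hi


def _quartile_argmax(matrix: np.ndarray, rng: FeatureRange) -> tuple[np.ndarray, np.ndarray]:
    """Per-row argmax (absolute grid index) in the first and last quartiles.

    Quartiles are defined by wavelength span; ties take the smaller
    wavelength (``argmax`` returns the first maximum).
    """
    i_lo, i_hi = _range_indices(rng)
    span = rng.hi - rng.lo
    q1_hi = int(np.searchsorted(ANALYSIS_WAVELENGTHS, rng.lo + 0.25 * span, side="right")) - 1
    q4_lo = int(np.searchsorted(ANALYSIS_WAVELENGTHS, rng.hi - 0.25 * span, side="left"))
    if q1_hi < i_lo + 1 or i_hi < q4_lo + 1:
        raise ValueError(f"range {rng.name}: quartiles too small on this grid")
    idx1 = i_lo + np.argmax(matrix[:, i_lo : q1_hi + 1], axis=1)
    idx2 = q4_lo + np.argmax(matrix[:, q4_lo : i_hi + 1], axis=1)
    return idx1, idx2


def range_feature_matrix(
    matrix: np.ndarray,
    rng: FeatureRange,
    d2: np.ndarray | None = None,
    sg_window: int = 11,
    sg_order: int = 2,
    deficit_mode: str = "deficit",
) -> np.ndarray:
    """Vectorized five-feature block for a (n_spectra, 1200) matrix.

    Returns an (n_spectra, 5) array ordered as ``OPERATORS``.  ``d2`` may
    carry a precomputed smoothed second derivative of ``matrix`` (same
    shape) to avoid re-filtering per range.
    """
    matrix = np.atleast_2d(np.asarray(matrix, float))
    if matrix.shape[1] != N_ANALYSIS_SAMPLES:
        raise ValueError("spectra must live on the 1200-sample analysis grid")
    n = matrix.shape[0]
    if d2 is None:
        d2 = savgol_filter(matrix, sg_window, sg_order, deriv=2, axis=-1)

    idx1, idx2 = _quartile_argmax(matrix, rng)
    lam1 = ANALYSIS_WAVELENGTHS[idx1]
    lam2 = ANALYSIS_WAVELENGTHS[idx2]
    i1 = matrix[np.arange(n), idx1]
    i2 = matrix[np.arange(n), idx2]
    if np.any(idx2 == idx1):
        raise ValueError(f"range {rng.name}: degenerate chord (coincident endpoints)")
    slope = (i2 - i1) / (lam2 - lam1)

    # chord deficit over [lambda1, lambda2]
    i_lo, i_hi = _range_indices(rng)
    cols = np.arange(i_lo, i_hi + 1)
    lam = ANALYSIS_WAVELENGTHS[cols]
    chord = i1[:, None] + slope[:, None] * (lam[None, :] - lam1[:, None])
    diff = chord - matrix[:, i_lo : i_hi + 1]
    if deficit_mode == "absolute":
        diff = np.abs(diff)
    inside = (cols[None, :] >= idx1[:, None]) & (cols[None, :] <= idx2[:, None])
    diff_masked = np.where(inside, diff, -np.inf)
    rel_max = np.argmax(diff_masked, axis=1)  # first occurrence on ties
    max_diff = diff_masked[np.arange(n), rel_max]
    m_abs = i_lo + rel_max
    lam_max_diff = ANALYSIS_WAVELENGTHS[m_abs]

    # inflection points: nearest second-derivative sign change on each side
    d2r = d2[:, i_lo : i_hi + 1]
    prod = d2r[:, :-1] * d2r[:, 1:]
    crossing = prod < 0  # (n, L-1); index i means a crossing in (i, i+1)
    seg = np.arange(crossing.shape[1])
    m_rel = rel_max

    left_valid = crossing & (seg[None, :] < m_rel[:, None])
    left_seg = np.where(left_valid, seg[None, :], -1).max(axis=1)
    right_valid = crossing & (seg[None, :] >= m_rel[:, None])
    right_seg = np.where(right_valid, seg[None, :], crossing.shape[1] + 1).min(axis=1)

    def _interp_crossing(seg_idx: np.ndarray) -> np.ndarray:
        rows = np.arange(n)
        s = np.clip(seg_idx, 0, crossing.shape[1] - 1)
        a = d2r[rows, s]
        b = d2r[rows, s + 1]
        denom = np.where(a != b, a - b, 1.0)
        frac = np.where(a != b, a / denom, 0.0)
        return ANALYSIS_WAVELENGTHS[i_lo + s] + frac

    lam_left = np.where(left_seg >= 0, _interp_crossing(left_seg), ANALYSIS_WAVELENGTHS[i_lo])
    lam_right = np.where(
        right_seg <= crossing.shape[1], _interp_crossing(right_seg), ANALYSIS_WAVELENGTHS[i_hi]
    )
    # the interpolated crossing can land a hair past lambda_max_diff; keep order
    lam_left = np.minimum(lam_left, lam_max_diff)
    lam_right = np.maximum(lam_right, lam_max_diff)

    return np.column_stack([slope, max_diff, lam_max_diff, lam_left, lam_right])


def chord_slope(
    spectrum: AnalysisSpectrum | np.ndarray, rng: FeatureRange
) -> tuple[float, tuple[float, float, float, float]]:
    """Chord slope plus its endpoints (lambda1, I1, lambda2, I2)."""
    x = spectrum.intensities if isinstance(spectrum, AnalysisSpectrum) else np.asarray(spectrum)
    matrix = np.atleast_2d(x)
    idx1, idx2 = _quartile_argmax(matrix, rng)
    lam1, lam2 = float(ANALYSIS_WAVELENGTHS[idx1[0]]), float(ANALYSIS_WAVELENGTHS[idx2[0]])
    i1, i2 = float(matrix[0, idx1[0]]), float(matrix[0, idx2[0]])
    if lam1 == lam2:
        raise ValueError("degenerate chord")
    return (i2 - i1) / (lam2 - lam1), (lam1, i1, lam2, i2)


def chord_deficit(
    spectrum: AnalysisSpectrum | np.ndarray,
    rng: FeatureRange,
    chord: tuple[float, float, float, float] | None = None,
) -> tuple[float, float]:
    """Maximum chord-minus-spectrum deficit and its wavelength."""
    x = spectrum.intensities if isinstance(spectrum, AnalysisSpectrum) else np.asarray(spectrum)
    feats = range_feature_matrix(np.atleast_2d(x), rng)
    return float(feats[0, 1]), float(feats[0, 2])


def inflection_points(
    spectrum: AnalysisSpectrum | np.ndarray,
    rng: FeatureRange,
    lambda_max_diff: float | None = None,
    sg_window: int = 11,
    sg_order: int = 2,
) -> tuple[float, float, tuple[bool, bool]]:
    """Nearest inflection wavelengths around the maximum-deficit point.

    Flags indicate clamping to the range edge (no curvature sign change on
    that side).
    """
    x = spectrum.intensities if isinstance(spectrum, AnalysisSpectrum) else np.asarray(spectrum)
    feats = range_feature_matrix(np.atleast_2d(x), rng, sg_window=sg_window, sg_order=sg_order)
    lam_left, lam_right = float(feats[0, 3]), float(feats[0, 4])
    i_lo, i_hi = _range_indices(rng)
    clamped = (
        lam_left == float(ANALYSIS_WAVELENGTHS[i_lo]),
        lam_right == float(ANALYSIS_WAVELENGTHS[i_hi]),
    )
    return lam_left, lam_right, clamped


def feature_names(
    ranges: tuple[FeatureRange, ...] = DEFAULT_RANGES, n_fibers: int = 5
) -> tuple[str, ...]:
    """Stable, order-deterministic names: fiber-major, then range, then operator."""
    return tuple(
        f"f{f}_{rng.name}_{op}"
        for f in range(1, n_fibers + 1)
        for rng in ranges
        for op in OPERATORS
    )


def extract_features(
    spectra: list[AnalysisSpectrum],
    ranges: tuple[FeatureRange, ...] = DEFAULT_RANGES,
    label: str = "",
    context: str = "",
    sg_window: int = 11,
    sg_order: int = 2,
) -> FeatureVector:
    """Assemble the full per-location feature vector from five fiber spectra."""
    if len(spectra) != 5:
        raise ValueError(f"expected exactly 5 fiber spectra, got {len(spectra)}")
    matrix = np.array([s.intensities for s in spectra])
    d2 = savgol_filter(matrix, sg_window, sg_order, deriv=2, axis=-1)
    blocks = [
        range_feature_matrix(matrix, rng, d2=d2, sg_window=sg_window, sg_order=sg_order)
        for rng in ranges
    ]
    # (5 fibers, n_ranges, 5 ops) -> fiber-major flat vector
    values = np.stack(blocks, axis=1).reshape(-1)
    return FeatureVector(
        location_id=spectra[0].location_id,
        patient_id=spectra[0].patient_id,
        context=context,
        label=label,
        names=feature_names(ranges),
        values=values,
    )
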