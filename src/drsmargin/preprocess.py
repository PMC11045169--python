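"""Spectral preprocessing: replicate averaging, range stitching, extremity
trimming, multiplicative scatter correction.

Pipeline order is fixed: average -> stitch -> trim -> MSC.  The analysis
grid is the uniform 1 nm grid over the half-open window [400, 1600) nm,
i.e. samples at 400, 401, ..., 1599 nm — exactly 1200 wavelengths.  The
extremity windows 350-400 and 1600-1700 nm are discarded because the
simulated (and real) instruments have a poor signal-to-noise ratio there.

MSC regresses each spectrum on a reference (the pointwise mean of the
*training* spectra) as x ~ a + b*m and returns (x - a)/b, removing
additive offsets and multiplicative path-length/scatter differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import RawMeasurement

__all__ = [
    "ANALYSIS_WAVELENGTHS",
    "STITCH_WAVELENGTHS",
    "N_ANALYSIS_SAMPLES",
    "AnalysisSpectrum",
    "MSCReference",
    "average_replicates",
    "stitch",
    "trim",
    "fit_msc_reference",
    "msc_normalize",
    "preprocess_measurement",
]

ANALYSIS_WAVELENGTHS = np.arange(400.0, 1600.0, 1.0)  # 1200 samples
N_ANALYSIS_SAMPLES = ANALYSIS_WAVELENGTHS.size
STITCH_WAVELENGTHS = np.arange(200.0, 1751.0, 1.0)

# Overlap of the two spectrometer ranges; the stitch crossfades linearly
# from pure-visible at 900 nm to pure-NIR at 1160 nm.
_OVERLAP_LO, _OVERLAP_HI = 900.0, 1160.0


@dataclass(frozen=True)
class AnalysisSpectrum:
    """One stitched, trimmed (and possibly MSC-normalized) fiber spectrum."""

    intensities: np.ndarray  # (1200,)
    fiber_index: int  # 1..5
    location_id: str = ""
    patient_id: str = ""
    wavelengths: np.ndarray = field(default_factory=lambda: ANALYSIS_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        if self.intensities.shape != (N_ANALYSIS_SAMPLES,):
            raise ValueError(
                f"expected {N_ANALYSIS_SAMPLES} samples, got {self.intensities.shape}"
            )
        if self.wavelengths.shape != (N_ANALYSIS_SAMPLES,):
            raise ValueError("wavelength grid must have 1200 samples")


@dataclass(frozen=True)
class MSCReference:
    """Frozen MSC reference: mean of the training spectra on the analysis grid."""

    mean_intensities: np.ndarray
    n_contributing: int
    wavelengths: np.ndarray = field(default_factory=lambda: ANALYSIS_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        if self.mean_intensities.shape != (N_ANALYSIS_SAMPLES,):
            raise ValueError("reference must live on the 1200-sample analysis grid")


def average_replicates(replicates: np.ndarray) -> np.ndarray:
    """Pointwise mean of the three consecutive replicate spectra.

    ``replicates`` is (n_replicates, n_wavelengths); all replicates share
    one wavelength grid by construction of ``RawMeasurement``.
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.ndim != 2:
        raise ValueError("replicates must be a 2-D (n_replicates, n_wavelengths) array")
    return replicates.mean(axis=0)


def stitch(
    vis_wavelengths: np.ndarray,
    vis: np.ndarray,
    nir_wavelengths: np.ndarray,
    nir: np.ndarray,
    policy: str = "crossfade",
) -> np.ndarray:
    """Merge the visible and NIR spectra onto the uniform 1 nm 200-1750 grid.

    Both inputs are resampled by linear interpolation.  Where only one
    range covers a wavelength it is used verbatim; in the overlap
    [900, 1160] nm the default policy is a linear crossfade with
    vis-weight 1 at 900 nm falling to 0 at 1160 nm.  ``policy`` may also be
    ``"vis-priority"`` or ``"nir-priority"`` (hard handover at the
    respective overlap edge).
    """
    vis_wavelengths = np.asarray(vis_wavelengths, float)
    nir_wavelengths = np.asarray(nir_wavelengths, float)
    if vis_wavelengths.size == 0 or nir_wavelengths.size == 0:
        raise ValueError("empty input spectrum")
    if nir_wavelengths[0] > vis_wavelengths[-1]:
        raise ValueError("spectrometer ranges do not overlap; cannot stitch")

    grid = STITCH_WAVELENGTHS
    out = np.empty_like(grid)
    vis_cover = grid <= vis_wavelengths[-1]
    nir_cover = grid >= nir_wavelengths[0]
    vis_i = np.interp(grid, vis_wavelengths, np.asarray(vis, float))
    nir_i = np.interp(grid, nir_wavelengths, np.asarray(nir, float))

    out[vis_cover & ~nir_cover] = vis_i[vis_cover & ~nir_cover]
    out[nir_cover & ~vis_cover] = nir_i[nir_cover & ~vis_cover]
    both = vis_cover & nir_cover
    if policy == "crossfade":
        w_vis = np.clip((_OVERLAP_HI - grid[both]) / (_OVERLAP_HI - _OVERLAP_LO), 0.0, 1.0)
        out[both] = w_vis * vis_i[both] + (1.0 - w_vis) * nir_i[both]
    elif policy == "vis-priority":
        out[both] = vis_i[both]
    elif policy == "nir-priority":
        out[both] = nir_i[both]
    else:
        raise ValueError(f"unknown stitch policy {policy!r}")
    return out


def trim(
    intensities: np.ndarray,
    wavelengths: np.ndarray | None = None,
    fiber_index: int = 0,
    location_id: str = "",
    patient_id: str = "",
) -> AnalysisSpectrum:
    """Cut a full-range stitched spectrum down to the 1200-sample window.

    Retains exactly the samples at 400, 401, ..., 1599 nm.  Accepts either
    a spectrum on the standard stitch grid or any grid covering [400,
    1599]; already-trimmed input passes through unchanged (idempotent).
    """
    intensities = np.asarray(intensities, float)
    if wavelengths is None:
        wavelengths = STITCH_WAVELENGTHS if intensities.size == STITCH_WAVELENGTHS.size else None
        if intensities.size == N_ANALYSIS_SAMPLES:
            wavelengths = ANALYSIS_WAVELENGTHS
        if wavelengths is None:
            raise ValueError("wavelengths required for non-standard grids")
    wavelengths = np.asarray(wavelengths, float)
    if wavelengths[0] > ANALYSIS_WAVELENGTHS[0] or wavelengths[-1] < ANALYSIS_WAVELENGTHS[-1]:
        raise ValueError("input must cover [400, 1599] nm")
    values = np.interp(ANALYSIS_WAVELENGTHS, wavelengths, intensities)
    return AnalysisSpectrum(
        intensities=values,
        fiber_index=fiber_index,
        location_id=location_id,
        patient_id=patient_id,
    )


def fit_msc_reference(
    spectra: list[AnalysisSpectrum] | np.ndarray, allow_single: bool = False
) -> MSCReference:
    """Pointwise mean over the provided (training) spectra.

    The reference is fitted on training data only and frozen into the model
    artifact, so applying it to test spectra leaks nothing.
    """
    if isinstance(spectra, np.ndarray):
        matrix = np.atleast_2d(spectra)
    else:
        matrix = np.array([s.intensities for s in spectra]) if spectra else np.empty((0, 0))
    if matrix.size == 0:
        raise ValueError("cannot fit an MSC reference from an empty spectrum list")
    if matrix.shape[0] < 2 and not allow_single:
        raise ValueError("need >= 2 spectra (pass allow_single=True to override)")
    if matrix.shape[1] != N_ANALYSIS_SAMPLES:
        raise ValueError("spectra must live on the 1200-sample analysis grid")
    return MSCReference(mean_intensities=matrix.mean(axis=0), n_contributing=matrix.shape[0])


def msc_coefficients(
    intensities: np.ndarray, reference: MSCReference
) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients (a, b) of x ~ a + b*m for each row of ``intensities``."""
    x = np.atleast_2d(np.asarray(intensities, float))
    m = reference.mean_intensities
    m_center = m - m.mean()
    denom = float(m_center @ m_center)
    if denom <= 0:
        raise ValueError("MSC reference is constant; cannot normalize")
    b = (x - x.mean(axis=1, keepdims=True)) @ m_center / denom
    a = x.mean(axis=1) - b * m.mean()
    return a, b


def msc_normalize(
    spectrum: AnalysisSpectrum | np.ndarray,
    reference: MSCReference,
    slope_tolerance: float = 1e-8,
) -> AnalysisSpectrum | np.ndarray:
    """Multiplicative scatter correction of one spectrum (or a matrix).

    Fits x ~ a + b*m over all 1200 wavelengths and returns (x - a)/b.
    Refitting the corrected spectrum against m yields a=0, b=1, so the
    operation is idempotent.  A slope magnitude below ``slope_tolerance``
    indicates a degenerate (near-constant) spectrum and raises.
    """
    if isinstance(spectrum, AnalysisSpectrum):
        a, b = msc_coefficients(spectrum.intensities[None, :], reference)
        if abs(b[0]) < slope_tolerance:
            raise ValueError("degenerate spectrum: MSC slope below tolerance")
        corrected = (spectrum.intensities - a[0]) / b[0]
        return AnalysisSpectrum(
            intensities=corrected,
            fiber_index=spectrum.fiber_index,
            location_id=spectrum.location_id,
            patient_id=spectrum.patient_id,
        )
    x = np.atleast_2d(np.asarray(spectrum, float))
    a, b = msc_coefficients(x, reference)
    if np.any(np.abs(b) < slope_tolerance):
        raise ValueError("degenerate spectrum: MSC slope below tolerance")
    return (x - a[:, None]) / b[:, None]


def preprocess_measurement(
    measurement: RawMeasurement, stitch_policy: str = "crossfade"
) -> list[AnalysisSpectrum]:
    """average -> stitch -> trim for all five fibers of one measurement.

    MSC is *not* applied here: the reference depends on the training fold
    and is applied later by the model pipeline.
    """
    spectra = []
    for i, fiber in enumerate(measurement.fibers, start=1):
        vis = average_replicates(fiber.vis_replicates)
        nir = average_replicates(fiber.nir_replicates)
        full = stitch(
            measurement.vis_wavelengths, vis, measurement.nir_wavelengths, nir, stitch_policy
        )
        spectra.append(
            trim(
                full,
                STITCH_WAVELENGTHS,
                fiber_index=i,
                location_id=measurement.location_id,
                patient_id=measurement.patient_id,
            )
        )
    return spectra
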