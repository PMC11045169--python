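"""Synthetic cohorts of five-fiber, dual-range diffuse reflectance spectra.

The clinical measurement this package analyses is a fiber-optic probe with
five illumination fibers around one detection fiber, read out by two
spectrometers (visible: 200-1160 nm, near-infrared: 900-1750 nm), three
consecutive acquisitions per probed tissue location.  No public dataset of
such measurements exists, so this module generates cohorts with the
statistical structure the downstream analysis assumes:

* two tissue classes — tumor (low fat, high water/collagen) and healthy
  breast tissue (high fat) — whose reflectance differs most around the fat
  (~1210 nm) and water (~1450 nm) absorption bands;
* in vivo vs ex vivo context expressed through blood oxygen saturation;
* strong class imbalance at the location level;
* patient-level random effects, so that patient-grouped cross-validation
  splitting is the statistically correct procedure;
* inflated noise at the spectral extremities (350-400 and 1600-1700 nm),
  which is why those windows are trimmed during preprocessing;
* a negative, roughly linear relation between the tumor area percentage in
  the 2-mm margin band and the tumor-margin distance.

The forward model is a semi-empirical modified Beer-Lambert law

    R(lambda) = g * exp(-ell * mu_a(lambda)),

with a wavelength-independent effective path length ``ell`` and a total
absorption coefficient assembled from Gaussian-band chromophore templates
(fat, water, collagen, oxy-/deoxy-hemoglobin).  This is deliberately not a
radiometrically accurate diffusion model: the pipeline only needs spectra
with realistic class structure, band locations and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChromophoreTemplate",
    "TissueComposition",
    "SimulationConfig",
    "NoiseConfig",
    "CompositionPriors",
    "FiberSpectra",
    "RawMeasurement",
    "GroundTruth",
    "DEFAULT_CHROMOPHORES",
    "VIS_WAVELENGTHS",
    "NIR_WAVELENGTHS",
    "evaluate_absorption",
    "total_absorption",
    "sample_composition",
    "simulate_measurement",
    "simulate_cohort",
    "render_section",
    "well_separated_config",
]

# Native spectrometer grids (nm).  The real instruments have non-uniform
# pixel-to-wavelength maps; a uniform 2 nm grid is sufficient because the
# preprocessing stage resamples everything to a common 1 nm grid anyway.
VIS_WAVELENGTHS = np.arange(200.0, 1161.0, 2.0)
NIR_WAVELENGTHS = np.arange(900.0, 1751.0, 2.0)

N_FIBERS = 5
N_REPLICATES = 3


@dataclass(frozen=True)
class ChromophoreTemplate:
    """Gaussian-band approximation of a chromophore absorption spectrum.

    ``bands`` is a sequence of ``(center_nm, width_nm, amplitude)`` triples;
    the template evaluates to ``baseline + sum_b amp_b *
    exp(-(lambda-center_b)^2 / (2 width_b^2))``.  Published extinction
    tables are not reproduced here: only the band *locations* matter for the
    behaviour of the downstream spectral features.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for center, width, amplitude in self.bands:
            if not (200.0 <= center <= 1750.0):
                raise ValueError(f"band center {center} nm outside 200-1750 nm")
            if width <= 0:
                raise ValueError(f"band width must be > 0, got {width}")
            if amplitude < 0:
                raise ValueError(f"band amplitude must be >= 0, got {amplitude}")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")


def evaluate_absorption(template: ChromophoreTemplate, wavelengths: np.ndarray) -> np.ndarray:
    """Evaluate a chromophore template on a sorted wavelength grid (nm)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength vector")
    if np.any(np.diff(wavelengths) < 0):
        raise ValueError("wavelengths must be sorted ascending")
    mu = np.full_like(wavelengths, float(template.baseline))
    for center, width, amplitude in template.bands:
        mu += amplitude * np.exp(-((wavelengths - center) ** 2) / (2.0 * width**2))
    return mu


# Band centers follow the optical-spectroscopy literature for breast tissue:
# fat ~930/1210 nm, water ~970/1190/1450 nm, collagen ~1030/1500 nm,
# hemoglobin visible bands (Soret ~420 nm, Q-bands ~540-580 nm, deoxy ~760 nm).
DEFAULT_CHROMOPHORES: dict[str, ChromophoreTemplate] = {
    "fat": ChromophoreTemplate(
        "fat", bands=((930.0, 20.0, 0.8), (1210.0, 28.0, 2.2), (1720.0, 30.0, 1.5)), baseline=0.02
    ),
    "water": ChromophoreTemplate(
        "water",
        bands=((970.0, 35.0, 0.45), (1190.0, 45.0, 0.55), (1450.0, 55.0, 3.0)),
        baseline=0.02,
    ),
    "collagen": ChromophoreTemplate(
        "collagen", bands=((1030.0, 30.0, 0.6), (1200.0, 40.0, 0.7), (1500.0, 60.0, 1.8)), baseline=0.05
    ),
    "hb_oxy": ChromophoreTemplate(
        "hb_oxy",
        bands=((415.0, 20.0, 25.0), (542.0, 14.0, 4.5), (577.0, 12.0, 4.5)),
        baseline=0.1,
    ),
    "hb_deoxy": ChromophoreTemplate(
        "hb_deoxy",
        bands=((430.0, 20.0, 22.0), (555.0, 18.0, 4.0), (760.0, 25.0, 1.2)),
        baseline=0.1,
    ),
}


@dataclass(frozen=True)
class TissueComposition:
    """Volume fractions of the modelled absorbers plus blood oxygenation.

    ``fat + water + collagen + blood`` must sum to 1 (closure); the blood
    fraction is split between oxy- and deoxy-hemoglobin by
    ``oxygen_saturation``.
    """

    fat_fraction: float
    water_fraction: float
    collagen_fraction: float
    blood_fraction: float
    oxygen_saturation: float

    def __post_init__(self) -> None:
        fractions = (
            self.fat_fraction,
            self.water_fraction,
            self.collagen_fraction,
            self.blood_fraction,
        )
        if any(f < 0 or f > 1 for f in fractions):
            raise ValueError(f"fractions must lie in [0,1]: {fractions}")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")
        if not (0.0 <= self.oxygen_saturation <= 1.0):
            raise ValueError("oxygen_saturation must lie in [0,1]")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.fat_fraction, self.water_fraction, self.collagen_fraction, self.blood_fraction]
        )


def total_absorption(
    composition: TissueComposition,
    wavelengths: np.ndarray,
    chromophores: dict[str, ChromophoreTemplate] | None = None,
) -> np.ndarray:
    """Composition-weighted absorption coefficient on a wavelength grid."""
    chromophores = chromophores or DEFAULT_CHROMOPHORES
    s = composition.oxygen_saturation
    mu = (
        composition.fat_fraction * evaluate_absorption(chromophores["fat"], wavelengths)
        + composition.water_fraction * evaluate_absorption(chromophores["water"], wavelengths)
        + composition.collagen_fraction * evaluate_absorption(chromophores["collagen"], wavelengths)
        + composition.blood_fraction
        * (
            s * evaluate_absorption(chromophores["hb_oxy"], wavelengths)
            + (1.0 - s) * evaluate_absorption(chromophores["hb_deoxy"], wavelengths)
        )
    )
    return mu


@dataclass(frozen=True)
class CompositionPriors:
    """Dirichlet-style per-class priors over (fat, water, collagen, blood).

    ``healthy_mean`` / ``tumor_mean`` are mean fraction vectors;
    ``concentration`` scales the Dirichlet sharpness (higher = tighter).
    The defaults encode the qualitative contrast the analysis relies on:
    healthy breast tissue is fat-dominated, tumor is water/collagen-
    dominated with low fat.  They are stand-ins, not estimates of any
    clinical cohort.
    """

    healthy_mean: tuple[float, float, float, float] = (0.60, 0.20, 0.13, 0.07)
    tumor_mean: tuple[float, float, float, float] = (0.25, 0.42, 0.25, 0.08)
    # second malignant mode: intraductal disease retains more surrounding
    # fat than invasive carcinoma, so its composition sits between the
    # invasive and healthy means
    tumor_mean_dcis: tuple[float, float, float, float] | None = None
    dcis_rate: float = 0.4
    concentration: float = 60.0
    in_vivo_so2: tuple[float, float] = (0.70, 0.95)
    ex_vivo_so2: tuple[float, float] = (0.10, 0.40)

    def separated(self, factor: float) -> "CompositionPriors":
        """Return priors with the class-mean gap scaled by ``factor``.

        ``factor`` > 1 pulls the tumor mean further from the healthy mean
        (and tightens nothing else); 0 collapses the two classes.  Used by
        tests that check that class separation drives downstream AUC.
        """
        h = np.array(self.healthy_mean)
        t = np.array(self.tumor_mean)
        t2 = h + factor * (t - h)
        t2 = np.clip(t2, 0.02, None)
        t2 = t2 / t2.sum()
        return replace(self, tumor_mean=tuple(t2))


@dataclass(frozen=True)
class NoiseConfig:
    """Replicate-level noise: multiplicative gain jitter, additive noise,
    and the extremity inflation that motivates the 350-400 / 1600-1700 nm
    trim."""

    gain_jitter_sd: float = 0.01
    additive_sd: float = 0.006
    extremity_inflation: float = 12.0
    fiber_composition_jitter_sd: float = 0.05
    patient_effect_sd: float = 0.15


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Defaults mirror the order of magnitude of the clinical study this
    pipeline is designed for: ~100 patients, a handful of probed locations
    each, ~10% of locations malignant, a mix of in vivo and ex vivo
    acquisition contexts.
    """

    n_patients: int = 100
    locations_per_patient: int = 6
    tumor_location_rate: float = 0.10
    in_vivo_proportion: float = 0.5
    priors: CompositionPriors = field(default_factory=CompositionPriors)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    path_length: float = 1.0
    gain: float = 1.0
    # Minimum tumor weight in the measured composition of a malignant
    # location; the weight grows linearly with the tumor area percentage, so
    # deep (low-percentage) tumors produce weaker spectral contrast.
    tumor_signal_floor: float = 0.3
    band_depth_mm: float = 2.0
    tumor_pct_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.locations_per_patient < 1:
            raise ValueError("counts must be >= 1")
        for p in (self.tumor_location_rate, self.in_vivo_proportion, self.tumor_signal_floor):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probabilities must lie in [0,1], got {p}")


@dataclass(frozen=True)
class FiberSpectra:
    """Raw spectra of one fiber: 3 replicates on each spectrometer grid."""

    vis_replicates: np.ndarray  # (3, len(VIS_WAVELENGTHS))
    nir_replicates: np.ndarray  # (3, len(NIR_WAVELENGTHS))


@dataclass(frozen=True)
class RawMeasurement:
    """One probed location: 5 fibers x 2 spectrometer ranges x 3 replicates."""

    patient_id: str
    location_id: str
    context: str  # "in_vivo" | "ex_vivo"
    fibers: tuple[FiberSpectra, ...]
    vis_wavelengths: np.ndarray = field(default_factory=lambda: VIS_WAVELENGTHS.copy())
    nir_wavelengths: np.ndarray = field(default_factory=lambda: NIR_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        if self.context not in ("in_vivo", "ex_vivo"):
            raise ValueError(f"context must be in_vivo or ex_vivo, got {self.context!r}")
        if len(self.fibers) != N_FIBERS:
            raise ValueError(f"expected {N_FIBERS} fibers, got {len(self.fibers)}")
        for f in self.fibers:
            if f.vis_replicates.shape != (N_REPLICATES, self.vis_wavelengths.size):
                raise ValueError("vis replicates must be (3, n_vis)")
            if f.nir_replicates.shape != (N_REPLICATES, self.nir_wavelengths.size):
                raise ValueError("nir replicates must be (3, n_nir)")
            if np.any(f.vis_replicates < 0) or np.any(f.nir_replicates < 0):
                raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Histology-derived truth for one location.

    Area percentages refer to the 2-mm band under the inked margin; the
    label is malignant iff any tumor tissue is present in that band.
    Margin distances are absent (None) for healthy locations.
    """

    location_id: str
    tumor_pct: float
    fat_pct: float
    connective_pct: float
    label: str  # "malignant" | "healthy"
    margin_distance_min: float | None = None
    margin_distance_central: float | None = None
    margin_distance_max: float | None = None
    margin_distance_mean: float | None = None

    def __post_init__(self) -> None:
        total = self.tumor_pct + self.fat_pct + self.connective_pct
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"tissue percentages must sum to 100, got {total}")
        if (self.label == "malignant") != (self.tumor_pct > 0):
            raise ValueError("label must be malignant iff tumor_pct > 0")
        if self.label == "malignant":
            d = (self.margin_distance_min, self.margin_distance_central, self.margin_distance_max)
            if any(v is None for v in d):
                raise ValueError("malignant locations need margin distances")
            expected_mean = (d[0] + d[1] + d[2]) / 3.0
            if abs(self.margin_distance_mean - expected_mean) > 1e-9:
                raise ValueError("margin_distance_mean must equal mean(min, central, max)")


def _dirichlet(mean: np.ndarray, concentration: float, rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(np.asarray(mean) * concentration)


def sample_composition(
    class_label: str,
    context: str,
    rng: np.random.Generator,
    priors: CompositionPriors | None = None,
) -> TissueComposition:
    """Draw a tissue composition for one class and acquisition context.

    Healthy draws are fat-dominated, tumor draws water/collagen-dominated;
    in vivo locations draw a high blood oxygen saturation, ex vivo a low
    one (perfusion stops after excision).
    """
    priors = priors or CompositionPriors()
    if class_label not in ("tumor", "healthy"):
        raise ValueError(f"class_label must be tumor or healthy, got {class_label!r}")
    if class_label == "tumor":
        # malignant tissue is a mixture of two histological modes
        # (invasive carcinoma vs intraductal disease)
        if priors.tumor_mean_dcis is not None and rng.random() < priors.dcis_rate:
            mean = priors.tumor_mean_dcis
        else:
            mean = priors.tumor_mean
    else:
        mean = priors.healthy_mean
    fractions = _dirichlet(np.array(mean), priors.concentration, rng)
    lo, hi = priors.in_vivo_so2 if context == "in_vivo" else priors.ex_vivo_so2
    so2 = rng.uniform(lo, hi)
    return TissueComposition(*fractions, oxygen_saturation=so2)


def _perturb_fractions(
    fractions: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative log-normal perturbation followed by renormalization."""
    jitter = np.exp(rng.normal(0.0, sd, size=fractions.size))
    perturbed = fractions * jitter
    return perturbed / perturbed.sum()


def simulate_measurement(
    composition: TissueComposition,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "P000",
    location_id: str = "L000",
    context: str = "in_vivo",
    chromophores: dict[str, ChromophoreTemplate] | None = None,
) -> RawMeasurement:
    """Forward-model one five-fiber measurement from a tissue composition.

    Each fiber sees a slightly perturbed composition (the five fibers probe
    overlapping but distinct tissue volumes); each replicate differs only
    by a multiplicative gain jitter and additive noise, with the noise SD
    inflated in the 350-400 and 1600-1700 nm extremity windows.
    """
    noise = config.noise
    fibers = []
    for _ in range(N_FIBERS):
        fr = _perturb_fractions(composition.as_array(), noise.fiber_composition_jitter_sd, rng)
        fiber_comp = TissueComposition(*fr, oxygen_saturation=composition.oxygen_saturation)
        reps = {}
        for name, grid in (("vis", VIS_WAVELENGTHS), ("nir", NIR_WAVELENGTHS)):
            mu = total_absorption(fiber_comp, grid, chromophores)
            clean = config.gain * np.exp(-config.path_length * mu)
            sd = np.full(grid.size, noise.additive_sd)
            extremity = ((grid >= 350.0) & (grid <= 400.0)) | ((grid >= 1600.0) & (grid <= 1700.0))
            sd[extremity] *= noise.extremity_inflation
            gains = np.exp(rng.normal(0.0, noise.gain_jitter_sd, size=N_REPLICATES)) \
                if noise.gain_jitter_sd > 0 else np.ones(N_REPLICATES)
            eps = rng.normal(0.0, 1.0, size=(N_REPLICATES, grid.size)) * sd \
                if noise.additive_sd > 0 else np.zeros((N_REPLICATES, grid.size))
            reps[name] = np.clip(gains[:, None] * clean[None, :] + eps, 0.0, None)
        fibers.append(FiberSpectra(vis_replicates=reps["vis"], nir_replicates=reps["nir"]))
    return RawMeasurement(
        patient_id=patient_id, location_id=location_id, context=context, fibers=tuple(fibers)
    )


def _sample_truth(
    location_id: str, malignant: bool, config: SimulationConfig, rng: np.random.Generator
) -> GroundTruth:
    """Draw the histology truth record for one location.

    For malignant locations the tumor percentage is a clipped negative-slope
    linear function of the sampled margin distance,
    ``p = clip(100 (1 - d / depth) + eps, floor, 100)``, which builds in the
    negative percentage-vs-distance correlation the downstream
    misclassification analysis looks for.
    """
    depth = config.band_depth_mm
    if malignant:
        d_central = rng.uniform(0.0, depth)
        p = 100.0 * (1.0 - d_central / depth) + rng.normal(0.0, config.tumor_pct_noise_sd)
        # label <=> tumor_pct > 0, so malignant percentages are floored at
        # a small positive value rather than clipped to 0
        tumor_pct = float(np.clip(p, 0.5, 100.0))
        d_min = max(0.0, d_central - rng.uniform(0.0, 0.3))
        d_max = min(depth, d_central + rng.uniform(0.0, 0.3))
        d_mean = (d_min + d_central + d_max) / 3.0
    else:
        tumor_pct = 0.0
        d_min = d_central = d_max = d_mean = None
    healthy_pct = 100.0 - tumor_pct
    fat_share = rng.uniform(0.5, 0.9) if tumor_pct == 0.0 else rng.uniform(0.2, 0.6)
    fat_pct = healthy_pct * fat_share
    connective_pct = healthy_pct - fat_pct
    return GroundTruth(
        location_id=location_id,
        tumor_pct=tumor_pct,
        fat_pct=fat_pct,
        connective_pct=connective_pct,
        label="malignant" if tumor_pct > 0 else "healthy",
        margin_distance_min=d_min,
        margin_distance_central=d_central,
        margin_distance_max=d_max,
        margin_distance_mean=d_mean,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[RawMeasurement], list[GroundTruth]]:
    """Generate a patient-clustered cohort of measurements and truths.

    All randomness flows from ``config.seed`` through a single
    ``numpy.random.Generator``, so identical configs give bit-identical
    cohorts.  Locations of one patient share a multiplicative random effect
    on composition, which is what makes patient-grouped CV splits the
    correct evaluation design downstream.
    """
    rng = np.random.default_rng(config.seed)
    measurements: list[RawMeasurement] = []
    truths: list[GroundTruth] = []
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        patient_jitter = np.exp(
            rng.normal(0.0, config.noise.patient_effect_sd, size=4)
        )
        for l in range(config.locations_per_patient):
            location_id = f"{patient_id}-L{l:02d}"
            malignant = rng.random() < config.tumor_location_rate
            context = "in_vivo" if rng.random() < config.in_vivo_proportion else "ex_vivo"
            truth = _sample_truth(location_id, malignant, config, rng)

            healthy_comp = sample_composition("healthy", context, rng, config.priors)
            if malignant:
                tumor_comp = sample_composition("tumor", context, rng, config.priors)
                w = config.tumor_signal_floor + (1.0 - config.tumor_signal_floor) * (
                    truth.tumor_pct / 100.0
                )
                mixed = w * tumor_comp.as_array() + (1.0 - w) * healthy_comp.as_array()
                so2 = tumor_comp.oxygen_saturation
            else:
                mixed = healthy_comp.as_array()
                so2 = healthy_comp.oxygen_saturation
            mixed = mixed * patient_jitter
            mixed = mixed / mixed.sum()
            comp = TissueComposition(*mixed, oxygen_saturation=so2)

            measurements.append(
                simulate_measurement(
                    comp, config, rng,
                    patient_id=patient_id, location_id=location_id, context=context,
                )
            )
            truths.append(truth)
    return measurements, truths


def well_separated_config(seed: int = 0) -> SimulationConfig:
    """The documented low-overlap cohort configuration.

    Class priors are pulled far apart, composition variability and noise
    are reduced, and even the deepest tumors keep a solid spectral
    footprint.  On this cohort a competent end-to-end pipeline should
    recover near-perfect cross-validated discrimination; it is the
    positive control for pipeline wiring, not a realistic clinical regime
    (the default config is calibrated to the much harder clinical
    ballpark).
    """
    return SimulationConfig(
        n_patients=100,
        locations_per_patient=6,
        tumor_location_rate=0.10,
        priors=CompositionPriors(
            healthy_mean=(0.65, 0.18, 0.12, 0.05),
            tumor_mean=(0.15, 0.45, 0.32, 0.08),
            tumor_mean_dcis=None,
            concentration=120.0,
        ),
        noise=NoiseConfig(
            additive_sd=0.004, fiber_composition_jitter_sd=0.04, patient_effect_sd=0.10
        ),
        tumor_signal_floor=0.4,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic histology sections


# RGB palette of the synthetic H&E renderer.  Fat is rendered with the
# highest green channel, tumor with the lowest; the quantification module's
# default green threshold (200/255) separates fat from connective tissue.
SECTION_PALETTE = {
    "background": (255, 255, 255),
    "fat": (245, 225, 235),
    "connective": (200, 140, 185),
    "tumor": (130, 60, 140),
}
LABEL_CODES = {"background": 0, "tumor": 1, "fat": 2, "connective": 3}


@dataclass(frozen=True)
class SectionGeometry:
    """Raster geometry of a rendered section."""

    width_px: int = 400
    height_px: int = 220
    pixel_size_um: float = 20.0
    ink_row: int = 10  # row of the straight ink polyline; tissue lies below

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass(frozen=True)
class SectionImage:
    """Synthetic stained section: RGB image, per-pixel class mask, ink line."""

    rgb: np.ndarray  # (H, W, 3) uint8
    label_mask: np.ndarray  # (H, W) uint8, LABEL_CODES
    ink_polyline: np.ndarray  # (n, 2) float, (row, col) pixel coordinates
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.label_mask.shape:
            raise ValueError("rgb and label_mask dimensions must match")
        if self.ink_polyline.shape[0] < 2:
            raise ValueError("ink polyline needs >= 2 points")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


def render_section(
    truth: GroundTruth,
    geometry: SectionGeometry | None = None,
    rng: np.random.Generator | None = None,
    band_depth_mm: float = 2.0,
) -> SectionImage:
    """Render a synthetic stained section consistent with a truth record.

    The ink mark is a straight horizontal line with tissue below it.  Within
    the 2-mm band under the ink, the tumor occupies the deepest
    ``tumor_pct`` percent as a full-width strip (its top edge therefore sits
    at depth ``(1 - tumor_pct/100) * band_depth``); the remaining band is
    split into fat (left) and connective (right) columns in proportion to
    the truth percentages.  Below the band, tissue continues with the same
    fat/connective split.
    """
    geometry = geometry or SectionGeometry()
    rng = rng or np.random.default_rng(0)
    h, w = geometry.height_px, geometry.width_px
    mask = np.zeros((h, w), dtype=np.uint8)

    px_mm = 1000.0 / geometry.pixel_size_um  # pixels per mm
    band_px = int(round(band_depth_mm * px_mm))
    top = geometry.ink_row + 1
    bottom = min(h, top + band_px)
    tissue_bottom = h

    fat_cols = 0
    healthy_pct = truth.fat_pct + truth.connective_pct
    if healthy_pct > 0:
        fat_cols = int(round(w * truth.fat_pct / healthy_pct))
    mask[top:tissue_bottom, :fat_cols] = LABEL_CODES["fat"]
    mask[top:tissue_bottom, fat_cols:] = LABEL_CODES["connective"]

    if truth.tumor_pct > 0:
        # full-width strip occupying the deepest tumor_pct% of the band
        # at least one pixel row so label consistency survives rounding
        strip_px = max(1, int(round(band_px * truth.tumor_pct / 100.0)))
        strip_top = bottom - strip_px
        mask[strip_top:bottom, :] = LABEL_CODES["tumor"]

    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for name, code in LABEL_CODES.items():
        rgb[mask == code] = SECTION_PALETTE[name]

    polyline = np.array(
        [[float(geometry.ink_row), 0.0], [float(geometry.ink_row), float(w - 1)]]
    )
    return SectionImage(
        rgb=rgb, label_mask=mask, ink_polyline=polyline, pixel_size_um=geometry.pixel_size_um
    )
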