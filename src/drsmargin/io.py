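"""CSV/PNG/JSON serialization of cohorts, truths, features and curves.

Spectra travel as long-format CSV (one row per wavelength sample) with
strict schema validation; ground truth and feature tables as wide CSV;
synthetic sections as RGB PNG + indexed-label PNG + a JSON sidecar with
the ink polyline and pixel size.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureVector
from .simulate import (
    NIR_WAVELENGTHS,
    VIS_WAVELENGTHS,
    FiberSpectra,
    GroundTruth,
    RawMeasurement,
    SectionImage,
)

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_features_csv",
    "write_roc_csv",
    "write_section",
    "read_section",
]

SPECTRA_COLUMNS = [
    "patient_id",
    "location_id",
    "context",
    "fiber",
    "range",
    "replicate",
    "wavelength_nm",
    "intensity",
]

TRUTH_COLUMNS = [
    "location_id",
    "tumor_pct",
    "fat_pct",
    "connective_pct",
    "label",
    "margin_distance_min",
    "margin_distance_central",
    "margin_distance_max",
    "margin_distance_mean",
]


class SchemaError(ValueError):
    """A CSV violated the expected schema; message names column and line."""


def write_spectra_csv(measurements: Sequence[RawMeasurement], path: str | Path) -> None:
    frames = []
    for m in measurements:
        for fi, fiber in enumerate(m.fibers, start=1):
            for rng_name, grid, reps in (
                ("vis", m.vis_wavelengths, fiber.vis_replicates),
                ("nir", m.nir_wavelengths, fiber.nir_replicates),
            ):
                for ri in range(reps.shape[0]):
                    frames.append(
                        pd.DataFrame(
                            {
                                "patient_id": m.patient_id,
                                "location_id": m.location_id,
                                "context": m.context,
                                "fiber": fi,
                                "range": rng_name,
                                "replicate": ri + 1,
                                "wavelength_nm": grid,
                                "intensity": reps[ri],
                            }
                        )
                    )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> list[RawMeasurement]:
    df = pd.read_csv(path)
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spectra CSV is missing column(s): {', '.join(missing)}")
    bad = df[(df["wavelength_nm"] < 200) | (df["wavelength_nm"] > 1750)]
    if len(bad):
        line = int(bad.index[0]) + 2  # header + 1-based
        raise SchemaError(
            f"column 'wavelength_nm', line {line}: value {bad['wavelength_nm'].iloc[0]} "
            "outside [200, 1750] nm"
        )
    bad = df[df["intensity"] < 0]
    if len(bad):
        raise SchemaError(f"column 'intensity', line {int(bad.index[0]) + 2}: negative intensity")

    measurements = []
    for (loc, pat, ctx), g in df.groupby(["location_id", "patient_id", "context"], sort=True):
        fibers = []
        for fi in range(1, 6):
            gf = g[g["fiber"] == fi]
            reps = {}
            for rng_name, grid in (("vis", VIS_WAVELENGTHS), ("nir", NIR_WAVELENGTHS)):
                gr = gf[gf["range"] == rng_name]
                rows = []
                for ri in range(1, 4):
                    spec = gr[gr["replicate"] == ri].sort_values("wavelength_nm")
                    if len(spec) != grid.size:
                        raise SchemaError(
                            f"location {loc} fiber {fi} range {rng_name} replicate {ri}: "
                            f"expected {grid.size} samples, found {len(spec)}"
                        )
                    rows.append(spec["intensity"].to_numpy())
                reps[rng_name] = np.array(rows)
            fibers.append(FiberSpectra(vis_replicates=reps["vis"], nir_replicates=reps["nir"]))
        measurements.append(
            RawMeasurement(patient_id=pat, location_id=loc, context=ctx, fibers=tuple(fibers))
        )
    return measurements


def write_truth_csv(truths: Sequence[GroundTruth], path: str | Path) -> None:
    rows = []
    for t in truths:
        rows.append(
            {
                "location_id": t.location_id,
                "tumor_pct": t.tumor_pct,
                "fat_pct": t.fat_pct,
                "connective_pct": t.connective_pct,
                "label": t.label,
                "margin_distance_min": t.margin_distance_min,
                "margin_distance_central": t.margin_distance_central,
                "margin_distance_max": t.margin_distance_max,
                "margin_distance_mean": t.margin_distance_mean,
            }
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> list[GroundTruth]:
    df = pd.read_csv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"truth CSV is missing column(s): {', '.join(missing)}")
    truths = []
    for i, row in df.iterrows():
        def _opt(v):
            return None if pd.isna(v) else float(v)

        try:
            truths.append(
                GroundTruth(
                    location_id=str(row["location_id"]),
                    tumor_pct=float(row["tumor_pct"]),
                    fat_pct=float(row["fat_pct"]),
                    connective_pct=float(row["connective_pct"]),
                    label=str(row["label"]),
                    margin_distance_min=_opt(row["margin_distance_min"]),
                    margin_distance_central=_opt(row["margin_distance_central"]),
                    margin_distance_max=_opt(row["margin_distance_max"]),
                    margin_distance_mean=_opt(row["margin_distance_mean"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"truth CSV line {int(i) + 2}: {exc}") from exc
    return truths


def write_features_csv(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    if not vectors:
        raise ValueError("no feature vectors to write")
    names = vectors[0].names
    rows = []
    for v in vectors:
        row = {
            "location_id": v.location_id,
            "patient_id": v.patient_id,
            "context": v.context,
            "label": v.label,
        }
        row.update(dict(zip(names, v.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_roc_csv(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr}).to_csv(path, index=False)


def write_section(section: SectionImage, stem: str | Path) -> None:
    """Write RGB PNG, indexed label-mask PNG, and a JSON geometry sidecar."""
    from PIL import Image

    stem = Path(stem)
    Image.fromarray(section.rgb, mode="RGB").save(stem.with_suffix(".rgb.png"))
    Image.fromarray(section.label_mask, mode="L").save(stem.with_suffix(".mask.png"))
    sidecar = {
        "ink_polyline": section.ink_polyline.tolist(),
        "pixel_size_um": section.pixel_size_um,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_section(stem: str | Path) -> SectionImage:
    from PIL import Image

    stem = Path(stem)
    rgb = np.asarray(Image.open(stem.with_suffix(".rgb.png")).convert("RGB"))
    mask = np.asarray(Image.open(stem.with_suffix(".mask.png")).convert("L"))
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    return SectionImage(
        rgb=rgb,
        label_mask=mask.astype(np.uint8),
        ink_polyline=np.asarray(sidecar["ink_polyline"], float),
        pixel_size_um=float(sidecar["pixel_size_um"]),
    )
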