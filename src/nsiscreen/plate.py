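"""Plate layout and on-disk simulation of the screen.

A plate is a 96-well layout; each well carries one compound on one cell
line and is imaged as several fields at two timepoints in three
channels.  ``simulate_plate`` writes single-channel 16-bit TIFFs named

    {plate}_{well}_{field}_{T0|T1}_{655|549|475}.tif

plus ``manifest.yaml`` (the layout), ``truth_cells.csv`` and
``truth_compounds.csv`` (generator ground truth) — everything the
quantification stages need, and everything parameter-recovery tests
compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kinetics import KineticTruth
from .library import CompoundLibrary
from .render import CHANNELS, FieldGeometry, NoiseParams, render_field, translation_drift

__all__ = [
    "WellSpec",
    "PlateManifest",
    "design_screen",
    "simulate_plate",
    "load_manifest",
    "read_field_images",
]

WELL_ROWS = "ABCDEFGH"
WELL_COLS = range(1, 13)


@dataclass
class WellSpec:
    well_id: str            # e.g. "B07"
    cell_line: str
    compound_id: str | None  # None = control well
    n_fields: int = 3

    def __post_init__(self):
        if not (1 <= self.n_fields <= 8):
            raise ValueError(f"n_fields={self.n_fields} out of range")


@dataclass
class PlateManifest:
    plate_id: str
    wells: list[WellSpec] = dc_field(default_factory=list)
    timepoints_min: tuple[float, float] = (0.0, 60.0)

    def __post_init__(self):
        if len(self.wells) > 96:
            raise ValueError(f"plate {self.plate_id}: {len(self.wells)} wells "
                             "exceeds the 96-well format")
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError(f"plate {self.plate_id}: duplicate well ids")


def _well_ids():
    for r in WELL_ROWS:
        for c in WELL_COLS:
            yield f"{r}{c:02d}"


def design_screen(
    library: CompoundLibrary,
    cell_lines: tuple[str, ...] = ("line1", "line2", "line3"),
    n_fields: int = 3,
) -> list[PlateManifest]:
    """Lay the library out on 96-well plates, one plate series per line."""
    manifests = []
    for line in cell_lines:
        wells: list[WellSpec] = []
        plate_no = 1
        slots = iter(_well_ids())
        for comp in library:
            try:
                wid = next(slots)
            except StopIteration:
                manifests.append(PlateManifest(f"{line}-P{plate_no}", wells))
                plate_no += 1
                wells = []
                slots = iter(_well_ids())
                wid = next(slots)
            wells.append(WellSpec(wid, line, comp.compound_id, n_fields))
        if wells:
            manifests.append(PlateManifest(f"{line}-P{plate_no}", wells))
    return manifests


def simulate_plate(
    manifest: PlateManifest,
    truth: KineticTruth,
    out_dir,
    seed: int = 0,
    geometry: FieldGeometry | None = None,
    noise: NoiseParams | None = None,
    max_drift: float = 8.0,
) -> dict:
    """Render every field of a plate to disk, with ground-truth tables.

    Fully reproducible under ``seed``; per-field seeds and drifts are
    drawn from a single stream in well order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = geometry or FieldGeometry()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    compound_keys = {cid for cid, _ in truth.keys()}
    for w in manifest.wells:
        if w.compound_id is not None and w.compound_id not in compound_keys:
            raise KeyError(
                f"well {w.well_id}: compound {w.compound_id!r} missing from "
                "the kinetic truth"
            )

    cell_rows = []
    n_images = 0
    for w in manifest.wells:
        kin = (truth[(w.compound_id, w.cell_line)]
               if w.compound_id is not None else None)
        for f in range(w.n_fields):
            drift = translation_drift(
                rng.uniform(-max_drift, max_drift),
                rng.uniform(-max_drift, max_drift),
            )
            fseed = int(rng.integers(0, 2**31 - 1))
            imgs0, imgs1, ftruth = render_field(kin, geometry, noise,
                                                drift, seed=fseed)
            fid = f"f{f}"
            for tp, imgs in (("T0", imgs0), ("T1", imgs1)):
                for ch in CHANNELS:
                    name = f"{manifest.plate_id}_{w.well_id}_{fid}_{tp}_{ch}.tif"
                    tifffile.imwrite(out / name, imgs[ch])
                    n_images += 1
            for cell in ftruth.cells:
                row = {
                    "plate_id": manifest.plate_id,
                    "well_id": w.well_id,
                    "field_id": fid,
                    "cell_id": cell.cell_id,
                    "compound_id": w.compound_id or "",
                    "cell_line": w.cell_line,
                    "centroid_t0_row": cell.centroid_t0[0],
                    "centroid_t0_col": cell.centroid_t0[1],
                    "centroid_t1_row": cell.centroid_t1[0],
                    "centroid_t1_col": cell.centroid_t1[1],
                    "nucleus_radius": cell.nucleus_radius,
                    "drift_row": drift[0, 2],
                    "drift_col": drift[1, 2],
                }
                for (ch, tp), v in cell.true_f.items():
                    row[f"true_f_{ch}_{tp}"] = v
                cell_rows.append(row)

    pd.DataFrame(cell_rows).to_csv(out / "truth_cells.csv", index=False)

    comp_rows = [
        {
            "compound_id": k.compound_id,
            "cell_line": k.cell_line,
            "behavior_class": k.behavior_class,
            "k_in": k.k_in,
            "k_out": k.k_out,
            "growth": k.growth,
            "localization": k.localization,
            "emission": k.emission,
            "cell_cv": k.cell_cv,
            "true_log_ratio": k.true_log_ratio,
        }
        for k in truth.values()
    ]
    pd.DataFrame(comp_rows).to_csv(out / "truth_compounds.csv", index=False)

    doc = {
        "plate_id": manifest.plate_id,
        "timepoints_min": list(manifest.timepoints_min),
        "wells": [
            {"well_id": w.well_id, "cell_line": w.cell_line,
             "compound_id": w.compound_id, "n_fields": w.n_fields}
            for w in manifest.wells
        ],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return {"n_images": n_images, "out_dir": str(out)}


def load_manifest(path) -> PlateManifest:
    with open(Path(path) / "manifest.yaml" if Path(path).is_dir() else path) as fh:
        doc = yaml.safe_load(fh)
    return PlateManifest(
        plate_id=doc["plate_id"],
        wells=[WellSpec(w["well_id"], w["cell_line"], w["compound_id"],
                        w["n_fields"]) for w in doc["wells"]],
        timepoints_min=tuple(doc.get("timepoints_min", (0.0, 60.0))),
    )


def read_field_images(plate_dir, plate_id: str, well_id: str, field_id: str,
                      timepoint: str) -> dict[str, np.ndarray]:
    """Load one field's channel stack from the simulator's file grammar."""
    out = {}
    for ch in CHANNELS:
        name = f"{plate_id}_{well_id}_{field_id}_{timepoint}_{ch}.tif"
        out[ch] = tifffile.imread(Path(plate_dir) / name)
    return out
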