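"""Case-bundle persistence: one HDF5 container per case.

A bundle stores the named arrays (ct, ptv_dose_mask, per-PTV and per-OAR
masks, dose, fluence) plus JSON metadata (grid spec, beam geometry,
prescriptions, seed, schema version, provenance).  Round trips are
bit-exact and every load re-validates the case invariants.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import BeamGeometry, GridSpec
from .phantom import OAR_NAMES, PTV_NAMES, PatientCase

__all__ = ["SCHEMA_VERSION", "save_case", "load_case", "simulate_cohort", "load_cohort"]

SCHEMA_VERSION = 1
_FORMAT = "dosefluence-case"


def save_case(case: PatientCase, path) -> Path:
    case.validate()
    path = Path(path)
    meta = {
        "grid": {
            "shape": case.grid.shape,
            "spacing": case.grid.spacing,
            "origin": case.grid.origin,
        },
        "beams": {
            "gantry_angles_deg": case.beams.gantry_angles_deg,
            "sad_mm": case.beams.sad_mm,
            "fluence_shape": case.beams.fluence_shape,
            "fluence_pitch_mm": case.beams.fluence_pitch_mm,
        },
        "prescriptions": case.prescriptions,
        "seed": case.seed,
    }
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["meta"] = json.dumps(meta)
        f.create_dataset("ct", data=case.ct)
        f.create_dataset("ptv_dose_mask", data=case.ptv_dose_mask)
        if case.dose is not None:
            f.create_dataset("dose", data=case.dose)
        if case.fluence is not None:
            f.create_dataset("fluence", data=case.fluence)
        gp = f.create_group("ptv")
        for name in PTV_NAMES:
            gp.create_dataset(name, data=case.ptv_masks[name].astype(np.uint8))
        go = f.create_group("oar")
        for name in OAR_NAMES:
            go.create_dataset(name, data=case.oar_masks[name].astype(np.uint8))
    return path


def load_case(path) -> PatientCase:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _FORMAT:
            raise ValueError(f"{path}: not a {_FORMAT} bundle")
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported schema version {version} "
                f"(this build reads version {SCHEMA_VERSION}); refusing to guess"
            )
        meta = json.loads(f.attrs["meta"])
        grid = GridSpec(
            shape=tuple(meta["grid"]["shape"]),
            spacing=tuple(meta["grid"]["spacing"]),
            origin=tuple(meta["grid"]["origin"]),
        )
        beams = BeamGeometry(
            gantry_angles_deg=tuple(meta["beams"]["gantry_angles_deg"]),
            sad_mm=meta["beams"]["sad_mm"],
            fluence_shape=tuple(meta["beams"]["fluence_shape"]),
            fluence_pitch_mm=meta["beams"]["fluence_pitch_mm"],
        )
        for required in ("ct", "ptv_dose_mask"):
            if required not in f:
                raise ValueError(f"{path}: bundle is missing array {required!r}")
        missing = [n for n in PTV_NAMES if n not in f.get("ptv", {})] + [
            n for n in OAR_NAMES if n not in f.get("oar", {})
        ]
        if missing:
            raise ValueError(f"{path}: bundle is missing masks {missing}")
        case = PatientCase(
            grid=grid,
            beams=beams,
            ct=f["ct"][:],
            ptv_masks={n: f["ptv"][n][:].astype(bool) for n in PTV_NAMES},
            oar_masks={n: f["oar"][n][:].astype(bool) for n in OAR_NAMES},
            prescriptions={k: float(v) for k, v in meta["prescriptions"].items()},
            ptv_dose_mask=f["ptv_dose_mask"][:],
            dose=f["dose"][:] if "dose" in f else None,
            fluence=f["fluence"][:] if "fluence" in f else None,
            seed=meta.get("seed"),
        )
    case.validate()
    return case


def simulate_cohort(out_dir, profile, seed: int, n_train: int | None = None,
                    n_val: int | None = None, n_test: int | None = None):
    """Generate a cohort of cases and write bundles plus a JSON manifest.

    Case seeds derive deterministically from the cohort seed; the manifest
    records seeds, prescriptions and train/val/test assignment.
    """
    from .geometry import build_all_operators
    from .phantom import DoseEngine, generate_anatomy, generate_case

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_train = profile.n_train if n_train is None else n_train
    n_val = profile.n_val if n_val is None else n_val
    n_test = profile.n_test if n_test is None else n_test
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    operators = build_all_operators(profile.phantom.grid, profile.phantom.beams)
    manifest = {"profile": profile.name, "seed": seed, "cases": []}
    rng = np.random.default_rng(seed)
    for i, split in enumerate(splits):
        case_seed = int(rng.integers(2**31 - 1))
        case = generate_case(case_seed, profile.phantom, operators=operators)
        name = f"case_{i:03d}.h5"
        save_case(case, out / name)
        manifest["cases"].append(
            {
                "file": name,
                "seed": case_seed,
                "split": split,
                "prescriptions": case.prescriptions,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_cohort(directory, split: str | None = None) -> list[PatientCase]:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cases = []
    for entry in manifest["cases"]:
        if split is not None and entry["split"] != split:
            continue
        cases.append(load_case(d / entry["file"]))
    return cases
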