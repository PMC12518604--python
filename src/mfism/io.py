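"""Reading and writing the package's on-disk formats.

Images travel as 32-bit float TIFF (phase maps in radians, intensity in
arbitrary units, scan stacks as multi-page TIFF) with a YAML text
sidecar carrying the sampling geometry, wavelength, seeds and
provenance. Design specs are flat YAML; foci tables are CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .design import LensDesignSpec, PhaseMap
from .grids import Grid
from .ism import FocusLattice, ScanProtocol, ScanStack
from .metrics import FociQualityReport, FocusRecord
from .optics import IntensityMap

__all__ = [
    "save_design_spec", "load_design_spec",
    "save_phase_map", "load_phase_map",
    "save_intensity_map", "load_intensity_map",
    "save_scan_stack", "load_scan_stack",
    "foci_table", "save_foci_csv", "save_report",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar_path(path).write_text(
        yaml.safe_dump(_plain(payload), sort_keys=False))


def _read_sidecar(path: Path) -> dict:
    return yaml.safe_load(_sidecar_path(path).read_text())


# -- design specs -----------------------------------------------------------

def save_design_spec(spec: LensDesignSpec, path: str | Path) -> None:
    path = Path(path)
    d = dataclasses.asdict(spec)
    d["center_um"] = list(d["center_um"])
    header = ("# multifocal lens design; lengths: wavelength nm, "
              "diameter/pitch/center μm\n")
    path.write_text(header + yaml.safe_dump(d, sort_keys=False))


def load_design_spec(path: str | Path) -> LensDesignSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["center_um"] = tuple(d.get("center_um", (0.0, 0.0)))
    return LensDesignSpec(**d)


# -- phase maps -------------------------------------------------------------

def save_phase_map(phase: PhaseMap, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, phase.values.astype(np.float32))
    _write_sidecar(path, {
        "kind": "phase_map", "units": "radians",
        "sampling_step_um": phase.grid.step, "n": phase.grid.n,
        "wavelength_nm": phase.wavelength_nm,
        "polarization": phase.polarization, "provenance": phase.provenance,
        "seed": phase.seed, "n_tie_broken": phase.n_tie_broken,
        "aperture_diameter_um": _mask_diameter(phase)})


def _mask_diameter(phase: PhaseMap) -> float:
    # recover the circular-aperture diameter from the mask area
    area = float(phase.aperture_mask.sum()) * phase.grid.step ** 2
    return float(2.0 * np.sqrt(area / np.pi))


def load_phase_map(path: str | Path) -> PhaseMap:
    path = Path(path)
    meta = _read_sidecar(path)
    grid = Grid(n=meta["n"], step=meta["sampling_step_um"])
    return PhaseMap(values=tifffile.imread(path), grid=grid,
                    aperture_mask=grid.aperture_mask(meta["aperture_diameter_um"]),
                    wavelength_nm=meta["wavelength_nm"],
                    polarization=meta.get("polarization", "none"),
                    provenance=meta.get("provenance", ""),
                    seed=meta.get("seed"))


# -- intensity maps ---------------------------------------------------------

def save_intensity_map(intensity: IntensityMap, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, intensity.values.astype(np.float32))
    _write_sidecar(path, {
        "kind": "intensity_map",
        "sampling_step_um": intensity.grid.step, "n": intensity.grid.n,
        "plane_z_um": intensity.plane_z_um, "formation": intensity.formation})


def load_intensity_map(path: str | Path) -> IntensityMap:
    path = Path(path)
    meta = _read_sidecar(path)
    return IntensityMap(values=np.clip(tifffile.imread(path).astype(float), 0, None),
                        grid=Grid(n=meta["n"], step=meta["sampling_step_um"]),
                        plane_z_um=meta.get("plane_z_um", 0.0),
                        formation=meta.get("formation", "coherent"))


# -- scan stacks ------------------------------------------------------------

def save_scan_stack(stack: ScanStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    _write_sidecar(path, {
        "kind": "scan_stack",
        "pixel_size_um": stack.protocol.pixel_size_um,
        "pitch_um": stack.protocol.pitch_um,
        "ns_per_axis": stack.protocol.ns_per_axis,
        "order": "row-major (dy, dx)",
        "lattice_base_rc": stack.lattice.base_rc.tolist(),
        "seed": stack.seed, "meta": stack.meta})


def load_scan_stack(path: str | Path) -> ScanStack:
    path = Path(path)
    meta = _read_sidecar(path)
    protocol = ScanProtocol(pixel_size_um=meta["pixel_size_um"],
                            pitch_um=meta["pitch_um"])
    lattice = FocusLattice(base_rc=np.asarray(meta["lattice_base_rc"], float),
                           pitch_um=meta["pitch_um"])
    return ScanStack(frames=tifffile.imread(path).astype(float),
                     protocol=protocol, lattice=lattice,
                     seed=meta.get("seed"), meta=meta.get("meta", {}))


# -- tables -----------------------------------------------------------------

def foci_table(records: list[FocusRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "x_um": r.x_um, "y_um": r.y_um, "peak": r.peak_amplitude,
        "fwhm_x_nm": r.fwhm_x_nm, "fwhm_y_nm": r.fwhm_y_nm,
        "r2": r.goodness, "success": r.fit_converged} for r in records])


def save_foci_csv(records: list[FocusRecord], path: str | Path) -> None:
    foci_table(records).to_csv(path, index=False)


def save_report(report: FociQualityReport, path: str | Path) -> None:
    d = {k: v for k, v in dataclasses.asdict(report).items() if k != "records"}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
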