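"""File formats: kinetic-trace and spectrum CSVs with flat-config sidecars,
trajectories (multi-MODEL PDB or plain xyz text), manifests, and reports.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, one header row; times in
seconds, absorbance unitless, wavelengths in nm. Floats are rendered at full
precision (Python repr), so write -> read round-trips are bit-exact for
finite values. Config files, sidecars and manifests are flat YAML mappings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emission import EmissionSpectrum
from .errors import ParseError
from .photon import BeamSpec
from .structure import Trajectory
from .traces import KineticTrace

def _full_precision(value: float) -> str:
    """Shortest decimal rendering that round-trips the float exactly."""
    return repr(float(value))


def _read_csv(path: Path, columns: tuple[str, str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV: surface pandas' line context
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != list(columns):
        raise ParseError(
            f"{path}: header line 1 must be {','.join(columns)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    for col in columns:
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float, na_value=np.nan))]
        if len(bad):
            raise ParseError(
                f"{path}: non-finite value in column {col!r} at line {bad[0] + 2}"
            )
    return df


def _check_monotone(path: Path, values: np.ndarray, name: str) -> None:
    steps = np.diff(values)
    if np.any(steps <= 0):
        line = int(np.argmax(steps <= 0)) + 3  # header + 1-based + offset
        raise ParseError(f"{path}: {name} not strictly increasing at line {line}")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.yaml")


def read_config(path: str | Path) -> dict:
    """Flat key-value configuration (YAML mapping of scalars)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    for key, value in data.items():
        if isinstance(value, (dict, list)):
            raise ParseError(f"{path}: key {key!r} is nested; config must be flat")
    return data


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_trace(trace: KineticTrace, path: str | Path, sidecar: bool = True) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s, "absorbance": trace.absorbance})
    df.to_csv(path, index=False, float_format=_full_precision)
    if sidecar:
        meta = {
            "wavelength_nm": float(trace.wavelength_nm),
            "path_cm": float(trace.path_cm),
            "label": trace.label,
            "light_on_s": trace.light_on_s,
            "light_off_s": trace.light_off_s,
        }
        if trace.beam is not None:
            meta["power_mW"] = float(trace.beam.power_mW)
            meta["beam_area_cm2"] = float(trace.beam.area_cm2)
            meta["excitation_nm"] = float(trace.beam.wavelength_nm)
        write_config(meta, _sidecar_path(path))


def read_trace(path: str | Path) -> KineticTrace:
    path = Path(path)
    df = _read_csv(path, ("time_s", "absorbance"))
    t = df["time_s"].to_numpy(dtype=float)
    _check_monotone(path, t, "time_s")
    meta: dict = {}
    if _sidecar_path(path).exists():
        meta = read_config(_sidecar_path(path))
    beam = None
    if "power_mW" in meta:
        beam = BeamSpec(
            wavelength_nm=meta.get("excitation_nm", 280.0),
            power_mW=meta["power_mW"],
            area_cm2=meta.get("beam_area_cm2", 0.64),
        )
    return KineticTrace(
        time_s=t,
        absorbance=df["absorbance"].to_numpy(dtype=float),
        wavelength_nm=meta.get("wavelength_nm", 0.0),
        path_cm=meta.get("path_cm", 1.0),
        label=meta.get("label", path.stem),
        light_on_s=meta.get("light_on_s"),
        light_off_s=meta.get("light_off_s"),
        beam=beam,
    )


def write_spectrum(spectrum: EmissionSpectrum, path: str | Path, sidecar: bool = True) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, "intensity": spectrum.intensity}
    )
    df.to_csv(path, index=False, float_format=_full_precision)
    if sidecar:
        write_config(
            {
                "excitation_nm": float(spectrum.excitation_nm),
                "absorbance_at_ex": float(spectrum.absorbance_at_ex),
                "emitter_fraction": float(spectrum.emitter_fraction),
                "label": spectrum.label,
            },
            _sidecar_path(path),
        )


def read_spectrum(path: str | Path) -> EmissionSpectrum:
    path = Path(path)
    df = _read_csv(path, ("wavelength_nm", "intensity"))
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    _check_monotone(path, wl, "wavelength_nm")
    meta: dict = {}
    if _sidecar_path(path).exists():
        meta = read_config(_sidecar_path(path))
    return EmissionSpectrum(
        wavelength_nm=wl,
        intensity=df["intensity"].to_numpy(dtype=float),
        excitation_nm=meta.get("excitation_nm", 270.0),
        absorbance_at_ex=meta.get("absorbance_at_ex", 0.0),
        emitter_fraction=meta.get("emitter_fraction", 1.0),
        label=meta.get("label", path.stem),
    )


def read_trajectory(path: str | Path) -> Trajectory:
    """Calpha trajectory from a multi-MODEL PDB or plain xyz-per-frame text.

    The text format holds one atom per line as ``resid x y z`` with frames
    separated by blank lines.
    """
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return _read_trajectory_pdb(path)
    return _read_trajectory_xyz(path)


def _read_trajectory_pdb(path: Path) -> Trajectory:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    try:
        stack = pdb.PDBFile.read(str(path)).get_structure()
    except Exception as exc:
        raise ParseError(f"{path}: not a readable PDB file: {exc}") from exc
    if stack.array_length() == 0:
        raise ParseError(f"{path}: PDB contains no atoms")
    ca = stack[:, stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ParseError(f"{path}: PDB contains no CA atoms")
    return Trajectory(coords=np.asarray(ca.coord, float), residue_ids=np.asarray(ca.res_id))


def _read_trajectory_xyz(path: Path) -> Trajectory:
    frames: list[list[list[float]]] = [[]]
    resids: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if frames[-1]:
                    frames.append([])
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'resid x y z', got {line!r}"
                )
            try:
                rid = int(parts[0])
                xyz = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if len(frames) == 1:
                resids.append(rid)
            frames[-1].append(xyz)
    if not frames[-1]:
        frames.pop()
    if not frames:
        raise ParseError(f"{path}: no frames found")
    n = len(frames[0])
    for i, fr in enumerate(frames):
        if len(fr) != n:
            raise ParseError(
                f"{path}: frame {i + 1} has {len(fr)} atoms, expected {n}"
            )
    return Trajectory(coords=np.asarray(frames, float), residue_ids=np.asarray(resids))


def write_trajectory_xyz(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for frame in traj.coords:
            for rid, (x, y, z) in zip(traj.residue_ids, frame):
                fh.write(
                    f"{int(rid)} {_full_precision(x)} {_full_precision(y)} "
                    f"{_full_precision(z)}\n"
                )
            fh.write("\n")


def write_rmsf_csv(profile, path: str | Path) -> None:
    pd.DataFrame(
        {"residue": profile.residue_ids, "rmsf_A": profile.rmsf_A}
    ).to_csv(path, index=False, float_format=_full_precision)


def read_manifest(path: str | Path) -> dict:
    """Manifest for multi-trace analyses: a mapping with a ``traces`` list of
    {path, power_mW | k_excit} entries plus shared sample metadata."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict) or "traces" not in data:
        raise ParseError(f"{path}: manifest must be a mapping with a 'traces' list")
    if not isinstance(data["traces"], list) or not data["traces"]:
        raise ParseError(f"{path}: 'traces' must be a non-empty list")
    base = Path(path).parent
    for entry in data["traces"]:
        if not isinstance(entry, dict) or "path" not in entry:
            raise ParseError(f"{path}: each trace entry needs a 'path'")
        entry["path"] = str((base / entry["path"]).resolve())
    return data


def write_report(report: dict, path: str | Path | None) -> str:
    """Serialize a report as deterministic JSON; write it if a path is given."""
    text = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
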