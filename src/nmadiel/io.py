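"""Readers and writers for mode ensembles, atom metadata and result tables.

Formats
-------
Frequency files
    XVG-dialect text: comment lines starting with ``#`` or ``@``, then two
    whitespace-separated columns ``index value``.  Values are wavenumbers in
    cm^-1 by default; pass ``units="hz"`` to override.
Eigenvector files
    Tab-separated, one row per (mode, atom):
    ``mode_index  atom_index  ex  ey  ez`` with components in kg^-1/2.
Atom metadata
    TSV with columns ``atom_index  mass_amu  charge_e  component
    residue_index``; coordinates come from a companion PDB/GRO file
    (read via MDAnalysis when available) or ``x_nm y_nm z_nm`` columns.

All result writers emit TSV with a header line naming the units.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ELEMENTARY_CHARGE, ATOMIC_MASS
from .modes import AtomSet, ModeEnsemble, ModeSet, wavenumber_to_frequency

__all__ = [
    "FormatError",
    "read_frequencies",
    "write_frequencies",
    "read_eigenvectors",
    "write_eigenvectors",
    "read_atom_metadata",
    "write_atom_metadata",
    "read_mode_ensemble",
    "write_mode_ensemble",
    "read_coordinates",
]

METADATA_COLUMNS = ["atom_index", "mass_amu", "charge_e", "component", "residue_index"]


class FormatError(ValueError):
    """An input file does not conform to its documented format."""


def read_frequencies(path: str | Path, units: str = "cm-1") -> np.ndarray:
    """Read an XVG-style frequency file, returning frequencies in Hz."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'index value' columns")
            try:
                values.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    arr = np.asarray(values, dtype=float)
    if units == "cm-1":
        # preserve the imaginary-frequency sign flag through conversion
        return np.sign(arr) * wavenumber_to_frequency(np.abs(arr))
    if units == "hz":
        return arr
    raise ValueError(f"unknown frequency units {units!r}; use 'cm-1' or 'hz'")


def write_frequencies(path: str | Path, frequencies_hz: np.ndarray, units: str = "cm-1") -> None:
    """Write frequencies as an XVG-style file (cm^-1 by default)."""
    freqs = np.asarray(frequencies_hz, dtype=float)
    if units == "cm-1":
        out = freqs / wavenumber_to_frequency(1.0)
        label = "wavenumber_cm-1"
    elif units == "hz":
        out = freqs
        label = "frequency_Hz"
    else:
        raise ValueError(f"unknown frequency units {units!r}")
    with open(path, "w") as fh:
        fh.write(f"# mode frequencies, columns: mode_index {label}\n")
        fh.write("@ xaxis label \"mode\"\n")
        for i, v in enumerate(out):
            fh.write(f"{i}\t{v:.17e}\n")


def read_eigenvectors(path: str | Path, n_atoms: int) -> np.ndarray:
    """Read an eigenvector table, returning an (M, N, 3) array in kg^-1/2."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"mode_index", "atom_index", "ex", "ey", "ez"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: eigenvector table must have columns {sorted(required)}"
        )
    if len(df) % n_atoms != 0:
        raise FormatError(
            f"{path}: {len(df)} rows is not a multiple of {n_atoms} atoms"
        )
    n_modes = len(df) // n_atoms
    df = df.sort_values(["mode_index", "atom_index"], kind="stable")
    atom_idx = df["atom_index"].to_numpy().reshape(n_modes, n_atoms)
    if not np.all(atom_idx == np.arange(n_atoms)):
        raise FormatError(f"{path}: atom indices must run 0..{n_atoms - 1} per mode")
    vecs = df[["ex", "ey", "ez"]].to_numpy(dtype=float).reshape(n_modes, n_atoms, 3)
    return vecs


def write_eigenvectors(path: str | Path, eigenvectors: np.ndarray) -> None:
    """Write an (M, N, 3) eigenvector array as the documented TSV table."""
    vecs = np.asarray(eigenvectors, dtype=float)
    n_modes, n_atoms, _ = vecs.shape
    with open(path, "w") as fh:
        fh.write("mode_index\tatom_index\tex\tey\tez\n")
        for l in range(n_modes):
            for i in range(n_atoms):
                ex, ey, ez = vecs[l, i]
                fh.write(f"{l}\t{i}\t{ex:.17e}\t{ey:.17e}\t{ez:.17e}\n")


def read_coordinates(path: str | Path) -> np.ndarray:
    """Read coordinates (nm) from a PDB or GRO file via MDAnalysis."""
    import MDAnalysis as mda  # optional heavy dependency, imported lazily

    u = mda.Universe(str(path))
    return u.atoms.positions.astype(float) / 10.0  # A -> nm


def read_atom_metadata(
    path: str | Path, coordinates: str | Path | None = None
) -> AtomSet:
    """Read the per-atom metadata TSV (optionally with a coordinate file).

    Masses arrive in amu, charges in elementary-charge units; both are
    converted to SI on ingest.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    df = df.sort_values("atom_index", kind="stable")
    if not np.all(df["atom_index"].to_numpy() == np.arange(len(df))):
        raise FormatError(f"{path}: atom_index must run 0..N-1")
    coords = None
    if coordinates is not None:
        coords = read_coordinates(coordinates)
    elif {"x_nm", "y_nm", "z_nm"}.issubset(df.columns):
        coords = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    return AtomSet(
        masses=df["mass_amu"].to_numpy(dtype=float) * ATOMIC_MASS,
        charges=df["charge_e"].to_numpy(dtype=float) * ELEMENTARY_CHARGE,
        component_labels=df["component"].to_numpy(dtype=object),
        residue_indices=df["residue_index"].to_numpy(dtype=int),
        coordinates=coords,
    )


def write_atom_metadata(path: str | Path, atoms: AtomSet) -> None:
    data = {
        "atom_index": np.arange(atoms.n_atoms),
        "mass_amu": atoms.masses / ATOMIC_MASS,
        "charge_e": atoms.charges / ELEMENTARY_CHARGE,
        "component": atoms.component_labels,
        "residue_index": atoms.residue_indices,
    }
    if atoms.coordinates is not None:
        data["x_nm"] = atoms.coordinates[:, 0]
        data["y_nm"] = atoms.coordinates[:, 1]
        data["z_nm"] = atoms.coordinates[:, 2]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_mode_ensemble(
    frequency_files: Sequence[str | Path],
    eigenvector_files: Sequence[str | Path],
    atom_metadata: str | Path,
    coordinates: str | Path | None = None,
    frequency_units: str = "cm-1",
    check: bool = True,
) -> ModeEnsemble:
    """Assemble a validated :class:`ModeEnsemble` from its on-disk parts."""
    if len(frequency_files) != len(eigenvector_files):
        raise FormatError(
            f"{len(frequency_files)} frequency files vs "
            f"{len(eigenvector_files)} eigenvector files"
        )
    atoms = read_atom_metadata(atom_metadata, coordinates)
    replicas = []
    for freq_path, vec_path in zip(frequency_files, eigenvector_files):
        freqs = read_frequencies(freq_path, units=frequency_units)
        vecs = read_eigenvectors(vec_path, atoms.n_atoms)
        if vecs.shape[0] != freqs.size:
            raise FormatError(
                f"{vec_path}: {vecs.shape[0]} modes but {freq_path} has {freqs.size}"
            )
        ms = ModeSet(atoms=atoms, mode_frequencies=freqs, eigenvectors=vecs)
        if check:
            ms.check_orthonormality()
        replicas.append(ms)
    return ModeEnsemble(replicas=tuple(replicas))


def write_mode_ensemble(
    directory: str | Path,
    ensemble: ModeEnsemble,
    prefix: str = "replica",
    frequency_units: str = "cm-1",
) -> dict:
    """Write an ensemble to ``directory``; returns the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_path = directory / "atoms.tsv"
    write_atom_metadata(meta_path, ensemble.replicas[0].atoms)
    freq_files, vec_files = [], []
    for r, ms in enumerate(ensemble):
        fpath = directory / f"{prefix}{r:03d}_frequencies.xvg"
        vpath = directory / f"{prefix}{r:03d}_eigenvectors.tsv"
        write_frequencies(fpath, ms.mode_frequencies, units=frequency_units)
        write_eigenvectors(vpath, ms.eigenvectors)
        freq_files.append(str(fpath))
        vec_files.append(str(vpath))
    return {
        "atom_metadata": str(meta_path),
        "frequency_files": freq_files,
        "eigenvector_files": vec_files,
        "frequency_units": frequency_units,
    }


def write_spectrum(path: str | Path, spectrum) -> None:
    """TSV: nu_Hz, chi_re, chi_im, eps_re, eps_im, k, alpha_per_m."""
    pd.DataFrame(
        {
            "nu_Hz": spectrum.grid,
            "chi_re": spectrum.chi_real,
            "chi_im": spectrum.chi_imag,
            "eps_re": spectrum.eps_real,
            "eps_im": spectrum.eps_imag,
            "k": spectrum.extinction,
            "alpha_per_m": spectrum.absorption,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12e")


def write_dipole_table(path: str | Path, table) -> None:
    """TSV: mode_index, frequency_Hz, component, dx, dy, dz, rho (C kg^-1/2)."""
    pd.DataFrame(
        {
            "mode_index": np.arange(table.n_modes),
            "frequency_Hz": table.mode_frequencies,
            "component": table.component,
            "dx": table.vectors[:, 0],
            "dy": table.vectors[:, 1],
            "dz": table.vectors[:, 2],
            "rho": table.magnitudes,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12e")


def write_angle_table(path: str | Path, table) -> None:
    """TSV: mode_rank, mean_deg, sd_deg, n_defined."""
    pd.DataFrame(
        {
            "mode_rank": np.arange(table.mean.size),
            "mean_deg": table.mean,
            "sd_deg": table.sd,
            "n_defined": table.n_defined,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12e")


def write_persistence(path: str | Path, result) -> None:
    """TSV: frame, shell, n_occupants, n_persistent, percent."""
    n_frames, n_shells = result.per_frame_percent.shape
    frames = np.repeat(np.arange(n_frames), n_shells)
    shells = np.tile(np.arange(n_shells), n_frames)
    pd.DataFrame(
        {
            "frame": frames,
            "shell": shells,
            "n_occupants": result.n_occupants.ravel(),
            "n_persistent": result.n_persistent.ravel(),
            "percent": result.per_frame_percent.ravel(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_shell_trajectory(path: str | Path, frame_spacing_ps: float, boundaries):
    """Read a (frame, water_index, shell) TSV into a ShellTrajectory."""
    from .synthetic import ShellTrajectory

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"frame", "water_index", "shell"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: shell table must have columns {sorted(required)}")
    n_frames = df["frame"].max() + 1
    n_waters = df["water_index"].max() + 1
    idx = np.full((n_frames, n_waters), -1, dtype=int)
    idx[df["frame"].to_numpy(), df["water_index"].to_numpy()] = df["shell"].to_numpy()
    return ShellTrajectory(
        shell_index=idx,
        frame_spacing_ps=frame_spacing_ps,
        boundaries=np.asarray(boundaries, dtype=float),
    )


def write_shell_trajectory(path: str | Path, traj) -> None:
    """TSV: frame, water_index, shell."""
    n_frames, n_waters = traj.shell_index.shape
    pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n_waters),
            "water_index": np.tile(np.arange(n_waters), n_frames),
            "shell": traj.shell_index.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)
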