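"""Plain-text formats: work-profile / PMF / RDF TSV and solvent-frame XYZ.

All tabular files are tab-separated with a mandatory header row, values at six
decimals, and optional ``# key = value`` comment lines up front (used to carry
provenance: config hash, seed, temperature).  Solvent frames use standard
multi-frame XYZ with the probe as the first atom; box and exclusion-zone
parameters ride in the comment line.  Readers tolerate comment lines and
trailing blank lines and raise distinct errors for missing columns,
non-monotone per-trajectory distances, and mixed grids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pmf import PMFProfile, WorkProfile, WorkProfileSet
from .simulate import SolventFrameSet
from .solvation import RDFProfile

__all__ = [
    "write_work_profiles",
    "read_work_profiles",
    "write_pmf_profile",
    "read_pmf_profile",
    "write_rdf_profile",
    "write_xyz_frames",
    "read_xyz_frames",
]

_FLOAT_FMT = "%.6f"


def _write_tsv(path, frame: pd.DataFrame, meta: dict | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key} = {value}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_work_profiles(
    path, work_set: WorkProfileSet, meta: dict | None = None, coarsen: int = 1
) -> None:
    """Write an ensemble as TSV (traj_id, distance_angstrom, work_kcal_mol).

    ``coarsen`` keeps every k-th grid point (always including the last) for
    compact files; the native grid spacing is 0.0005 Å.
    """
    if coarsen < 1:
        raise ValueError("coarsen must be >= 1")
    idx = np.arange(work_set.grid.size)
    if coarsen > 1:
        idx = np.unique(np.r_[idx[::coarsen], idx[-1]])
    meta = dict(meta or {})
    meta.setdefault("temperature_k", work_set.temperature)
    frames = []
    for i in range(work_set.n_traj):
        frames.append(
            pd.DataFrame(
                {
                    "traj_id": int(work_set.traj_ids[i]),
                    "distance_angstrom": work_set.grid[idx],
                    "work_kcal_mol": work_set.works[i, idx],
                }
            )
        )
    _write_tsv(path, pd.concat(frames, ignore_index=True), meta)


def read_work_profiles(path, temperature: float | None = None) -> WorkProfileSet:
    """Read a work-profile TSV back into a :class:`WorkProfileSet`.

    Comment lines (``#``) and trailing blank lines are tolerated.  The
    temperature is taken from the ``temperature_k`` metadata comment unless
    overridden.  Distinct errors: missing columns; non-monotone distances
    (naming the trajectory); mixed grids across trajectories.
    """
    table = pd.read_csv(path, sep="\t", comment="#", skip_blank_lines=True)
    required = ["traj_id", "distance_angstrom", "work_kcal_mol"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"work-profile file {path}: missing columns {missing}")
    if temperature is None:
        temperature = float(_read_meta(path).get("temperature_k", 298.0))
    profiles = []
    grid = None
    for traj_id, group in table.groupby("traj_id", sort=True):
        d = group["distance_angstrom"].to_numpy(dtype=float)
        w = group["work_kcal_mol"].to_numpy(dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError(
                f"work-profile file {path}: non-monotone distances in traj_id {traj_id}"
            )
        if grid is None:
            grid = d
        elif d.shape != grid.shape or not np.allclose(d, grid, atol=1e-9):
            raise ValueError(
                f"work-profile file {path}: traj_id {traj_id} uses a different "
                "distance grid (mixed grids)"
            )
        profiles.append(WorkProfile(grid=d, work=w, traj_id=int(traj_id)))
    if not profiles:
        raise ValueError(f"work-profile file {path}: no trajectories found")
    return WorkProfileSet.from_profiles(profiles, temperature=temperature)


def write_pmf_profile(path, profile: PMFProfile, meta: dict | None = None) -> None:
    """Write a PMF profile as TSV (distance_angstrom, pmf_kcal_mol, sd_kcal_mol)."""
    sd = profile.sd if profile.sd is not None else np.zeros_like(profile.pmf)
    _write_tsv(
        path,
        pd.DataFrame(
            {
                "distance_angstrom": profile.grid,
                "pmf_kcal_mol": profile.pmf,
                "sd_kcal_mol": sd,
            }
        ),
        meta,
    )


def read_pmf_profile(path, temperature: float = 298.0) -> PMFProfile:
    table = pd.read_csv(path, sep="\t", comment="#", skip_blank_lines=True)
    required = ["distance_angstrom", "pmf_kcal_mol", "sd_kcal_mol"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"PMF file {path}: missing columns {missing}")
    return PMFProfile(
        grid=table["distance_angstrom"].to_numpy(dtype=float),
        pmf=table["pmf_kcal_mol"].to_numpy(dtype=float),
        sd=table["sd_kcal_mol"].to_numpy(dtype=float),
        temperature=temperature,
    )


def write_rdf_profile(path, rdf: RDFProfile, meta: dict | None = None) -> None:
    """Write an RDF as TSV (r_angstrom, g)."""
    _write_tsv(path, pd.DataFrame({"r_angstrom": rdf.r, "g": rdf.g}), meta)


def write_xyz_frames(path, frames: SolventFrameSet) -> None:
    """Write frames as concatenated XYZ; first atom P = probe, then O = solvent.

    Box and exclusion parameters are stored on each comment line so the file
    round-trips through :func:`read_xyz_frames`.
    """
    with open(path, "w") as fh:
        for i in range(frames.n_frames):
            solv = frames.solvent[i]
            fh.write(f"{len(solv) + 1}\n")
            fh.write(
                f"frame {i} box_radius={frames.box_radius} "
                f"exclusion_radius={frames.exclusion_radius} "
                f"exclusion_prob={frames.exclusion_prob}\n"
            )
            p = frames.probe[i]
            fh.write(f"P {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            for s in solv:
                fh.write(f"O {s[0]:.6f} {s[1]:.6f} {s[2]:.6f}\n")


def read_xyz_frames(path) -> SolventFrameSet:
    """Read frames written by :func:`write_xyz_frames`."""
    probes = []
    solvents = []
    box_radius = exclusion_radius = exclusion_prob = 0.0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n_atoms = int(lines[pos].strip())
        comment = lines[pos + 1]
        for token in comment.split():
            if "=" in token:
                key, _, value = token.partition("=")
                if key == "box_radius":
                    box_radius = float(value)
                elif key == "exclusion_radius":
                    exclusion_radius = float(value)
                elif key == "exclusion_prob":
                    exclusion_prob = float(value)
        atoms = []
        for ln in lines[pos + 2 : pos + 2 + n_atoms]:
            parts = ln.split()
            atoms.append([float(parts[1]), float(parts[2]), float(parts[3])])
        atoms = np.asarray(atoms)
        probes.append(atoms[0])
        solvents.append(atoms[1:])
        pos += 2 + n_atoms
    if not probes:
        raise ValueError(f"XYZ file {path}: no frames found")
    return SolventFrameSet(
        probe=np.asarray(probes),
        solvent=solvents,
        box_radius=box_radius,
        exclusion_radius=exclusion_radius,
        exclusion_prob=exclusion_prob,
    )
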