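"""Trajectory and curve I/O.

The interchange format is multi-frame XYZ in which the ion's lone-pair
sites (Wannier centers) appear as pseudo-atoms with a dedicated label
(default ``X``) alongside the ion and the water atoms.  A variant reader
merges a separate per-frame centers file (CPMD-style IONS + CENTERS dumps)
into the same in-memory representation.  ``dt`` and ``box_edge`` are
required configuration rather than parsed from comment lines, because XYZ
comments are non-standard.

Output formats: two-column text curves and Gaussian cube volumetric grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_geometry import (
    ContractError,
    FormatError,
    Frame,
    Trajectory,
    minimum_image,
)

__all__ = [
    "SpeciesMap",
    "read_xyz_trajectory",
    "read_xyz_with_centers",
    "write_xyz_trajectory",
    "write_curve",
    "read_curve",
    "write_cube",
]

BOHR_PER_ANGSTROM = 1.8897259886


@dataclass(frozen=True)
class SpeciesMap:
    """Atom labels identifying the four roles in the XYZ file."""

    ion_label: str = "Cl"
    water_O_label: str = "O"
    water_H_label: str = "H"
    lp_label: str = "X"

    def __post_init__(self) -> None:
        labels = (self.ion_label, self.water_O_label, self.water_H_label, self.lp_label)
        if len(set(labels)) != 4:
            raise ContractError(f"species labels must be pairwise distinct: {labels}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _load_xyz(path) -> tuple[list[str], np.ndarray]:
    """Return (names, coords[f, atom, 3]) for a multi-frame XYZ file."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="XYZ", topology_format="XYZ")
            names = [str(n) for n in u.atoms.names]
            coords = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                              dtype=float)
        except FormatError:
            raise
        except Exception as exc:  # inconsistent atom counts, truncation, ...
            raise FormatError(f"cannot parse XYZ file {path}: {exc}") from exc
    return names, coords


def _assemble_frame(
    names: list[str],
    xyz: np.ndarray,
    species_map: SpeciesMap,
    box_edge: float,
    time: float,
    frame_index: int,
) -> Frame:
    names_arr = np.array(names)
    ion_rows = np.nonzero(names_arr == species_map.ion_label)[0]
    if ion_rows.size != 1:
        raise FormatError(
            f"{ion_rows.size} ion atoms ({species_map.ion_label}) in frame {frame_index}, expected 1"
        )
    ion = xyz[ion_rows[0]]

    # Lone pairs: pseudo-atom rows within box_edge/4 of the ion. Water
    # Wannier centers (near O) are discarded by this proximity rule; if more
    # than four survive, the four nearest are kept.
    lp_rows = np.nonzero(names_arr == species_map.lp_label)[0]
    d_lp = np.linalg.norm(minimum_image(xyz[lp_rows] - ion, box_edge), axis=1)
    near = lp_rows[d_lp < box_edge / 4.0]
    if near.size < 4:
        raise FormatError(f"{near.size} lone pairs in frame {frame_index}, expected 4")
    if near.size > 4:
        order = np.argsort(d_lp[d_lp < box_edge / 4.0], kind="stable")[:4]
        near = near[np.sort(order)]
    lp_xyz = xyz[near]

    o_rows = np.nonzero(names_arr == species_map.water_O_label)[0]
    h_rows = np.nonzero(names_arr == species_map.water_H_label)[0]
    if h_rows.size != 2 * o_rows.size:
        raise FormatError(
            f"frame {frame_index}: {h_rows.size} H atoms for {o_rows.size} O atoms"
        )
    if o_rows.size == 0:
        raise FormatError(f"frame {frame_index}: no water atoms found")

    # Each hydrogen joins its nearest oxygen (minimum-image metric).
    sep = minimum_image(
        xyz[h_rows][:, None, :] - xyz[o_rows][None, :, :], box_edge
    )
    nearest_o = np.argmin(np.linalg.norm(sep, axis=2), axis=1)
    h1 = np.full((o_rows.size, 3), np.nan)
    h2 = np.full((o_rows.size, 3), np.nan)
    counts = np.zeros(o_rows.size, dtype=int)
    for h_i, o_i in zip(h_rows, nearest_o):
        if counts[o_i] == 0:
            h1[o_i] = xyz[h_i]
        elif counts[o_i] == 1:
            h2[o_i] = xyz[h_i]
        counts[o_i] += 1
    if np.any(counts != 2):
        bad = int(np.nonzero(counts != 2)[0][0])
        raise FormatError(
            f"frame {frame_index}: oxygen {bad} has {int(counts[bad])} assigned hydrogens, expected 2"
        )

    return Frame(
        time=time,
        box_edge=box_edge,
        ion_xyz=ion,
        lp_xyz=lp_xyz,
        o_xyz=xyz[o_rows],
        h1_xyz=h1,
        h2_xyz=h2,
        water_ids=np.arange(o_rows.size),
    )


def read_xyz_trajectory(path, species_map: SpeciesMap, dt: float, box_edge: float) -> Trajectory:
    """Read a merged XYZ trajectory (ion + lone-pair pseudo-atoms + waters).

    Waters are assembled by nearest-H-to-O assignment; water ids follow
    first-frame oxygen order and are preserved by list position across
    frames (XYZ atom order must be consistent, which the constant-atom-count
    requirement enforces).
    """
    names, coords = _load_xyz(path)
    frames = [
        _assemble_frame(names, coords[i], species_map, box_edge, i * dt, i)
        for i in range(coords.shape[0])
    ]
    return Trajectory(frames=frames, dt=dt)


def read_xyz_with_centers(
    traj_path, centers_path, species_map: SpeciesMap, dt: float, box_edge: float
) -> Trajectory:
    """Read an atoms-only XYZ plus a separate Wannier-centers XYZ and merge
    them frame by frame.  Both files must have equal frame counts."""
    names_a, coords_a = _load_xyz(traj_path)
    names_c, coords_c = _load_xyz(centers_path)
    if coords_a.shape[0] != coords_c.shape[0]:
        raise FormatError(
            f"frame count mismatch: {coords_a.shape[0]} atom frames vs "
            f"{coords_c.shape[0]} centers frames"
        )
    names = names_a + names_c
    frames = [
        _assemble_frame(
            names,
            np.vstack([coords_a[i], coords_c[i]]),
            species_map,
            box_edge,
            i * dt,
            i,
        )
        for i in range(coords_a.shape[0])
    ]
    return Trajectory(frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_xyz_trajectory(traj: Trajectory, path, species_map: SpeciesMap) -> None:
    """Write frames as multi-frame XYZ: ion, 4 lone pairs, then O,H,H per water."""
    with open(path, "w") as fh:
        for frame in traj.frames:
            natoms = 5 + 3 * frame.n_waters
            fh.write(f"{natoms}\n")
            fh.write(f"t= {frame.time:.6f} ps\n")
            def line(label, p):
                fh.write(f"{label} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            line(species_map.ion_label, frame.ion_xyz)
            for lp in frame.lp_xyz:
                line(species_map.lp_label, lp)
            for i in range(frame.n_waters):
                line(species_map.water_O_label, frame.o_xyz[i])
                line(species_map.water_H_label, frame.h1_xyz[i])
                line(species_map.water_H_label, frame.h2_xyz[i])


def write_curve(x, y, path, xlabel: str = "x", ylabel: str = "y") -> None:
    """Two-column whitespace-delimited text with a '#' header."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ContractError(f"length mismatch: {x.shape} vs {y.shape}")
    with open(path, "w") as fh:
        fh.write(f"# {xlabel}  {ylabel}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.8g} {yi:.8g}\n")


def read_curve(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns")
    return data[:, 0], data[:, 1]


def write_cube(grid, path, atomic_number: int = 17) -> None:
    """Write a volumetric grid in Gaussian cube format (lengths in bohr).

    The ion sits at the origin of the local reference frame and is emitted
    as the single atom record.  Densities are written in z-fastest order.
    """
    values = np.asarray(grid.density, dtype=float)
    if values.size == 0:
        raise ContractError("empty grid")
    nx, ny, nz = values.shape
    vs = grid.voxel_size * BOHR_PER_ANGSTROM
    origin = np.asarray(grid.origin, dtype=float) * BOHR_PER_ANGSTROM
    with open(path, "w") as fh:
        fh.write("lpshells spatial distribution function\n")
        fh.write(f"normalized density, {getattr(grid, 'n_frames', 0)} frames\n")
        fh.write(f"{1:5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {vs:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {vs:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {vs:12.6f}\n")
        fh.write(f"{atomic_number:5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        for i in range(nx):
            for j in range(ny):
                row = values[i, j, :]
                for k0 in range(0, nz, 6):
                    fh.write(" ".join(f"{v:13.5e}" for v in row[k0:k0 + 6]) + "\n")
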