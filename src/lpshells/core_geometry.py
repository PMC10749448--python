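"""Periodic-boundary vector math and the domain types shared by all stages.

A trajectory is a time-ordered list of frames, each holding one monatomic
anion, its four lone-pair sites (e.g. maximally localized Wannier-function
centers), and rigid water molecules, in a cubic periodic box.  Coordinates
are stored unwrapped exactly as read; every interparticle vector passes
through the minimum-image convention, so all analyses are independent of
the wrapping convention of the input file.

Angles are reported in degrees throughout (chemistry convention for
hydrogen-bond geometry); distances are in angstroms, times in picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LPShellsError",
    "InvalidGeometryError",
    "FormatError",
    "ContractError",
    "GenerationError",
    "NoMinimumError",
    "NoIntersectionError",
    "DegenerateFrameError",
    "SingularFitError",
    "UndefinedNMRTError",
    "DomainError",
    "Frame",
    "Trajectory",
    "PairGeometry",
    "minimum_image",
    "angle_between",
    "smooth5",
]

DT_TOLERANCE_PS = 1e-9  # allowed jitter in inter-frame spacing


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class LPShellsError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(LPShellsError):
    """Non-finite coordinates or degenerate (zero-length) vectors."""


class FormatError(LPShellsError):
    """Malformed trajectory or table input."""


class ContractError(LPShellsError):
    """An operation was called outside its stated preconditions."""


class GenerationError(LPShellsError):
    """The synthetic generator could not place molecules without overlap."""


class NoMinimumError(LPShellsError):
    """No local minimum of g(r) exists inside the search window."""


class NoIntersectionError(LPShellsError):
    """Two distributions never cross in the required direction."""


class DegenerateFrameError(LPShellsError):
    """Lone-pair sites too collinear to define a local reference frame."""


class SingularFitError(LPShellsError):
    """Regression abscissae are degenerate."""


class UndefinedNMRTError(LPShellsError):
    """Residence time requested for a shell with zero exchange events."""


class DomainError(LPShellsError):
    """Argument outside the valid domain of a formula."""


# ---------------------------------------------------------------------------
# Vector operations
# ---------------------------------------------------------------------------

def minimum_image(v: np.ndarray, box_edge: float) -> np.ndarray:
    """Map vector components into [-box_edge/2, box_edge/2).

    Works on a single vector or an (..., 3) array of vectors.  Translation
    of the input by any lattice vector leaves the output unchanged, and the
    map is idempotent.
    """
    if box_edge <= 0:
        raise ContractError(f"box_edge must be positive, got {box_edge}")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidGeometryError("non-finite component in vector")
    # floor-based rounding keeps the half-open convention at exactly L/2
    return v - box_edge * np.floor(v / box_edge + 0.5)


def angle_between(u: np.ndarray, w: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise InvalidGeometryError("zero-length vector in angle computation")
    c = np.dot(u, w) / (nu * nw)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def smooth5(y: np.ndarray) -> np.ndarray:
    """5-point moving average with edge reflection, used before every
    extremum/intersection search on binned curves."""
    y = np.asarray(y, dtype=float)
    if y.size < 5:
        return y.copy()
    padded = np.concatenate([y[2:0:-1], y, y[-2:-4:-1]])
    kernel = np.ones(5) / 5.0
    return np.convolve(padded, kernel, mode="valid")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """One snapshot: ion, four lone-pair sites and rigid waters.

    Waters are stored as parallel (n, 3) arrays ``o_xyz``, ``h1_xyz``,
    ``h2_xyz`` with stable integer ``water_ids`` aligned by row.
    """

    time: float                 # ps
    box_edge: float             # A, cubic
    ion_xyz: np.ndarray         # (3,)
    lp_xyz: np.ndarray          # (4, 3) lone-pair sites
    o_xyz: np.ndarray           # (n, 3)
    h1_xyz: np.ndarray          # (n, 3)
    h2_xyz: np.ndarray          # (n, 3)
    water_ids: np.ndarray       # (n,) int

    def __post_init__(self) -> None:
        self.ion_xyz = np.asarray(self.ion_xyz, dtype=float).reshape(3)
        self.lp_xyz = np.asarray(self.lp_xyz, dtype=float).reshape(-1, 3)
        self.o_xyz = np.asarray(self.o_xyz, dtype=float).reshape(-1, 3)
        self.h1_xyz = np.asarray(self.h1_xyz, dtype=float).reshape(-1, 3)
        self.h2_xyz = np.asarray(self.h2_xyz, dtype=float).reshape(-1, 3)
        self.water_ids = np.asarray(self.water_ids, dtype=int).reshape(-1)
        if self.box_edge <= 0:
            raise InvalidGeometryError("box_edge must be positive")
        if self.lp_xyz.shape[0] != 4:
            raise InvalidGeometryError(
                f"expected exactly 4 lone-pair sites, got {self.lp_xyz.shape[0]}"
            )
        for arr in (self.ion_xyz, self.lp_xyz, self.o_xyz, self.h1_xyz, self.h2_xyz):
            if not np.all(np.isfinite(arr)):
                raise InvalidGeometryError("non-finite coordinate in frame")
        lp_d = np.linalg.norm(
            minimum_image(self.lp_xyz - self.ion_xyz, self.box_edge), axis=1
        )
        if np.any(lp_d >= self.box_edge / 4.0):
            raise InvalidGeometryError(
                "lone-pair site farther than box_edge/4 from the ion"
            )
        if len(set(self.water_ids.tolist())) != self.water_ids.size:
            raise InvalidGeometryError("water_ids not unique within frame")
        n = self.o_xyz.shape[0]
        if not (self.h1_xyz.shape[0] == self.h2_xyz.shape[0] == self.water_ids.size == n):
            raise InvalidGeometryError("water arrays have inconsistent lengths")

    @property
    def n_waters(self) -> int:
        return self.o_xyz.shape[0]

    def water_index(self, water_id: int) -> int:
        idx = np.nonzero(self.water_ids == water_id)[0]
        if idx.size == 0:
            raise ContractError(f"water_id {water_id} not present in frame")
        return int(idx[0])


@dataclass
class Trajectory:
    """Time-ordered frames with a constant inter-frame spacing ``dt`` (ps)."""

    frames: list[Frame]
    dt: float
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ContractError("trajectory needs at least one frame")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ContractError("frame times must be strictly increasing")
            if np.any(np.abs(steps - self.dt) > DT_TOLERANCE_PS):
                raise ContractError("inter-frame spacing is not constant dt")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def box_edge(self) -> float:
        return self.frames[0].box_edge

    @property
    def t_sim(self) -> float:
        """Production span: time(last) - time(first), in ps."""
        return self.frames[-1].time - self.frames[0].time


@dataclass
class PairGeometry:
    """Hydrogen-bond geometry of one ion–water contact through one lone pair.

    ``alpha`` is the angle at the ion between the ion→lone-pair direction and
    the ion→H direction; ``beta`` the angle at the hydrogen between the O→H
    bond direction and the H→lone-pair direction.  The ideal linear hydrogen
    bond has alpha = beta = 0.
    """

    water_id: int
    lp_index: int               # 0-3
    h_index: int                # 0-1
    r_lp_h: float               # A
    alpha: float                # deg
    beta: float                 # deg
    eta: float                  # A
    r_xo: float                 # A  ion-oxygen
    r_xh: float                 # A  ion-hydrogen

    def __post_init__(self) -> None:
        if min(self.r_lp_h, self.r_xo, self.r_xh) <= 0:
            raise InvalidGeometryError("pair distances must be positive")
        for a in (self.alpha, self.beta):
            if not (0.0 <= a <= 180.0):
                raise InvalidGeometryError(f"angle {a} outside [0, 180]")
        if self.eta <= 0:
            raise InvalidGeometryError("eta must be positive")
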