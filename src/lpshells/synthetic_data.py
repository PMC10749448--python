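"""Synthetic halide-hydration trajectories with known ground truth.

The generator emulates the statistical structure that the lone-pair
analysis assumes: four lone-pair sites tetrahedrally arranged around the
ion (rigidly rotated by a slow random walk), up to four "tight" waters
each anchored to a distinct lone pair with one O–H bond aimed at it,
"loose" first-shell waters placed in a spherical shell with random
orientation (optionally forced to point both hydrogens away from the ion,
mimicking misoriented second-shell-like molecules), and bulk waters
outside the first shell.  Region membership per water evolves as a
continuous-time Markov chain discretized at the frame spacing; the
geometry is resampled for the current region every frame, so there is no
vibrational dynamics — only the region kinetics are dynamical.

Ground-truth region labels and misorientation flags are carried in
``Trajectory.metadata`` for label-recovery tests; analysis stages never
read them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .core_geometry import ContractError, Frame, GenerationError, Trajectory

__all__ = [
    "SynthParams",
    "TETRAHEDRAL_DIRECTIONS",
    "chloride_preset",
    "iodide_preset",
    "simulate_regions",
    "generate_trajectory",
    "generate_pair_energies",
]

# Ideal rigid water geometry
OH_BOND = 0.97          # A
HOH_ANGLE = 104.5       # deg
# Minimum O-O separation enforced during placement.  Being > 2*OH_BOND it
# guarantees every hydrogen is nearer to its own oxygen than to any other
# (nearest-H-to-O assembly of written trajectories is unambiguous), while
# leaving the thin loose shell enough room for occupancy fluctuations.
MIN_OO_SEPARATION = 2.0
MAX_PLACEMENT_ATTEMPTS = 100

TETRAHEDRAL_DIRECTIONS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for the synthetic generator.

    Defaults describe a chloride-like system: a 14 A cubic box, four tight
    waters anchored on the lone pairs at an ion–H distance centered on
    2.24 A (giving ion–O near the 3.21 A first-shell distance), loose
    first-shell waters in the outer first-shell region between 3.4 A and
    the 4.0 A first-minimum cutoff (loose waters sit at larger distances
    than the tight peak), and tight<->loose exchange at 1 / ps.
    """

    n_tight: int = 4
    n_loose: int = 6
    n_bulk: int = 20
    box_edge: float = 14.0          # A
    d_lp: float = 0.5               # A, ion -> lone-pair offset
    r_tight_mean: float = 2.24      # A, ion-H distance of tight waters
    r_tight_sigma: float = 0.10     # A
    r_loose_range: tuple[float, float] = (3.4, 4.0)   # A, ion-O shell
    angular_noise_deg: float = 10.0  # sigma of LP- and O-H-alignment jitter
    rotation_walk_deg: float = 1.0   # per-frame rigid LP-frame random walk
    k_TL: float = 1.0               # 1/ps  tight -> loose
    k_LT: float = 1.0               # 1/ps  loose -> tight (needs a free lone pair)
    k_LB: float = 2.0               # 1/ps  loose -> bulk
    k_BL: float = 0.6               # 1/ps  bulk -> loose
    misoriented_fraction: float = 0.0
    dt: float = 0.005               # ps
    n_frames: int = 2000
    seed: int = 0
    ion_label: str = "Cl"

    def __post_init__(self) -> None:
        if min(self.k_TL, self.k_LT, self.k_LB, self.k_BL) < 0:
            raise ContractError("exchange rates must be non-negative")
        if self.n_tight > 4:
            raise ContractError("at most 4 tight waters (one per lone pair)")
        if not (0.0 <= self.misoriented_fraction <= 1.0):
            raise ContractError("misoriented_fraction must lie in [0, 1]")
        if self.n_frames < 1 or self.dt <= 0 or self.box_edge <= 0:
            raise ContractError("n_frames, dt and box_edge must be positive")
        if self.r_loose_range[0] >= self.r_loose_range[1]:
            raise ContractError("r_loose_range must be an increasing interval")
        # bulk waters live outside the loose shell; require room for them
        free_volume = self.box_edge**3 - 4.0 / 3.0 * np.pi * self.r_loose_range[1] ** 3
        if self.n_bulk * (4.0 / 3.0) * np.pi * MIN_OO_SEPARATION**3 > free_volume:
            raise ContractError("box too small for the requested bulk waters")


def chloride_preset(**overrides) -> SynthParams:
    """Chloride-like conditions (first-shell distance near 3.21 A)."""
    return replace(SynthParams(), **overrides)


def iodide_preset(**overrides) -> SynthParams:
    """Iodide-like conditions: longer first-shell distances (X-O near
    3.58 A, first minimum 4.37 A) and a misoriented loose-water fraction."""
    base = SynthParams(
        r_tight_mean=2.61,
        r_loose_range=(3.7, 4.37),
        misoriented_fraction=0.15,
        ion_label="I",
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# Region kinetics (continuous-time Markov chain, discretized at dt)
# ---------------------------------------------------------------------------

def simulate_regions(params: SynthParams, rng: np.random.Generator | None = None):
    """Simulate per-water region labels ('T'/'L'/'B') over the run.

    Returns ``(regions, slots)`` with shapes (n_frames, n_waters); ``slots``
    holds the lone-pair index (0-3) occupied by each tight water, -1
    otherwise.  Loose->tight transitions require a free lone-pair slot;
    candidates are drawn in random order when slots are scarce.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_tight + params.n_loose + params.n_bulk
    region = np.array(
        ["T"] * params.n_tight + ["L"] * params.n_loose + ["B"] * params.n_bulk
    )
    slot = np.full(n, -1, dtype=int)
    slot[: params.n_tight] = np.arange(params.n_tight)

    p_tl = 1.0 - np.exp(-params.k_TL * params.dt)
    k_l_out = params.k_LT + params.k_LB
    p_l = 1.0 - np.exp(-k_l_out * params.dt)
    frac_lt = params.k_LT / k_l_out if k_l_out > 0 else 0.0
    p_bl = 1.0 - np.exp(-params.k_BL * params.dt)

    regions = np.empty((params.n_frames, n), dtype="U1")
    slots = np.empty((params.n_frames, n), dtype=int)
    regions[0] = region
    slots[0] = slot
    for f in range(1, params.n_frames):
        u = rng.random(n)
        pick = rng.random(n)
        # departures from tight
        leaving_t = (region == "T") & (u < p_tl)
        slot[leaving_t] = -1
        region[leaving_t] = "L"
        # bulk -> loose
        entering_l = (region == "B") & (u < p_bl)
        region[entering_l] = "L"
        # loose transitions: split between tight (slot permitting) and bulk
        loose_moving = np.nonzero(
            (region == "L") & ~leaving_t & ~entering_l & (u < p_l)
        )[0]
        to_tight = loose_moving[pick[loose_moving] < frac_lt]
        to_bulk = loose_moving[pick[loose_moving] >= frac_lt]
        region[to_bulk] = "B"
        free = [s for s in range(4) if s not in set(slot[slot >= 0].tolist())]
        for w in rng.permutation(to_tight):
            if not free:
                break  # no vacancy: the attempted entry is cancelled
            region[w] = "T"
            slot[w] = free.pop(0)
        regions[f] = region
        slots[f] = slot
    return regions, slots


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u and to each other."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _jitter(u: np.ndarray, sigma_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Tilt unit vector u by an angle ~ |N(0, sigma)| about a random
    perpendicular axis."""
    if sigma_deg == 0.0:
        return u
    e1, e2 = _perp_basis(u)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.cos(phi) * e1 + np.sin(phi) * e2
    theta = np.radians(rng.normal(0.0, sigma_deg))
    return Rotation.from_rotvec(theta * axis).apply(u)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _second_hydrogen(o: np.ndarray, h1: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d1 = (h1 - o) / np.linalg.norm(h1 - o)
    e1, e2 = _perp_basis(d1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    p = np.cos(phi) * e1 + np.sin(phi) * e2
    ang = np.radians(HOH_ANGLE)
    d2 = np.cos(ang) * d1 + np.sin(ang) * p
    return o + OH_BOND * d2


def _water_from_o(o, orientation_dir, rng):
    """Rigid water at oxygen position o with O-H1 along orientation_dir."""
    h1 = o + OH_BOND * orientation_dir
    h2 = _second_hydrogen(o, h1, rng)
    return h1, h2


def _misoriented_water(o, away, rng):
    """Both hydrogens in the hemisphere away from the ion: the H-O-H
    bisector points along ``away`` (jittered), so each O-H direction sits
    ~52 deg from it."""
    e1, e2 = _perp_basis(away)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    p = np.cos(phi) * e1 + np.sin(phi) * e2
    half = np.radians(HOH_ANGLE / 2.0)
    d1 = np.cos(half) * away + np.sin(half) * p
    d2 = np.cos(half) * away - np.sin(half) * p
    return o + OH_BOND * d1, o + OH_BOND * d2


def generate_trajectory(params: SynthParams) -> Trajectory:
    """Generate a synthetic trajectory; fixed seed gives bit-identical output.

    ``Trajectory.metadata`` carries ``true_regions`` (n_frames, n_waters)
    with values 'T'/'L'/'B', ``true_slots`` (assigned lone-pair index or
    -1) and ``true_misoriented`` (bool mask, set only for loose waters
    drawn misoriented in that frame).
    """
    rng = np.random.default_rng(params.seed)
    regions, slots = simulate_regions(params, rng)
    n = regions.shape[1]
    center = np.full(3, params.box_edge / 2.0)

    rot = Rotation.identity()
    frames: list[Frame] = []
    misoriented = np.zeros((params.n_frames, n), dtype=bool)
    r_lo, r_hi = params.r_loose_range

    for f in range(params.n_frames):
        if f > 0 and params.rotation_walk_deg > 0:
            step = Rotation.from_rotvec(
                np.radians(rng.normal(0.0, params.rotation_walk_deg, 3))
            )
            rot = step * rot
        dirs = rot.apply(TETRAHEDRAL_DIRECTIONS)
        lp_xyz = center + params.d_lp * dirs

        o_xyz = np.empty((n, 3))
        h1_xyz = np.empty((n, 3))
        h2_xyz = np.empty((n, 3))
        placed: list[np.ndarray] = []

        # anchored tight waters first, so loose/bulk placement can avoid them
        order = [w for w in range(n) if regions[f, w] == "T"]
        order += [w for w in range(n) if regions[f, w] != "T"]
        for w in order:
            reg = regions[f, w]
            if reg == "T":
                axis = _jitter(dirs[slots[f, w]], params.angular_noise_deg, rng)
                r = rng.normal(params.r_tight_mean, params.r_tight_sigma)
                h1 = center + r * axis
                # O behind H on the (jittered) lone-pair axis, so the O-H
                # bond points at the assigned lone pair
                o = h1 + OH_BOND * _jitter(axis, params.angular_noise_deg, rng)
                h2 = _second_hydrogen(o, h1, rng)
            else:
                for attempt in range(MAX_PLACEMENT_ATTEMPTS + 1):
                    if reg == "L":
                        r = (rng.random() * (r_hi**3 - r_lo**3) + r_lo**3) ** (1.0 / 3.0)
                        o = center + r * _random_unit(rng)
                    else:
                        o = rng.random(3) * params.box_edge
                        d = o - center
                        d -= params.box_edge * np.floor(d / params.box_edge + 0.5)
                        if np.linalg.norm(d) <= r_hi:
                            continue
                    if not placed:
                        break
                    sep = np.array(placed) - o
                    sep -= params.box_edge * np.floor(sep / params.box_edge + 0.5)
                    if np.min(np.linalg.norm(sep, axis=1)) >= MIN_OO_SEPARATION:
                        break
                else:
                    raise GenerationError(
                        f"could not place a {reg} water without overlap in frame {f}"
                    )
                if reg == "L" and rng.random() < params.misoriented_fraction:
                    away = _jitter(
                        (o - center) / np.linalg.norm(o - center),
                        params.angular_noise_deg,
                        rng,
                    )
                    h1, h2 = _misoriented_water(o, away, rng)
                    misoriented[f, w] = True
                else:
                    h1, h2 = _water_from_o(o, _random_unit(rng), rng)
            o_xyz[w], h1_xyz[w], h2_xyz[w] = o, h1, h2
            placed.append(o)

        frames.append(
            Frame(
                time=f * params.dt,
                box_edge=params.box_edge,
                ion_xyz=center.copy(),
                lp_xyz=lp_xyz,
                o_xyz=o_xyz,
                h1_xyz=h1_xyz,
                h2_xyz=h2_xyz,
                water_ids=np.arange(n),
            )
        )

    traj = Trajectory(frames=frames, dt=params.dt)
    traj.metadata["true_regions"] = regions
    traj.metadata["true_slots"] = slots
    traj.metadata["true_misoriented"] = misoriented
    traj.metadata["params"] = params
    return traj


# ---------------------------------------------------------------------------
# Pair energies
# ---------------------------------------------------------------------------

def generate_pair_energies(etas, slope, intercept, noise_sd, seed=0):
    """Linear eta -> interaction-energy model with Gaussian noise (kJ/mol)."""
    etas = np.asarray(etas, dtype=float)
    if etas.size == 0:
        raise ContractError("etas must be nonempty")
    rng = np.random.default_rng(seed)
    return slope * etas + intercept + rng.normal(0.0, noise_sd, etas.size)
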