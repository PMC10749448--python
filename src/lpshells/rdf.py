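"""Ion–water radial distribution functions and coordination numbers.

g(r) is the histogram of minimum-image ion–partner distances normalized
per frame by the exact spherical-shell volume and by the mean partner
number density of the whole box.  Masked variants (per-frame, per-water
0/1 weights) share the total's normalization, so the g(r) of a subset and
of its complement sum bin-by-bin to the full curve — this is how the
tight-shell / loose+bulk decomposition is produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import (
    ContractError,
    NoMinimumError,
    Trajectory,
    minimum_image,
    smooth5,
)

__all__ = [
    "RDF",
    "ShellCutoffs",
    "ion_partner_distances",
    "compute_rdf",
    "first_minimum",
    "coordination_number",
    "coordination_number_from_rdf",
]


@dataclass
class RDF:
    r_centers: np.ndarray      # A, uniformly spaced bin centers
    g: np.ndarray              # dimensionless
    bin_width: float           # A
    pair_kind: str             # "XO" or "XH"
    n_frames: int
    mean_density: float        # partner number density of the whole box, 1/A^3


@dataclass(frozen=True)
class ShellCutoffs:
    """First-shell distance cutoff (first g(r) minimum) and the eta cutoff
    separating tight from loose waters."""

    r_cut: float   # A
    eta_cut: float  # A

    def __post_init__(self) -> None:
        if self.r_cut <= 0 or self.eta_cut <= 0:
            raise ContractError("cutoffs must be positive")


def ion_partner_distances(traj: Trajectory, pair_kind: str = "XO") -> np.ndarray:
    """Minimum-image ion–partner distances.

    Returns (n_frames, n_waters) for ``XO`` and (n_frames, 2*n_waters) for
    ``XH`` (both hydrogens of each water counted independently; columns
    [h1 of w0, h2 of w0, h1 of w1, ...]).
    """
    if pair_kind not in ("XO", "XH"):
        raise ContractError(f"pair_kind must be 'XO' or 'XH', got {pair_kind!r}")
    box = traj.box_edge
    rows = []
    for frame in traj.frames:
        if pair_kind == "XO":
            sep = minimum_image(frame.o_xyz - frame.ion_xyz, box)
            rows.append(np.linalg.norm(sep, axis=1))
        else:
            h = np.stack([frame.h1_xyz, frame.h2_xyz], axis=1).reshape(-1, 3)
            sep = minimum_image(h - frame.ion_xyz, box)
            rows.append(np.linalg.norm(sep, axis=1))
    return np.array(rows)


def compute_rdf(
    traj: Trajectory,
    pair_kind: str = "XO",
    bin_width: float = 0.02,
    r_max: float | None = None,
    weights: np.ndarray | None = None,
) -> RDF:
    """Ion–partner g(r) with optional per-(frame, water) 0/1 mask.

    The mask is shaped (n_frames, n_waters) regardless of pair kind; for
    ``XH`` it is expanded to both hydrogens of each water.  Masked curves
    keep the whole-box normalization.
    """
    if bin_width <= 0:
        raise ContractError("bin_width must be positive")
    box = traj.box_edge
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0:
        raise ContractError(f"r_max {r_max} exceeds box_edge/2 = {box / 2.0}")

    dists = ion_partner_distances(traj, pair_kind)
    n_partner = dists.shape[1]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if pair_kind == "XH":
            weights = np.repeat(weights, 2, axis=1)
        if weights.shape != dists.shape:
            raise ContractError("weights mask not aligned with trajectory")
        w = weights.ravel()
    else:
        w = None

    n_bins = int(np.floor(r_max / bin_width + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dists.ravel(), bins=edges, weights=w)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = n_partner / box**3
    g = counts / (traj.n_frames * shell_vol * rho)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDF(
        r_centers=centers,
        g=g,
        bin_width=bin_width,
        pair_kind=pair_kind,
        n_frames=traj.n_frames,
        mean_density=rho,
    )


def first_minimum(rdf: RDF, search_window: tuple[float, float]) -> float:
    """Abscissa of the first-shell minimum of a 5-bin-smoothed copy of g(r)
    inside ``search_window``; ties resolve to the smallest r."""
    s = smooth5(rdf.g)
    lo, hi = search_window
    idx = np.nonzero((rdf.r_centers >= lo) & (rdf.r_centers <= hi))[0]
    idx = idx[(idx > 0) & (idx < len(s) - 1)]
    if idx.size == 0:
        raise NoMinimumError("search window contains no interior bins")
    is_min = (
        (s[idx] <= s[idx - 1])
        & (s[idx] <= s[idx + 1])
        & ((s[idx] < s[idx - 1]) | (s[idx] < s[idx + 1]))
    )
    cand = idx[is_min]
    if cand.size == 0:
        raise NoMinimumError("no local minimum of g(r) inside the window")
    best = cand[np.argmin(s[cand])]
    # ties -> smallest r
    tied = cand[s[cand] == s[best]]
    return float(rdf.r_centers[tied.min()])


def coordination_number(
    traj: Trajectory, r_cut: float, weights: np.ndarray | None = None
) -> float:
    """Time-average count of O atoms with ion–O distance < r_cut."""
    if r_cut > traj.box_edge / 2.0:
        raise ContractError("r_cut exceeds box_edge/2")
    dists = ion_partner_distances(traj, "XO")
    inside = (dists < r_cut).astype(float)
    if weights is not None:
        inside = inside * np.asarray(weights, dtype=float)
    return float(inside.sum(axis=1).mean())


def coordination_number_from_rdf(rdf: RDF, r_cut: float) -> float:
    """Running coordination number by integrating g(r)·4πr²ρ up to r_cut."""
    mask = rdf.r_centers < r_cut
    r = rdf.r_centers[mask]
    integrand = rdf.g[mask] * 4.0 * np.pi * r**2 * rdf.mean_density
    return float(np.sum(integrand) * rdf.bin_width)
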