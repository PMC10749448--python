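"""The lone-pair hydrogen-bond descriptor η.

η is an angle-weighted lone-pair–hydrogen distance,

    η = r^LP-H / ( cos(α/2) · cos(β/2) ),

where r^LP-H is the distance between an ion lone pair and a water
hydrogen, α is the angle at the ion between the ion→lone-pair and ion→H
directions (how well the lone pair points at the hydrogen), and β is the
angle at the hydrogen between the O→H bond direction and the H→lone-pair
direction (how well the O–H vector points at the lone pair).  For the
ideal linear hydrogen bond α = β = 0 and η equals the bare lone-pair–H
distance; each angular weight grows monotonically as the geometry bends,
diverging as an angle approaches 180°.  Lower η therefore means a
stronger, more linear ion–water hydrogen bond, and η correlates linearly
with the ion–water pair interaction energy.

The per-water descriptor η_ij is the minimum over the 4 × 2 (lone pair,
hydrogen) combinations — the strongest available contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import (
    ContractError,
    DomainError,
    Frame,
    NoIntersectionError,
    PairGeometry,
    Trajectory,
    angle_between,
    minimum_image,
    smooth5,
)

__all__ = [
    "EtaDistribution",
    "eta_value",
    "pair_geometry",
    "eta_ion_water",
    "eta_series",
    "eta_distribution",
    "eta_cutoff_from_intersection",
    "eta_peak",
]

DEFAULT_BIN_WIDTH = 0.02   # A
DEFAULT_ETA_RANGE = (0.0, 8.0)  # A, histogram support for distributions


def eta_value(r_lp_h, alpha, beta):
    """Evaluate η (Å) from the lone-pair–H distance and the two angles (deg).

    Accepts scalars or arrays.  Angles must lie in [0, 180]; values outside
    raise rather than being clamped.  At exactly 180° the weight diverges
    and η is +inf.
    """
    r = np.asarray(r_lp_h, dtype=float)
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    if np.any(r <= 0):
        raise DomainError("r_lp_h must be positive")
    if np.any((a < 0) | (a > 180) | (b < 0) | (b > 180)):
        raise DomainError("alpha and beta must lie in [0, 180] degrees")
    with np.errstate(divide="ignore"):
        out = r / (np.cos(np.radians(a) / 2.0) * np.cos(np.radians(b) / 2.0))
    if out.ndim == 0:
        return float(out)
    return out


def pair_geometry(frame: Frame, water_id: int, lp_index: int, h_index: int) -> PairGeometry:
    """Full hydrogen-bond geometry of one (lone pair, hydrogen) contact.

    All interparticle vectors use the minimum image.  Conventions: the
    ideal linear bond (H on the ion→LP axis beyond the LP, O–H pointing at
    the LP) gives α = β = 0.
    """
    if not (0 <= lp_index < 4) or h_index not in (0, 1):
        raise ContractError(f"invalid lp_index={lp_index} or h_index={h_index}")
    w = frame.water_index(water_id)
    box = frame.box_edge
    h = frame.h1_xyz[w] if h_index == 0 else frame.h2_xyz[w]
    o = frame.o_xyz[w]
    lp = frame.lp_xyz[lp_index]

    ion_to_lp = minimum_image(lp - frame.ion_xyz, box)
    ion_to_h = minimum_image(h - frame.ion_xyz, box)
    o_to_h = minimum_image(h - o, box)
    h_to_lp = minimum_image(lp - h, box)

    alpha = angle_between(ion_to_lp, ion_to_h)
    beta = angle_between(o_to_h, h_to_lp)
    r_lp_h = float(np.linalg.norm(h_to_lp))
    return PairGeometry(
        water_id=water_id,
        lp_index=lp_index,
        h_index=h_index,
        r_lp_h=r_lp_h,
        alpha=alpha,
        beta=beta,
        eta=eta_value(r_lp_h, alpha, beta),
        r_xo=float(np.linalg.norm(minimum_image(o - frame.ion_xyz, box))),
        r_xh=float(np.linalg.norm(ion_to_h)),
    )


def eta_ion_water(frame: Frame, water_id: int) -> PairGeometry:
    """The ion–water descriptor η_ij: the minimum-η contact over all 8
    (lone pair, hydrogen) combinations; ties resolve to the lowest
    (lp_index, h_index) lexicographically."""
    best: PairGeometry | None = None
    for lp_index in range(4):
        for h_index in range(2):
            pg = pair_geometry(frame, water_id, lp_index, h_index)
            if best is None or pg.eta < best.eta:
                best = pg
    assert best is not None
    return best


def eta_series(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized η_ij and ion–O distances for every (frame, water).

    Returns ``(etas, r_xo)``, both (n_frames, n_waters).
    """
    box = traj.box_edge
    etas = []
    rxos = []
    for frame in traj.frames:
        v_lp = minimum_image(frame.lp_xyz - frame.ion_xyz, box)        # (4,3)
        h = np.stack([frame.h1_xyz, frame.h2_xyz], axis=1)             # (n,2,3)
        v_h = minimum_image(h - frame.ion_xyz, box)                    # (n,2,3)
        oh = minimum_image(h - frame.o_xyz[:, None, :], box)           # (n,2,3)
        hlp = minimum_image(frame.lp_xyz[None, None] - h[:, :, None], box)  # (n,2,4,3)

        r_lph = np.linalg.norm(hlp, axis=-1)                           # (n,2,4)
        cos_a = np.einsum("nhx,lx->nhl", v_h, v_lp)
        cos_a /= np.linalg.norm(v_h, axis=-1)[:, :, None]
        cos_a /= np.linalg.norm(v_lp, axis=-1)[None, None, :]
        cos_b = np.einsum("nhx,nhlx->nhl", oh, hlp)
        cos_b /= np.linalg.norm(oh, axis=-1)[:, :, None]
        cos_b /= np.where(r_lph > 0, r_lph, np.inf)
        a = np.arccos(np.clip(cos_a, -1.0, 1.0))
        b = np.arccos(np.clip(cos_b, -1.0, 1.0))
        with np.errstate(divide="ignore"):
            e = r_lph / (np.cos(a / 2.0) * np.cos(b / 2.0))
        etas.append(e.min(axis=(1, 2)))
        rxos.append(
            np.linalg.norm(minimum_image(frame.o_xyz - frame.ion_xyz, box), axis=1)
        )
    return np.array(etas), np.array(rxos)


@dataclass
class EtaDistribution:
    """Normalized histogram of η_ij values (∫ p dη = 1 over the binned range)."""

    eta_centers: np.ndarray
    p: np.ndarray
    selection: str
    bin_width: float
    n_samples: int


def _rank_mask(r_xo: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Mask selecting, per frame, the lo-th..hi-th closest waters (1-based)."""
    order = np.argsort(r_xo, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(r_xo.shape[0])[:, None]
    ranks[rows, order] = np.arange(r_xo.shape[1])[None, :]
    return (ranks >= lo - 1) & (ranks <= hi - 1)


def eta_distribution(
    traj: Trajectory,
    selection="all",
    bin_width: float = DEFAULT_BIN_WIDTH,
    eta_range: tuple[float, float] = DEFAULT_ETA_RANGE,
) -> EtaDistribution:
    """P(η) over frames × selected waters.

    ``selection`` is one of ``"all"``, ``"rank14"`` (four closest waters by
    ion–O distance, per frame), ``"rank57"`` (5th–7th closest), or a custom
    boolean mask of shape (n_frames, n_waters).
    """
    etas, r_xo = eta_series(traj)
    if isinstance(selection, str):
        if selection == "all":
            mask = np.ones_like(etas, dtype=bool)
        elif selection == "rank14":
            mask = _rank_mask(r_xo, 1, 4)
        elif selection == "rank57":
            if r_xo.shape[1] < 7:
                raise ContractError("rank57 selection needs at least 7 waters")
            mask = _rank_mask(r_xo, 5, 7)
        else:
            raise ContractError(f"unknown selection {selection!r}")
        tag = selection
    else:
        mask = np.asarray(selection, dtype=bool)
        if mask.shape != etas.shape:
            raise ContractError("custom mask not aligned with trajectory")
        tag = "custom"
    samples = etas[mask]
    if samples.size == 0:
        raise ContractError("empty selection")

    lo, hi = eta_range
    n_bins = int(np.round((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(samples, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ContractError("no η samples fall inside eta_range")
    p = counts / (total * bin_width)
    return EtaDistribution(
        eta_centers=0.5 * (edges[1:] + edges[:-1]),
        p=p,
        selection=tag,
        bin_width=bin_width,
        n_samples=int(samples.size),
    )


def eta_cutoff_from_intersection(d14: EtaDistribution, d57: EtaDistribution) -> float:
    """η cutoff: where the 1st–4th and 5th–7th rank distributions cross.

    After 5-bin smoothing, the smallest η in the overlap region at which
    (P_1-4 − P_5-7) changes sign from positive to negative, linearly
    interpolated between the bracketing bin centers.
    """
    if d14.bin_width != d57.bin_width:
        raise ContractError("distributions must share a bin width")
    x = d14.eta_centers
    p57 = np.interp(x, d57.eta_centers, d57.p, left=0.0, right=0.0)
    s14 = smooth5(d14.p)
    s57 = smooth5(p57)
    support = np.nonzero((s14 > 0) & (s57 > 0))[0]
    if support.size == 0:
        raise NoIntersectionError("distributions have no common support")
    lo, hi = support.min(), support.max()
    diff = s14 - s57
    for i in range(lo, hi):
        if diff[i] > 0 and diff[i + 1] < 0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    raise NoIntersectionError(
        "no positive-to-negative crossing of the rank distributions"
    )


def eta_peak(dist: EtaDistribution) -> float:
    """Abscissa of the global maximum of the 5-bin-smoothed P(η); ties
    resolve to the smallest η."""
    if dist.p.size == 0:
        raise ContractError("empty distribution")
    s = smooth5(dist.p)
    tied = np.nonzero(s == s.max())[0]
    # smoothing flattens an isolated spike into a plateau: prefer the raw
    # maximum among tied smoothed bins, then the smallest η
    best = tied[np.argmax(dist.p[tied])]
    return float(dist.eta_centers[int(best)])
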