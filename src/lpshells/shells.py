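"""Tight / loose / bulk classification of waters and derived statistics.

The conventional first shell (ion–O distance below the first g(r)
minimum, r_cut) is split by the η descriptor: waters with η below the η
cutoff form the *tight* shell regardless of distance — strongly
hydrogen-bonded molecules slightly beyond r_cut still belong to it —
while the remaining waters inside r_cut form the *loose* shell and
everything else is bulk.  Both cutoffs use strict ``<`` with ties going
to the outer region.

Loose waters that point both hydrogens away from the ion (each O–H more
than 90° from the O→ion direction) are additionally flagged as
misoriented: they sit fortuitously inside the distance cutoff but are
oriented like second-shell molecules.  They stay labeled loose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import ContractError, Frame, Trajectory, minimum_image
from .eta import eta_series
from .rdf import RDF, ShellCutoffs, compute_rdf

__all__ = [
    "ShellLabels",
    "CNDistribution",
    "classify",
    "cn_distribution",
    "flag_misoriented",
    "decomposed_rdf",
]


@dataclass
class ShellLabels:
    """Per-frame, per-water region assignment plus the quantities behind it."""

    region: np.ndarray        # (n_frames, n_waters), 'T'/'L'/'B'
    eta: np.ndarray           # (n_frames, n_waters)
    r_xo: np.ndarray          # (n_frames, n_waters)
    misoriented: np.ndarray   # (n_frames, n_waters) bool; meaningful inside r_cut
    water_ids: np.ndarray     # (n_waters,)
    cutoffs: ShellCutoffs
    dt: float                 # ps

    @property
    def n_frames(self) -> int:
        return self.region.shape[0]

    @property
    def t_sim(self) -> float:
        return (self.n_frames - 1) * self.dt

    def occupancy(self, region: str) -> float:
        """Time-averaged number of waters in a region (n̄)."""
        return float((self.region == region).sum(axis=1).mean())


def _misoriented_mask(frame: Frame) -> np.ndarray:
    """True where both O–H bonds point more than 90° away from the ion."""
    box = frame.box_edge
    to_ion = minimum_image(frame.ion_xyz - frame.o_xyz, box)
    d1 = np.einsum("ij,ij->i", minimum_image(frame.h1_xyz - frame.o_xyz, box), to_ion)
    d2 = np.einsum("ij,ij->i", minimum_image(frame.h2_xyz - frame.o_xyz, box), to_ion)
    return (d1 < 0) & (d2 < 0)


def classify(traj: Trajectory, cutoffs: ShellCutoffs) -> ShellLabels:
    """Assign every water in every frame to tight, loose or bulk."""
    etas, r_xo = eta_series(traj)
    region = np.where(
        etas < cutoffs.eta_cut, "T", np.where(r_xo < cutoffs.r_cut, "L", "B")
    ).astype("U1")
    mis = np.array([_misoriented_mask(f) for f in traj.frames])
    mis &= r_xo < cutoffs.r_cut
    return ShellLabels(
        region=region,
        eta=etas,
        r_xo=r_xo,
        misoriented=mis,
        water_ids=traj.frames[0].water_ids.copy(),
        cutoffs=cutoffs,
        dt=traj.dt,
    )


@dataclass
class CNDistribution:
    """Probability of each instantaneous coordination number of a region."""

    probabilities: dict[int, float]
    region: str

    @property
    def mode(self) -> int:
        best = max(self.probabilities.items(), key=lambda kv: (kv[1], -kv[0]))
        return best[0]

    def probability(self, n: int) -> float:
        return self.probabilities.get(n, 0.0)


def cn_distribution(labels: ShellLabels, region: str = "T") -> CNDistribution:
    """Normalized histogram of the per-frame occupancy of a region."""
    if labels.region.size == 0:
        raise ContractError("empty labels")
    counts = (labels.region == region).sum(axis=1)
    values, freq = np.unique(counts, return_counts=True)
    probs = {int(v): float(f) / labels.n_frames for v, f in zip(values, freq)}
    return CNDistribution(probabilities=probs, region=region)


def flag_misoriented(frame: Frame, water_id: int, r_cut: float) -> bool:
    """True iff both hydrogens of the water sit in the hemisphere away from
    the ion (angle at O between O→H and O→ion exceeding 90° for both)."""
    w = frame.water_index(water_id)
    box = frame.box_edge
    d = np.linalg.norm(minimum_image(frame.o_xyz[w] - frame.ion_xyz, box))
    if d >= r_cut:
        raise ContractError(
            f"water {water_id} at r_xo = {d:.3f} A is outside r_cut = {r_cut} A"
        )
    return bool(_misoriented_mask(frame)[w])


def decomposed_rdf(
    traj: Trajectory,
    labels: ShellLabels,
    bin_width: float = 0.02,
    r_max: float | None = None,
) -> tuple[RDF, RDF]:
    """Split the ion–O g(r) into tight-shell and loose+bulk components.

    Both components keep the whole-box normalization, so they sum
    bin-by-bin to the total X–O g(r).
    """
    if labels.region.shape[0] != traj.n_frames:
        raise ContractError("labels not aligned with trajectory")
    tight_mask = (labels.region == "T").astype(float)
    g_tight = compute_rdf(traj, "XO", bin_width, r_max, weights=tight_mask)
    g_rest = compute_rdf(traj, "XO", bin_width, r_max, weights=1.0 - tight_mask)
    return g_tight, g_rest
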