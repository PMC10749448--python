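"""Linear calibration between η and the ion–water interaction energy.

Pair interaction energies (magnitudes, kJ/mol) computed for isolated
ion–water dimers correlate linearly with η; an ordinary least-squares fit
of E against η then converts η values — e.g. the peak positions of P(η)
— into estimated interaction energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_geometry import ContractError, SingularFitError

__all__ = ["EnergyFit", "fit_eta_energy", "eta_to_energy"]


@dataclass(frozen=True)
class EnergyFit:
    slope: float        # kJ/mol per A
    intercept: float    # kJ/mol
    r_squared: float
    rmse: float         # kJ/mol
    n_points: int


def fit_eta_energy(pairs) -> EnergyFit:
    """Ordinary least squares of energy on η.

    ``pairs`` is an iterable of (η, E) tuples or an (n, 2) array.
    r² = 1 − SS_res/SS_tot; rmse = sqrt(SS_res/n).
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ContractError("pairs must be (η, E) tuples")
    if arr.shape[0] < 3:
        raise ContractError("need at least 3 points to fit")
    eta, energy = arr[:, 0], arr[:, 1]
    if np.ptp(eta) == 0.0:
        raise SingularFitError("all η values identical; slope is undefined")
    res = stats.linregress(eta, energy)
    pred = res.slope * eta + res.intercept
    ss_res = float(np.sum((energy - pred) ** 2))
    ss_tot = float(np.sum((energy - energy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return EnergyFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        rmse=float(np.sqrt(ss_res / arr.shape[0])),
        n_points=int(arr.shape[0]),
    )


def eta_to_energy(eta, fit: EnergyFit):
    """Convert η (Å, scalar or array) to estimated interaction energy (kJ/mol)."""
    return fit.slope * np.asarray(eta, dtype=float) + fit.intercept
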