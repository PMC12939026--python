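"""Membrane process bookkeeping: flux, VRR, transmission/rejection,
permeance coefficients and the resistance-in-series partition.

Internal units are SI (m s^-1, Pa, Pa s); the customary L h^-1 m^-2 flux
unit is accepted at the boundaries and converted explicitly
(1 L h^-1 m^-2 = 2.7778e-7 m s^-1).

The resistance partition uses four clean-water permeances measured at
successive stages of a run: Lp0 clean membrane, Lp1 after processing,
Lp2 after physical cleaning, Lp3 after chemical cleaning.  Differences
of reciprocal permeances split the total resistance into membrane (R_M),
concentration-polarization (R_C), reversible (R_R) and irreversible
(R_I) contributions, with fouling resistance R_F = R_R + R_I and the
telescoping identity R_M + R_C + R_R + R_I = 1/(mu_w * Lp1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "LHM_TO_MS",
    "FluxRecord",
    "SoluteConcPair",
    "PermeanceSet",
    "ResistancePartition",
    "permeate_flux",
    "vrr",
    "transmission",
    "rejection",
    "permeance",
    "resistance_partition",
    "dominant_resistance",
    "flux_decline_pct",
]

#: 1 L h^-1 m^-2 in m s^-1.
LHM_TO_MS = 1e-3 / 3600.0

#: Water viscosity default, Pa s.
MU_WATER = 1.0e-3


@dataclass(frozen=True)
class FluxRecord:
    """A permeate collection interval: volume (L), duration (h), area (m^2)."""

    t_h: float
    Vp_L: float
    Am_m2: float

    def __post_init__(self) -> None:
        if self.t_h <= 0 or self.Am_m2 <= 0 or self.Vp_L < 0:
            raise ValueError("time and area must be positive, volume non-negative")


def permeate_flux(record: FluxRecord) -> float:
    """Permeate flux J_p = V_p / (t * A_m) in L h^-1 m^-2."""
    return record.Vp_L / (record.t_h * record.Am_m2)


def vrr(V_F: float, V_R: float) -> float:
    """Volumetric retention ratio, feed volume over retentate volume."""
    if V_R <= 0:
        raise ValueError("retentate volume must be positive")
    return V_F / V_R


@dataclass(frozen=True)
class SoluteConcPair:
    """Permeate and feed solute concentrations (mg/L)."""

    C_P: float
    C_A: float

    def __post_init__(self) -> None:
        if self.C_A <= 0 or self.C_P < 0:
            raise ValueError("feed concentration must be positive, permeate non-negative")


def transmission(pair: SoluteConcPair) -> float:
    """Solute transmission T = 100 * C_P / C_A (%)."""
    return 100.0 * pair.C_P / pair.C_A


def rejection(pair: SoluteConcPair) -> float:
    """Solute rejection R = 100 * (1 - C_P / C_A) (%); T + R = 100."""
    return 100.0 * (1.0 - pair.C_P / pair.C_A)


def permeance(J_w_lhm: float, dP_Pa: float) -> float:
    """Hydraulic permeance Lp = J_w / dP in m Pa^-1 s^-1.

    ``J_w_lhm`` is a clean-water flux in L h^-1 m^-2; it is converted to
    m s^-1 before dividing by the transmembrane pressure in Pa.
    """
    if dP_Pa <= 0:
        raise ValueError("transmembrane pressure must be positive")
    return J_w_lhm * LHM_TO_MS / dP_Pa


@dataclass(frozen=True)
class PermeanceSet:
    """Stage permeances Lp0..Lp3 (m Pa^-1 s^-1) plus water viscosity."""

    Lp0: float
    Lp1: float
    Lp2: float
    Lp3: float
    mu_w: float = MU_WATER

    def __post_init__(self) -> None:
        for name in ("Lp0", "Lp1", "Lp2", "Lp3", "mu_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.Lp0 >= self.Lp3 >= self.Lp2 >= self.Lp1):
            warnings.warn(
                "permeances violate the expected staircase Lp0 >= Lp3 >= Lp2 >= Lp1",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ResistancePartition:
    """Resistance-in-series components (m^-1) and the fouling index (%)."""

    R_M: float
    R_C: float
    R_R: float
    R_I: float

    @property
    def R_F(self) -> float:
        return self.R_R + self.R_I

    @property
    def R_T(self) -> float:
        return self.R_M + self.R_C + self.R_F

    @property
    def components(self) -> dict[str, float]:
        return {"R_M": self.R_M, "R_C": self.R_C, "R_F": self.R_F}


def resistance_partition(p: PermeanceSet) -> tuple[ResistancePartition, float]:
    """Partition the total resistance and compute the fouling index.

    Returns ``(partition, FI)`` with FI = 100 * (1 - Lp1/Lp0) in percent.
    A negative FI (flux enhancement, Lp1 > Lp0) is physically anomalous
    and triggers a warning.
    """
    mu = p.mu_w
    R_M = 1.0 / (mu * p.Lp0)
    R_C = (1.0 / p.Lp1 - 1.0 / p.Lp2) / mu
    R_R = (1.0 / p.Lp2 - 1.0 / p.Lp3) / mu
    R_I = (1.0 / p.Lp3 - 1.0 / p.Lp0) / mu
    fi = 100.0 * (1.0 - p.Lp1 / p.Lp0)
    if fi < 0:
        warnings.warn("negative fouling index: permeance increased during the run")
    return ResistancePartition(R_M=R_M, R_C=R_C, R_R=R_R, R_I=R_I), fi


_TIE_ORDER = ("R_C", "R_F", "R_M")


def dominant_resistance(partition: ResistancePartition) -> list[tuple[str, float]]:
    """Rank (R_C, R_F, R_M) by decreasing magnitude; ties keep the fixed
    order R_C, R_F, R_M."""
    comp = partition.components
    return sorted(
        ((k, comp[k]) for k in _TIE_ORDER),
        key=lambda kv: (-kv[1], _TIE_ORDER.index(kv[0])),
    )


def flux_decline_pct(J0: float, J_end: float) -> float:
    """Relative in-run flux decline 100 * (1 - J_end/J0) (%).

    Distinct from the permeance-based fouling index: this compares fluxes
    within a single run and includes fully reversible polarization.
    """
    if J0 <= 0:
        raise ValueError("initial flux must be positive")
    return 100.0 * (1.0 - J_end / J0)
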