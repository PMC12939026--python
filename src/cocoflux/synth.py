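"""Synthetic-data generators mirroring the statistical structure of each
pipeline stage.

Every generator is a pure function of its spec plus seed.  Defaults
mirror the magnitudes of the pilot study (flux ~300-680 L h^-1 m^-2,
fouling index ~78-95%, replicate SD ~15 for flux) so that tolerance
choices transfer to the embedded dataset.  Noise models: Gaussian
additive for design responses (matching replicate-SD reporting),
lognormal multiplicative for flux decay (preserving positivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cocoflux.doe import (
    FCDDataset,
    FactorSpec,
    PRESSURE,
    TEMPERATURE,
    build_fcd,
)
from cocoflux.hermia import BlockingLaw, FluxSeries, simulate_decay
from cocoflux.membrane import PermeanceSet
from cocoflux.rsm import _columns

__all__ = [
    "FCDGenSpec",
    "DecayGenSpec",
    "epsilon_for_decline",
    "gen_fcd_dataset",
    "gen_flux_series",
    "gen_permeances",
]

#: Reduced-model flux coefficients refit from the pilot design, used as a
#: realistic default truth (term order 1, x1, x2, x1^2, x2^2, x1:x2).
PILOT_FLUX_BETA = (660.59, 0.0, 79.86, -110.48, -141.86, 19.35)
PILOT_FI_BETA = (85.31, 5.81, 0.0, 0.0, 3.72, 0.75)


@dataclass
class FCDGenSpec:
    """Generator spec for a two-factor FCD with replicate noise."""

    beta: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"flux": PILOT_FLUX_BETA, "fouling_index": PILOT_FI_BETA}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"flux": 15.0, "fouling_index": 1.0}
    )
    replicates: tuple[int, int] = (3, 5)
    factors: tuple[FactorSpec, FactorSpec] = (PRESSURE, TEMPERATURE)
    seed: int = 0


def gen_fcd_dataset(spec: FCDGenSpec) -> FCDDataset:
    """Simulate an FCD dataset: polynomial truth plus Gaussian replicate noise."""
    rng = np.random.default_rng(spec.seed)
    ds = build_fcd(spec.factors, response_names=list(spec.beta), replicates=spec.replicates)
    for cond in ds.conditions:
        n_rep = cond.metadata["planned_replicates"]
        x = np.asarray(cond.coded, dtype=float).reshape(1, 2)
        for resp, beta in spec.beta.items():
            mean = float(_columns(x)[0] @ np.asarray(beta, dtype=float))
            sd = spec.noise_sd.get(resp, 0.0)
            vals = mean + sd * rng.standard_normal(n_rep) if sd > 0 else np.full(n_rep, mean)
            cond.replicate_responses[resp] = vals.tolist()
    return ds


def epsilon_for_decline(
    law: BlockingLaw, J0: float, duration_h: float, decline_frac: float
) -> float:
    """Decay constant giving a prescribed relative flux decline.

    Inverts the closed-form decay so that J(duration)/J0 = 1 - decline_frac.
    Used for the generator default (the pilot run lost about 91% of its
    initial flux over 2 h).
    """
    if not (0.0 < decline_frac < 1.0):
        raise ValueError("decline fraction must lie in (0, 1)")
    frac = 1.0 - decline_frac
    if law is BlockingLaw.COMPLETE:
        return float(-np.log(frac) / duration_h)
    if law is BlockingLaw.STANDARD:
        return float((frac**-0.5 - 1.0) * J0**-0.5 / duration_h)
    if law is BlockingLaw.INTERMEDIATE:
        return float((1.0 / frac - 1.0) / (J0 * duration_h))
    return float((frac**-2.0 - 1.0) * J0**-2.0 / duration_h)


@dataclass
class DecayGenSpec:
    """Generator spec for a Hermia-type flux-decline series.

    Default sampling is every 2 minutes over a 2 h run (61 points), the
    acquisition cadence of the pilot rig; the default decay constant
    reproduces the pilot's ~91% in-run flux decline under the
    intermediate law.
    """

    law: BlockingLaw = BlockingLaw.INTERMEDIATE
    J0: float = 600.0
    epsilon: float = epsilon_for_decline(BlockingLaw.INTERMEDIATE, 600.0, 2.0, 0.91)
    duration_h: float = 2.0
    interval_h: float = 2.0 / 60.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.J0, self.duration_h, self.interval_h) <= 0 or self.epsilon < 0:
            raise ValueError("decay spec parameters must be positive")


def gen_flux_series(spec: DecayGenSpec) -> FluxSeries:
    """Closed-form decay times lognormal multiplicative noise.

    The first point equals J0 exactly (noise applies from the second
    sample on) so that round-trip fits recover the initial flux.
    """
    n = int(round(spec.duration_h / spec.interval_h)) + 1
    times = np.arange(n) * spec.interval_h
    clean = simulate_decay(spec.law, spec.J0, spec.epsilon, times)
    J = clean.fluxes.copy()
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
        factors[0] = 1.0
        J = J * factors
    return FluxSeries(times=times, fluxes=J)


def gen_permeances(
    shares: dict[str, float],
    Lp0: float = 1.0e-9,
    rr_fraction: float = 0.5,
    mu_w: float = 1.0e-3,
    seed: int | None = None,
) -> PermeanceSet:
    """Construct a permeance staircase realizing requested resistance shares.

    ``shares`` gives the fractions of the total resistance attributed to
    R_M, R_C and R_F (they must be positive-or-zero and sum to 1, with
    R_M > 0 since the membrane always resists); ``rr_fraction`` splits
    R_F between its reversible and irreversible parts.  The construction
    inverts the telescoping identity exactly, so recomputing the
    partition from the generated set returns the shares to machine
    precision.  Deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    s_m = shares.get("R_M", 0.0)
    s_c = shares.get("R_C", 0.0)
    s_f = shares.get("R_F", 0.0)
    if min(s_m, s_c, s_f) < 0 or abs(s_m + s_c + s_f - 1.0) > 1e-9:
        raise ValueError("shares must be non-negative and sum to 1")
    if s_m <= 0:
        raise ValueError("membrane share R_M must be positive")
    if not (0.0 <= rr_fraction <= 1.0):
        raise ValueError("rr_fraction must lie in [0, 1]")
    R_M = 1.0 / (mu_w * Lp0)
    R_T = R_M / s_m
    inv = lambda resist: 1.0 / (mu_w * resist)  # noqa: E731
    Lp1 = inv(R_T)
    Lp2 = inv((s_m + s_f) * R_T) if (s_m + s_f) > 0 else Lp0
    Lp3 = inv((s_m + (1.0 - rr_fraction) * s_f) * R_T)
    return PermeanceSet(Lp0=Lp0, Lp1=Lp1, Lp2=Lp2, Lp3=Lp3, mu_w=mu_w)
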