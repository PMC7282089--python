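"""Synthetic fermentation runs with known ground truth.

The batch generator emulates the qualitative structure of pH-controlled,
sparged bioreactor runs of a thermophilic succinate producer: exponential
growth at a fixed specific rate until an OD ceiling (or glucose exhaustion)
triggers growth arrest, a slow post-stationary OD decline (10% per day),
glucose consumption coupled to biomass formation during growth plus a
reduced maintenance drain afterwards, and products accumulating in
proportion to cumulative glucose consumption at fixed molar yields. Lactate
can optionally start only at the growth-arrest transition, as observed in
such runs; its endpoint still satisfies lactate = yield x total consumed
glucose so that whole-run yield estimates recover the ground truth exactly.

Measurement noise is multiplicative Gaussian (HPLC-like, default CV 2%,
truncated at -90% to keep observations positive), applied independently per
measurement to OD and every concentration. All randomness flows through
``numpy.random.default_rng`` (PCG64), so a scenario with a fixed seed
reproduces bit-identically across platforms.

Reference yield sets
--------------------
``BATCH_YIELDS_LOW_CO2`` and ``BATCH_YIELDS_HIGH_CO2`` hold the reported
whole-run molar yields of *P. thermosuccinogenes* batch fermentations
sparged with 1% and 20% CO2 (v/v in N2) respectively; they parameterize the
default condition pair and serve as the reference input for the cofactor
analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .yield_pipeline import ConditionMeta, TimeSeries

__all__ = [
    "BATCH_YIELDS_LOW_CO2",
    "BATCH_YIELDS_HIGH_CO2",
    "SyntheticScenario",
    "simulate_batch",
    "simulate_chemostat",
    "make_condition_pair",
]

#: Molar yields (mol per mol glucose) at 1% CO2 sparge (CO2 limitation).
BATCH_YIELDS_LOW_CO2 = {
    "succinate": 0.47,
    "acetate": 0.56,
    "formate": 0.17,
    "lactate": 0.34,
    "ethanol": 0.23,
}

#: Molar yields at 20% CO2 sparge (CO2 replete).
BATCH_YIELDS_HIGH_CO2 = {
    "succinate": 0.64,
    "acetate": 0.69,
    "formate": 0.53,
    "lactate": 0.29,
    "ethanol": 0.05,
}

# Post-arrest maintenance glucose drain, as a fraction of the volumetric
# consumption rate at the moment of arrest.
_MAINTENANCE_FRACTION = 0.2
# Post-stationary OD decline: 10% per day.
_OD_DECAY_PER_DAY = 0.10


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters of one simulated fermentation.

    Defaults describe a CO2-limited batch: mu = 0.15 1/h, 25 g/l glucose
    (139 mM), OD ceiling 4.0, 22 mM glucose consumed per OD unit formed,
    lactate onset at the stationary transition, 2% measurement CV, 12
    samples over 48 h, sparged at 1 l/h in a 0.5 l working volume.
    """

    mu: float = 0.15  # 1/h
    od0: float = 0.05
    glucose0: float = 139.0  # mM (25 g/l)
    yields: dict[str, float] = field(
        default_factory=lambda: dict(BATCH_YIELDS_LOW_CO2)
    )
    biomass_glucose_coupling: float = 22.0  # mM glucose per OD unit
    stationary_od: float = 4.0
    lactate_onset: str = "at_stationary"  # or "with_growth"
    noise_cv: float = 0.02
    sample_times: np.ndarray | None = None  # default: 12 points over 48 h
    seed: int = 0
    label: str = "synthetic"
    co2_fraction: float | None = None
    gas_flow_l_per_h: float = 1.0
    working_volume_l: float = 0.5

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.glucose0 <= 0:
            raise ValueError("glucose0 must be > 0")
        if self.od0 <= 0 or self.stationary_od <= self.od0:
            raise ValueError("need 0 < od0 < stationary_od")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.biomass_glucose_coupling <= 0:
            raise ValueError("biomass_glucose_coupling must be > 0")
        if self.lactate_onset not in ("with_growth", "at_stationary"):
            raise ValueError(f"unknown lactate_onset {self.lactate_onset!r}")
        if any(v < 0 for v in self.yields.values()):
            raise ValueError("yields must be >= 0")
        accounted = 3.0 * sum(
            self.yields.get(p, 0.0)
            for p in ("succinate", "acetate", "lactate", "ethanol")
        )
        if accounted > 6.0 + 1e-9:
            raise ValueError(f"infeasible yields: {accounted:.3f} C-mol > 6")

    def times(self) -> np.ndarray:
        if self.sample_times is not None:
            return np.asarray(self.sample_times, dtype=float)
        return np.linspace(0.0, 48.0, 12)

    def meta(self, **extras) -> ConditionMeta:
        return ConditionMeta(
            label=self.label,
            co2_fraction=self.co2_fraction,
            gas_flow_l_per_h=self.gas_flow_l_per_h,
            working_volume_l=self.working_volume_l,
            **extras,
        )


def _noisy(rng: np.random.Generator, true: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative Gaussian noise, truncated at -90%."""
    if cv == 0:
        return true.copy()
    eps = np.clip(rng.normal(0.0, cv, size=true.shape), -0.9, None)
    return true * (1.0 + eps)


def _batch_truth(
    scenario: SyntheticScenario, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Noise-free OD, glucose and product trajectories at the sample times."""
    s = scenario
    c = s.biomass_glucose_coupling
    # arrest when OD hits the ceiling or glucose would run out mid-growth
    t_od = math.log(s.stationary_od / s.od0) / s.mu
    t_glc = math.log(1.0 + s.glucose0 / (c * s.od0)) / s.mu
    t_arrest = min(t_od, t_glc)
    od_arrest = s.od0 * math.exp(s.mu * t_arrest)
    consumed_arrest = min(c * (od_arrest - s.od0), s.glucose0)
    maintenance_rate = _MAINTENANCE_FRACTION * c * s.mu * od_arrest  # mM/h

    growing = t <= t_arrest
    od = np.where(
        growing,
        s.od0 * np.exp(s.mu * t),
        od_arrest * (1.0 - _OD_DECAY_PER_DAY) ** ((t - t_arrest) / 24.0),
    )
    consumed = np.where(
        growing,
        c * (s.od0 * np.exp(s.mu * t) - s.od0),
        consumed_arrest + maintenance_rate * (t - t_arrest),
    )
    consumed = np.minimum(consumed, s.glucose0)
    glucose = s.glucose0 - consumed

    products: dict[str, np.ndarray] = {}
    consumed_end = consumed[-1]
    for p, y in s.yields.items():
        if p == "lactate" and s.lactate_onset == "at_stationary":
            post = consumed_end - consumed_arrest
            if post <= 0:
                if y > 0:
                    warnings.warn(
                        "no post-arrest glucose consumption; stationary-phase "
                        "lactate cannot form and stays 0"
                    )
                products[p] = np.zeros_like(t)
            else:
                ramp = np.clip((consumed - consumed_arrest) / post, 0.0, 1.0)
                products[p] = y * consumed_end * ramp
        else:
            products[p] = y * consumed
    return od, glucose, products


def simulate_batch(scenario: SyntheticScenario) -> TimeSeries:
    """Simulate one batch run of the scenario (deterministic under its seed)."""
    t = scenario.times()
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("sample_times must be >= 2 strictly increasing points")
    od, glucose, products = _batch_truth(scenario, t)
    rng = np.random.default_rng(scenario.seed)
    cv = scenario.noise_cv
    conc = {"glucose": _noisy(rng, glucose, cv)}
    for p in sorted(products):  # fixed draw order for reproducibility
        conc[p] = _noisy(rng, products[p], cv)
    return TimeSeries(
        mode="batch",
        times=t,
        conc=conc,
        od600=_noisy(rng, od, cv),
        meta=scenario.meta(),
    )


def simulate_chemostat(
    scenario: SyntheticScenario,
    dilution_rates: list[float],
    ks_mM: float = 0.3,
    n_samples: int = 3,
) -> list[TimeSeries]:
    """Steady states of a glucose-limited chemostat at stepped dilution rates.

    Rates must be strictly descending (the step-down operating protocol) and
    below mu; a rate at or above mu washes the culture out. Residual glucose
    follows the Monod relation S = Ks * D / (mu - D), capped just below the
    feed (with a warning) when D approaches mu, where the yield estimate
    becomes ill-conditioned. Each steady state yields ``n_samples`` replicate
    samples taken at 3, 4, 5, ... hydraulic retention times.
    """
    if any(b >= a for a, b in zip(dilution_rates, dilution_rates[1:])):
        raise ValueError("dilution rates must be strictly descending")
    feed = scenario.glucose0
    rng = np.random.default_rng(scenario.seed)
    runs: list[TimeSeries] = []
    for D in dilution_rates:
        if D <= 0:
            raise ValueError("dilution rates must be > 0")
        if D >= scenario.mu:
            raise ValueError(
                f"dilution rate {D:g} 1/h >= mu {scenario.mu:g} 1/h: washout"
            )
        residual = ks_mM * D / (scenario.mu - D)
        if residual > 0.95 * feed:
            warnings.warn(
                f"D = {D:g} 1/h leaves residual glucose near the feed value; "
                "yield estimates will be ill-conditioned"
            )
            residual = 0.95 * feed
        consumed = feed - residual
        times = (3.0 + np.arange(n_samples)) / D
        cv = scenario.noise_cv
        conc = {
            "glucose": _noisy(rng, np.full(n_samples, residual), cv),
        }
        for p in sorted(scenario.yields):
            true = np.full(n_samples, scenario.yields[p] * consumed)
            conc[p] = _noisy(rng, true, cv)
        runs.append(
            TimeSeries(
                mode="chemostat",
                times=times,
                conc=conc,
                meta=scenario.meta(
                    feed_glucose_mM=feed, dilution_rate_per_h=D
                ),
            )
        )
    return runs


def make_condition_pair(
    seed: int = 0,
) -> tuple[SyntheticScenario, SyntheticScenario]:
    """The default study pair: (CO2-replete 20%-like, CO2-limited 1%-like).

    Yield parameters are the reported whole-run values of the two sparge
    conditions; the CO2-replete culture grows at 0.33 1/h (the reported
    batch rate) and the CO2-limited one at 0.15 1/h, i.e. more than two-fold
    slower, matching the reported growth-rate reduction.
    """
    high = SyntheticScenario(
        mu=0.33,
        yields=dict(BATCH_YIELDS_HIGH_CO2),
        label="20% CO2",
        co2_fraction=0.20,
        seed=seed,
    )
    low = SyntheticScenario(
        mu=0.15,
        yields=dict(BATCH_YIELDS_LOW_CO2),
        label="1% CO2",
        co2_fraction=0.01,
        seed=seed + 1,
    )
    return high, low
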