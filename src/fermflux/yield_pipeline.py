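"""Yields, growth rates and the glucose C-mole balance from fermentation data.

Batch runs are reduced to one molar yield per product (mol formed per mol
glucose consumed) over a window of the time course; chemostat records are
reduced per steady state with replicate averaging. The carbon balance follows
the C-mole rule of the study design: glucose counts 6 C-mol per mol, and each
of succinate, acetate, lactate and ethanol counts 3 (formate and fixed CO2
are folded into those coefficients), so at most 6 C-mol per mol glucose can
be accounted for by the four products.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .stoich_model import (
    EXCRETED_CARBON_PRODUCTS,
    MEASURED_PRODUCTS,
    PathwayModel,
    glucose_carbon_coefficients,
)

__all__ = [
    "ConditionMeta",
    "TimeSeries",
    "YieldProfile",
    "CarbonBalance",
    "estimate_yields_batch",
    "estimate_growth_rate",
    "estimate_yields_chemostat",
    "carbon_balance",
    "relative_yield_change",
]

GLUCOSE_CMOL = 6.0


@dataclass
class ConditionMeta:
    """Cultivation metadata attached to a run."""

    label: str = ""
    co2_fraction: float | None = None  # v/v fraction of CO2 in the sparge gas
    gas_flow_l_per_h: float | None = None
    working_volume_l: float | None = None
    feed_glucose_mM: float | None = None  # chemostat feed
    dilution_rate_per_h: float | None = None  # chemostat D
    extras: dict = field(default_factory=dict)


@dataclass
class TimeSeries:
    """One fermentation run: times in hours, concentrations in mM.

    ``conc`` maps species name (``glucose`` plus products) to an array over
    time points; NaN marks a missing measurement. In chemostat mode the rows
    are replicate samples of one steady state.
    """

    mode: str  # "batch" | "chemostat"
    times: np.ndarray
    conc: dict[str, np.ndarray]
    od600: np.ndarray | None = None
    dilution_factor: np.ndarray | None = None  # base-titration volume correction
    meta: ConditionMeta = field(default_factory=ConditionMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = {k: np.asarray(v, dtype=float) for k, v in self.conc.items()}
        if self.od600 is not None:
            self.od600 = np.asarray(self.od600, dtype=float)
        if self.mode not in ("batch", "chemostat"):
            raise ValueError(f"mode must be 'batch' or 'chemostat', got {self.mode!r}")
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if self.mode == "batch":
            if self.times.size < 2:
                raise ValueError("batch mode requires at least 2 time points")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
        for name, values in self.conc.items():
            if values.shape != self.times.shape:
                raise ValueError(f"concentration {name!r} length mismatch")
            if np.any(values[np.isfinite(values)] < 0):
                raise ValueError(f"negative concentration in {name!r}")
        if "glucose" not in self.conc:
            raise ValueError("a glucose concentration column is required")

    def corrected_conc(self) -> dict[str, np.ndarray]:
        """Concentrations with the dilution correction applied, if present."""
        if self.dilution_factor is None:
            return self.conc
        f = np.asarray(self.dilution_factor, dtype=float)
        return {k: v * f for k, v in self.conc.items()}


@dataclass
class YieldProfile:
    """Molar product yields of one run or steady state."""

    yields: dict[str, float]
    glucose_consumed: float  # mM over the evaluation window
    growth_rate: float | None = None  # 1/h
    yields_std: dict[str, float] | None = None  # replicate spread (chemostat)
    meta: ConditionMeta = field(default_factory=ConditionMeta)

    def __post_init__(self) -> None:
        if self.glucose_consumed <= 0:
            raise ValueError("glucose_consumed must be > 0")
        for p, y in self.yields.items():
            if y < 0:
                raise ValueError(f"negative yield for {p!r}: {y}")
        accounted = 3.0 * sum(
            self.yields.get(p, 0.0) for p in EXCRETED_CARBON_PRODUCTS
        )
        if accounted > GLUCOSE_CMOL + 1e-9:
            raise ValueError(
                f"infeasible yields: {accounted:.3f} C-mol accounted per mol "
                f"glucose exceeds {GLUCOSE_CMOL:.0f}"
            )

    def to_dict(self) -> dict:
        d = {
            "label": self.meta.label,
            "yields": dict(self.yields),
            "glucose_consumed_mM": self.glucose_consumed,
            "growth_rate_per_h": self.growth_rate,
        }
        if self.yields_std is not None:
            d["yields_std"] = dict(self.yields_std)
        meta = dataclasses.asdict(self.meta)
        meta.pop("label")
        d["meta"] = meta
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "YieldProfile":
        meta = ConditionMeta(label=d.get("label", ""), **dict(d.get("meta", {})))
        return cls(
            yields={k: float(v) for k, v in d["yields"].items()},
            glucose_consumed=float(d.get("glucose_consumed_mM", 1.0)),
            growth_rate=d.get("growth_rate_per_h"),
            yields_std=(
                {k: float(v) for k, v in d["yields_std"].items()}
                if d.get("yields_std")
                else None
            ),
            meta=meta,
        )


@dataclass(frozen=True)
class CarbonBalance:
    """Glucose carbon recovered in the four C-balanced products."""

    accounted_cmol: float  # C-mol per mol glucose
    accounted_fraction: float
    unaccounted_fraction: float

    def __post_init__(self) -> None:
        if abs(self.accounted_fraction + self.unaccounted_fraction - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")


def _window_indices(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.arange(times.size)
    t0, t1 = window
    idx = np.nonzero((times >= t0) & (times <= t1))[0]
    if idx.size < 2:
        raise ValueError(f"window {window} contains fewer than 2 samples")
    return idx


def _endpoint_value(values: np.ndarray, idx: np.ndarray, position: int) -> float:
    """Value at a window endpoint, falling back to the nearest finite sample."""
    v = values[idx[position]]
    if np.isfinite(v):
        return float(v)
    finite = idx[np.isfinite(values[idx])]
    if finite.size == 0:
        return np.nan
    target = idx[position]
    return float(values[finite[np.argmin(np.abs(finite - target))]])


def estimate_yields_batch(
    ts: TimeSeries,
    window: tuple[float, float] | None = None,
    products: Sequence[str] = MEASURED_PRODUCTS,
    method: str = "endpoint",
) -> YieldProfile:
    """Molar yields of a batch run.

    The default ``endpoint`` method takes concentration deltas between the
    first sample of the window and the sample of maximal cumulative glucose
    consumption (normally the last sample; late lactate formed after growth
    arrest is thereby included). The ``regression`` method instead regresses
    each product on cumulative glucose consumed over all window samples,
    which averages measurement noise but assumes yield-proportional
    accumulation throughout.

    Concentrations are corrected for base-titration dilution only when the
    run carries a dilution-factor column.
    """
    if ts.mode != "batch":
        raise ValueError("estimate_yields_batch requires a batch time series")
    if method not in ("endpoint", "regression"):
        raise ValueError(f"unknown method {method!r}")
    conc = ts.corrected_conc()
    idx = _window_indices(ts.times, window)
    glucose = conc["glucose"]
    g0 = _endpoint_value(glucose, idx, 0)
    consumption = g0 - glucose[idx]
    consumption = np.where(np.isfinite(consumption), consumption, -np.inf)
    end_pos = int(np.argmax(consumption))
    consumed = float(consumption[end_pos])
    if not consumed > 0:
        raise ValueError(
            f"non-positive glucose consumption over the window ({consumed:.4g} mM)"
        )

    yields: dict[str, float] = {}
    for p in products:
        if p not in conc or not np.any(np.isfinite(conc[p][idx])):
            warnings.warn(f"product {p!r} missing from run; yield set to 0")
            yields[p] = 0.0
            continue
        if method == "endpoint":
            p0 = _endpoint_value(conc[p], idx, 0)
            p1 = _endpoint_value(conc[p], idx, end_pos)
            y = (p1 - p0) / consumed
        else:
            x = g0 - glucose[idx]
            yv = conc[p][idx]
            ok = np.isfinite(x) & np.isfinite(yv)
            if ok.sum() < 2:
                raise ValueError(f"too few finite samples for regression on {p!r}")
            y = float(np.polyfit(x[ok], yv[ok], 1)[0])
        if y < 0:
            if y < -0.02:
                warnings.warn(f"negative yield {y:.3f} for {p!r} clipped to 0")
            y = 0.0
        yields[p] = float(y)

    growth_rate = None
    if ts.od600 is not None and np.sum(ts.od600[idx] > 0) >= 3:
        growth_rate = estimate_growth_rate(ts, window)
    return YieldProfile(
        yields=yields,
        glucose_consumed=consumed,
        growth_rate=growth_rate,
        meta=ts.meta,
    )


def _lnfit(t: np.ndarray, ln_od: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of ln(OD) vs t and the fit's R^2.

    A window with zero variance in ln(OD) (constant OD) is a perfect flat
    fit: slope 0, R^2 1.
    """
    slope, intercept = np.polyfit(t, ln_od, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((ln_od - pred) ** 2))
    ss_tot = float(np.sum((ln_od - ln_od.mean()) ** 2))
    if ss_tot < 1e-30:
        return float(slope), 1.0 if ss_res < 1e-30 else 0.0
    return float(slope), 1.0 - ss_res / ss_tot


def estimate_growth_rate(
    ts: TimeSeries,
    window: tuple[float, float] | None = None,
    min_points: int = 3,
    r2_threshold: float = 0.999,
) -> float:
    """Specific growth rate from a log-linear fit of OD600 vs time.

    Without an explicit window, every contiguous run of >= ``min_points``
    positive-OD samples is fitted and the longest run with positive slope
    whose R^2 reaches ``r2_threshold`` is taken as the exponential phase
    (ties broken by R^2; if no run qualifies, the best-R^2 run is used,
    which also covers the constant-OD case, mu = 0). The positive-slope
    requirement keeps the post-stationary OD decline — itself log-linear —
    out of the automatic fit; pass an explicit ``window`` to fit a decline.
    """
    if ts.od600 is None:
        raise ValueError("growth-rate estimation requires OD600 data")
    idx = _window_indices(ts.times, window)
    od = ts.od600[idx]
    t = ts.times[idx]
    ok = np.isfinite(od) & (od > 0)
    t, od = t[ok], od[ok]
    if t.size < min_points:
        raise ValueError(
            f"growth-rate fit needs >= {min_points} positive OD points, got {t.size}"
        )
    ln_od = np.log(od)
    if window is not None:
        return _lnfit(t, ln_od)[0]

    best: tuple[int, float, float] | None = None  # (length, r2, slope), eligible
    fallback: tuple[float, float] | None = None  # (r2, slope)
    n = t.size
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            slope, r2 = _lnfit(t[i:j], ln_od[i:j])
            if fallback is None or r2 > fallback[0]:
                fallback = (r2, slope)
            if r2 >= r2_threshold and slope > 0:
                cand = (j - i, r2, slope)
                if best is None or cand[:2] > best[:2]:
                    best = cand
    if best is not None:
        return best[2]
    return fallback[1]


def estimate_yields_chemostat(ts: TimeSeries) -> YieldProfile:
    """Per-steady-state yields from replicate chemostat samples.

    Yields are computed per sample as P_out / (S_feed - S_residual) and
    averaged over replicates, with the replicate standard deviation recorded.
    Samples taken before three hydraulic retention times have elapsed mark
    the profile as not steady (``meta.extras['steady_state_ok']``) rather
    than being dropped.
    """
    if ts.mode != "chemostat":
        raise ValueError("estimate_yields_chemostat requires a chemostat record")
    feed = ts.meta.feed_glucose_mM
    if feed is None:
        raise ValueError("chemostat metadata must carry feed_glucose_mM")
    residual = ts.conc["glucose"]
    consumed = feed - residual
    if np.any(consumed <= 0):
        bad = float(residual[np.argmin(consumed)])
        raise ValueError(
            f"residual glucose {bad:.3g} mM >= feed {feed:.3g} mM "
            "(washout or bad record)"
        )

    yields: dict[str, float] = {}
    stds: dict[str, float] = {}
    for p in MEASURED_PRODUCTS:
        if p not in ts.conc or not np.any(np.isfinite(ts.conc[p])):
            warnings.warn(f"product {p!r} missing from steady state; yield set to 0")
            yields[p], stds[p] = 0.0, 0.0
            continue
        per_sample = ts.conc[p] / consumed
        ok = np.isfinite(per_sample)
        yields[p] = float(np.mean(per_sample[ok]))
        stds[p] = float(np.std(per_sample[ok]))

    meta = dataclasses.replace(ts.meta, extras=dict(ts.meta.extras))
    D = ts.meta.dilution_rate_per_h
    if D is not None and ts.times.size:
        meta.extras["steady_state_ok"] = bool(np.all(ts.times >= 3.0 / D - 1e-9))
    return YieldProfile(
        yields=yields,
        glucose_consumed=float(np.mean(consumed)),
        growth_rate=D,
        yields_std=stds,
        meta=meta,
    )


def carbon_balance(profile: YieldProfile, model: PathwayModel) -> CarbonBalance:
    """Glucose C-mole balance of a yield profile.

    accounted = sum of coefficient x yield over succinate, acetate, lactate
    and ethanol; the fraction is taken against glucose's 6 C-mol.
    """
    coeffs = glucose_carbon_coefficients(model)
    accounted = sum(c * profile.yields.get(p, 0.0) for p, c in coeffs.items())
    if accounted > GLUCOSE_CMOL + 1e-9:
        raise ValueError(
            f"infeasible profile: accounted C-mol {accounted:.4f} exceeds "
            f"{GLUCOSE_CMOL:.0f} per mol glucose"
        )
    frac = accounted / GLUCOSE_CMOL
    return CarbonBalance(
        accounted_cmol=accounted,
        accounted_fraction=frac,
        unaccounted_fraction=1.0 - frac,
    )


def relative_yield_change(
    a: YieldProfile, b: YieldProfile, product: str
) -> float:
    """Relative change of one product's yield, (b - a)/b, e.g. the drop in
    succinate yield when moving from the reference condition ``b`` to ``a``."""
    yb = b.yields.get(product, 0.0)
    if yb == 0:
        raise ValueError(f"reference yield for {product!r} is zero")
    return (yb - a.yields.get(product, 0.0)) / yb
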