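"""Synthetic district-by-day panels with known generating truth.

Everything the fitting pipeline assumes is present can be generated here:
episode-linked pollutant levels (period-specific truncated Gaussians),
a seasonal temperature series, day-of-week and episode rate multipliers,
a smooth long-term trend, a nonlinear temperature effect, an intrinsic
CAR spatial field, and Poisson counts with a population offset.  Default
parameters give the simulated panels realistic Taipei-area scale:
episode-elevated PM10/O3 levels, seasonal temperature, strong weekday
visit cycles, and modest episode rate increases.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import ValidationError
from .exposure_calendar import (
    ADS,
    OTHER,
    POST_ADS,
    STUDY_END,
    STUDY_START,
    ADSEvent,
    ExposureCalendar,
    label_periods,
    load_event_fixture,
)
from .spatial_graph import DistrictGraph, car_structure, lattice_graph, ring_graph
from .star_model import POLLUTANTS, PanelData

#: Episode-stratified pollutant (mean, sd) defaults per period label.
DEFAULT_REGIME: dict[str, dict[str, tuple[float, float]]] = {
    "CO": {ADS: (0.82, 0.30), POST_ADS: (1.01, 0.33), OTHER: (0.88, 0.32)},
    "NOx": {ADS: (45.50, 17.43), POST_ADS: (60.10, 23.38), OTHER: (49.77, 19.51)},
    "O3": {ADS: (25.13, 7.40), POST_ADS: (20.60, 8.00), OTHER: (18.99, 8.29)},
    "PM10": {ADS: (81.11, 35.41), POST_ADS: (63.04, 25.44), OTHER: (53.32, 22.51)},
    "SO2": {ADS: (3.91, 2.03), POST_ADS: (4.17, 2.28), OTHER: (4.35, 2.08)},
}

#: Day-of-week rate multipliers (Sunday = 1), schoolchildren effect sizes.
DEFAULT_DOW_MULTIPLIERS: dict[str, float] = {
    "Mon": 1.2675,
    "Tue": 0.9287,
    "Wed": 1.2682,
    "Thu": 0.8677,
    "Fri": 1.0417,
    "Sat": 1.7470,
    "Sun": 1.0,
}

#: Reference interquartile ranges used to back-transform pollutant effects.
REFERENCE_IQR = {"NOx": 22.16, "O3": 11.22, "PM10": 29.88, "SO2": 2.63}

#: Pollutant log-rate slopes per raw unit (schoolchildren, IQR back-transformed).
DEFAULT_POLLUTANT_COEFS: dict[str, float] = {
    "CO": 0.0,
    "NOx": math.log(1.0349) / REFERENCE_IQR["NOx"],
    "O3": math.log(1.0621) / REFERENCE_IQR["O3"],
    "PM10": 0.0,
    "SO2": 0.0,
}


def default_temperature_effect(tp: np.ndarray) -> np.ndarray:
    """Smooth bump peaking in the hot range, qualitatively like the study's smoother."""
    tp = np.asarray(tp, dtype=float)
    return 0.15 * np.exp(-(((tp - 28.0) / 6.0) ** 2))


def default_trend(t: np.ndarray, n_days: int) -> np.ndarray:
    """Gentle long-term oscillation over the study span."""
    t = np.asarray(t, dtype=float)
    return 0.05 * np.sin(2.0 * np.pi * t / max(n_days, 1) * 2.0)


@dataclass
class SimConfig:
    """Parameters of the generating model; defaults mirror the study's scale."""

    seed: int = 0
    n_districts: int = 41
    graph_type: str = "lattice"  # lattice | ring
    graph: DistrictGraph | None = None
    start: dt.date = STUDY_START
    end: dt.date = STUDY_END
    events: Sequence[ADSEvent] | None = None  # None -> packaged fixture
    post_window: int = 7
    baseline_rate: float = 1.5e-3  # visits per child-day on a reference Sunday
    dow_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOW_MULTIPLIERS)
    )
    beta_ads: float = math.log(1.0948)
    beta_post: float = math.log(1.0232)
    pollutant_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POLLUTANT_COEFS)
    )
    regime: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGIME.items()})
    pollutant_ar1: float = 0.0  # optional AR(1) on pollutant anomalies
    temp_mean: float = 23.0
    temp_amplitude: float = 6.0
    temp_noise_sd: float = 1.5
    temp_phase_day: int = 196  # mid-July peak
    temperature_effect: Callable[[np.ndarray], np.ndarray] | None = None
    trend: Callable[[np.ndarray, int], np.ndarray] | None = None
    sigma2_spat: float = 0.05
    pop_range: tuple[float, float] = (2_000.0, 60_000.0)

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be positive")
        if self.n_districts < 2:
            raise ValidationError("need at least 2 districts")
        if self.end < self.start:
            raise ValidationError("empty date range")
        if any(m <= 0 for m in self.dow_multipliers.values()):
            raise ValidationError("day-of-week multipliers must be positive")
        if any(p[0] <= 0 for p in [self.pop_range]):
            raise ValidationError("populations must be positive")
        for pol, per in self.regime.items():
            for period, (mean, sd) in per.items():
                if sd < 0:
                    raise ValidationError(f"negative SD for {pol} in {period}")


@dataclass
class TruthRecord:
    """Everything needed to rebuild the generating linear predictor exactly."""

    config_summary: dict
    calendar: ExposureCalendar
    spatial_field: dict
    populations: dict
    temperature: np.ndarray
    trend_values: np.ndarray
    temperature_effect_values: np.ndarray
    log_baseline: float

    def linear_predictor(self, district, day_index: int) -> float:
        cal = self.calendar.frame
        dow = cal["dow"].iloc[day_index]
        period = cal["period"].iloc[day_index]
        eta = self.log_baseline
        eta += math.log(self.config_summary["dow_multipliers"][dow])
        if period == ADS:
            eta += self.config_summary["beta_ads"]
        elif period == POST_ADS:
            eta += self.config_summary["beta_post"]
        eta += self.trend_values[day_index]
        eta += self.temperature_effect_values[day_index]
        eta += self.spatial_field[district]
        eta += self.config_summary["pollutant_contrib"][day_index]
        return eta

    def to_json(self, path: str | Path) -> None:
        out = {
            "config": {
                k: v
                for k, v in self.config_summary.items()
                if k != "pollutant_contrib"
            },
            "spatial_field": self.spatial_field,
            "populations": self.populations,
            "log_baseline": self.log_baseline,
            "trend_values": np.asarray(self.trend_values).tolist(),
            "temperature_effect_values": np.asarray(
                self.temperature_effect_values
            ).tolist(),
        }
        Path(path).write_text(json.dumps(out))


def make_graph(config: SimConfig) -> DistrictGraph:
    if config.graph is not None:
        return config.graph
    if config.graph_type == "lattice":
        return lattice_graph(config.n_districts)
    if config.graph_type == "ring":
        return ring_graph(config.n_districts)
    raise ValidationError(f"unknown graph type {config.graph_type!r}")


def sample_spatial_field(
    graph: DistrictGraph, sigma2: float, rng: np.random.Generator
) -> dict:
    """Draw an intrinsic CAR field restricted to the sum-to-zero subspace.

    The draw has covariance ``sigma2 * K^+`` (pseudo-inverse of the graph
    Laplacian); on a disconnected graph each component is centred separately.
    """
    if sigma2 < 0:
        raise ValidationError("sigma2 must be non-negative")
    ids = graph.ids
    if sigma2 == 0:
        return {d: 0.0 for d in ids}
    car = car_structure(graph)
    eigval, eigvec = np.linalg.eigh(car.matrix)
    tol = 1e-9 * max(eigval.max(), 1.0)
    keep = eigval > tol
    z = rng.standard_normal(int(keep.sum()))
    f = eigvec[:, keep] @ (z * np.sqrt(sigma2 / eigval[keep]))
    # per-component centring (automatic for connected graphs)
    comps = car.components
    for c in np.unique(comps):
        f[comps == c] -= f[comps == c].mean()
    return {d: float(v) for d, v in zip(ids, f)}


def _truncated_loc(target_mean: float, sd: float) -> float:
    """Location of a zero-truncated Gaussian whose mean equals ``target_mean``.

    Truncating at zero inflates the mean, so the location is shifted down by
    root-finding; for mildly truncated regimes the shift is small.
    """
    if target_mean <= 0:
        raise ValidationError("truncated-at-zero draws need a positive target mean")
    if sd == 0:
        return target_mean

    def gap(loc: float) -> float:
        return truncnorm.mean((0.0 - loc) / sd, np.inf, loc=loc, scale=sd) - target_mean

    lo = target_mean - 8.0 * sd
    return float(brentq(gap, lo, target_mean, xtol=1e-10))


def sample_covariates(
    calendar: ExposureCalendar,
    regime: dict | None = None,
    rng: np.random.Generator | None = None,
    temp_mean: float = 23.0,
    temp_amplitude: float = 6.0,
    temp_noise_sd: float = 1.5,
    temp_phase_day: int = 196,
    ar1: float = 0.0,
) -> pd.DataFrame:
    """Daily pollutant and temperature table driven by the period labels.

    Pollutants are drawn independently per day from the period-specific
    Gaussian truncated at zero, with the location moment-matched so the
    post-truncation mean equals the configured period mean; temperature is
    an annual sinusoid plus Gaussian noise.  Setting ``ar1`` adds
    first-order autocorrelation to the pollutant anomalies instead (cruder:
    clipped at zero, no moment matching).
    """
    regime = {k: dict(v) for k, v in (regime or DEFAULT_REGIME).items()}
    rng = rng or np.random.default_rng()
    cal = calendar.frame
    n = len(cal)
    out = pd.DataFrame({"date": cal["date"]})
    periods = cal["period"].to_numpy()
    for pol, per_period in regime.items():
        means = np.empty(n)
        sds = np.empty(n)
        locs = np.empty(n)
        for period, (m, s) in per_period.items():
            if s < 0:
                raise ValidationError(f"negative SD for {pol} in {period}")
            mask = periods == period
            means[mask], sds[mask] = m, s
            locs[mask] = _truncated_loc(m, s)
        if ar1:
            eps = np.empty(n)
            eps[0] = rng.standard_normal()
            innov = rng.standard_normal(n) * math.sqrt(max(1.0 - ar1**2, 1e-12))
            for i in range(1, n):
                eps[i] = ar1 * eps[i - 1] + innov[i]
            vals = np.maximum(means + sds * eps, 0.0)
        else:
            safe_sd = np.where(sds > 0, sds, 1.0)
            a = np.where(sds > 0, (0.0 - locs) / safe_sd, -np.inf)
            vals = np.where(
                sds > 0,
                truncnorm.rvs(a, np.inf, loc=locs, scale=safe_sd, random_state=rng),
                means,
            )
        out[pol] = vals
    doy = np.array([d.timetuple().tm_yday for d in cal["date"]], dtype=float)
    seasonal = temp_mean + temp_amplitude * np.cos(
        2.0 * np.pi * (doy - temp_phase_day) / 365.25
    )
    out["temperature"] = seasonal + rng.standard_normal(n) * temp_noise_sd
    return out


def generate_panel(config: SimConfig) -> tuple[PanelData, TruthRecord, DistrictGraph]:
    """Generate a Poisson panel with fully recorded generating truth."""
    rng = np.random.default_rng(config.seed)
    graph = make_graph(config)
    events = list(config.events) if config.events is not None else load_event_fixture()
    calendar = label_periods(config.start, config.end, events, config.post_window)
    n_days = len(calendar)
    cal = calendar.frame

    covariates = sample_covariates(
        calendar,
        config.regime,
        rng,
        temp_mean=config.temp_mean,
        temp_amplitude=config.temp_amplitude,
        temp_noise_sd=config.temp_noise_sd,
        temp_phase_day=config.temp_phase_day,
        ar1=config.pollutant_ar1,
    )

    spatial = sample_spatial_field(graph, config.sigma2_spat, rng)
    lo, hi = config.pop_range
    pops = np.exp(rng.uniform(math.log(lo), math.log(hi), graph.n))
    populations = {d: float(round(p)) for d, p in zip(graph.ids, pops)}

    t_idx = np.arange(n_days, dtype=float)
    trend_fn = config.trend or default_trend
    trend_vals = np.asarray(trend_fn(t_idx, n_days), dtype=float)
    temp_fn = config.temperature_effect or default_temperature_effect
    tp = covariates["temperature"].to_numpy()
    temp_raw = np.asarray(temp_fn(tp), dtype=float)
    # centre the smooth truths so the baseline keeps its interpretation
    trend_vals = trend_vals - trend_vals.mean()
    temp_vals = temp_raw - temp_raw.mean()

    pollutant_contrib = np.zeros(n_days)
    for pol, coef in config.pollutant_coefs.items():
        if coef and pol in covariates.columns:
            pollutant_contrib += coef * covariates[pol].to_numpy()

    dow_log = np.array(
        [math.log(config.dow_multipliers[d]) for d in cal["dow"]], dtype=float
    )
    periods = cal["period"].to_numpy()
    period_log = np.where(
        periods == ADS, config.beta_ads, np.where(periods == POST_ADS, config.beta_post, 0.0)
    )
    log_baseline = math.log(config.baseline_rate)
    day_eta = log_baseline + dow_log + period_log + trend_vals + temp_vals + pollutant_contrib

    records = []
    for d in graph.ids:
        eta = day_eta + spatial[d] + math.log(populations[d])
        if np.any(eta > 30):
            worst = int(np.argmax(eta))
            raise ValidationError(
                f"rate overflow at district {d!r}, day {worst}: linear predictor "
                f"{eta[worst]:.2f}; reduce effect sizes or populations"
            )
        counts = rng.poisson(np.exp(eta))
        records.append(
            pd.DataFrame(
                {
                    "district": d,
                    "date": cal["date"],
                    "count": counts,
                    "population": populations[d],
                }
            )
        )
    panel = pd.concat(records, ignore_index=True)

    truth = TruthRecord(
        config_summary={
            "seed": config.seed,
            "n_districts": graph.n,
            "n_days": n_days,
            "baseline_rate": config.baseline_rate,
            "dow_multipliers": dict(config.dow_multipliers),
            "beta_ads": config.beta_ads,
            "beta_post": config.beta_post,
            "pollutant_coefs": dict(config.pollutant_coefs),
            "sigma2_spat": config.sigma2_spat,
            "pollutant_contrib": pollutant_contrib,
        },
        calendar=calendar,
        spatial_field=spatial,
        populations=populations,
        temperature=tp,
        trend_values=trend_vals,
        temperature_effect_values=temp_vals,
        log_baseline=log_baseline,
    )
    return PanelData(panel=panel, covariates=covariates), truth, graph
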