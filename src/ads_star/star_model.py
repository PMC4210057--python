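"""Poisson structured additive regression: design assembly, penalized IRLS,
and restricted-maximum-likelihood estimation of the smoothing variances.

The linear predictor for district ``d`` on day ``t`` is

    log mu_dt = X beta + Z gamma + f_time(t) + f_temp(TP_t) + f_spat(d) + log POP_d

with ``X`` the intercept, six day-of-week dummies and the two episode
dummies, ``Z`` the selected pollutant columns in raw units, the two smooth
terms P-splines with second-order difference penalties, and ``f_spat`` an
intrinsic CAR (graph Laplacian) random field.  All penalized blocks carry
sum-to-zero constraints so the intercept is identifiable.

Coefficients are fitted by penalized iteratively reweighted least squares
for fixed variances; the variances are updated in an outer loop by
Fellner–Schall REML steps (optionally damped by an inverse-gamma prior).
The reported covariance is the inverse penalized information, and model
complexity is the trace of the hat operator (effective degrees of freedom).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .errors import ConvergenceError, ValidationError
from .exposure_calendar import DOW_COLUMNS, ExposureCalendar, dow_design, period_design
from .smoothers import SplineBlock, apply_sum_to_zero, make_spline_block, sum_to_zero_transform
from .spatial_graph import DistrictGraph, car_structure

logger = logging.getLogger(__name__)

POLLUTANTS = ("CO", "NOx", "O3", "PM10", "SO2")

FIXED_COLUMNS = ("(Intercept)",) + DOW_COLUMNS + ("I_ADS", "I_POST_ADS")

# variance bounds for the REML outer loop
TAU2_FLOOR = 1e-10
TAU2_CEIL = 1e8


@dataclass
class PanelData:
    """District-by-day counts joined with a single-station daily covariate table."""

    panel: pd.DataFrame
    covariates: pd.DataFrame
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        need = {"district", "date", "count", "population"}
        if not need.issubset(self.panel.columns):
            raise ValidationError(f"panel must have columns {sorted(need)}")
        if "temperature" not in self.covariates.columns or "date" not in self.covariates.columns:
            raise ValidationError("covariates must have 'date' and 'temperature' columns")
        p = self.panel
        y = p["count"].to_numpy()
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValidationError("counts must be non-negative integers")
        if np.any(p["population"].to_numpy() <= 0):
            raise ValidationError("populations must be positive")
        if p.duplicated(["district", "date"]).any():
            raise ValidationError("panel has duplicate (district, date) rows")
        if not self.allow_gaps:
            dates = pd.to_datetime(pd.Series(sorted(p["date"].unique())))
            if len(dates) > 1:
                gaps = dates.diff().dt.days.iloc[1:]
                if (gaps != 1).any():
                    raise ValidationError(
                        "panel has missing dates; pass allow_gaps=True to accept"
                    )

    @property
    def districts(self) -> list:
        """District ids in order of first appearance (fixes the spatial order)."""
        return list(dict.fromkeys(self.panel["district"]))

    @property
    def dates(self) -> list:
        return sorted(self.panel["date"].unique())

    @classmethod
    def from_csv(
        cls, panel_path: str | Path, covariates_path: str | Path, allow_gaps: bool = False
    ) -> "PanelData":
        panel = pd.read_csv(panel_path)
        panel["date"] = pd.to_datetime(panel["date"]).dt.date
        cov = pd.read_csv(covariates_path)
        cov["date"] = pd.to_datetime(cov["date"]).dt.date
        return cls(panel=panel, covariates=cov, allow_gaps=allow_gaps)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the model and how the fit is controlled."""

    pollutants: tuple[str, ...] = ()
    time_n_basis: int = 20
    temp_n_basis: int = 10
    degree: int = 3
    use_time_smooth: bool = True
    use_temp_smooth: bool = True
    use_spatial: bool = True
    post_window: int = 7
    dow_reference: str = "Sun"
    pollutant_lag: int = 0
    ig_prior: tuple[float, float] = (0.001, 0.001)
    ig_damping: bool = True
    inner_tol: float = 1e-8
    inner_max_iter: int = 100
    outer_tol: float = 1e-6
    outer_max_iter: int = 200

    def __post_init__(self) -> None:
        dupes = {p for p in self.pollutants if list(self.pollutants).count(p) > 1}
        if dupes:
            raise ValidationError(f"duplicate pollutants {sorted(dupes)}")
        unknown = set(self.pollutants) - set(POLLUTANTS)
        if unknown:
            raise ValidationError(f"unknown pollutants {sorted(unknown)}")


@dataclass
class PenalizedBlock:
    """A penalized coefficient block inside the full design matrix."""

    name: str
    sl: slice
    penalty: np.ndarray
    rank: int


@dataclass
class Design:
    """Assembled model matrices: response, offset, columns, penalty blocks."""

    y: np.ndarray
    offset: np.ndarray
    C: np.ndarray
    col_names: list[str]
    blocks: list[PenalizedBlock]
    meta: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.C.shape[0]

    @property
    def n_coef(self) -> int:
        return self.C.shape[1]

    def block(self, name: str) -> PenalizedBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass
class FitResult:
    """Converged fit: coefficients, posterior covariance, complexity, fit quality."""

    beta: np.ndarray
    col_names: list[str]
    cov: np.ndarray
    blocks: list[PenalizedBlock]
    tau2: dict
    edf_blocks: dict
    edf_total: float
    loglik: float
    deviance: float
    aic: float
    iterations: int
    outer_iterations: int
    converged: bool
    grad_norm: float
    meta: dict = field(default_factory=dict)
    trace: list = field(default_factory=list, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef(self, name: str) -> float:
        return float(self.beta[self.col_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.col_names.index(name)])

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.col_names, "estimate": self.beta, "se": self.se}
        )

    def block_slice(self, name: str) -> slice:
        for b in self.blocks:
            if b.name == name:
                return b.sl
        raise KeyError(name)

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        meta = dict(self.meta)
        for key in ("time_block", "temp_block"):
            blk = meta.get(key)
            if isinstance(blk, SplineBlock):
                meta[key] = {
                    "__spline__": True,
                    "name": blk.name,
                    "knots": blk.knots.tolist(),
                    "degree": blk.degree,
                    "domain": list(blk.domain),
                    "transform": None if blk.transform is None else blk.transform.tolist(),
                    "penalty": blk.penalty.tolist(),
                }
        if "spatial_transform" in meta and meta["spatial_transform"] is not None:
            meta["spatial_transform"] = np.asarray(meta["spatial_transform"]).tolist()
        if "date0" in meta and isinstance(meta["date0"], dt.date):
            meta["date0"] = meta["date0"].isoformat()
        return {
            "beta": self.beta.tolist(),
            "col_names": self.col_names,
            "cov": self.cov.tolist(),
            "blocks": [
                {
                    "name": b.name,
                    "start": b.sl.start,
                    "stop": b.sl.stop,
                    "penalty": b.penalty.tolist(),
                    "rank": b.rank,
                }
                for b in self.blocks
            ],
            "tau2": self.tau2,
            "edf_blocks": self.edf_blocks,
            "edf_total": self.edf_total,
            "loglik": self.loglik,
            "deviance": self.deviance,
            "aic": self.aic,
            "iterations": self.iterations,
            "outer_iterations": self.outer_iterations,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "meta": meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        meta = dict(d.get("meta", {}))
        for key in ("time_block", "temp_block"):
            blk = meta.get(key)
            if isinstance(blk, dict) and blk.get("__spline__"):
                meta[key] = SplineBlock(
                    name=blk["name"],
                    knots=np.asarray(blk["knots"]),
                    degree=blk["degree"],
                    basis=np.zeros((0, 0)),
                    penalty=np.asarray(blk["penalty"]),
                    domain=tuple(blk["domain"]),
                    transform=None
                    if blk["transform"] is None
                    else np.asarray(blk["transform"]),
                )
        if meta.get("spatial_transform") is not None:
            meta["spatial_transform"] = np.asarray(meta["spatial_transform"])
        if "date0" in meta and isinstance(meta["date0"], str):
            meta["date0"] = dt.date.fromisoformat(meta["date0"])
        return cls(
            beta=np.asarray(d["beta"]),
            col_names=list(d["col_names"]),
            cov=np.asarray(d["cov"]),
            blocks=[
                PenalizedBlock(
                    name=b["name"],
                    sl=slice(b["start"], b["stop"]),
                    penalty=np.asarray(b["penalty"]),
                    rank=b["rank"],
                )
                for b in d["blocks"]
            ],
            tau2=dict(d["tau2"]),
            edf_blocks=dict(d["edf_blocks"]),
            edf_total=d["edf_total"],
            loglik=d["loglik"],
            deviance=d["deviance"],
            aic=d["aic"],
            iterations=d["iterations"],
            outer_iterations=d["outer_iterations"],
            converged=d["converged"],
            grad_norm=d["grad_norm"],
            meta=meta,
        )

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _penalty_rank(k: np.ndarray) -> int:
    eig = np.linalg.eigvalsh(k)
    return int(np.sum(eig > 1e-9 * max(float(eig.max()), 1.0)))


def build_design(
    panel: PanelData,
    calendar: ExposureCalendar,
    graph: DistrictGraph | None,
    spec: ModelSpec,
) -> Design:
    """Assemble the full design: fixed block, pollutants, smooths, spatial term.

    The row order is (date, district) sorted; the offset is ``log population``.
    """
    districts = panel.districts
    if spec.use_spatial:
        if graph is None:
            raise ValidationError("spatial term requested but no district graph given")
        missing = [d for d in districts if d not in set(graph.ids)]
        if missing:
            raise ValidationError(f"districts missing from adjacency graph: {missing}")

    cal = calendar.frame.copy()
    cal_dates = set(cal["date"])
    panel_dates = set(panel.panel["date"])
    if not panel_dates.issubset(cal_dates):
        raise ValidationError("panel contains dates outside the exposure calendar")

    cov = panel.covariates.copy()
    if spec.pollutant_lag:
        lagged = cov.sort_values("date").copy()
        for p in POLLUTANTS:
            if p in lagged.columns:
                lagged[p] = lagged[p].shift(spec.pollutant_lag)
        cov = lagged.dropna(subset=[p for p in POLLUTANTS if p in lagged.columns])
    missing_cov = panel_dates - set(cov["date"])
    if missing_cov:
        raise ValidationError(
            f"{len(missing_cov)} panel dates missing from the covariate table "
            f"(earliest: {min(missing_cov)})"
        )
    for p in spec.pollutants:
        if p not in cov.columns:
            raise ValidationError(f"pollutant {p!r} not in the covariate table")

    rows = panel.panel.sort_values(["date", "district"], kind="mergesort").reset_index(drop=True)
    rows = rows.merge(cov, on="date", how="left", validate="many_to_one")

    # per-day design pieces from the calendar
    dow = dow_design(calendar, reference=spec.dow_reference)
    per = period_design(calendar)
    day_fixed = pd.concat([cal[["date"]], dow, per], axis=1)
    rows = rows.merge(day_fixed, on="date", how="left", validate="many_to_one")

    n = len(rows)
    pieces: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["(Intercept)"]
    pieces.append(rows[list(DOW_COLUMNS)].to_numpy(float))
    names += list(DOW_COLUMNS)
    pieces.append(rows[["I_ADS", "I_POST_ADS"]].to_numpy(float))
    names += ["I_ADS", "I_POST_ADS"]
    n_unpenalized = 9

    for p in spec.pollutants:
        pieces.append(rows[[p]].to_numpy(float))
        names.append(p)
        n_unpenalized += 1

    blocks: list[PenalizedBlock] = []
    meta: dict = {
        "districts": districts,
        "pollutants": list(spec.pollutants),
        "date0": min(calendar.frame["date"]),
        "spec": {
            "time_n_basis": spec.time_n_basis,
            "temp_n_basis": spec.temp_n_basis,
            "degree": spec.degree,
        },
    }
    start = n_unpenalized

    date0 = meta["date0"]
    if spec.use_time_smooth:
        t_idx = rows["date"].map(lambda d: (d - date0).days).to_numpy(float)
        t_domain = (0.0, float((max(calendar.frame["date"]) - date0).days))
        blk = make_spline_block(
            t_idx, spec.time_n_basis, spec.degree, name="time", domain=t_domain
        )
        blk = apply_sum_to_zero(blk)
        m = blk.n_coef
        pieces.append(blk.basis)
        names += [f"time_{j + 1}" for j in range(m)]
        blocks.append(
            PenalizedBlock("time", slice(start, start + m), blk.penalty, _penalty_rank(blk.penalty))
        )
        meta["time_block"] = blk
        start += m

    if spec.use_temp_smooth:
        tp = rows["temperature"].to_numpy(float)
        blk = make_spline_block(tp, spec.temp_n_basis, spec.degree, name="temp")
        blk = apply_sum_to_zero(blk)
        m = blk.n_coef
        pieces.append(blk.basis)
        names += [f"temp_{j + 1}" for j in range(m)]
        blocks.append(
            PenalizedBlock("temp", slice(start, start + m), blk.penalty, _penalty_rank(blk.penalty))
        )
        meta["temp_block"] = blk
        start += m

    if spec.use_spatial:
        car = car_structure(graph)
        order = {d: i for i, d in enumerate(graph.ids)}
        row_district = rows["district"].map(order).to_numpy()
        incidence = np.zeros((n, graph.n))
        incidence[np.arange(n), row_district] = 1.0
        z = sum_to_zero_transform(incidence.sum(axis=0))
        pieces.append(incidence @ z)
        kc = z.T @ car.matrix @ z
        m = z.shape[1]
        names += [f"spat_{j + 1}" for j in range(m)]
        blocks.append(PenalizedBlock("spatial", slice(start, start + m), kc, _penalty_rank(kc)))
        meta["spatial_transform"] = z
        meta["spatial_ids"] = list(graph.ids)
        start += m

    C = np.hstack(pieces)
    y = rows["count"].to_numpy(float)
    offset = np.log(rows["population"].to_numpy(float))
    return Design(y=y, offset=offset, C=C, col_names=names, blocks=blocks, meta=meta)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(xlogy(y, y / mu) - (y - mu)))


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(xlogy(y, mu) - mu - gammaln(y + 1.0)))


def _assemble_penalty(design: Design, tau2: dict) -> np.ndarray:
    s = np.zeros((design.n_coef, design.n_coef))
    for b in design.blocks:
        v = tau2.get(b.name)
        if v is None or not np.isfinite(v):
            continue  # no penalty on this block
        if v <= 0:
            raise ValidationError(f"variance for block {b.name!r} must be positive")
        s[b.sl, b.sl] += b.penalty / v
    return s


def fit_pirls(
    design: Design,
    tau2: dict | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Penalized IRLS at fixed smoothing variances.

    ``tau2`` maps block name to its variance (``inf``/``None`` disables the
    penalty).  Convergence is declared when the relative change of the
    penalized deviance drops below ``tol``; deviance increases trigger
    step-halving.
    """
    y, C, off = design.y, design.C, design.offset
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValidationError("response must be non-negative integer counts")
    tau2 = dict(tau2 or {})
    for b in design.blocks:
        tau2.setdefault(b.name, 1.0)
    s_pen = _assemble_penalty(design, tau2)

    p = design.n_coef
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log((y.sum() + 0.5) / np.exp(off).sum())
    else:
        beta = np.asarray(beta0, dtype=float).copy()

    def predictor(b):
        eta = off + C @ b
        return eta, np.exp(np.clip(eta, -300, 300))

    eta, mu = predictor(beta)
    pdev = _poisson_deviance(y, mu) + float(beta @ s_pen @ beta)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.maximum(mu, 1e-10)
        z = (eta - off) + (y - mu) / w
        cw = C * w[:, None]
        h = C.T @ cw
        a = h + s_pen
        rhs = cw.T @ z
        try:
            beta_prop = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular penalized information at iteration {it}; "
                "design may be rank deficient",
                trace,
            ) from exc
        step = beta_prop - beta
        pdev_new = np.inf
        for half in range(31):
            cand = beta + step * 0.5**half
            eta_c, mu_c = predictor(cand)
            pdev_new = _poisson_deviance(y, mu_c) + float(cand @ s_pen @ cand)
            if pdev_new <= pdev * (1 + 1e-12) + 1e-12:
                break
        rel = abs(pdev - pdev_new) / (abs(pdev_new) + 0.1)
        beta, eta, mu, pdev = cand, eta_c, mu_c, pdev_new
        trace.append({"iter": it, "penalized_deviance": pdev, "rel_change": rel})
        logger.debug("pirls iter=%d pdev=%.8g rel=%.3g", it, pdev, rel)
        if rel < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"penalized IRLS did not converge in {max_iter} iterations "
            f"(last relative change {trace[-1]['rel_change']:.3g})",
            trace,
        )

    w = np.maximum(mu, 1e-10)
    cw = C * w[:, None]
    h = C.T @ cw
    a = h + s_pen
    cov = np.linalg.inv(a)
    cov = 0.5 * (cov + cov.T)
    hat = cov @ h
    edf_diag = np.diag(hat)
    edf_blocks = {}
    pen_cols = np.zeros(p, dtype=bool)
    for b in design.blocks:
        edf_blocks[b.name] = float(edf_diag[b.sl].sum())
        pen_cols[b.sl] = True
    edf_blocks["fixed"] = float(edf_diag[~pen_cols].sum())
    edf_total = float(edf_diag.sum())
    loglik = _poisson_loglik(y, mu)
    grad = C.T @ (y - mu) - s_pen @ beta
    return FitResult(
        beta=beta,
        col_names=list(design.col_names),
        cov=cov,
        blocks=list(design.blocks),
        tau2={k: float(v) if v is not None else None for k, v in tau2.items()},
        edf_blocks=edf_blocks,
        edf_total=edf_total,
        loglik=loglik,
        deviance=_poisson_deviance(y, mu),
        aic=-2.0 * loglik + 2.0 * edf_total,
        iterations=it,
        outer_iterations=0,
        converged=True,
        grad_norm=float(np.linalg.norm(grad)),
        meta=dict(design.meta),
        trace=trace,
    )


def estimate_variances(
    design: Design,
    spec: ModelSpec | None = None,
    tau2_init: dict | None = None,
) -> FitResult:
    """Outer REML loop: Fellner–Schall variance updates around penalized IRLS.

    Each block's variance update is ``tau2 = (b'Kb + 2*b_ig) / (rank -
    tr(P S) + 2*a_ig)`` with ``P`` the inverse penalized information and
    ``S`` the block's current scaled penalty; the inverse-gamma terms are
    the optional damping and drop out when disabled.
    """
    spec = spec or ModelSpec()
    if not design.blocks:
        return fit_pirls(design, {}, tol=spec.inner_tol, max_iter=spec.inner_max_iter)

    a_ig, b_ig = spec.ig_prior if spec.ig_damping else (0.0, 0.0)
    tau2 = {b.name: 1.0 for b in design.blocks}
    if tau2_init:
        tau2.update(tau2_init)
    beta = None
    fit = None
    outer = 0
    converged = False
    for outer in range(1, spec.outer_max_iter + 1):
        fit = fit_pirls(
            design, tau2, beta0=beta, tol=spec.inner_tol, max_iter=spec.inner_max_iter
        )
        beta = fit.beta
        new = {}
        for b in design.blocks:
            bj = beta[b.sl]
            quad = float(bj @ b.penalty @ bj)
            tr_ps = float(np.trace(fit.cov[b.sl, b.sl] @ b.penalty)) / tau2[b.name]
            denom = b.rank - tr_ps + 2.0 * a_ig
            t_new = (quad + 2.0 * b_ig) / max(denom, 1e-12)
            if t_new < TAU2_FLOOR:
                warnings.warn(
                    f"variance for block {b.name!r} collapsed below floor; clamped",
                    RuntimeWarning,
                    stacklevel=2,
                )
            new[b.name] = float(np.clip(t_new, TAU2_FLOOR, TAU2_CEIL))
        rel = max(
            abs(new[k] - tau2[k]) / (abs(tau2[k]) + 1e-12) for k in new
        )
        logger.debug("reml outer=%d tau2=%s rel=%.3g", outer, new, rel)
        tau2 = new
        if rel < spec.outer_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"REML variance loop did not settle in {spec.outer_max_iter} iterations"
        )
    final = fit_pirls(
        design, tau2, beta0=beta, tol=spec.inner_tol, max_iter=spec.inner_max_iter
    )
    return replace(final, outer_iterations=outer)


def aic(fit: FitResult) -> float:
    """Akaike criterion with effective (hat-trace) degrees of freedom."""
    return -2.0 * fit.loglik + 2.0 * fit.edf_total


def fit_model(
    panel: PanelData,
    calendar: ExposureCalendar,
    graph: DistrictGraph | None,
    spec: ModelSpec,
) -> FitResult:
    """Convenience wrapper: build the design and run the full REML fit."""
    design = build_design(panel, calendar, graph, spec)
    return estimate_variances(design, spec)
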