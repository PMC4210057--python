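"""Reporting transforms: relative-rate percentage changes, spatial effect
maps with posterior classification, smoother curves, and episode summaries.

Coefficient-scale results are mapped to percentage changes in the relative
rate via ``(exp(scale * coef) - 1) * 100`` — scale 1 for indicator terms and
the pollutant's interquartile range for pollutant terms.  Interval endpoints
use the same monotone transform of the Gaussian coefficient interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, norm

from .errors import ValidationError
from .exposure_calendar import DOW_COLUMNS, PERIODS, ExposureCalendar
from .star_model import POLLUTANTS, FitResult

POSITIVE = "positive"
NEGATIVE = "negative"
NONSIGNIFICANT = "nonsignificant"


def pct_rr_change(
    coef: float, scale: float = 1.0, se: float = 0.0, level: float = 0.95
) -> tuple[float, float, float]:
    """Percentage change in relative rate for a ``scale``-unit covariate change.

    Returns ``(point, lo, hi)``; the interval is the transform of
    ``coef ± z*se``.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    if se < 0:
        raise ValidationError("se must be non-negative")
    z = norm.ppf(0.5 + level / 2.0)
    point = (np.exp(scale * coef) - 1.0) * 100.0
    lo = (np.exp(scale * (coef - z * se)) - 1.0) * 100.0
    hi = (np.exp(scale * (coef + z * se)) - 1.0) * 100.0
    return float(point), float(lo), float(hi)


def iqr(series, skip_missing: bool = True) -> float:
    """Interquartile range with the linear-interpolation quantile definition."""
    x = np.asarray(series, dtype=float)
    if skip_missing:
        x = x[np.isfinite(x)]
    elif not np.all(np.isfinite(x)):
        raise ValidationError("series contains missing values")
    if x.size < 4:
        raise ValidationError("need at least 4 finite values for an IQR")
    q25, q75 = np.percentile(x, [25.0, 75.0])
    return float(q75 - q25)


def effect_report(
    fit: FitResult, covariates: pd.DataFrame | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Relative-rate table: day-of-week and episode dummies plus pollutants.

    Dummy terms use scale 1; pollutant terms use the interquartile range of
    their daily series (``covariates`` must then be supplied).
    """
    rows = []
    for name in DOW_COLUMNS + ("I_ADS", "I_POST_ADS"):
        if name not in fit.col_names:
            continue
        pct, lo, hi = pct_rr_change(fit.coef(name), 1.0, fit.coef_se(name), level)
        rows.append((name, 1.0, pct, lo, hi))
    for p in fit.meta.get("pollutants", []):
        if covariates is None:
            raise ValidationError("covariates needed to scale pollutant effects by IQR")
        scale = iqr(covariates[p])
        pct, lo, hi = pct_rr_change(fit.coef(p), scale, fit.coef_se(p), level)
        rows.append((p, scale, pct, lo, hi))
    return pd.DataFrame(rows, columns=["term", "scale", "pct_change", "ci_low", "ci_high"])


def classify_spatial(
    means: np.ndarray, sds: np.ndarray, level: float = 0.95
) -> list[str]:
    """Three-way class per district from the posterior interval's position
    relative to an RR of one (classification done on the log scale)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(sds <= 0):
        raise ValidationError("posterior sds must be positive")
    z = norm.ppf(0.5 + level / 2.0)
    lo = means - z * sds
    hi = means + z * sds
    return [
        POSITIVE if l > 0 else NEGATIVE if h < 0 else NONSIGNIFICANT
        for l, h in zip(lo, hi)
    ]


def spatial_effect_map(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Per-district RR (exp of the spatial effect), interval, and class."""
    z_tr = fit.meta.get("spatial_transform")
    ids = fit.meta.get("spatial_ids")
    if z_tr is None or ids is None:
        raise ValidationError("fit has no spatial term")
    sl = fit.block_slice("spatial")
    coef = fit.beta[sl]
    f = z_tr @ coef
    cov_f = z_tr @ fit.cov[sl, sl] @ z_tr.T
    sd = np.sqrt(np.maximum(np.diag(cov_f), 1e-300))
    z = norm.ppf(0.5 + level / 2.0)
    classes = classify_spatial(f, sd, level)
    return pd.DataFrame(
        {
            "district": ids,
            "effect": f,
            "sd": sd,
            "rr": np.exp(f),
            "rr_low": np.exp(f - z * sd),
            "rr_high": np.exp(f + z * sd),
            "class": classes,
        }
    )


def smoother_curve(
    fit: FitResult,
    term: str,
    grid: np.ndarray,
    levels: tuple[float, ...] = (0.8, 0.95),
) -> pd.DataFrame:
    """Relative-rate curve of a smooth term with nested credible bands."""
    key = {"time": "time_block", "temp": "temp_block"}.get(term)
    if key is None or key not in fit.meta:
        raise ValidationError(f"no smooth term {term!r} in this fit")
    blk = fit.meta[key]
    grid = np.asarray(grid, dtype=float)
    basis = blk.basis_at(grid)  # raises if grid leaves the fitted domain
    sl = fit.block_slice(term)
    est = basis @ fit.beta[sl]
    cov = basis @ fit.cov[sl, sl] @ basis.T
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out = pd.DataFrame({"x": grid, "rr": np.exp(est)})
    for level in levels:
        z = norm.ppf(0.5 + level / 2.0)
        pct = int(round(level * 100))
        out[f"rr_low_{pct}"] = np.exp(est - z * sd)
        out[f"rr_high_{pct}"] = np.exp(est + z * sd)
    return out


def episode_pollutant_summary(
    covariates: pd.DataFrame, calendar: ExposureCalendar, anova: bool = True
) -> pd.DataFrame:
    """Mean/SD of each pollutant within the ADS / post-ADS / other strata.

    The optional one-way F test compares the three period means per
    pollutant.  Strata with fewer than two days get their SD omitted.
    """
    merged = covariates.merge(
        calendar.frame[["date", "period"]], on="date", how="inner", validate="one_to_one"
    )
    if merged.empty:
        raise ValidationError("covariates and calendar share no dates")
    rows = []
    for pol in [p for p in POLLUTANTS if p in covariates.columns]:
        rec: dict = {"pollutant": pol}
        groups = []
        for period in PERIODS:
            vals = merged.loc[merged["period"] == period, pol].dropna().to_numpy()
            rec[f"{period}_n"] = len(vals)
            rec[f"{period}_mean"] = float(vals.mean()) if len(vals) else np.nan
            rec[f"{period}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
            if len(vals):
                groups.append(vals)
        if anova and len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            stat, p = f_oneway(*groups)
            rec["anova_F"] = float(stat)
            rec["anova_p"] = float(p)
        rows.append(rec)
    return pd.DataFrame(rows)
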