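"""Pollutant-subset selection: enumerate, fit, screen, rank by AIC.

Every non-empty subset of the monitored pollutants defines a candidate
model.  A candidate is eligible only if all its pollutant coefficients are
significantly positive (Gaussian interval excluding zero); the selected
model is the eligible candidate with the smallest AIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConvergenceError, ValidationError
from .exposure_calendar import ExposureCalendar
from .spatial_graph import DistrictGraph
from .star_model import FitResult, ModelSpec, PanelData, build_design, estimate_variances

logger = logging.getLogger(__name__)

ELIGIBLE = "eligible"
EXCLUDED = "excluded"


@dataclass
class CandidateResult:
    """One pollutant subset's fit summary and screening outcome."""

    subset: tuple[str, ...]
    aic: float
    coefs: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    cis: dict = field(default_factory=dict)
    significant_positive: dict = field(default_factory=dict)
    status: str = ELIGIBLE
    reason: str = ""


def enumerate_subsets(pollutants: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    pollutants = list(pollutants)
    if not pollutants:
        raise ValidationError("pollutant list is empty")
    if len(set(pollutants)) != len(pollutants):
        raise ValidationError("duplicate pollutant names")
    subsets: list[tuple[str, ...]] = []
    for k in range(1, len(pollutants) + 1):
        subsets.extend(sorted(combinations(sorted(pollutants), k)))
    return subsets


def summarize_fit(subset: tuple[str, ...], fit: FitResult, alpha: float = 0.05) -> CandidateResult:
    """Screen one converged fit: every pollutant CI must exclude 0 from above."""
    z = norm.ppf(1.0 - alpha / 2.0)
    coefs, ses, cis, sig = {}, {}, {}, {}
    for p in subset:
        c = fit.coef(p)
        s = fit.coef_se(p)
        coefs[p], ses[p] = c, s
        cis[p] = (c - z * s, c + z * s)
        sig[p] = bool(c - z * s > 0.0)
    status = ELIGIBLE if all(sig.values()) else EXCLUDED
    reason = "" if status == ELIGIBLE else (
        "non-significant or significantly negative: "
        + ", ".join(p for p, ok in sig.items() if not ok)
    )
    return CandidateResult(
        subset=tuple(subset),
        aic=fit.aic,
        coefs=coefs,
        ses=ses,
        cis=cis,
        significant_positive=sig,
        status=status,
        reason=reason,
    )


def fit_candidates(
    panel: PanelData,
    calendar: ExposureCalendar,
    graph: DistrictGraph | None,
    base_spec: ModelSpec,
    subsets: Sequence[tuple[str, ...]] | None = None,
    alpha: float = 0.05,
) -> list[CandidateResult]:
    """Fit one model per pollutant subset and screen each.

    Non-convergence excludes the candidate with a recorded reason instead of
    aborting the sweep.
    """
    if subsets is None:
        subsets = enumerate_subsets(
            [p for p in ("CO", "NOx", "O3", "PM10", "SO2") if p in panel.covariates.columns]
        )
    results = []
    for subset in subsets:
        spec = replace(base_spec, pollutants=tuple(subset))
        try:
            design = build_design(panel, calendar, graph, spec)
            fit = estimate_variances(design, spec)
        except ConvergenceError as exc:
            logger.warning("subset %s did not converge: %s", subset, exc)
            results.append(
                CandidateResult(
                    subset=tuple(subset),
                    aic=float("nan"),
                    status=EXCLUDED,
                    reason=f"did not converge: {exc}",
                )
            )
            continue
        results.append(summarize_fit(tuple(subset), fit, alpha=alpha))
        logger.info("subset %s aic=%.2f status=%s", subset, results[-1].aic, results[-1].status)
    return results


def staged_candidates(pollutants: Sequence[str], single_results: Sequence[CandidateResult]) -> list[tuple[str, ...]]:
    """The narrated staged strategy: keep significant singles, then build
    their two- and three-pollutant combinations."""
    keep = sorted(
        {r.subset[0] for r in single_results if len(r.subset) == 1 and r.status == ELIGIBLE}
    )
    out: list[tuple[str, ...]] = [(p,) for p in keep]
    for k in (2, 3):
        out.extend(sorted(combinations(keep, k)))
    return out


def rescreen(candidate: CandidateResult, alpha: float) -> CandidateResult:
    """Re-apply the positivity screen at a new significance level."""
    if not candidate.coefs or not np.isfinite(candidate.aic):
        return candidate  # non-converged stays excluded
    z = norm.ppf(1.0 - alpha / 2.0)
    cis = {}
    sig = {}
    for p, c in candidate.coefs.items():
        s = candidate.ses[p]
        cis[p] = (c - z * s, c + z * s)
        sig[p] = bool(c - z * s > 0.0)
    status = ELIGIBLE if all(sig.values()) else EXCLUDED
    reason = "" if status == ELIGIBLE else (
        "non-significant or significantly negative: "
        + ", ".join(p for p, ok in sig.items() if not ok)
    )
    return replace(
        candidate, cis=cis, significant_positive=sig, status=status, reason=reason
    )


def screen_and_rank(
    candidates: Sequence[CandidateResult], alpha: float = 0.05
) -> tuple[list[CandidateResult], CandidateResult | None]:
    """Rank eligible candidates by AIC; ties prefer the smaller subset.

    The positivity screen is re-evaluated at ``alpha`` from the stored
    coefficients; the selected model is the smallest-AIC survivor (``None``
    when nothing survives).
    """
    screened = [rescreen(c, alpha) for c in candidates]
    eligible = [c for c in screened if c.status == ELIGIBLE and np.isfinite(c.aic)]
    ranked = sorted(eligible, key=lambda c: (c.aic, len(c.subset), c.subset))
    selected = ranked[0] if ranked else None
    return ranked, selected
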