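"""Dose-response curve fitting and AAC summarization.

Viability as a function of dose is modelled with the three-parameter
Hill / log-logistic curve

    v(d) = e_inf + (1 - e_inf) / (1 + (d / EC50)^HS)

where ``e_inf`` is the lower viability asymptote in [0, 1], ``EC50`` the
dose of half-maximal effect and ``HS`` a positive Hill slope. The curve is
summarized by the area above the curve on the tested log10-dose range,
normalized so that AAC in [0, 1]; higher AAC means higher sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datasets import DoseResponseExperiment

__all__ = [
    "HillFit",
    "UnfittableError",
    "hill_viability",
    "preprocess_srb",
    "fit_hill",
    "compute_aac",
]


class UnfittableError(ValueError):
    """Raised when an experiment cannot produce a dose-response fit."""


@dataclass
class HillFit:
    """Fitted Hill curve parameters for one (cell line, drug) experiment."""

    ec50: float
    slope: float
    e_inf: float
    residual_sse: float
    converged: bool

    def viability(self, doses) -> np.ndarray:
        return hill_viability(np.asarray(doses, float), self.ec50, self.slope, self.e_inf)


def hill_viability(d, ec50: float, slope: float, e_inf: float):
    """Three-parameter Hill curve evaluated at dose(s) ``d``."""
    d = np.asarray(d, dtype=float)
    # computed on log-dose for numerical stability at extreme slopes
    t = slope * (np.log10(d) - np.log10(ec50))
    return e_inf + (1.0 - e_inf) / (1.0 + 10.0 ** np.clip(t, -300, 300))


def preprocess_srb(
    exp: DoseResponseExperiment, qc_threshold: float = 0.2
) -> tuple[DoseResponseExperiment, int]:
    """Normalize an SRB plate and apply replicate-agreement quality control.

    Steps, in order:

    1. subtract the mean blank (cell-free PBS well) signal from every well;
    2. divide treated wells by the mean blank-corrected control signal,
       yielding viabilities on a 0-1 scale;
    3. discard any dose whose replicate set has standard deviation > ``qc_threshold``
       or coefficient of variation > ``qc_threshold`` (both computed on the
       normalized viabilities).

    Returns the filtered, normalized experiment and the number of discarded
    doses. Idempotent: a second application is the identity (blanks are zeroed
    and controls normalized on the first pass).

    Raises
    ------
    UnfittableError
        if controls/blanks are missing, the mean control signal is not
        positive, or every dose fails quality control.
    """
    if exp.normalized:
        blank_mean = float(exp.blank_wells.mean()) if exp.blank_wells.size else 0.0
    else:
        if exp.blank_wells.size == 0 or exp.control_wells.size == 0:
            raise UnfittableError("blank and control wells required for SRB preprocessing")
        blank_mean = float(exp.blank_wells.mean())
    control = exp.control_wells - blank_mean
    control_mean = float(control.mean()) if control.size else 1.0
    if control_mean <= 0:
        raise UnfittableError("mean control signal is not positive after blank subtraction")

    viab = (exp.viabilities - blank_mean) / control_mean

    sd = np.nanstd(viab, axis=0, ddof=1) if viab.shape[0] > 1 else np.zeros(viab.shape[1])
    sd = np.nan_to_num(sd, nan=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.nanmean(viab, axis=0)
        cv = np.where(mean != 0, sd / np.abs(mean), np.inf * (sd > 0))
    bad = (sd > qc_threshold) | (cv > qc_threshold)
    n_discarded = int(bad.sum())
    if n_discarded == viab.shape[1]:
        raise UnfittableError("all doses discarded by quality control")

    keep = ~bad
    out = exp.replace(
        doses=exp.doses[keep],
        viabilities=viab[:, keep],
        control_wells=control / control_mean,
        blank_wells=exp.blank_wells - blank_mean,
        normalized=True,
    )
    return out, n_discarded


# Multi-start grid: EC50 anchored at the dose-range ends and the median dose,
# slopes spanning shallow to steep, e_inf at full and partial efficacy.
_SLOPE_STARTS = (0.5, 1.0, 2.0)
_EINF_STARTS = (0.0, 0.5)


def fit_hill(exp: DoseResponseExperiment, viability_cap: float = 1.2) -> HillFit:
    """Least-squares Hill fit on log10 dose with multi-start initialization.

    Requires a normalized experiment (run :func:`preprocess_srb` first when
    starting from raw signal) with at least 3 distinct usable doses.
    Viabilities are clipped to [0, ``viability_cap``] before fitting so that
    modest growth above control is tolerated. The start with the smallest
    residual sum of squares wins; ties go to the smallest Hill slope.
    Deterministic for fixed input.
    """
    if not exp.normalized:
        exp, _ = preprocess_srb(exp)
    usable = ~np.all(np.isnan(exp.viabilities), axis=0)
    doses = exp.doses[usable]
    if np.unique(doses).size < 3:
        raise UnfittableError("need at least 3 distinct usable doses")
    viab = np.clip(exp.viabilities[:, usable], 0.0, viability_cap)

    d_min_, d_max_ = float(doses[0]), float(doses[-1])
    dose_means = np.nanmean(viab, axis=0)
    if np.ptp(dose_means) < 1e-9:
        # flat response: the curve parameters are unidentifiable; pin the
        # level on e_inf with the decline pushed below the dose range, and
        # flag the degeneracy via converged=False
        level = float(np.clip(np.nanmean(dose_means), 0.0, 1.0))
        sse = float(np.nansum((viab - level) ** 2))
        return HillFit(ec50=d_min_ * 1e-3, slope=20.0, e_inf=level, residual_sse=sse, converged=False)

    d_flat = np.repeat(doses[None, :], viab.shape[0], axis=0).ravel()
    v_flat = viab.ravel()
    ok = np.isfinite(v_flat)
    d_flat, v_flat = d_flat[ok], v_flat[ok]
    log_d = np.log10(d_flat)

    d_min, d_max = float(doses[0]), float(doses[-1])
    # EC50 guarded within 10^+/-3 of the tested dose range
    lo = np.array([np.log10(d_min) - 3.0, 0.05, 0.0])
    hi = np.array([np.log10(d_max) + 3.0, 20.0, 1.0])

    def residuals(theta):
        log_ec50, slope, e_inf = theta
        t = np.clip(slope * (log_d - log_ec50), -300, 300)
        return e_inf + (1.0 - e_inf) / (1.0 + 10.0**t) - v_flat

    ec50_starts = (d_min, float(np.median(doses)), d_max)
    results = []
    for ec50_0 in ec50_starts:
        for slope_0 in _SLOPE_STARTS:
            for einf_0 in _EINF_STARTS:
                x0 = np.clip(np.array([np.log10(ec50_0), slope_0, einf_0]), lo, hi)
                try:
                    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
                except Exception:
                    continue
                sse = float(2.0 * sol.cost)
                results.append((sse, float(sol.x[1]), sol))
        # noiseless data: stop once a start lands on an essentially perfect fit
        if results and min(r[0] for r in results) < 1e-16:
            break
    if not results:
        raise UnfittableError("all fit starts diverged")

    best_sse = min(r[0] for r in results)
    tol = best_sse * 1e-9 + 1e-15
    sse, slope, sol = min(
        (r for r in results if r[0] <= best_sse + tol), key=lambda r: (r[1], r[0])
    )
    log_ec50, slope, e_inf = sol.x
    return HillFit(
        ec50=float(10.0**log_ec50),
        slope=float(slope),
        e_inf=float(e_inf),
        residual_sse=sse,
        converged=bool(sol.success),
    )


def compute_aac(fit: HillFit, dose_range: tuple[float, float], n_points: int = 2001) -> float:
    """Area above the fitted curve over a log10-dose range, in [0, 1].

    AUC is the mean fitted viability over log10 dose on [d_min, d_max]
    (composite Simpson rule, ``n_points`` >= 1001 grid points); AAC = 1 - AUC,
    clipped to [0, 1].
    """
    d_min, d_max = dose_range
    if not (0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    n_points = max(int(n_points), 1001)
    if n_points % 2 == 0:
        n_points += 1
    x = np.linspace(np.log10(d_min), np.log10(d_max), n_points)
    v = np.clip(fit.viability(10.0**x), 0.0, 1.0)
    from scipy.integrate import simpson

    auc = simpson(v, x=x) / (x[-1] - x[0])
    return float(np.clip(1.0 - auc, 0.0, 1.0))
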