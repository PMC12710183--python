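"""Linear free-energy relationship (LFER) analyses.

All fits are unweighted ordinary least squares on base-10 logarithms of
rate constants, the convention of the field:

* Hammett:       log k1 = intercept + rho * sigma          (or sigma+)
* Yukawa-Tsuno:  log k1 = intercept + rho * [sigma + r (sigma+ - sigma)]
* Mayr-Patz:     log k  = s_N (E + N)   =>  OLS of log k1 on E gives
                 slope s_N and intercept s_N * N, hence N = intercept / s_N
* N vs sigma+:   N = intercept + slope * sigma+, the predictive model for
                 ring-substituted analogs.

The Yukawa-Tsuno resonance-demand parameter r enters multiplicatively with
rho; the default "joint-bilinear" method linearises by fitting the two
regressors (sigma, sigma+ - sigma) jointly and taking r as the coefficient
ratio, which is the global least-squares optimum.  A "grid-conditional"
scan over r is kept as a diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import linregress

from .records import ElectrophileRecord, PredictionRecord

__all__ = [
    "HammettFit",
    "YukawaTsunoFit",
    "MayrFit",
    "SigmaPlusModel",
    "average_log_rate",
    "hammett_fit",
    "yukawa_tsuno_fit",
    "mayr_fit",
    "n_from_single_rate",
    "fit_sigma_plus_model",
    "predict_N",
    "predict_rate",
    "validate_predictions",
    "MAYR_CONFIDENCE_FACTOR",
]

#: Accepted deviation factor between predicted and measured rate constants
#: in the Mayr reactivity-scale framework.
MAYR_CONFIDENCE_FACTOR = 100.0


@dataclass(frozen=True)
class HammettFit:
    rho: float
    intercept: float
    r2: float
    scale_used: str
    n_points: int


@dataclass(frozen=True)
class YukawaTsunoFit:
    rho: float
    r: float
    intercept: float
    r2: float
    sse: float
    method: str
    r_identifiable: bool = True


@dataclass(frozen=True)
class MayrFit:
    s_N: float
    N: float
    intercept: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class SigmaPlusModel:
    slope: float
    intercept: float
    r2: float
    n_points: int


def average_log_rate(record: ElectrophileRecord, deuterio: bool = False) -> float:
    """Mean of log10 k1 over the available pH values.

    k1 is pH-independent by construction, so averaging the two pH
    determinations is the natural single number per electrophile.
    """
    k1s = record.k1_values(deuterio=deuterio)
    if not k1s:
        raise ValueError(f"record {record.label}: no k1 value present")
    return float(np.mean([math.log10(v) for v in k1s.values()]))


def _check_lengths(*arrays, minimum: int) -> None:
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("input lists must have equal lengths")
    if n < minimum:
        raise ValueError(f"need at least {minimum} points, got {n}")


def hammett_fit(
    log_k: Sequence[float], sigma: Sequence[float], scale: str = "sigma"
) -> HammettFit:
    """OLS Hammett fit: slope is the reaction constant rho."""
    _check_lengths(log_k, sigma, minimum=3)
    res = linregress(np.asarray(sigma, float), np.asarray(log_k, float))
    return HammettFit(
        rho=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        scale_used=scale,
        n_points=len(log_k),
    )


def _yt_sse(log_k, sigma, sigma_plus, rho, r, intercept) -> float:
    pred = intercept + rho * (sigma + r * (sigma_plus - sigma))
    return float(np.sum((log_k - pred) ** 2))


def yukawa_tsuno_fit(
    log_k: Sequence[float],
    sigma: Sequence[float],
    sigma_plus: Sequence[float],
    method: str = "joint-bilinear",
    grid: Tuple[float, float, float] = (-1.0, 3.0, 0.01),
) -> YukawaTsunoFit:
    """Fit log k = intercept + rho [sigma + r (sigma+ - sigma)].

    ``joint-bilinear``: two-regressor OLS on (sigma, sigma+ - sigma) with
    coefficients b1 = rho, b2 = rho*r, so r = b2/b1; this attains the
    global minimum SSE of the three-parameter model.

    ``grid-conditional``: scan r over ``grid`` = (lo, hi, step); at each r
    do a one-regressor OLS on the effective constant
    sigma_eff = sigma + r (sigma+ - sigma), and keep the r of least SSE.

    When sigma+ == sigma for every point r is unidentifiable: the joint
    method raises, the grid method returns the plain Hammett fit flagged
    ``r_identifiable=False``.
    """
    _check_lengths(log_k, sigma, sigma_plus, minimum=4)
    y = np.asarray(log_k, float)
    s = np.asarray(sigma, float)
    sp = np.asarray(sigma_plus, float)
    resonance = sp - s
    degenerate = np.allclose(resonance, 0.0)

    if method == "joint-bilinear":
        if degenerate:
            raise ValueError(
                "sigma+ equals sigma for every point: resonance term vanishes "
                "and r is undefined (use grid-conditional for the degenerate fit)"
            )
        X = np.column_stack([np.ones_like(s), s, resonance])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercept, b1, b2 = (float(b) for b in beta)
        if b1 == 0.0:
            raise ValueError("rho = 0 in joint fit: r = rho*r / rho is undefined")
        rho, r = b1, b2 / b1
        fitted = X @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        sse = float(np.sum((y - fitted) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - sse / ss_tot
        return YukawaTsunoFit(
            rho=rho, r=r, intercept=intercept, r2=r2, sse=sse, method=method
        )

    if method == "grid-conditional":
        if degenerate:
            h = hammett_fit(y, s)
            sse = _yt_sse(y, s, sp, h.rho, 0.0, h.intercept)
            return YukawaTsunoFit(
                rho=h.rho,
                r=0.0,
                intercept=h.intercept,
                r2=h.r2,
                sse=sse,
                method=method,
                r_identifiable=False,
            )
        lo, hi, step = grid
        best = None
        for r_try in np.arange(lo, hi + step / 2, step):
            sigma_eff = s + r_try * resonance
            if np.ptp(sigma_eff) == 0:
                continue
            res = linregress(sigma_eff, y)
            sse = _yt_sse(y, s, sp, res.slope, r_try, res.intercept)
            if best is None or sse < best[0]:
                best = (sse, float(r_try), float(res.slope), float(res.intercept),
                        float(res.rvalue**2))
        assert best is not None
        sse, r_best, rho, intercept, r2 = best
        return YukawaTsunoFit(
            rho=rho, r=r_best, intercept=intercept, r2=r2, sse=sse, method=method
        )

    raise ValueError(f"unknown method {method!r}")


def mayr_fit(log_k1: Sequence[float], E: Sequence[float]) -> MayrFit:
    """Nucleophile parameters (s_N, N) from rates against reference
    electrophiles of known E: OLS slope is s_N, and N = intercept / s_N."""
    _check_lengths(log_k1, E, minimum=3)
    res = linregress(np.asarray(E, float), np.asarray(log_k1, float))
    if res.slope <= 0:
        raise ValueError(
            "nucleophile-electrophile scale inverted: fitted sensitivity "
            f"s_N = {res.slope:.3g} <= 0"
        )
    return MayrFit(
        s_N=float(res.slope),
        N=float(res.intercept / res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=len(log_k1),
    )


def n_from_single_rate(k: float, E: float, s_N: float = 1.0) -> float:
    """N from one rate constant against one reference electrophile:
    N = log10(k) / s_N - E.  The s_N = 1 convention is the standard
    single-rate estimate."""
    if not k > 0:
        raise ValueError("k must be positive")
    return math.log10(k) / s_N - E


def fit_sigma_plus_model(
    N: Sequence[float], sigma_plus: Sequence[float]
) -> SigmaPlusModel:
    """OLS of nucleophilicity N on the sigma+ constant of the ring
    substituent — the predictive structure-reactivity model."""
    _check_lengths(N, sigma_plus, minimum=3)
    sp = np.asarray(sigma_plus, float)
    if np.ptp(sp) == 0:
        raise ValueError("all sigma+ values identical: slope is undetermined")
    res = linregress(sp, np.asarray(N, float))
    return SigmaPlusModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=len(N),
    )


def predict_N(
    model: SigmaPlusModel, sigma_plus: float, coefficient_precision: Optional[int] = 2
) -> float:
    """Predicted N at a given sigma+.

    By default the model's coefficients are used at their reporting
    precision (2 decimals): the published correlation equation is the
    deliverable, and downstream rate predictions chain from its printed
    coefficients.  Pass ``coefficient_precision=None`` to evaluate the
    unrounded fitted line.
    """
    if coefficient_precision is None:
        slope, intercept = model.slope, model.intercept
    else:
        slope = round(model.slope, coefficient_precision)
        intercept = round(model.intercept, coefficient_precision)
    return intercept + slope * sigma_plus


def predict_rate(N: float, s_N: float, E: float) -> float:
    """Rate constant from the Mayr-Patz relation: k = 10^(s_N (E + N))."""
    for name, v in (("N", N), ("s_N", s_N), ("E", E)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    return 10.0 ** (s_N * (E + N))


def validate_predictions(
    k_exp: Sequence[float],
    k_calc: Sequence[float],
    names: Optional[Sequence[str]] = None,
    N_pred: Optional[Sequence[float]] = None,
    E: Optional[float] = None,
    confidence_factor: float = MAYR_CONFIDENCE_FACTOR,
) -> Tuple[list[PredictionRecord], bool]:
    """Experimental/calculated ratios and the reactivity-scale verdict.

    The flag is true when every ratio, taken as the deviation factor
    max(ratio, 1/ratio), stays within ``confidence_factor`` (the accepted
    tolerance of rate predictions on the Mayr scale).
    """
    _check_lengths(k_exp, k_calc, minimum=1)
    if names is None:
        names = [f"nucleophile_{i + 1}" for i in range(len(k_exp))]
    records = []
    within = True
    for i, (ke, kc) in enumerate(zip(k_exp, k_calc)):
        if not (ke > 0 and kc > 0):
            raise ValueError(f"non-positive rate constant in pair {i}")
        ratio = ke / kc
        if max(ratio, 1.0 / ratio) > confidence_factor:
            within = False
        records.append(
            PredictionRecord(
                nucleophile_name=names[i],
                k_exp=ke,
                k_calc=kc,
                ratio=ratio,
                N_pred=None if N_pred is None else N_pred[i],
                E=E,
            )
        )
    return records, within
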