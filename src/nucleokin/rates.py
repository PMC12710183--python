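"""Rate-constant extraction from stopped-flow traces.

Stages, mirroring the experimental workflow:

1. ``fit_kobsd`` — pseudo-first-order relaxation rate from one trace,
   either by the linearised log-transform ln(A_inf - A_t) = -k_obsd t +
   ln(A_inf - A0) or by direct nonlinear exponential fitting.
2. ``fit_bimolecular`` — apparent second-order constant k as the slope of
   k_obsd against total nucleophile concentration at one pH.
3. ``to_k1`` — speciation correction to the free-base constant
   k1 = k (1 + 10^(pKa - pH)), pH-independent by construction.
4. ``kie_ratios`` — protio/deuterio rate ratios; values near 1 mean the
   C-H bond is untouched in the rate-determining step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .mechanism import Campaign, free_base_fraction
from .records import AbsorbanceTrace, RateMeasurement

__all__ = [
    "fit_kobsd",
    "fit_bimolecular",
    "to_k1",
    "kie_ratios",
    "BimolecularFit",
    "extract_campaign_rates",
]

_MIN_POINTS = 5


@dataclass(frozen=True)
class BimolecularFit:
    """OLS of k_obsd vs total nucleophile concentration at a single pH.

    The slope is the apparent second-order constant k (M^-1 s^-1); a
    near-zero intercept is the internal consistency check of the
    pseudo-first-order rate law.
    """

    k: float
    intercept: float
    r2: float
    pH: float
    n_points: int


def _r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def fit_kobsd(
    trace: AbsorbanceTrace,
    method: str = "guggenheim-linear",
    a_inf: Optional[float] = None,
    estimate_a_inf: bool = False,
) -> Tuple[float, float]:
    """Relaxation rate k_obsd (s^-1) and fit r^2 from one trace.

    ``method`` is ``"guggenheim-linear"`` (regress ln|A_inf - A_t| on t,
    k_obsd = -slope) or ``"exp-nonlinear"`` (least-squares fit of the full
    exponential with A0, A_inf and k_obsd free).  ``a_inf`` overrides the
    trace's recorded endpoint; ``estimate_a_inf`` instead takes the mean of
    the final 5% of points.  Points at or past the endpoint (log of a
    non-positive number) are dropped with a warning.
    """
    if len(trace) < _MIN_POINTS:
        raise ValueError(f"need at least {_MIN_POINTS} points, got {len(trace)}")
    t = trace.times
    a = trace.absorbances
    if estimate_a_inf:
        tail = max(1, int(round(0.05 * len(a))))
        A_inf = float(np.mean(a[-tail:]))
    else:
        A_inf = trace.A_inf if a_inf is None else a_inf

    if method == "guggenheim-linear":
        sign = 1.0 if A_inf >= trace.A0 else -1.0
        resid = sign * (A_inf - a)
        beyond = resid <= 0
        if np.any(beyond):
            warnings.warn(
                f"dropping {int(np.sum(beyond))} point(s) at or beyond A_inf "
                "before log-linear fit",
                stacklevel=2,
            )
        # points within 0.5% of the endpoint carry exponentially amplified
        # A_inf error under the log transform; trim them like the
        # beyond-endpoint points (routine, so no warning)
        usable = resid > 0.005 * abs(A_inf - trace.A0)
        if int(np.sum(usable)) < _MIN_POINTS:
            raise ValueError(
                f"fewer than {_MIN_POINTS} usable points after dropping "
                "points beyond A_inf"
            )
        res = linregress(t[usable], np.log(resid[usable]))
        kobsd = -res.slope
        if not kobsd > 0:
            raise ValueError("no relaxation detected (non-negative log-linear slope)")
        return float(kobsd), float(res.rvalue**2)

    if method == "exp-nonlinear":
        # initial guesses from the data; rate from a rough log-linear pass
        try:
            k0, _ = fit_kobsd(trace, method="guggenheim-linear", a_inf=A_inf)
        except ValueError:
            k0 = 1.0 / max(t[-1] - t[0], np.finfo(float).tiny)

        def model(tt, A0, Ainf, k):
            return Ainf - (Ainf - A0) * np.exp(-k * tt)

        popt, _ = curve_fit(model, t, a, p0=[a[0], A_inf, k0], maxfev=10000)
        kobsd = float(popt[2])
        if not kobsd > 0:
            raise ValueError("no relaxation detected (non-positive fitted rate)")
        return kobsd, _r2(a, model(t, *popt))

    raise ValueError(f"unknown method {method!r}")


def fit_bimolecular(measurements: Sequence[RateMeasurement]) -> BimolecularFit:
    """Apparent second-order constant from a concentration series at one pH.

    Ordinary least squares of k_obsd on total nucleophile concentration;
    the intercept is fitted, not forced through zero, as a diagnostic of
    the expected zero-intercept rate law.
    """
    if len(measurements) < 3:
        raise ValueError("need at least 3 measurements")
    ph_values = {m.pH for m in measurements}
    if len(ph_values) != 1:
        raise ValueError(f"measurements span multiple pH values: {sorted(ph_values)}")
    conc = np.array([m.nucleophile_total_conc for m in measurements])
    kobs = np.array([m.kobsd for m in measurements])
    if len(np.unique(conc)) < 2:
        raise ValueError("all concentrations identical: slope is undetermined")
    res = linregress(conc, kobs)
    return BimolecularFit(
        k=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        pH=ph_values.pop(),
        n_points=len(measurements),
    )


def to_k1(k: float, pH: float, pKa: float = 3.38) -> float:
    """Speciation-corrected second-order constant for the free-base
    nucleophile: k1 = k (1 + 10^(pKa - pH)) = k / f(pH, pKa)."""
    if not k > 0:
        raise ValueError("k must be positive")
    return k / free_base_fraction(pH, pKa)


def kie_ratios(
    protio_k1: Mapping, deuterio_k1: Mapping
) -> Tuple[dict, Tuple[float, float]]:
    """Elementwise kinetic-isotope-effect ratios kH/kD on matched keys.

    Both mappings must be keyed identically (conventionally by
    (electrophile label, pH)); every deuterio entry must have a protio
    partner and vice versa.  Returns the ratio per key and the (min, max)
    summary.
    """
    unpaired = set(protio_k1) ^ set(deuterio_k1)
    if unpaired:
        raise ValueError(f"unpaired isotope entries for key(s): {sorted(unpaired)}")
    if not protio_k1:
        raise ValueError("no isotope pairs supplied")
    ratios = {key: protio_k1[key] / deuterio_k1[key] for key in protio_k1}
    values = list(ratios.values())
    return ratios, (min(values), max(values))


def extract_campaign_rates(
    campaign: Campaign,
    method: str = "guggenheim-linear",
    pKa: Optional[float] = None,
) -> pd.DataFrame:
    """Run the full extraction chain on a synthetic campaign.

    Per (electrophile label, pH): fit every trace's k_obsd, regress against
    concentration, and speciation-correct the slope.  Returns a tidy frame
    with columns label, pH, k, intercept, r2, n, k1.
    """
    if pKa is None:
        pKa = campaign.manifest["truth"]["pKa"]
    groups: dict[tuple, list[RateMeasurement]] = {}
    for ct in campaign.traces:
        kobsd, r2 = fit_kobsd(ct.trace, method=method)
        groups.setdefault((ct.label, ct.trace.pH), []).append(
            RateMeasurement(
                nucleophile_total_conc=ct.trace.nucleophile_total_conc,
                kobsd=kobsd,
                pH=ct.trace.pH,
                fit_r2=min(r2, 1.0),
            )
        )
    rows = []
    for (label, ph), ms in sorted(groups.items()):
        fit = fit_bimolecular(ms)
        rows.append(
            {
                "label": label,
                "pH": ph,
                "k": fit.k,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "n": fit.n_points,
                "k1": to_k1(fit.k, ph, pKa),
            }
        )
    return pd.DataFrame(rows)
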