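"""Core record types shared across the kinetics and LFER modules.

Absent quantities (a rate that was not measured, an electrophilicity that
was never tabulated) are encoded as ``None``, never as 0 or NaN, so that
downstream fits skip them instead of silently corrupting a regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ElectrophileRecord",
    "NucleophileRecord",
    "PredictionRecord",
    "RateMeasurement",
    "MechanismParameters",
    "ExperimentDesign",
    "AbsorbanceTrace",
]


def _require_positive(name: str, value: Optional[float]) -> None:
    if value is not None and not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ElectrophileRecord:
    """One benzenediazonium electrophile with its substituent constants and
    measured second-order rate constants.

    ``k_*`` are apparent constants referred to the total nucleophile
    concentration at the stated pH; ``k1_*`` are the speciation-corrected
    constants referred to the free-base nucleophile (pH-independent).
    ``*_deuterio_*`` are the values measured with the 2-deuterio nucleophile.
    """

    label: str
    substituent: str
    sigma_p: Optional[float] = None
    sigma_p_plus: Optional[float] = None
    E: Optional[float] = None
    k_pH2: Optional[float] = None
    k1_pH2: Optional[float] = None
    k_pH1: Optional[float] = None
    k1_pH1: Optional[float] = None
    k_deuterio_pH2: Optional[float] = None
    k1_deuterio_pH2: Optional[float] = None
    k_deuterio_pH1: Optional[float] = None
    k1_deuterio_pH1: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("k"):
                _require_positive(f.name, getattr(self, f.name))
        # speciation correction multiplies by (1 + 10^(pKa-pH)) >= 1
        for k, k1 in ((self.k_pH2, self.k1_pH2), (self.k_pH1, self.k1_pH1)):
            if k is not None and k1 is not None and k1 < k:
                raise ValueError(
                    f"record {self.label}: corrected k1 ({k1}) below apparent k ({k})"
                )

    def k1_values(self, deuterio: bool = False) -> dict[float, float]:
        """Available speciation-corrected constants keyed by pH."""
        if deuterio:
            pairs = {1.0: self.k1_deuterio_pH1, 2.0: self.k1_deuterio_pH2}
        else:
            pairs = {1.0: self.k1_pH1, 2.0: self.k1_pH2}
        return {ph: v for ph, v in pairs.items() if v is not None}


@dataclass(frozen=True)
class NucleophileRecord:
    """A carbon nucleophile characterised against a reference electrophile.

    ``k_ref`` is the second-order rate constant toward the reference
    electrophile of electrophilicity ``E_ref``; ``N`` is the nucleophilicity
    estimated from a single rate (sensitivity ``s_N``); ``N_exp`` holds a
    directly measured N when one exists.
    """

    name: str
    sigma_plus_C3: Optional[float] = None
    k_ref: Optional[float] = None
    E_ref: Optional[float] = None
    N: Optional[float] = None
    s_N: Optional[float] = None
    N_exp: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("k_ref", self.k_ref)
        if self.N is not None and not np.isfinite(self.N):
            raise ValueError(f"{self.name}: N must be finite")

    @property
    def best_N(self) -> Optional[float]:
        """Experimental N when measured, single-rate estimate otherwise."""
        return self.N_exp if self.N_exp is not None else self.N


@dataclass(frozen=True)
class PredictionRecord:
    """An experimental vs calculated rate-constant comparison for one
    nucleophile against a test electrophile."""

    nucleophile_name: str
    k_exp: float
    k_calc: float
    ratio: float
    N_pred: Optional[float] = None
    E: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("k_exp", self.k_exp)
        _require_positive("k_calc", self.k_calc)
        _require_positive("ratio", self.ratio)


@dataclass(frozen=True)
class RateMeasurement:
    """One (total nucleophile concentration, k_obsd) point at a stated pH."""

    nucleophile_total_conc: float
    kobsd: float
    pH: float
    fit_r2: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("nucleophile_total_conc", self.nucleophile_total_conc)
        _require_positive("kobsd", self.kobsd)
        if self.fit_r2 is not None and not 0.0 <= self.fit_r2 <= 1.0 + 1e-12:
            raise ValueError(f"fit_r2 out of [0, 1]: {self.fit_r2}")


@dataclass(frozen=True)
class MechanismParameters:
    """Ground-truth rate constants of the two-step electrophilic aromatic
    substitution: bimolecular addition (k1_true), reversion (k_minus1) and
    re-aromatization (k2), plus the nucleophile conjugate-acid pKa."""

    k1_true: float
    k_minus1: float
    k2: float
    pKa: float = 3.38

    def __post_init__(self) -> None:
        _require_positive("k1_true", self.k1_true)
        if self.k2 < 0 or self.k_minus1 < 0:
            raise ValueError("k_minus1 and k2 must be non-negative")
        if self.k_minus1 + self.k2 == 0:
            raise ValueError("sigma-complex needs at least one decay channel")
        if not np.isfinite(self.pKa):
            raise ValueError("pKa must be finite")

    @property
    def partition_factor(self) -> float:
        """Fraction of the sigma-complex that proceeds to product."""
        return self.k2 / (self.k_minus1 + self.k2)


@dataclass(frozen=True)
class ExperimentDesign:
    """A stopped-flow campaign layout: concentration ladder, pH, sampling
    grid and absorbance/noise model.

    ``time_grid=None`` means each trace gets an automatic grid of
    ``n_points`` samples spanning ``span_relaxations / k_obsd`` (five
    relaxation times captures >99% of the amplitude).
    """

    nucleophile_total_concs: Sequence[float] = (0.004, 0.010, 0.016, 0.022, 0.028)
    electrophile_conc: float = 5e-5
    pH: float = 2.0
    time_grid: Optional[np.ndarray] = None
    A0: float = 0.02
    A_inf: float = 0.80
    noise_sd: float = 0.002
    seed: int = 0
    n_points: int = 200
    span_relaxations: float = 5.0

    def __post_init__(self) -> None:
        _require_positive("electrophile_conc", self.electrophile_conc)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for c in self.nucleophile_total_concs:
            if c < 20.0 * self.electrophile_conc:
                raise ValueError(
                    "pseudo-first-order regime requires nucleophile excess "
                    f">= 20x electrophile; got {c} vs {self.electrophile_conc}"
                )
        if self.time_grid is not None:
            t = np.asarray(self.time_grid, dtype=float)
            if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
                raise ValueError("time_grid must be 1-D and strictly increasing")
            object.__setattr__(self, "time_grid", t)

    def times_for(self, kobsd: float) -> np.ndarray:
        if self.time_grid is not None:
            return self.time_grid
        return np.linspace(0.0, self.span_relaxations / kobsd, self.n_points)


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A single stopped-flow run: absorbance vs time with its endpoints.

    ``true_kobsd`` is populated only for synthetic traces and carries the
    generating relaxation rate for recovery tests.
    """

    times: np.ndarray
    absorbances: np.ndarray
    A0: float
    A_inf: float
    pH: float
    nucleophile_total_conc: float
    true_kobsd: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or len(t) != len(a):
            raise ValueError("times and absorbances must be 1-D of equal length")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)

    def __len__(self) -> int:
        return len(self.times)
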