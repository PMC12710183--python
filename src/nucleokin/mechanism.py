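"""Simulation of the two-step electrophilic aromatic substitution mechanism.

The ground-truth model is the classic S_EAr scheme: bimolecular addition of
the electrophile E+ to the free-base nucleophile Nu (rate constant k1),
giving a cationic Wheland sigma-complex I+ that either reverts (k-1) or
re-aromatizes to product (k2)::

    Nu + E+  <--k1/k-1-->  I+  --k2-->  product

Only the free base reacts; at pH well below the conjugate-acid pKa the
operative nucleophile concentration is the total concentration scaled by the
free-base fraction f = 1 / (1 + 10^(pKa - pH)).  Under pseudo-first-order
conditions (nucleophile in >= 20-fold excess) the quasi-steady-state
treatment of I+ gives a single-exponential relaxation with

    k_obsd = k1 * k2 / (k-1 + k2) * f * [Nu]_total

which reduces to k_obsd = k1 * f * [Nu]_total when re-aromatization is fast
(k2 >> k-1), the regime the kinetic isotope analysis establishes.

The generator emits stopped-flow absorbance traces
A(t) = A_inf - (A_inf - A0) * exp(-k_obsd * t) with i.i.d. Gaussian noise,
and full campaigns (electrophile x concentration x pH) whose ground-truth
rate constants follow the Mayr-Patz relation log k1 = s_N (E + N), so the
entire downstream inference chain is testable by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .records import AbsorbanceTrace, ExperimentDesign, MechanismParameters

__all__ = [
    "free_base_fraction",
    "steady_state_kobsd",
    "simulate_mechanism_ode",
    "generate_trace",
    "generate_campaign",
    "CampaignTruth",
    "Campaign",
    "CampaignTrace",
    "MechanismTrajectory",
    "write_campaign",
    "read_campaign",
]


def free_base_fraction(pH: float, pKa: float) -> float:
    """Fraction of the nucleophile present as reactive free base.

    f = 1 / (1 + 10^(pKa - pH)); 0.5 at half-neutralization, -> 1 far above
    the pKa.
    """
    if not (np.isfinite(pH) and np.isfinite(pKa)):
        raise ValueError("pH and pKa must be finite")
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def steady_state_kobsd(
    params: MechanismParameters, nucleophile_total_conc: float, pH: float
) -> float:
    """Quasi-steady-state pseudo-first-order rate constant (s^-1).

    k_obsd = k1 * k2/(k-1 + k2) * f(pH, pKa) * [Nu]_total.  With k-1 = 0 the
    partition factor is 1 and the simplified limit k_obsd = k1 * f * [Nu]
    is exact.
    """
    if not nucleophile_total_conc > 0:
        raise ValueError("nucleophile_total_conc must be positive")
    f = free_base_fraction(pH, params.pKa)
    return params.k1_true * params.partition_factor * f * nucleophile_total_conc


@dataclass(frozen=True)
class MechanismTrajectory:
    """Concentration trajectories from the full (non-QSSA) rate equations."""

    times: np.ndarray
    electrophile: np.ndarray
    intermediate: np.ndarray
    product: np.ndarray
    electrophile_0: float

    def mass_balance_error(self) -> float:
        total = self.electrophile + self.intermediate + self.product
        return float(np.max(np.abs(total - self.electrophile_0)))


def simulate_mechanism_ode(
    params: MechanismParameters,
    design: ExperimentDesign,
    conc_index: int = 0,
    time_grid: Optional[np.ndarray] = None,
) -> MechanismTrajectory:
    """Integrate the full two-step mechanism without the QSSA.

    The nucleophile is clamped at its free-base concentration
    (pseudo-first-order excess), so the system is linear:

        d[E]/dt = -ka [E] + k-1 [I]
        d[I]/dt =  ka [E] - (k-1 + k2) [I]
        d[P]/dt =  k2 [I]

    with ka = k1 * f * [Nu]_total.  Mass balance [E]+[I]+[P] = [E]0 is
    preserved to integrator tolerance (~1e-12 absolute here).
    """
    conc = design.nucleophile_total_concs[conc_index]
    f = free_base_fraction(design.pH, params.pKa)
    ka = params.k1_true * f * conc
    kobsd = steady_state_kobsd(params, conc, design.pH)
    if time_grid is None:
        time_grid = design.times_for(kobsd)
    time_grid = np.asarray(time_grid, dtype=float)
    e0 = design.electrophile_conc

    def rhs(_t, y):
        e, i, _p = y
        return [
            -ka * e + params.k_minus1 * i,
            ka * e - (params.k_minus1 + params.k2) * i,
            params.k2 * i,
        ]

    sol = solve_ivp(
        rhs,
        (time_grid[0], time_grid[-1]),
        [e0, 0.0, 0.0],
        t_eval=time_grid,
        method="LSODA",
        rtol=1e-11,
        atol=1e-16 * e0,
    )
    if not sol.success:
        raise RuntimeError(f"mechanism ODE integration failed: {sol.message}")
    return MechanismTrajectory(
        times=sol.t,
        electrophile=sol.y[0],
        intermediate=sol.y[1],
        product=sol.y[2],
        electrophile_0=e0,
    )


def generate_trace(
    kobsd: float,
    design: ExperimentDesign,
    nucleophile_total_conc: float,
    seed: Optional[Union[int, np.random.Generator, np.random.SeedSequence]] = None,
) -> AbsorbanceTrace:
    """One noisy single-exponential stopped-flow trace.

    A(t) = A_inf - (A_inf - A0) exp(-k_obsd t) + N(0, noise_sd^2), i.i.d.
    per point.  Deterministic for a fixed seed; the generating rate is
    recorded on the trace as ``true_kobsd``.
    """
    if not kobsd > 0:
        raise ValueError("kobsd must be positive")
    if design.A_inf == design.A0:
        raise ValueError("degenerate trace: A_inf equals A0 (no relaxation amplitude)")
    times = design.times_for(kobsd)
    clean = design.A_inf - (design.A_inf - design.A0) * np.exp(-kobsd * times)
    if design.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, design.noise_sd, size=times.shape)
    return AbsorbanceTrace(
        times=times,
        absorbances=clean,
        A0=design.A0,
        A_inf=design.A_inf,
        pH=design.pH,
        nucleophile_total_conc=nucleophile_total_conc,
        true_kobsd=kobsd,
    )


@dataclass(frozen=True)
class CampaignTruth:
    """Ground truth for a synthetic study: the Mayr-Patz parameters of the
    nucleophile and the electrophilicity of every electrophile screened.

    ``electrophiles`` maps label -> E.  Per-electrophile free-base rate
    constants follow log10 k1 = s_N (E + N).
    """

    N_true: float
    sN_true: float
    electrophiles: dict[str, float]
    pKa: float = 3.38
    sigma_p: dict[str, float] = field(default_factory=dict)
    sigma_p_plus: dict[str, float] = field(default_factory=dict)

    def k1_for(self, label: str) -> float:
        return 10.0 ** (self.sN_true * (self.electrophiles[label] + self.N_true))


@dataclass(frozen=True)
class CampaignTrace:
    label: str
    trace: AbsorbanceTrace


@dataclass(frozen=True)
class Campaign:
    """A full synthetic study plus its ground-truth manifest."""

    traces: list[CampaignTrace]
    manifest: dict


def generate_campaign(
    truth: CampaignTruth,
    design: ExperimentDesign,
    seed: Optional[int] = None,
    ph_values: Sequence[float] = (1.0, 2.0),
) -> Campaign:
    """Simulate every electrophile x concentration x pH stopped-flow run.

    One integer seed controls the whole campaign; each trace draws its noise
    from a deterministically spawned substream, so campaigns are exactly
    reproducible and individual traces are statistically independent.
    """
    if not truth.electrophiles:
        raise ValueError("truth.electrophiles must be non-empty")
    root = np.random.SeedSequence(seed)
    n_traces = len(truth.electrophiles) * len(ph_values) * len(design.nucleophile_total_concs)
    streams = iter(root.spawn(n_traces))
    traces: list[CampaignTrace] = []
    manifest_traces = []
    for label, E in truth.electrophiles.items():
        k1_true = truth.k1_for(label)
        for ph in ph_values:
            d = replace(design, pH=ph)
            f = free_base_fraction(ph, truth.pKa)
            for conc in d.nucleophile_total_concs:
                kobsd = k1_true * f * conc
                rng = np.random.default_rng(next(streams))
                tr = generate_trace(kobsd, d, conc, seed=rng)
                traces.append(CampaignTrace(label=label, trace=tr))
                manifest_traces.append(
                    {
                        "label": label,
                        "pH": ph,
                        "conc": conc,
                        "true_kobsd": kobsd,
                    }
                )
    manifest = {
        "seed": seed,
        "truth": {
            "N_true": truth.N_true,
            "sN_true": truth.sN_true,
            "pKa": truth.pKa,
            "electrophiles": dict(truth.electrophiles),
            "k1_true": {lab: truth.k1_for(lab) for lab in truth.electrophiles},
            "sigma_p": dict(truth.sigma_p),
            "sigma_p_plus": dict(truth.sigma_p_plus),
        },
        "design": {
            "nucleophile_total_concs": list(design.nucleophile_total_concs),
            "electrophile_conc": design.electrophile_conc,
            "ph_values": list(ph_values),
            "A0": design.A0,
            "A_inf": design.A_inf,
            "noise_sd": design.noise_sd,
            "n_points": design.n_points,
            "span_relaxations": design.span_relaxations,
        },
        "traces": manifest_traces,
    }
    return Campaign(traces=traces, manifest=manifest)


def write_campaign(campaign: Campaign, out_dir: Union[str, Path]) -> Path:
    """Export a campaign: one time/absorbance CSV per trace + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, ct in enumerate(campaign.traces):
        tr = ct.trace
        fname = out / f"trace_{i:04d}_{ct.label}_pH{tr.pH:g}_c{tr.nucleophile_total_conc:g}.csv"
        with open(fname, "w", encoding="utf-8") as fh:
            fh.write("time_s,absorbance\n")
            for t, a in zip(tr.times, tr.absorbances):
                fh.write(f"{float(t)!r},{float(a)!r}\n")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(campaign.manifest, fh, indent=1, sort_keys=True)
    return out


def read_campaign(in_dir: Union[str, Path]) -> Campaign:
    """Re-load a campaign written by :func:`write_campaign`."""
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    files = sorted(in_dir.glob("trace_*.csv"))
    if len(files) != len(manifest["traces"]):
        raise ValueError(
            f"manifest lists {len(manifest['traces'])} traces, found {len(files)} files"
        )
    design = manifest["design"]
    traces = []
    for fname, meta in zip(files, manifest["traces"]):
        data = np.loadtxt(fname, delimiter=",", skiprows=1)
        tr = AbsorbanceTrace(
            times=data[:, 0],
            absorbances=data[:, 1],
            A0=design["A0"],
            A_inf=design["A_inf"],
            pH=meta["pH"],
            nucleophile_total_conc=meta["conc"],
            true_kobsd=meta["true_kobsd"],
        )
        traces.append(CampaignTrace(label=meta["label"], trace=tr))
    return Campaign(traces=traces, manifest=manifest)
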