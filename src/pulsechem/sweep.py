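"""Pulse-duration sweeps, power-law fitting, yield ratios, peak power.

The Results layer: simulate replicate pulses across a grid of pulse
durations (optionally electron counts / energies), score per-electron and
per-100 eV yields at the scoring end time, fit the power law

    y = a * tau^b + c

by multi-start weighted nonlinear least squares, and form scale-invariant
summaries (exponent b, R^2, short/long-pulse yield ratios, peak power).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import FitError, InvalidParameterError, ScoreError
from .geometry import Phantom
from .irt import run_irt
from .pulse import PulseSpec, assemble_pulse
from .registry import Registry, default_registry
from .scoring import score_time_series, scoring_end_time
from .tracks import StoppingPower, TrackParams

__all__ = [
    "FitResult",
    "DEFAULT_TAU_GRID",
    "run_single_pulse",
    "run_sweep",
    "fit_power_law",
    "power_law",
    "yield_ratio",
    "ratio_from_fit",
    "peak_power",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C (J/eV)

#: desk-scale default: one pulse duration per decade over the studied range
DEFAULT_TAU_GRID = tuple(10.0 ** -k for k in range(13, 5, -1))  # 1e-13 .. 1e-6 s

DEFAULT_SPECIES = ("OH", "e_aq", "H2O2", "H3O+", "H", "H2", "OH-", "HO2", "O2-")


@dataclass
class FitResult:
    """Parameters of the power-law fit y = a tau^b + c."""

    a: float
    b: float
    c: float
    r_squared: float
    n_points: int
    converged: bool = True
    degenerate: bool = False
    message: str = ""

    def evaluate(self, tau):
        return power_law(np.asarray(tau, dtype=float), self.a, self.b, self.c)


def power_law(tau, a, b, c):
    return a * np.power(tau, b) + c


def derive_seed(master_seed: int, *indices: int) -> int:
    """Deterministic child seed below 2^31 for a grid cell / replicate."""
    h = np.uint64(master_seed % (2**31))
    for ix in indices:
        h = np.uint64((int(h) * 2654435761 + ix + 1) % (2**61))
    return int(h % np.uint64(2**31))


def run_single_pulse(
    spec: PulseSpec,
    track_params: TrackParams,
    registry: Registry,
    seed: int,
    t_end_rule: str = "pulse_end",
    window: float = 1e-6,
    cutoff_factor: float = 10.0,
    r_cut_max: float = 3e-7,
    phantom: Phantom | None = None,
    stopping: StoppingPower | None = None,
    species: tuple[str, ...] = DEFAULT_SPECIES,
):
    """Assemble, react and score one pulse; returns (frame, t_end, deposited).

    The frame has one row per requested species with the counts at t_end.
    """
    rng = np.random.default_rng(seed)
    ensemble, deposited, _ = assemble_pulse(
        spec, track_params, registry, rng, phantom=phantom, stopping=stopping
    )
    if deposited <= 0:
        raise ScoreError("pulse deposited no energy in the phantom")
    t_end = scoring_end_time(
        spec.pulse_duration, t_end_rule, window=window, pc_offset=track_params.pc_offset
    )
    ensemble, log = run_irt(
        ensemble, registry, t_end, rng, cutoff_factor=cutoff_factor, r_cut_max=r_cut_max
    )
    records = score_time_series(
        ensemble, log, [t_end], spec.n_electrons, deposited, registry, t_end
    )
    wanted = {s for s in species}
    rows = {
        r.species: (r.count, r.g_value, r.per_electron_yield)
        for r in records
        if r.species in wanted
    }
    frame = pd.DataFrame(
        {
            "species": list(species),
            "count": [rows.get(s, (0, 0.0, 0.0))[0] for s in species],
            "g_per_100ev": [rows.get(s, (0, 0.0, 0.0))[1] for s in species],
            "yield_per_electron": [rows.get(s, (0, 0.0, 0.0))[2] for s in species],
        }
    )
    return frame, t_end, log, deposited


def run_sweep(
    tau_grid=DEFAULT_TAU_GRID,
    replicates: int = 8,
    n_electrons: int = 10,
    kinetic_energy: float = 1e4,
    beam_fwhm: float = 5e-6,
    envelope: str = "tophat",
    master_seed: int = 1,
    registry: Registry | None = None,
    track_params: TrackParams | None = None,
    t_end_rule: str = "pulse_end",
    window: float = 1e-6,
    cutoff_factor: float = 10.0,
    r_cut_max: float = 3e-7,
    species: tuple[str, ...] = DEFAULT_SPECIES,
    n_electrons_grid=None,
) -> pd.DataFrame:
    """Replicate pulses over a pulse-duration (and optional electron-count)
    grid; returns one row per (tau, n_electrons, species) with mean +- SE of
    both yield normalisations.

    Replicate seeds derive deterministically from the master seed and the
    grid indices, so any cell can be reproduced in isolation.
    """
    tau_grid = list(tau_grid)
    if not tau_grid:
        raise InvalidParameterError("tau grid must be non-empty")
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    if registry is None:
        registry = default_registry()
    if track_params is None:
        track_params = TrackParams(kinetic_energy=kinetic_energy)
    stopping = StoppingPower.bundled()
    n_grid = list(n_electrons_grid) if n_electrons_grid is not None else [n_electrons]

    rows = []
    for i_tau, tau in enumerate(tau_grid):
        for i_n, n_e in enumerate(n_grid):
            per_rep = {s: [] for s in species}
            per_rep_g = {s: [] for s in species}
            for rep in range(replicates):
                seed = derive_seed(master_seed, i_tau, i_n, rep)
                spec = PulseSpec(
                    n_electrons=n_e,
                    pulse_duration=tau,
                    kinetic_energy=kinetic_energy,
                    beam_fwhm=beam_fwhm,
                    envelope=envelope,
                    seed=seed,
                )
                frame, _, _, _ = run_single_pulse(
                    spec,
                    track_params,
                    registry,
                    seed,
                    t_end_rule=t_end_rule,
                    window=window,
                    cutoff_factor=cutoff_factor,
                    r_cut_max=r_cut_max,
                    species=species,
                )
                for _, r in frame.iterrows():
                    per_rep[r["species"]].append(r["yield_per_electron"])
                    per_rep_g[r["species"]].append(r["g_per_100ev"])
            for s in species:
                y = np.array(per_rep[s])
                g = np.array(per_rep_g[s])
                se = y.std(ddof=1) / np.sqrt(len(y)) if len(y) > 1 else 0.0
                se_g = g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0
                rows.append(
                    {
                        "pulse_duration_s": tau,
                        "n_electrons": n_e,
                        "species": s,
                        "n_replicates": replicates,
                        "mean_yield_per_electron": y.mean(),
                        "se_yield_per_electron": se,
                        "mean_g": g.mean(),
                        "se_g": se_g,
                    }
                )
    return pd.DataFrame(rows)


def fit_power_law(
    tau,
    y,
    weights=None,
    n_starts: int = 20,
    b_range: tuple[float, float] = (-0.5, -1e-3),
) -> FitResult:
    """Weighted nonlinear least squares of y = a tau^b + c.

    The model is linear in (a, c) for fixed b, so the fit profiles the
    weighted loss over b: a log grid of starts brackets the minimum and a
    bounded 1-D minimiser refines it; (a, c) then follow from weighted
    linear least squares at the optimal b.  R^2 is reported unweighted on
    the supplied points, matching the convention of plotting replicate
    means.
    """
    tau = np.asarray(tau, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(tau) < 4:
        raise InvalidParameterError("need >= 4 points to fit the power law")
    if np.any(tau <= 0):
        raise InvalidParameterError("tau values must be > 0")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return FitResult(
            a=0.0, b=0.0, c=float(y.mean()), r_squared=1.0, n_points=len(y),
            converged=True, degenerate=True,
            message="constant data: exponent unidentifiable",
        )

    sw = np.sqrt(w)

    def linear_ac(b):
        design = np.column_stack([tau**b, np.ones_like(tau)])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        resid = y - design @ coef
        return coef, float(np.sum(w * resid**2))

    b_starts = -np.logspace(
        np.log10(-b_range[1]), np.log10(-b_range[0]), n_starts
    )
    b_starts = np.sort(b_starts)  # ascending (most negative first)
    losses = np.array([linear_ac(b0)[1] for b0 in b_starts])
    if not np.all(np.isfinite(losses)):
        raise FitError("power-law fit failed from every start: non-finite loss")
    k = int(np.argmin(losses))
    lo = b_starts[k - 1] if k > 0 else 4.0 * b_starts[0]
    hi = b_starts[k + 1] if k + 1 < len(b_starts) else b_starts[-1] / 4.0
    sol = minimize_scalar(
        lambda b0: linear_ac(b0)[1],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    converged = bool(sol.success)
    if not converged:
        raise FitError(f"power-law fit did not converge: {sol.message}")
    b = float(sol.x)
    (a, c), _ = linear_ac(b)

    ss_res = float(np.sum((y - power_law(tau, a, b, c)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    degenerate = bool(abs(b) <= 1.05 * abs(b_range[1]))
    return FitResult(
        a=float(a), b=float(b), c=float(c), r_squared=r2, n_points=len(y),
        converged=converged, degenerate=degenerate,
        message="b at grid floor: data nearly flat" if degenerate else "",
    )


def yield_ratio(
    sweep: pd.DataFrame, tau_short: float, tau_long: float, species: str = "OH"
) -> tuple[float, float]:
    """Per-electron yield ratio short/long with propagated standard error."""

    def cell(tau):
        sel = sweep[
            np.isclose(sweep["pulse_duration_s"], tau, rtol=1e-6, atol=0.0)
            & (sweep["species"] == species)
        ]
        if sel.empty:
            raise InvalidParameterError(f"tau={tau:g} not present in sweep")
        return float(sel["mean_yield_per_electron"].iloc[0]), float(
            sel["se_yield_per_electron"].iloc[0]
        )

    m_s, se_s = cell(tau_short)
    m_l, se_l = cell(tau_long)
    if m_l == 0:
        raise ScoreError("zero long-pulse yield: ratio undefined")
    ratio = m_s / m_l
    rel_s = (se_s / m_s) ** 2 if m_s != 0 else 0.0
    se = abs(ratio) * np.sqrt(rel_s + (se_l / m_l) ** 2)
    return ratio, se


def ratio_from_fit(fit: FitResult, tau_short: float, tau_long: float) -> float:
    """Yield ratio implied by a fitted power law at two pulse durations."""
    y_l = float(fit.evaluate(tau_long))
    if y_l == 0:
        raise ScoreError("fit evaluates to zero at tau_long")
    return float(fit.evaluate(tau_short)) / y_l


def peak_power(n_electrons: int, kinetic_energy: float, tau: float) -> float:
    """Peak power (W) of a pulse: n * E / tau with E in eV."""
    if tau <= 0:
        raise InvalidParameterError("tau must be > 0")
    return n_electrons * kinetic_energy * ELEMENTARY_CHARGE / tau
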