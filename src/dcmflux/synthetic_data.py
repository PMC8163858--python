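"""Seeded generators for culture time series and isotopologue observations.

The time-series generator emulates the batch experiments the analysis is
built for: a lag phase at the initial substrate concentration, zero-order
consumption (with optional repeat amendments), products accumulating at
fixed molar yields, and cells growing at a fixed cells-per-mole yield before
plateauing when the substrate runs out.  Measurement noise is additive
Gaussian on concentrations (s.d. = cv x initial substrate, truncated at
zero) and multiplicative lognormal (mean-preserving) on qPCR counts.

Presets mirror the characterised growth conditions (substrate, lag, rate,
yields, cell yield) for DCM, methanol, choline, glycine betaine, and
glycine betaine + H2.

The per-molecule isotopologue sampler draws an acetogenic route and a label
state for every acetate molecule independently; at large n it converges to
the analytic forward model at the usual n^-1/2 rate and therefore doubles as
an independent Monte-Carlo oracle for it.

Determinism contract: every generator call builds one
``numpy.random.default_rng(seed)`` stream and touches no global state, so
identical config + seed gives byte-identical CSV output.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .kinetics import CONC_UNIT, QPCR_ANALYTE, QPCR_UNIT, TimeSeriesExperiment
from .wlp_model import IsotopologueDistribution, WLPParameters, solve_fluxes, SCENARIOS

__all__ = [
    "GeneratorConfig",
    "generate_timeseries",
    "generate_isotopologue_obs",
    "preset",
    "PRESET_NAMES",
]


class GeneratorConfig(BaseModel):
    """Ground-truth parameters and sampling design for one experiment."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    substrate: str
    initial_substrate_um: float = Field(ge=0)
    lag_days: float = Field(ge=0)
    rate_um_per_day: float = Field(ge=0)
    yields: dict[str, float] = Field(default_factory=dict)
    cell_yield_per_mol: float = Field(ge=0, default=0.0)
    initial_cells_per_ml: float = Field(ge=0, default=5e6)
    conc_noise_cv: float = Field(ge=0, default=0.05)
    qpcr_noise_cv: float = Field(ge=0, default=0.20)
    replicates: int = Field(ge=1, default=3)
    timepoints: tuple[float, ...]
    amendments: tuple[tuple[float, float], ...] = ()
    operon_count: int = Field(ge=1, default=4)
    seed: int

    @field_validator("yields")
    @classmethod
    def _yields_nonneg(cls, v):
        if any(y < 0 for y in v.values()):
            raise ValueError("yields must be non-negative")
        return v

    @field_validator("timepoints")
    @classmethod
    def _times_increasing(cls, v):
        if len(v) < 2 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("timepoints must be strictly increasing")
        return v


def _true_trajectories(cfg: GeneratorConfig, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free substrate concentration and cumulative consumption.

    Piecewise-linear event walk: no consumption before the lag or once the
    pool is empty; amendments top the pool up at their stated times.
    """
    events = sorted(cfg.amendments)
    conc_out = np.empty_like(times)
    cons_out = np.empty_like(times)
    t, conc, cons = 0.0, float(cfg.initial_substrate_um), 0.0
    pending = list(events)
    horizon = float(times[-1])

    segments = []  # (t_start, t_end, conc_start, cons_start, rate)
    while t < horizon:
        active = t >= cfg.lag_days and conc > 0 and cfg.rate_um_per_day > 0
        rate = cfg.rate_um_per_day if active else 0.0
        nxt = horizon
        if t < cfg.lag_days:
            nxt = min(nxt, cfg.lag_days)
        if active:
            nxt = min(nxt, t + conc / rate)
        if pending and pending[0][0] > t:
            nxt = min(nxt, pending[0][0])
        segments.append((t, nxt, conc, cons, rate))
        dt = nxt - t
        conc = max(conc - rate * dt, 0.0)
        cons += rate * dt
        t = nxt
        while pending and pending[0][0] <= t:
            conc += pending[0][1]
            pending.pop(0)
    segments.append((t, math.inf, conc, cons, 0.0))

    for i, ti in enumerate(times):
        # amendments at exactly ti take effect at ti (the next segment starts
        # there), so evaluate on the *last* segment containing ti
        matches = [s for s in segments if s[0] <= ti <= s[1]]
        t0, t1, c0, s0, rate = matches[-1]
        dt = ti - t0
        conc_out[i] = max(c0 - rate * dt, 0.0)
        cons_out[i] = s0 + rate * dt
    return conc_out, cons_out


def generate_timeseries(cfg: GeneratorConfig) -> TimeSeriesExperiment:
    """Simulate one experiment (all replicates) from a config.

    Analytes: the substrate, each product in ``yields`` (sorted by name),
    and qPCR 16S copies (cells x operon count).  Identical config and seed
    give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.timepoints, dtype=float)
    conc_true, cons_true = _true_trajectories(cfg, times)
    cells_true = cfg.initial_cells_per_ml + cfg.cell_yield_per_mol * cons_true * 1e-9
    copies_true = cells_true * cfg.operon_count

    sigma = cfg.conc_noise_cv * cfg.initial_substrate_um
    rows = []
    products = sorted(cfg.yields)
    for r in range(cfg.replicates):
        rep = f"R{r + 1}"
        analyte_values = {cfg.substrate: conc_true}
        for p in products:
            analyte_values[p] = cfg.yields[p] * cons_true
        for analyte, truth in analyte_values.items():
            noisy = truth + rng.normal(0.0, sigma, size=times.size) if sigma > 0 else truth
            noisy = np.clip(noisy, 0.0, None)
            rows += [
                {"time_d": t, "replicate": rep, "analyte": analyte, "value": v, "unit": CONC_UNIT}
                for t, v in zip(times, noisy)
            ]
        if cfg.qpcr_noise_cv > 0:
            s = math.sqrt(math.log1p(cfg.qpcr_noise_cv**2))
            factor = rng.lognormal(-(s**2) / 2.0, s, size=times.size)
        else:
            factor = np.ones(times.size)
        copies = copies_true * factor
        rows += [
            {"time_d": t, "replicate": rep, "analyte": QPCR_ANALYTE, "value": v, "unit": QPCR_UNIT}
            for t, v in zip(times, copies)
        ]
    return TimeSeriesExperiment(
        data=pd.DataFrame(rows, columns=["time_d", "replicate", "analyte", "value", "unit"]),
        substrate=cfg.substrate,
        amendments=cfg.amendments,
    )


def generate_isotopologue_obs(
    params: WLPParameters, scenario: str, n_molecules: int, seed: int
) -> IsotopologueDistribution:
    """Empirical isotopologue fractions from per-molecule sampling.

    For each acetate molecule: draw the route (pool vs methylene) from the
    steady-state route shares; then each bicarbonate-derived carbon draws its
    source (fresh, w.p. q, vs bulk) and its label from that source's atom
    fraction, independently; a methylene-route methyl carbon is labelled with
    the methylene atom fraction.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    sol = solve_fluxes(params.f)
    share_pool = float(2 * sol.acetate_via_pool)

    pool_route = rng.random(n_molecules) < share_pool

    def bicarb_carbon_label(n: int) -> np.ndarray:
        fresh = rng.random(n) < params.q
        p = np.where(fresh, params.p_methylene, params.p_pool)
        return rng.random(n) < p

    # carboxyl (C1) always comes from bicarbonate; methyl (C2) depends on route
    c1 = bicarb_carbon_label(n_molecules)
    c2_pool = bicarb_carbon_label(n_molecules)
    c2_methylene = rng.random(n_molecules) < params.p_methylene
    c2 = np.where(pool_route, c2_pool, c2_methylene)

    counts = np.bincount(c1.astype(int) + 2 * c2.astype(int), minlength=4)
    # index: 0 -> M0, 1 -> [1-13C], 2 -> [2-13C], 3 -> [1,2-13C]
    fractions = counts / n_molecules
    return IsotopologueDistribution(*fractions.tolist())


# ---------------------------------------------------------------------------
# Presets mirroring the characterised growth experiments

_PRESET_TRUTH: dict[str, dict] = {
    "dcm": dict(
        substrate="DCM",
        initial_substrate_um=2000.0,
        lag_days=21.0,
        rate_um_per_day=133.0,
        yields={"acetate": 0.76},
        cell_yield_per_mol=2.0e14,
    ),
    "methanol": dict(
        substrate="methanol",
        initial_substrate_um=5000.0,
        lag_days=14.0,
        rate_um_per_day=309.0,
        yields={"acetate": 0.74},
        cell_yield_per_mol=5.7e14,
    ),
    "choline": dict(
        substrate="choline",
        initial_substrate_um=5000.0,
        lag_days=11.0,
        rate_um_per_day=344.0,
        yields={"acetate": 3.1, "monomethylamine": 1.3},
        cell_yield_per_mol=3.0e14,
    ),
    "glycine-betaine": dict(
        substrate="glycine-betaine",
        initial_substrate_um=5000.0,
        lag_days=7.0,
        rate_um_per_day=328.0,
        yields={"acetate": 2.3, "monomethylamine": 0.95},
        cell_yield_per_mol=1.1e14,
    ),
    "glycine-betaine-h2": dict(
        substrate="glycine-betaine",
        initial_substrate_um=4400.0,
        lag_days=3.5,
        rate_um_per_day=170.0,
        yields={"acetate": 3.41, "monomethylamine": 1.25},
        cell_yield_per_mol=9.1e13,
    ),
}

PRESET_NAMES = tuple(sorted(_PRESET_TRUTH))


def _default_timepoints(lag: float, initial: float, rate: float) -> tuple[float, ...]:
    """Sampling design: weekly during the lag, twice-weekly during
    consumption, the depletion day itself, and two post-depletion points so
    the cell plateau is observable."""
    duration = initial / rate if rate > 0 else 14.0
    pts = set(np.arange(0.0, lag, 7.0))
    pts.add(lag)
    pts.update(lag + np.arange(3.5, duration, 3.5))
    pts.add(lag + duration)
    pts.update({lag + duration + 3.5, lag + duration + 7.0})
    return tuple(sorted(round(p, 6) for p in pts))


def preset(name: str, seed: int, **overrides) -> GeneratorConfig:
    """A ready-made :class:`GeneratorConfig` for a named growth condition.

    ``overrides`` replace any config field (e.g. ``conc_noise_cv=0`` for a
    noise-free run).
    """
    if name not in _PRESET_TRUTH:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    truth = dict(_PRESET_TRUTH[name])
    truth["timepoints"] = _default_timepoints(
        truth["lag_days"], truth["initial_substrate_um"], truth["rate_um_per_day"]
    )
    truth.update(overrides)
    return GeneratorConfig(seed=seed, **truth)
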