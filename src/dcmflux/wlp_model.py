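"""Forward and inverse model of acetate isotopologues under DCM disproportionation.

Model
-----
Each mole of dichloromethane (DCM) enters the Wood-Ljungdahl pathway (WLP) as
one methylene-tetrahydrofolate.  A fraction ``w`` of that methylene is
oxidised to bicarbonate, releasing 4 electrons per carbon.  The electrons are
split by the *partition fraction* ``f``: a share ``f`` reduces bulk-pool
bicarbonate to acetate (8 e- per acetate; both carbons from bicarbonate),
and ``1 - f`` reduces the remaining methylene to the methyl group of acetate
(4 e- per acetate; the carboxyl carbon still comes from bicarbonate).
Steady state of the methylene and electron pools forces

    w = 1 / (2 - f),
    acetate via the methylene route = (1 - f) / (2 - f)   per mol DCM,
    acetate via the pool route      = f / (2 (2 - f))     per mol DCM,

so total acetate is exactly 1/2 per DCM for any f, and bicarbonate production
by oxidation exactly cancels bicarbonate consumption by acetogenesis (net
flux zero) -- the overall fermentation reduces to
``2 CH2Cl2 + 2 H2O -> CH3COO- + 5 H+ + 4 Cl-``.

Isotope labels: the methylene pool carries 13C atom fraction ``p_methylene``
(1 for [13C]DCM feeding, ~0 otherwise) and the bulk bicarbonate pool
``p_pool``.  *Channeling* ``q`` is the probability that a carbon drawn from
bicarbonate uses freshly oxidised, methylene-derived bicarbonate (label
fraction ``p_methylene``) rather than the well-mixed bulk pool; it applies
identically to the carboxyl carbon of both routes and to both pool-route
carbons, which are labelled independently.  Acetate positions follow standard
numbering: C1 = carboxyl, C2 = methyl.

Flux arithmetic is exact (:class:`fractions.Fraction`); isotopologue
probabilities are floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import chem_core

__all__ = [
    "SCENARIOS",
    "WLPParameters",
    "FluxSolution",
    "IsotopologueDistribution",
    "IsotopeFit",
    "solve_fluxes",
    "partition_from_ratio",
    "forward_isotopologues",
    "expected_pool_dilution",
    "fit_isotope_params",
]

#: Label-feeding scenarios: 13C supplied as DCM, or as bicarbonate.
SCENARIOS = ("dcm_labelled", "bicarb_labelled")

#: Default label atom fractions implied by each feeding scenario.
SCENARIO_DEFAULTS: dict[str, dict[str, float]] = {
    "dcm_labelled": {"p_methylene": 1.0, "p_pool": 0.0},
    "bicarb_labelled": {"p_methylene": 0.0, "p_pool": 1.0},
}

#: Acetate isotopologue class labels, in canonical order.
CLASS_LABELS = ("M0", "[1-13C]", "[2-13C]", "[1,2-13C]")

_PARAM_ORDER = ("f", "q", "p_pool", "p_methylene")


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class WLPParameters:
    """Free parameters of the isotopologue model (all in [0, 1])."""

    f: float
    q: float = 0.0
    p_pool: float = 0.0
    p_methylene: float = 1.0

    def __post_init__(self) -> None:
        for name in _PARAM_ORDER:
            _check_unit(name, getattr(self, name))

    @classmethod
    def for_scenario(cls, scenario: str, f: float, q: float = 0.0, **overrides: float) -> "WLPParameters":
        """Build parameters with the label fractions a scenario implies."""
        _check_scenario(scenario)
        pools = dict(SCENARIO_DEFAULTS[scenario])
        pools.update(overrides)
        return cls(f=f, q=q, **pools)


@dataclass(frozen=True)
class FluxSolution:
    """Steady-state fluxes per mole of DCM, as exact rationals."""

    f: Fraction
    w: Fraction  # fraction of methylene oxidised
    acetate_via_methylene: Fraction
    acetate_via_pool: Fraction
    hco3_produced: Fraction
    hco3_consumed: Fraction

    @property
    def total_acetate(self) -> Fraction:
        return self.acetate_via_methylene + self.acetate_via_pool

    @property
    def net_hco3_flux(self) -> Fraction:
        return self.hco3_produced - self.hco3_consumed


def solve_fluxes(f: float | Fraction) -> FluxSolution:
    """Steady-state route fluxes for electron-partition fraction ``f``.

    Electron production (4 per oxidised methylene) equals electron
    consumption (4 and 8 per acetate on the two routes) exactly, and the
    methylene pool closes, which determines all fluxes; see the module
    docstring for the algebra.
    """
    f_exact = Fraction(f).limit_denominator(10**15) if isinstance(f, float) else Fraction(f)
    if not 0 <= f_exact <= 1:
        raise ValueError(f"partition fraction must lie in [0, 1], got {f}")
    w = 1 / (2 - f_exact)
    via_methylene = (1 - f_exact) * w
    via_pool = f_exact * w / 2
    hco3_produced = w  # one bicarbonate per oxidised methylene
    hco3_consumed = via_methylene + 2 * via_pool  # carboxyl + both pool carbons
    return FluxSolution(
        f=f_exact,
        w=w,
        acetate_via_methylene=via_methylene,
        acetate_via_pool=via_pool,
        hco3_produced=hco3_produced,
        hco3_consumed=hco3_consumed,
    )


def partition_from_ratio(r: float) -> float:
    """Electron-partition fraction ``f`` from a labelled:unlabelled acetate ratio.

    Under [13C]DCM feeding with a fully labelled methylene pool and an
    effectively unlabelled bulk pool, labelled acetate comes from the
    methylene route and unlabelled from the pool route.  Weighting each route
    by its electron cost per acetate (derived from the balanced route
    reactions, 8 for pool bicarbonate vs 4 for methylene) gives

        f = e_pool / (e_pool + e_methylene * r).

    A ~1:1 ratio therefore implies f ~ 2/3 of the electrons go to bulk
    bicarbonate reduction.  Consistent with :func:`solve_fluxes`: the route
    molar ratio of its solution at this ``f`` equals ``r``.
    """
    if r < 0:
        raise ValueError("ratio must be non-negative")
    e_pool = chem_core.electrons_per_acetate("pool_bicarbonate")
    e_methylene = chem_core.electrons_per_acetate("methylene")
    return e_pool / (e_pool + e_methylene * r)


def expected_pool_dilution(labelled_source_um: float, unlabelled_pool_um: float) -> float:
    """Expected labelled percentage of a well-mixed bicarbonate pool.

    The labelled carbon released into a large unlabelled pool would, with
    perfect mixing, label this percentage of draws from the pool; observing
    double-labelled acetate well above it is the signature of channeling.
    """
    if unlabelled_pool_um <= 0:
        raise ValueError("pool concentration must be positive")
    if labelled_source_um < 0:
        raise ValueError("labelled source must be non-negative")
    return 100.0 * labelled_source_um / unlabelled_pool_um


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Acetate isotopologue fractions: M0, [1-13C], [2-13C], [1,2-13C]."""

    m0: float
    carboxyl: float  # [1-13C]
    methyl: float  # [2-13C]
    double: float  # [1,2-13C]

    def __post_init__(self) -> None:
        fractions = self.as_array()
        if np.any(fractions < -1e-12):
            raise ValueError("isotopologue fractions must be non-negative")
        if abs(float(fractions.sum()) - 1.0) > 1e-9:
            raise ValueError(f"isotopologue fractions must sum to 1, got {fractions.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.m0, self.carboxyl, self.methyl, self.double], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CLASS_LABELS, self.as_array()))

    @classmethod
    def from_mapping(cls, fractions: Mapping[str, float]) -> "IsotopologueDistribution":
        unknown = set(fractions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown isotopologue classes: {sorted(unknown)}")
        vals = [float(fractions.get(label, 0.0)) for label in CLASS_LABELS]
        return cls(*vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": CLASS_LABELS, "fraction": self.as_array()})

    @classmethod
    def from_csv(cls, path) -> "IsotopologueDistribution":
        df = pd.read_csv(path)
        missing = {"species", "fraction"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls.from_mapping(dict(zip(df["species"], df["fraction"])))


def _check_scenario(scenario: str) -> None:
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def _class_probabilities(f, q, p_pool, p_methylene):
    """Vectorised class probabilities; arguments broadcast like numpy arrays.

    Returns an array with a trailing axis of length 4 in CLASS_LABELS order.
    """
    f = np.asarray(f, dtype=float)
    share_pool = f / (2.0 - f)  # pool-route share of acetate molecules
    share_methylene = 1.0 - share_pool
    p_carboxyl = q * p_methylene + (1.0 - q) * p_pool  # any bicarbonate-derived carbon
    # Methylene route: C2 labelled w.p. p_methylene, C1 w.p. p_carboxyl.
    # Pool route: both carbons labelled independently w.p. p_carboxyl.
    m0 = share_methylene * (1 - p_methylene) * (1 - p_carboxyl) + share_pool * (1 - p_carboxyl) ** 2
    c1 = share_methylene * (1 - p_methylene) * p_carboxyl + share_pool * p_carboxyl * (1 - p_carboxyl)
    c2 = share_methylene * p_methylene * (1 - p_carboxyl) + share_pool * (1 - p_carboxyl) * p_carboxyl
    c12 = share_methylene * p_methylene * p_carboxyl + share_pool * p_carboxyl**2
    return np.stack(np.broadcast_arrays(m0, c1, c2, c12), axis=-1)


def forward_isotopologues(params: WLPParameters, scenario: str) -> IsotopologueDistribution:
    """Predicted acetate isotopologue distribution for given parameters.

    ``scenario`` is a validation tag describing which substrate carried the
    label; the arithmetic itself is driven entirely by the label fractions in
    ``params`` (see :meth:`WLPParameters.for_scenario`).
    """
    _check_scenario(scenario)
    probs = _class_probabilities(params.f, params.q, params.p_pool, params.p_methylene)
    return IsotopologueDistribution(*probs.tolist())


@dataclass(frozen=True)
class IsotopeFit:
    """Result of an inverse fit: best parameters, residual, diagnostics."""

    params: WLPParameters
    residual: float
    free: tuple[str, ...]
    identifiable: bool


def fit_isotope_params(
    observed: IsotopologueDistribution | Mapping[str, float],
    scenario: str,
    free: Sequence[str] = ("f", "q"),
    fixed: Mapping[str, float] | None = None,
    mask: Iterable[str] = (),
) -> IsotopeFit:
    """Least-squares fit of model parameters to an observed distribution.

    A deterministic grid (step 0.01 per free parameter, 0.05 when more than
    two are free) is scanned first, taking the smallest parameter vector in
    ``(f, q, p_pool, p_methylene)`` lexicographic order among ties, then
    refined by a bounded Nelder-Mead search.  ``mask`` lists isotopologue
    classes to exclude from the residual (e.g. a class that was not resolved
    analytically); both model and observation are renormalised over the
    remaining classes.

    Fixed parameters default to the scenario's label fractions and may be
    overridden via ``fixed``.  Observations with essentially all mass in one
    class cannot pin down more than one parameter; such fits are flagged
    ``identifiable=False`` (the residual is still reported).
    """
    _check_scenario(scenario)
    free = tuple(free)
    if not free:
        raise ValueError("at least one parameter must be free")
    for name in free:
        if name not in _PARAM_ORDER:
            raise ValueError(f"unknown parameter {name!r}")

    base: dict[str, float] = {"f": 0.5, "q": 0.0}
    base.update(SCENARIO_DEFAULTS[scenario])
    if fixed:
        for name, value in fixed.items():
            if name not in _PARAM_ORDER:
                raise ValueError(f"unknown parameter {name!r}")
            _check_unit(name, value)
            base[name] = float(value)

    if isinstance(observed, Mapping):
        obs_map = {k: float(v) for k, v in observed.items()}
    else:
        obs_map = observed.as_dict()
    mask = set(mask)
    unknown = mask - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown masked classes: {sorted(unknown)}")
    keep = np.array([label not in mask for label in CLASS_LABELS])
    if keep.sum() < 2:
        raise ValueError("masking leaves fewer than two isotopologue classes")
    obs = np.array([obs_map.get(label, 0.0) for label in CLASS_LABELS])[keep]
    if obs.sum() <= 0:
        raise ValueError("observation has no mass in unmasked classes")
    obs = obs / obs.sum()

    def residual_vec(values: np.ndarray) -> np.ndarray:
        kwargs = dict(base)
        kwargs.update(dict(zip(free, np.clip(values, 0.0, 1.0).T)))
        probs = _class_probabilities(kwargs["f"], kwargs["q"], kwargs["p_pool"], kwargs["p_methylene"])
        model = probs[..., keep]
        total = model.sum(axis=-1, keepdims=True)
        model = np.divide(model, total, out=np.full_like(model, 1.0 / keep.sum()), where=total > 0)
        return ((model - obs) ** 2).sum(axis=-1)

    step = 0.01 if len(free) <= 2 else 0.05
    axis = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    grids = np.meshgrid(*[axis] * len(free), indexing="ij")
    points = np.stack([g.ravel() for g in grids], axis=-1)
    ssr = residual_vec(points)
    best = points[int(np.argmin(ssr))]  # first minimum = lexicographically smallest

    opt = minimize(
        lambda x: float(residual_vec(x[np.newaxis, :])[0]),
        best,
        method="Nelder-Mead",
        bounds=[(0.0, 1.0)] * len(free),
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
    )
    refined = np.clip(opt.x, 0.0, 1.0)

    kwargs = dict(base)
    kwargs.update({name: float(v) for name, v in zip(free, refined)})
    params = WLPParameters(**{k: kwargs[k] for k in _PARAM_ORDER})
    identifiable = not (obs.max() > 0.999 and len(free) > 1)
    return IsotopeFit(params=params, residual=float(opt.fun), free=free, identifiable=identifiable)
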