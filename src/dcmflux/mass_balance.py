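"""Closed-system 13C ledger: labelled carbon per pool and percent recovery.

In a closed culture bottle every 13C atom supplied (as labelled substrate or
labelled bicarbonate) must end up in one of the measurable pools: acetate,
aqueous bicarbonate, headspace CO2 (in liquid-equivalent units), or biomass.
Summing the pools and dividing by the labelled carbon consumed gives the
recovery; values near 100% mean no unknown fate.  Recovery is reported
unclamped -- measurement uncertainty can push it above 100%.

All pool concentrations are µM 13C atoms per litre of culture liquid.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import pandas as pd

from .wlp_model import IsotopologueDistribution

__all__ = [
    "LabeledPoolSet",
    "MassBalanceResult",
    "acetate_labelled_carbon",
    "recovery",
    "biomass_label_equiv",
    "pools_from_csv",
    "CARBON_MOLAR_MASS",
]

#: Molar mass of carbon, g/mol.
CARBON_MOLAR_MASS = 12.011

#: Default cellular carbon content, fg C per cell (typical small rod).
DEFAULT_CARBON_PER_CELL_FG = 50.0

_POOL_FIELDS = ("acetate", "hco3", "co2_gas", "biomass")


@dataclass(frozen=True)
class LabeledPoolSet:
    """Measured labelled-carbon pools (µM 13C) and the labelled supply."""

    acetate: float
    hco3: float
    co2_gas: float
    biomass: float
    consumed: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"pool {f.name} must be non-negative")


@dataclass(frozen=True)
class MassBalanceResult:
    """Total recovered labelled carbon, recovery %, and per-pool shares (%
    of the recovered total; shares sum to 100 whenever anything was
    recovered)."""

    total_recovered: float
    recovery_pct: float
    pool_shares_pct: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pool": name, "share_pct": share}
            for name, share in self.pool_shares_pct.items()
        ]
        return pd.DataFrame(rows)


def acetate_labelled_carbon(
    total_acetate_um: float, dist: IsotopologueDistribution
) -> float:
    """µM of 13C atoms carried by an acetate pool with the given isotopologue
    distribution: single-labelled classes contribute one atom per molecule,
    the double-labelled class two."""
    if total_acetate_um < 0:
        raise ValueError("acetate concentration must be non-negative")
    atoms_per_molecule = dist.carboxyl + dist.methyl + 2.0 * dist.double
    return total_acetate_um * atoms_per_molecule


def recovery(pools: LabeledPoolSet) -> MassBalanceResult:
    """Percent recovery of labelled carbon across the measured pools."""
    if pools.consumed <= 0:
        raise ValueError("labelled carbon consumed must be positive")
    total = sum(getattr(pools, name) for name in _POOL_FIELDS)
    shares = {
        name: (100.0 * getattr(pools, name) / total if total > 0 else 0.0)
        for name in _POOL_FIELDS
    }
    return MassBalanceResult(
        total_recovered=total,
        recovery_pct=100.0 * total / pools.consumed,
        pool_shares_pct=shares,
    )


def biomass_label_equiv(
    cell_increase_per_l: float,
    carbon_per_cell_fg: float = DEFAULT_CARBON_PER_CELL_FG,
    label_fraction: float = 1.0,
) -> float:
    """Labelled biomass carbon, µM, from a net cell increase.

    Converts cells per litre of culture into µmol carbon per litre using the
    per-cell carbon content, scaled by the fraction of that carbon that is
    labelled.  The result shares units with the other ledger pools
    (µM carbon, i.e. "acetate-carbon equivalents").
    """
    if cell_increase_per_l < 0 or carbon_per_cell_fg < 0:
        raise ValueError("inputs must be non-negative")
    if not 0.0 <= label_fraction <= 1.0:
        raise ValueError("label_fraction must lie in [0, 1]")
    grams_c_per_l = cell_increase_per_l * carbon_per_cell_fg * 1e-15
    return grams_c_per_l / CARBON_MOLAR_MASS * 1e6 * label_fraction


def pools_from_csv(path) -> LabeledPoolSet:
    """Read a pool ledger CSV with columns (pool, uM).

    Required pools: acetate, hco3, co2_gas, biomass, consumed.
    """
    df = pd.read_csv(path)
    missing_cols = {"pool", "uM"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    values = dict(zip(df["pool"], df["uM"]))
    required = set(_POOL_FIELDS) | {"consumed"}
    missing = required - set(values)
    if missing:
        raise ValueError(f"{path}: missing pools {sorted(missing)}")
    return LabeledPoolSet(**{k: float(values[k]) for k in required})
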