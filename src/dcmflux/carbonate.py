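"""Dissolved-inorganic-carbon speciation and headspace partitioning.

Closed anaerobic culture bottles hold a bicarbonate-buffered liquid phase in
equilibrium with a headspace.  Given a measured aqueous bicarbonate
concentration, this module computes the co-existing dissolved CO2 (first
carbonate dissociation equilibrium) and the headspace CO2 (Henry's law plus
the ideal gas law), and expresses the gas-phase amount in *liquid-equivalent*
micromolar units (µmol per litre of culture liquid) -- the convention used
when tallying labelled-carbon pools.

Carbonate ion (CO3^2-) is neglected: it is a negligible fraction of DIC below
pH 8 in bicarbonate-buffered medium.  Isotopologues are assumed to partition
identically, so the same arithmetic applies to a 13C-labelled sub-pool.
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field

__all__ = ["CarbonateConditions", "Speciation", "speciate", "labelled_headspace", "R_L_ATM"]

#: Ideal gas constant, l·atm·mol^-1·K^-1.
R_L_ATM = 0.082057366


class CarbonateConditions(BaseModel):
    """Flask conditions for carbonate speciation.

    Defaults for the equilibrium constants are the conventional 25 °C values:
    Ka1 = 4.45e-7 mol/l for CO2(aq) + H2O <=> HCO3- + H+, and a Henry
    constant KH = 29.4 l·atm/mol for CO2.  Both are overridable because flask
    pH, temperature and volumes vary between setups.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    pH: float = Field(gt=0, lt=14)
    temperature_c: float = 25.0
    liquid_volume_ml: float = Field(ge=0)
    headspace_volume_ml: float = Field(ge=0)
    ka1: float = Field(default=4.45e-7, gt=0)
    kh: float = Field(default=29.4, gt=0)


@dataclass(frozen=True)
class Speciation:
    """Speciation result; concentrations in µM, amounts in µmol.

    ``co2_gas_liquid_equiv_um`` is the headspace amount divided by the liquid
    volume, i.e. the concentration the gas-phase pool would have if dissolved
    back into the liquid.
    """

    hco3_um: float
    co2_aq_um: float
    co2_gas_liquid_equiv_um: float
    totals_umol: dict[str, float]


def speciate(hco3_um: float, cond: CarbonateConditions) -> Speciation:
    """Partition DIC given the aqueous bicarbonate concentration.

    CO2(aq) follows from the dissociation equilibrium,
    ``[CO2aq] = [HCO3-][H+]/Ka1``; the headspace partial pressure from
    Henry's law ``p = KH [CO2aq]``; and the headspace amount from the ideal
    gas law at the flask temperature.
    """
    if hco3_um < 0:
        raise ValueError("negative bicarbonate concentration")
    if cond.liquid_volume_ml == 0:
        raise ValueError("zero liquid volume: liquid-equivalent units undefined")
    h_plus = 10.0 ** (-cond.pH)
    co2_aq_um = hco3_um * h_plus / cond.ka1
    v_liq_l = cond.liquid_volume_ml / 1000.0
    v_gas_l = cond.headspace_volume_ml / 1000.0
    t_k = cond.temperature_c + 273.15
    p_atm = cond.kh * co2_aq_um * 1e-6  # mol/l -> atm
    co2_gas_umol = p_atm * v_gas_l / (R_L_ATM * t_k) * 1e6
    totals = {
        "hco3": hco3_um * v_liq_l,
        "co2_aq": co2_aq_um * v_liq_l,
        "co2_gas": co2_gas_umol,
    }
    totals["dic"] = totals["hco3"] + totals["co2_aq"] + totals["co2_gas"]
    return Speciation(
        hco3_um=hco3_um,
        co2_aq_um=co2_aq_um,
        co2_gas_liquid_equiv_um=co2_gas_umol / v_liq_l,
        totals_umol=totals,
    )


def labelled_headspace(hco3_labelled_um: float, cond: CarbonateConditions) -> float:
    """Headspace CO2 (µM liquid-equivalents) for a labelled bicarbonate sub-pool.

    Isotopologues are assumed to speciate identically, so this is
    :func:`speciate` applied to the labelled fraction alone; the result is
    linear in the labelled concentration.
    """
    return speciate(hco3_labelled_um, cond).co2_gas_liquid_equiv_um
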