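"""Per-layer thermal and perfusion parameters for the four-layer phantom.

The phantom's outer layer merges scalp and skull, while the thermal tables
list them separately; the merged layer uses thickness-weighted means
(scalp 6 mm / skull 7 mm of the 13 mm default).

Two printed densities are physically impossible (CSF 0 kg/m³, brain
0.08 kg/m³) and specific heats are not tabulated at all. Defaults substitute
standard literature values (CSF 1007, brain 1040 kg/m³; c: scalp 3391,
skull 1313, CSF 4096, brain 3630 J/kg·°C). ``strict=True`` keeps the printed
densities (warning emitted); steady-state solutions do not depend on rho or
c, so strict mode only degrades transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tables import TISSUES, load_reference_tables

__all__ = ["LayerThermalTable", "tissue_thermal_parameters"]

#: Sub-thicknesses used to merge scalp and skull into the outer layer, m.
SCALP_THICKNESS = 6e-3
SKULL_THICKNESS = 7e-3

#: Literature specific heats, J/kg·°C (not tabulated in the source data).
SPECIFIC_HEAT = {"scalp": 3391.0, "skull": 1313.0, "csf": 4096.0, "brain": 3630.0}

#: Substituted densities for the impossible printed values, kg/m³.
DENSITY_SUBSTITUTES = {"csf": 1007.0, "brain": 1040.0}

#: Arterial blood temperature, °C.
ARTERIAL_TEMPERATURE = 37.0

#: Blood specific heat: 3600 J/kg·K from the perfusion table (the running text
#: quotes 3664; select it by passing blood_specific_heat explicitly).
BLOOD_SPECIFIC_HEAT_TEXT = 3664.0


@dataclass(frozen=True)
class LayerThermalTable:
    """Thermal/perfusion parameters indexed by phantom tissue code."""

    K: np.ndarray        # W/m·°C
    rho: np.ndarray      # kg/m³
    c: np.ndarray        # J/kg·°C
    q_met: np.ndarray    # W/m³
    omega_b: np.ndarray  # 1/s
    rho_b: float
    c_b: float
    T_a: float


def _weighted(scalp: float, skull: float) -> float:
    w = SCALP_THICKNESS / (SCALP_THICKNESS + SKULL_THICKNESS)
    return w * scalp + (1.0 - w) * skull


def tissue_thermal_parameters(
    strict: bool = False,
    blood_specific_heat: float | None = None,
) -> LayerThermalTable:
    """Thermal/perfusion parameter table for the four phantom layers.

    ``strict`` uses the printed densities verbatim (CSF 0, brain 0.08 kg/m³)
    instead of the substituted defaults.
    """
    tab = load_reference_tables()
    th = tab.thermal_printed.set_index("tissue")
    pf = tab.perfusion.set_index("tissue")

    def density(tissue: str) -> float:
        printed = float(th.loc[tissue, "density_kg_per_m3"])
        if strict or tissue not in DENSITY_SUBSTITUTES:
            return printed
        return DENSITY_SUBSTITUTES[tissue]

    if strict:
        warnings.warn(
            "strict thermal mode keeps the printed densities (CSF 0, brain "
            "0.08 kg/m³); transient solves will be unphysical",
            stacklevel=2,
        )

    K = np.empty(len(TISSUES))
    rho = np.empty(len(TISSUES))
    c = np.empty(len(TISSUES))
    q_met = np.empty(len(TISSUES))
    omega = np.empty(len(TISSUES))

    source = {"scalp_skull": None, "csf": "csf", "gray_matter": "brain",
              "white_matter": "brain"}
    for code, name in enumerate(TISSUES):
        src = source[name]
        if src is None:  # merged scalp+skull
            K[code] = _weighted(
                float(th.loc["scalp", "thermal_conductivity_w_per_m_c"]),
                float(th.loc["skull", "thermal_conductivity_w_per_m_c"]),
            )
            rho[code] = _weighted(
                float(th.loc["scalp", "density_kg_per_m3"]),
                float(th.loc["skull", "density_kg_per_m3"]),
            )
            c[code] = _weighted(SPECIFIC_HEAT["scalp"], SPECIFIC_HEAT["skull"])
            q_met[code] = _weighted(
                float(th.loc["scalp", "metabolic_heat_w_per_m3"]),
                float(th.loc["skull", "metabolic_heat_w_per_m3"]),
            )
            omega[code] = _weighted(
                float(pf.loc["scalp", "blood_perfusion_per_s"]),
                float(pf.loc["skull", "blood_perfusion_per_s"]),
            )
        else:
            K[code] = float(th.loc[src, "thermal_conductivity_w_per_m_c"])
            rho[code] = density(src)
            c[code] = SPECIFIC_HEAT[src]
            q_met[code] = float(th.loc[src, "metabolic_heat_w_per_m3"])
            omega[code] = float(pf.loc[src, "blood_perfusion_per_s"])

    c_b = (
        float(pf.loc["brain", "blood_specific_heat_j_per_kg_k"])
        if blood_specific_heat is None
        else float(blood_specific_heat)
    )
    return LayerThermalTable(
        K=K,
        rho=rho,
        c=c,
        q_met=q_met,
        omega_b=omega,
        rho_b=float(pf.loc["brain", "blood_density_kg_per_m3"]),
        c_b=c_b,
        T_a=ARTERIAL_TEMPERATURE,
    )
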