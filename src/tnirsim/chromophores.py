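"""Tissue absorption composed from chromophore contributions, and diffusion-theory
derived quantities.

In the red/NIR window the absorption coefficient of brain tissue is, to good
approximation, the sum of independent chromophore contributions::

    mu_a(tissue) = sum_i  c_i * epsilon_i

where each term is the product of a concentration descriptor ``c_i`` (water
volume fraction, lipid dry-mass fraction times tissue density, blood volume
fraction with an oxygen saturation split, or a molar concentration of
cytochrome c oxidase) with the matching specific absorption ``epsilon_i``.
Scattering, by contrast, is a property of tissue microstructure and is kept
fixed when single-chromophore absorption is studied.

Diffusion-theory helpers: reduced scattering ``mu_s' = mu_s (1 - g)``, the
diffusion coefficient ``D = 1 / (3 (mu_a + mu_s'))`` and the effective
attenuation ``mu_eff = sqrt(mu_a / D) = sqrt(3 mu_a (mu_a + mu_s'))`` that
sets the asymptotic exponential decay of fluence with depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, DegenerateMediumError, DomainError
from .tables import ANISOTROPY_G, REFRACTIVE_INDEX, load_reference_tables

__all__ = [
    "TissueOpticalProperties",
    "ChromophoreContribution",
    "DiffusionConstants",
    "reduced_scattering",
    "diffusion_coefficient",
    "effective_attenuation",
    "diffusion_constants",
    "chromophore_mu_a",
    "compose_tissue_mu_a",
    "tissue_optical_properties",
]


@dataclass(frozen=True)
class TissueOpticalProperties:
    """Whole-tissue optical properties at one wavelength (SI units, 1/m)."""

    tissue_id: str
    mu_a: float
    mu_s_prime: float
    g: float = ANISOTROPY_G
    refractive_index: float = REFRACTIVE_INDEX

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_prime < 0:
            raise DomainError("mu_a and mu_s_prime must be non-negative")
        if not 0.0 <= self.g < 1.0:
            raise DomainError("anisotropy g must lie in [0, 1)")

    @property
    def mu_s(self) -> float:
        """Unreduced scattering coefficient mu_s' / (1 - g), 1/m."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def diffusion(self) -> "DiffusionConstants":
        return diffusion_constants(self.mu_a, self.mu_s_prime)


@dataclass(frozen=True)
class DiffusionConstants:
    """Diffusion coefficient D (m) and effective attenuation mu_eff (1/m)."""

    D: float
    mu_eff: float


@dataclass(frozen=True)
class ChromophoreContribution:
    """One chromophore's contribution to a tissue absorption coefficient.

    ``kind`` selects the concentration descriptor:

    - ``volume_fraction``: params ``(fraction,)``, specific_absorption is the
      pure-substance mu_a (1/m). Used for water.
    - ``mass_fraction_x_density``: params ``(dry_mass_fraction, tissue_density)``,
      specific_absorption in 1/m per kg/m³. Used for lipid.
    - ``molar_concentration``: params ``(concentration_mM,)``,
      specific_absorption in 1/m per mM. Used for both CCO redox states.
    - ``blood_volume_fraction_with_SO2``: params ``(blood_volume_fraction, SO2)``,
      specific_absorption ``(mu_a_oxy_blood, mu_a_deoxy_blood)`` of whole blood.
    - ``direct``: params ``()``, specific_absorption is already the tissue-level
      contribution (how the packaged table values are represented).
    """

    name: str
    kind: str
    params: tuple = ()
    specific_absorption: float | tuple = 0.0

    @property
    def mu_a_contribution(self) -> float:
        return chromophore_mu_a(self)


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = mu_s (1 - g), 1/m.

    ``g`` is the scattering anisotropy (mean cosine); g = 1 (fully forward)
    is permitted and yields zero.
    """
    mu_s = np.asarray(mu_s, dtype=float)
    if np.any(mu_s < 0):
        raise DomainError("mu_s must be non-negative")
    if not np.all((0.0 <= np.asarray(g)) & (np.asarray(g) <= 1.0)):
        raise DomainError("g must lie in [0, 1]")
    out = mu_s * (1.0 - np.asarray(g, dtype=float))
    return float(out) if out.ndim == 0 else out


def diffusion_coefficient(mu_a: float, mu_s_prime: float):
    """Diffusion coefficient D = 1 / (3 (mu_a + mu_s')), in meters."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_a < 0) or np.any(mu_s_prime < 0):
        raise DomainError("optical coefficients must be non-negative")
    total = mu_a + mu_s_prime
    if np.any(total <= 0):
        raise DegenerateMediumError("mu_a + mu_s_prime must be positive")
    out = 1.0 / (3.0 * total)
    return float(out) if out.ndim == 0 else out


def effective_attenuation(mu_a: float, mu_s_prime: float):
    """Effective attenuation mu_eff = sqrt(3 mu_a (mu_a + mu_s')), 1/m."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_a < 0) or np.any(mu_s_prime < 0):
        raise DomainError("optical coefficients must be non-negative")
    out = np.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))
    return float(out) if out.ndim == 0 else out


def diffusion_constants(mu_a: float, mu_s_prime: float) -> DiffusionConstants:
    return DiffusionConstants(
        D=diffusion_coefficient(mu_a, mu_s_prime),
        mu_eff=effective_attenuation(mu_a, mu_s_prime),
    )


def chromophore_mu_a(contribution: ChromophoreContribution) -> float:
    """Tissue absorption contributed by one chromophore (1/m).

    Applies the product rule matching the contribution's descriptor kind; see
    :class:`ChromophoreContribution`.
    """
    kind = contribution.kind
    p = contribution.params
    eps = contribution.specific_absorption
    if kind == "volume_fraction":
        (fraction,) = p
        if not 0.0 <= fraction <= 1.0:
            raise DomainError("volume fraction must lie in [0, 1]")
        value = fraction * float(eps)
    elif kind == "mass_fraction_x_density":
        mass_fraction, density = p
        if not 0.0 <= mass_fraction <= 1.0:
            raise DomainError("mass fraction must lie in [0, 1]")
        if density < 0:
            raise DomainError("density must be non-negative")
        value = mass_fraction * density * float(eps)
    elif kind == "molar_concentration":
        (conc_mm,) = p
        if conc_mm < 0:
            raise DomainError("concentration must be non-negative")
        value = conc_mm * float(eps)
    elif kind == "blood_volume_fraction_with_SO2":
        bvf, so2 = p
        if not (0.0 <= bvf <= 1.0 and 0.0 <= so2 <= 1.0):
            raise DomainError("blood volume fraction and SO2 must lie in [0, 1]")
        mu_oxy, mu_deoxy = eps
        value = bvf * (so2 * mu_oxy + (1.0 - so2) * mu_deoxy)
    elif kind == "direct":
        value = float(eps)
    else:
        raise ConfigurationError(f"unknown concentration descriptor {kind!r}")
    if value < 0:
        raise DomainError("absorption contribution must be non-negative")
    return float(value)


def compose_tissue_mu_a(contributions: Iterable[ChromophoreContribution | float]) -> float:
    """Total tissue mu_a as the sum of chromophore contributions (1/m).

    Accepts either :class:`ChromophoreContribution` objects or plain
    already-computed contribution values; an empty list composes to zero.
    """
    total = 0.0
    for c in contributions:
        v = chromophore_mu_a(c) if isinstance(c, ChromophoreContribution) else float(c)
        if v < 0:
            raise DomainError("absorption contributions must be non-negative")
        total += v
    return total


def tissue_optical_properties(
    tissue: str,
    wavelength: float,
    overrides: Mapping[str, float] | None = None,
) -> TissueOpticalProperties:
    """Whole-tissue optical properties from the packaged tables.

    ``overrides`` may supply/replace ``mu_a`` and/or ``mu_s_prime`` (e.g. to
    run a single chromophore's absorption with unchanged scattering).
    """
    overrides = dict(overrides or {})
    tab = load_reference_tables()
    try:
        mu_a = overrides.get("mu_a", None)
        if mu_a is None:
            mu_a = tab.lookup(tissue, wavelength, "mu_a")
        mu_s_prime = overrides.get("mu_s_prime", None)
        if mu_s_prime is None:
            mu_s_prime = tab.lookup(tissue, wavelength, "mu_s_prime")
    except ConfigurationError:
        raise ConfigurationError(
            f"no tabulated optical properties for {tissue} at {wavelength} nm "
            "and overrides do not supply them"
        )
    return TissueOpticalProperties(tissue_id=tissue, mu_a=mu_a, mu_s_prime=mu_s_prime)
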