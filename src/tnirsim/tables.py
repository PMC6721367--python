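"""Packaged reference tables of tissue optical, thermal and perfusion parameters.

The package ships the parameter set of the four-layer adult head model it
implements: whole-tissue absorption and reduced scattering per wavelength
(630/700/810 nm), thermal conductivity / density / metabolic heat, blood
perfusion parameters, and the per-chromophore decomposition of gray- and
white-matter absorption (water, fat, oxy-/deoxyhemoglobin, oxidized and
reduced cytochrome c oxidase).

All values are stored verbatim in SI units (1/m, W/m·°C, kg/m³, 1/s, W/m³)
in CSV files under ``tnirsim/data`` and verified against a SHA-256 sidecar
at load time.  Two printed densities (CSF 0 kg/m³, brain 0.08 kg/m³) are
physically impossible; :mod:`tnirsim.bioheat` substitutes documented
defaults unless the caller asks for the as-printed values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .errors import ConfigurationError, TableIntegrityError

#: Supported wavelengths (nm) of the packaged optical tables.
WAVELENGTHS = (630, 700, 810)

#: Phantom layer labels, outermost first.
TISSUES = ("scalp_skull", "csf", "gray_matter", "white_matter")

#: Chromophores of the gray/white-matter absorption decomposition.
CHROMOPHORES = (
    "water",
    "fat",
    "oxyhemoglobin",
    "deoxyhemoglobin",
    "oxidized_cco",
    "reduced_cco",
)

#: Anisotropy factor assumed for every tissue layer.
ANISOTROPY_G = 0.89

#: Default refractive index (index-matched boundaries; reflection not modeled).
REFRACTIVE_INDEX = 1.37


@dataclass(frozen=True)
class ReferenceTables:
    """Container of the packaged parameter tables as DataFrames.

    Attributes
    ----------
    optical
        Whole-tissue ``mu_a`` and ``mu_s_prime`` (1/m) per tissue and wavelength.
    thermal_printed
        Thermal conductivity (W/m·°C), density (kg/m³) and metabolic heat
        (W/m³) per tissue, **as printed** (including the impossible densities).
    perfusion
        Blood specific heat (J/kg·K), perfusion rate (1/s), blood density
        (kg/m³) and metabolic heat (W/m³) per tissue.
    chromophores
        Per-chromophore absorption contribution (1/m) in gray and white matter.
    whole_tissue
        Total gray/white-matter absorption (1/m), the column sums of
        ``chromophores`` up to printed rounding.
    """

    optical: pd.DataFrame
    thermal_printed: pd.DataFrame
    perfusion: pd.DataFrame
    chromophores: pd.DataFrame
    whole_tissue: pd.DataFrame

    def lookup(self, tissue: str, wavelength: float, quantity: str) -> float:
        """Look up one scalar value.

        ``quantity`` is one of ``mu_a``, ``mu_s_prime``, ``whole_tissue_mu_a``
        or a chromophore name.
        """
        if quantity in ("mu_a", "mu_s_prime"):
            df = self.optical
            sel = df[(df.tissue == tissue) & (df.wavelength_nm == wavelength)]
            col = {"mu_a": "mu_a_per_m", "mu_s_prime": "mu_s_prime_per_m"}[quantity]
        elif quantity == "whole_tissue_mu_a":
            df = self.whole_tissue
            sel = df[(df.tissue == tissue) & (df.wavelength_nm == wavelength)]
            col = "mu_a_per_m"
        elif quantity in CHROMOPHORES:
            df = self.chromophores
            sel = df[
                (df.tissue == tissue)
                & (df.wavelength_nm == wavelength)
                & (df.chromophore == quantity)
            ]
            col = "mu_a_per_m"
        else:
            raise ConfigurationError(f"unknown quantity {quantity!r}")
        if len(sel) != 1:
            raise ConfigurationError(
                f"no tabulated value for ({tissue}, {wavelength} nm, {quantity})"
            )
        return float(sel[col].iloc[0])

    def chromophore_mu_a_map(self, wavelength: float) -> dict[str, dict[str, float]]:
        """Per-tissue ``{chromophore: mu_a}`` dict for ``wavelength``."""
        df = self.chromophores
        out: dict[str, dict[str, float]] = {}
        for tissue in ("gray_matter", "white_matter"):
            sel = df[(df.tissue == tissue) & (df.wavelength_nm == wavelength)]
            if sel.empty:
                raise ConfigurationError(f"wavelength {wavelength} nm not tabulated")
            out[tissue] = dict(zip(sel.chromophore, sel.mu_a_per_m))
        return out


def _read_verified(name: str, checksums: dict[str, str]) -> pd.DataFrame:
    ref = resources.files("tnirsim.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksums[name]:
        raise TableIntegrityError(
            f"packaged table {name} is corrupted "
            f"(sha256 {digest} != recorded {checksums[name]})"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


@lru_cache(maxsize=1)
def load_reference_tables() -> ReferenceTables:
    """Load (and integrity-check) the packaged parameter tables."""
    checksums = json.loads(
        (resources.files("tnirsim.data") / "checksums.json").read_text()
    )
    return ReferenceTables(
        optical=_read_verified("optical.csv", checksums),
        thermal_printed=_read_verified("thermal.csv", checksums),
        perfusion=_read_verified("perfusion.csv", checksums),
        chromophores=_read_verified("chromophores.csv", checksums),
        whole_tissue=_read_verified("whole_tissue.csv", checksums),
    )
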