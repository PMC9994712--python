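"""Acetyl-CoA-equivalent C:N ratios for PHA production media.

The "C:N" ratio here is *mol acetyl-CoA equivalents per mol nitrogen* — the
substrate concentration (g/L) is converted to molarity via the molar mass of
the supplied form (e.g. sodium salt), multiplied by the assumed number of
acetyl-CoA equivalents generated per molecule, and divided by the total
molar nitrogen supplied by the medium.  ``design_concentration`` inverts the
calculation to hit a target ratio.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_MOLAR_MASS",
    "SubstrateSpec",
    "NitrogenSource",
    "MediumSpec",
    "CNResult",
    "MM_PHA1",
    "MM_PHA2",
    "cn_ratio",
    "cn_summary",
    "design_concentration",
    "load_substrate_table",
    "nh4cl_nitrogen_fraction",
]

N_MOLAR_MASS = 14.007  # g/mol
NH4CL_MOLAR_MASS = 53.49  # g/mol

#: Grams of nitrogen per gram of yeast extract.  Assumed composition value
#: (typical total-N content of commercial yeast extract); configurable.
YE_NITROGEN_FRACTION = 0.105


def nh4cl_nitrogen_fraction() -> float:
    """Mass fraction of nitrogen in ammonium chloride."""
    return N_MOLAR_MASS / NH4CL_MOLAR_MASS


@dataclass(frozen=True)
class SubstrateSpec:
    """Substrate chemistry: concentration, supplied-form molar mass, equivalents.

    ``conc`` is g/L by default, or mol/L with ``conc_unit="mol_per_L"``.
    ``n_atoms`` counts nitrogen atoms per molecule (used only when the medium
    includes substrate-intrinsic nitrogen in the denominator).
    """

    name: str
    conc: float
    molar_mass: float
    acetyl_coa_equiv: float
    n_atoms: int = 0
    conc_unit: str = "g_per_L"

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError("conc must be >= 0")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")
        if self.acetyl_coa_equiv < 0:
            raise ValueError("acetyl_coa_equiv must be >= 0")
        if self.conc_unit not in ("g_per_L", "mol_per_L"):
            raise ValueError("conc_unit must be 'g_per_L' or 'mol_per_L'")

    @property
    def molarity(self) -> float:
        """mol substrate per liter."""
        if self.conc_unit == "mol_per_L":
            return self.conc
        return self.conc / self.molar_mass

    @property
    def equivalents_molarity(self) -> float:
        """mol acetyl-CoA equivalents per liter."""
        return self.molarity * self.acetyl_coa_equiv


@dataclass(frozen=True)
class NitrogenSource:
    name: str
    conc_g_per_L: float
    n_mass_fraction: float  # g N per g of the source

    @property
    def n_molarity(self) -> float:
        return self.conc_g_per_L * self.n_mass_fraction / N_MOLAR_MASS


@dataclass(frozen=True)
class MediumSpec:
    """Nitrogen supply of a production medium."""

    nitrogen_sources: tuple[NitrogenSource, ...]
    include_substrate_nitrogen: bool = False
    name: str = ""

    def n_molarity(self, substrate: SubstrateSpec | None = None) -> float:
        total = sum(src.n_molarity for src in self.nitrogen_sources)
        if (self.include_substrate_nitrogen and substrate is not None
                and substrate.n_atoms > 0):
            total += substrate.molarity * substrate.n_atoms
        return total


#: Nitrogen-limited production medium with 0.20 g/L ammonium chloride.
MM_PHA1 = MediumSpec(
    nitrogen_sources=(NitrogenSource("NH4Cl", 0.20, nh4cl_nitrogen_fraction()),),
    name="MM_PHA1",
)

#: Variant replacing ammonium chloride with 1.0 g/L yeast extract.
MM_PHA2 = MediumSpec(
    nitrogen_sources=(NitrogenSource("yeast extract", 1.0, YE_NITROGEN_FRACTION),),
    name="MM_PHA2",
)

_MEDIA = {"MM_PHA1": MM_PHA1, "MM_PHA2": MM_PHA2}


def get_medium(name: str) -> MediumSpec:
    try:
        return _MEDIA[name]
    except KeyError:
        raise KeyError(f"unknown medium {name!r}; available: {sorted(_MEDIA)}") from None


@dataclass(frozen=True)
class CNResult:
    substrate: str
    ratio: float  # mol acetyl-CoA equivalents per mol N


def cn_ratio(sub: SubstrateSpec, medium: MediumSpec) -> CNResult:
    """Acetyl-CoA-equivalent-to-nitrogen molar ratio for one substrate."""
    n = medium.n_molarity(sub)
    if n <= 0:
        raise ValueError("medium supplies no nitrogen; ratio undefined")
    return CNResult(substrate=sub.name, ratio=sub.equivalents_molarity / n)


def cn_summary(subs: Sequence[SubstrateSpec],
               medium: MediumSpec) -> tuple[float, float]:
    """Mean and sample SD of per-substrate ratios across a substrate set."""
    if len(subs) < 2:
        raise ValueError("need at least 2 substrates for a summary")
    ratios = np.array([cn_ratio(s, medium).ratio for s in subs])
    return float(np.mean(ratios)), float(np.std(ratios, ddof=1))


def design_concentration(target_ratio: float, sub_template: SubstrateSpec,
                         medium: MediumSpec) -> float:
    """Substrate concentration (g/L) achieving a target equivalents:N ratio.

    Inverse of :func:`cn_ratio`; exact round-trip by construction.  Substrate
    nitrogen cannot be included here (the inversion would become quadratic),
    so the medium must not set ``include_substrate_nitrogen``.
    """
    if sub_template.acetyl_coa_equiv <= 0:
        raise ValueError("substrate has zero acetyl-CoA equivalents")
    if target_ratio < 0:
        raise ValueError("target ratio must be >= 0")
    if medium.include_substrate_nitrogen and sub_template.n_atoms > 0:
        raise ValueError("cannot invert with substrate-intrinsic nitrogen included")
    n = medium.n_molarity()
    if n <= 0:
        raise ValueError("medium supplies no nitrogen")
    return target_ratio * n * sub_template.molar_mass / sub_template.acetyl_coa_equiv


def load_substrate_table(path: str | Path | None = None) -> list[SubstrateSpec]:
    """Load substrate specs from CSV (packaged reference table by default).

    Expected columns: ``name, acetyl_coa_equiv, conc_g_per_L, molar_mass,
    n_atoms``; extra columns are ignored.
    """
    if path is None:
        ref = importlib.resources.files("phascreen.data") / "substrates.csv"
        frame = pd.read_csv(str(ref))
    else:
        frame = pd.read_csv(path)
    required = {"name", "acetyl_coa_equiv", "conc_g_per_L", "molar_mass"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"substrate table missing columns: {sorted(missing)}")
    return [
        SubstrateSpec(
            name=row["name"],
            conc=float(row["conc_g_per_L"]),
            molar_mass=float(row["molar_mass"]),
            acetyl_coa_equiv=float(row["acetyl_coa_equiv"]),
            n_atoms=int(row.get("n_atoms", 0) or 0),
        )
        for _, row in frame.iterrows()
    ]


def results_to_frame(results: Sequence[CNResult]) -> pd.DataFrame:
    return pd.DataFrame([{"substrate": r.substrate, "ratio": r.ratio}
                         for r in results])
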