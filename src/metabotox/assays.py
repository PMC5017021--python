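"""Closed-form calculators for the companion biochemical assays:
dissolution stoichiometry of metal-oxide particles, glutathione redox
ratios, and efficiency-corrected relative qPCR quantification.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

#: IUPAC conventional atomic weights (u), 4-5 significant figures.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "S": 32.06,
    "Cl": 35.453,
    "K": 39.098,
    "Ti": 47.867,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
}

_PART = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    """Parse a simple chemical formula into an element -> count map.

    Hydrates/composites are joined by ``.``, ``*`` or the middle dot, with
    an optional integer multiplier (e.g. ``CuCl2.2H2O``).
    """
    counts: dict[str, int] = {}
    for part in re.split(r"[.*·⋅]", formula.strip()):
        if not part:
            continue
        m = re.match(r"(\d+)(.*)", part)
        mult = 1
        if m and m.group(1):
            mult = int(m.group(1))
            part = m.group(2)
        consumed = 0
        for sym, num in _PART.findall(part):
            if not sym:
                continue
            if sym not in ATOMIC_MASS:
                raise ValueError(f"unknown element {sym!r} in {formula!r}")
            counts[sym] = counts.get(sym, 0) + mult * (int(num) if num else 1)
            consumed += len(sym) + len(num)
        if consumed != len(part):
            raise ValueError(f"could not parse formula part {part!r}")
    if not counts:
        raise ValueError(f"empty formula {formula!r}")
    return counts


def formula_mass(formula: str | dict) -> float:
    """Formula weight in u (hydrates handled additively)."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


def metal_mass_fraction(formula: str | dict, element: str) -> float:
    """Mass fraction of ``element`` in the compound, in (0, 1]."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if element not in counts:
        raise ValueError(f"element {element!r} absent from formula")
    return ATOMIC_MASS[element] * counts[element] / formula_mass(counts)


def max_ion_release(conc_compound: float, formula: str | dict, element: str) -> float:
    """Maximum ion concentration released on complete dissolution of the
    compound at ``conc_compound`` (same mass-per-volume units)."""
    if conc_compound <= 0:
        raise ValueError("concentration must be positive")
    return conc_compound * metal_mass_fraction(formula, element)


def required_compound_conc(target_ion_conc: float, formula: str | dict, element: str) -> float:
    """Compound concentration needed to deliver ``target_ion_conc`` of the
    element on complete dissolution (inverse of :func:`max_ion_release`)."""
    if target_ion_conc <= 0:
        raise ValueError("target concentration must be positive")
    return target_ion_conc / metal_mass_fraction(formula, element)


def dissolution_percent(measured_ion_conc: float, max_ion_conc: float) -> float:
    """Measured release as a percentage of the stoichiometric maximum."""
    if max_ion_conc <= 0:
        raise ValueError("maximum release must be positive")
    return 100.0 * measured_ion_conc / max_ion_conc


#: Moles of reduced glutathione detected per mole of oxidized glutathione
#: after the assay's reduction step.
GSSG_TO_GSH_FACTOR = 2.0


def gsh_gssg_ratio(total_gsh_equiv_uM: float, gssg_well_gsh_equiv_uM: float) -> float:
    """GSH/GSSG ratio from the two-well luminescence assay.

    The total-glutathione well reports everything as reduced GSH; the
    NEM-blocked well reports only oxidized glutathione, also in GSH
    equivalents (one GSSG is reduced to two GSH for detection).  Hence
    GSSG = gssg_equiv / 2, reduced GSH = total - gssg_equiv, and the ratio
    is reduced/GSSG (infinite when no GSSG was detected).
    """
    if gssg_well_gsh_equiv_uM < 0 or total_gsh_equiv_uM < 0:
        raise ValueError("concentrations must be non-negative")
    if gssg_well_gsh_equiv_uM > total_gsh_equiv_uM:
        raise ValueError("GSSG equivalents cannot exceed total glutathione")
    gssg = gssg_well_gsh_equiv_uM / GSSG_TO_GSH_FACTOR
    reduced = total_gsh_equiv_uM - gssg_well_gsh_equiv_uM
    if gssg == 0:
        return math.inf
    return reduced / gssg


@dataclass
class QpcrMeasure:
    """Ct values and amplification efficiencies for one target/reference
    gene pair in treated vs control samples.

    Efficiencies are fold-amplification per cycle in (1, 2] (2 = perfect
    doubling); Ct values are non-negative cycle numbers.
    """

    ct_target_control: float
    ct_target_treated: float
    ct_ref_control: float
    ct_ref_treated: float
    e_target: float = 2.0
    e_ref: float = 2.0

    def __post_init__(self) -> None:
        for name in ("e_target", "e_ref"):
            e = getattr(self, name)
            if not 1.0 < e <= 2.0:
                raise ValueError(f"{name} must be in (1, 2]")
        for name in ("ct_target_control", "ct_target_treated", "ct_ref_control", "ct_ref_treated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def pfaffl_ratio(m: QpcrMeasure) -> float:
    """Efficiency-corrected relative expression ratio.

    ratio = E_target^(dCt_target) / E_ref^(dCt_ref), with dCt = control -
    treated for each gene.
    """
    d_target = m.ct_target_control - m.ct_target_treated
    d_ref = m.ct_ref_control - m.ct_ref_treated
    return m.e_target**d_target / m.e_ref**d_ref
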