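"""Formulation planning and RiboGreen encapsulation-efficiency QC.

A four-component LNP (ionizable lipid : sterol : phospholipid : PEG-lipid,
e.g. 50 : 38.5 : 10 : 1.5 molar) is charge-matched to its mRNA payload
through the N:P ratio — moles of ionizable amine per mole of nucleic-acid
phosphate.  Encapsulation efficiency comes from the dye-exclusion assay:
fluorescence of intact particles reports unencapsulated mRNA, fluorescence
after detergent lysis reports total mRNA, and

    EE = (1 - unencapsulated / total) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ValidationError, require

__all__ = [
    "FormulationSpec",
    "EEResult",
    "Recipe",
    "PLATE_COLUMNS",
    "validate_plate",
    "encapsulation_efficiency",
    "plan_formulation",
]

#: mean nucleotide mass used to convert mRNA mass to phosphate moles, g/mol.
#: One phosphate (and so one charge) per nucleotide; overridable per call.
MEAN_NUCLEOTIDE_MASS_G_PER_MOL = 330.0

#: required columns of a plate-reader table
PLATE_COLUMNS = ("well", "fluorescence", "lysed", "blank", "replicate")

DEFAULT_COMPONENTS = {
    "ionizable_lipid": 50.0,
    "sterol": 38.5,
    "phospholipid": 10.0,
    "peg_lipid": 1.5,
}


@dataclass(frozen=True)
class FormulationSpec:
    """Lipid recipe parameters.

    components maps the four lipid roles to molar-ratio numbers (any positive
    scale; only ratios matter).  np_ratio is ionizable amine : phosphate,
    assuming one protonatable amine per ionizable lipid (true for the
    MC3/DODMA class).  lipid_mix_concentration_mM sets the organic phase,
    aqueous_to_organic the mixing volume ratio.
    """

    components: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    lipid_mix_concentration_mM: float = 5.5
    np_ratio: float = 5.67
    aqueous_to_organic: float = 3.0
    mrna_length_nt: int | None = None

    def __post_init__(self) -> None:
        require(len(self.components) > 0, "components must not be empty")
        for name, ratio in self.components.items():
            require(ratio > 0, f"molar ratio of {name!r} must be > 0")
        require(self.np_ratio > 0, "np_ratio must be > 0")
        require(self.lipid_mix_concentration_mM > 0, "lipid concentration must be > 0")
        require(self.aqueous_to_organic > 0, "aqueous:organic ratio must be > 0")

    @property
    def mole_fractions(self) -> dict:
        total = sum(self.components.values())
        return {k: v / total for k, v in self.components.items()}


@dataclass(frozen=True)
class EEResult:
    ee_percent: float
    unencapsulated_signal: float
    total_signal: float
    per_replicate_ee: dict
    sd: float
    clamped: bool = False
    negative_signal_floored: bool = False


@dataclass(frozen=True)
class Recipe:
    """Per-batch amounts derived from a FormulationSpec and an mRNA mass."""

    mrna_mass_ug: float
    phosphate_nmol: float
    lipid_nmol: dict
    total_lipid_nmol: float
    organic_volume_uL: float
    aqueous_volume_uL: float


def validate_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Check a plate table's schema and minimal content for EE computation."""
    missing = [c for c in PLATE_COLUMNS if c not in wells.columns]
    require(not missing, f"plate table missing columns: {missing}")
    require(bool((wells["fluorescence"] >= 0).all()), "fluorescence must be >= 0")
    data = wells[~wells["blank"].astype(bool)]
    require(bool(data["lysed"].astype(bool).any()),
            "need >= 1 lysed (total-mRNA) well")
    require(bool((~data["lysed"].astype(bool)).any()),
            "need >= 1 unlysed (unencapsulated-mRNA) well")
    return wells


def encapsulation_efficiency(wells: pd.DataFrame) -> EEResult:
    """Encapsulation efficiency from a RiboGreen-style plate table.

    Blank wells (if any) define the background, subtracted from the mean
    unlysed (unencapsulated) and lysed (total) signals; then
    EE = (1 - unenc/total) * 100.  Negative blank-corrected signals are
    floored at 0 and EE is clamped to [0, 100]; both conditions are flagged
    on the result.  When the replicate column pairs wells, per-replicate EEs
    and their SD are reported too.
    """
    wells = validate_plate(wells)
    blank_mask = wells["blank"].astype(bool)
    blank = float(wells.loc[blank_mask, "fluorescence"].mean()) if blank_mask.any() else 0.0
    data = wells[~blank_mask]
    lysed = data[data["lysed"].astype(bool)]
    unlysed = data[~data["lysed"].astype(bool)]

    floored = False

    def corrected(df: pd.DataFrame) -> float:
        nonlocal floored
        v = float(df["fluorescence"].mean()) - blank
        if v < 0:
            floored = True
            v = 0.0
        return v

    total = corrected(lysed)
    if total <= 0:
        raise ValidationError("total-mRNA signal <= 0 after blank correction")
    unenc = corrected(unlysed)

    def ee_of(u: float, t: float) -> tuple[float, bool]:
        raw = (1.0 - u / t) * 100.0
        return min(max(raw, 0.0), 100.0), not (0.0 <= raw <= 100.0)

    ee, clamped = ee_of(unenc, total)

    per_rep: dict = {}
    reps = sorted(set(lysed["replicate"]) & set(unlysed["replicate"]))
    for rep in reps:
        t = float(lysed.loc[lysed["replicate"] == rep, "fluorescence"].mean()) - blank
        u = float(unlysed.loc[unlysed["replicate"] == rep, "fluorescence"].mean()) - blank
        if t > 0:
            per_rep[rep], c = ee_of(max(u, 0.0), t)
            clamped = clamped or c
    sd = float(np.std(list(per_rep.values()), ddof=1)) if len(per_rep) > 1 else 0.0

    return EEResult(
        ee_percent=ee,
        unencapsulated_signal=unenc,
        total_signal=total,
        per_replicate_ee=per_rep,
        sd=sd,
        clamped=clamped,
        negative_signal_floored=floored,
    )


def plan_formulation(
    spec: FormulationSpec,
    mrna_mass_ug: float,
    *,
    nucleotide_mass: float = MEAN_NUCLEOTIDE_MASS_G_PER_MOL,
) -> Recipe:
    """Per-batch lipid amounts and phase volumes for a given mRNA mass.

    phosphate nmol = mass / nucleotide mass; ionizable-lipid nmol =
    N:P * phosphate nmol (one amine per lipid); the remaining lipids follow
    from the molar ratios; the organic volume from the lipid-mix
    concentration and the aqueous volume from the aqueous:organic ratio.
    """
    require(mrna_mass_ug >= 0, "mRNA mass must be >= 0")
    require("ionizable_lipid" in spec.components,
            "formulation must contain an 'ionizable_lipid' component")
    fractions = spec.mole_fractions

    phosphate_nmol = mrna_mass_ug / nucleotide_mass * 1e3   # µg/(g/mol) -> nmol
    ionizable_nmol = spec.np_ratio * phosphate_nmol
    total_lipid = ionizable_nmol / fractions["ionizable_lipid"]
    lipid_nmol = {name: total_lipid * frac for name, frac in fractions.items()}
    organic_uL = total_lipid / spec.lipid_mix_concentration_mM  # nmol / (nmol/µL)
    aqueous_uL = spec.aqueous_to_organic * organic_uL

    return Recipe(
        mrna_mass_ug=float(mrna_mass_ug),
        phosphate_nmol=float(phosphate_nmol),
        lipid_nmol=lipid_nmol,
        total_lipid_nmol=float(total_lipid),
        organic_volume_uL=float(organic_uL),
        aqueous_volume_uL=float(aqueous_uL),
    )
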