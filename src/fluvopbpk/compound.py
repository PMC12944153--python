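"""Fluvoxamine compound definition.

The compound model bundles the physicochemical, absorption, distribution and
elimination parameters needed by the IVIVE chain and the minimal-PBPK engine:

* physicochemistry — molecular weight 318.3 g/mol, logP(o:w) 3, pKa 8.7
  (monoprotic base), fraction unbound in plasma (fup) 0.14, blood-to-plasma
  concentration ratio (B:P) 1.5;
* absorption — first-order, with the absorption rate constant derived from
  the effective human jejunal permeability via the cylindrical-gut relation
  ka = 2·Peff/R;
* distribution — minimal-PBPK: steady-state volume Vss 21 L/kg split into a
  central compartment and a single adjusting (peripheral) compartment of
  Vsac 6 L/kg, exchanging at inter-compartmental clearance Q 0.5 L/h;
* elimination — a CYP2D6 Michaelis–Menten pathway (Vmax 70 pmol/min/pmol
  enzyme, Km 38.6 uM) plus one lumped linear non-CYP2D6 intrinsic clearance
  whose magnitude is set by calibration (see :mod:`fluvopbpk.ivive`).

All containers are frozen dataclasses; a compound round-trips loss-free
through a plain YAML mapping (:func:`to_dict` / :func:`from_dict`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "AbsorptionParams",
    "DistributionParams",
    "EnzymePathway",
    "EliminationParams",
    "CompoundModel",
    "default_fluvoxamine",
    "ka_from_peff",
    "fu_blood",
    "to_dict",
    "from_dict",
    "save_yaml",
    "load_yaml",
]


class CompoundValidationError(ValueError):
    """A compound parameter violates its physical constraints."""


def ka_from_peff(peff_cm_s: float, radius_cm: float = 1.75) -> float:
    """First-order absorption rate constant from intestinal permeability.

    Treats the small intestine as a cylinder of radius ``radius_cm``; the
    fractional absorption rate is then surface-to-volume times permeability,
    ka = 2·Peff/R, converted from 1/s to 1/h.
    """
    if peff_cm_s <= 0 or radius_cm <= 0:
        raise CompoundValidationError("peff and radius must be positive")
    return 2.0 * peff_cm_s / radius_cm * 3600.0


@dataclass(frozen=True)
class AbsorptionParams:
    """First-order oral absorption."""

    model: str = "first_order"
    fa: float = 1.0          # fraction absorbed from gut lumen
    fg: float = 1.0          # gut-wall availability
    ka_per_h: float = 2.333  # 1/h
    # provenance of ka: permeability inputs (not re-derived at run time)
    peff_1e4_cm_s: float = 5.67          # Peff,man, 1e-4 cm/s
    mdck_papp_1e6_cm_s: float = 31.7     # apparent MDCK II Papp, 1e-6 cm/s
    mdck_scalar: float = 1.3983

    def __post_init__(self) -> None:
        if not (0 < self.fa <= 1 and 0 < self.fg <= 1):
            raise CompoundValidationError("fa and fg must lie in (0, 1]")
        if self.ka_per_h <= 0:
            raise CompoundValidationError("ka must be positive")


@dataclass(frozen=True)
class DistributionParams:
    """Minimal-PBPK distribution: central + single adjusting compartment."""

    vss_l_kg: float = 21.0
    q_inter_l_h: float = 0.5
    vsac_l_kg: float = 6.0

    def __post_init__(self) -> None:
        if not (self.vss_l_kg > self.vsac_l_kg > 0):
            raise CompoundValidationError("require vss > vsac > 0")
        if self.q_inter_l_h <= 0:
            raise CompoundValidationError("q_inter must be positive")

    @property
    def v_central_l_kg(self) -> float:
        """Central volume preserving the stated Vss: (Vss - Vsac) L/kg."""
        return self.vss_l_kg - self.vsac_l_kg


@dataclass(frozen=True)
class EnzymePathway:
    """Enzyme-kinetic elimination pathway (per pmol of enzyme)."""

    enzyme: str = "CYP2D6"
    vmax_pmol_min_pmol: float = 70.0
    km_um: float = 38.6
    # dimensionless activity scalar applied during IVIVE; set by calibration
    activity_scalar: float = 1.0

    def __post_init__(self) -> None:
        if self.vmax_pmol_min_pmol <= 0 or self.km_um <= 0:
            raise CompoundValidationError("vmax and km must be positive")
        if self.activity_scalar < 0:
            raise CompoundValidationError("activity scalar must be >= 0")


@dataclass(frozen=True)
class EliminationParams:
    pathways: tuple[EnzymePathway, ...] = (EnzymePathway(),)
    # lumped non-CYP2D6 unbound intrinsic clearance, uL/min/mg microsomal
    # protein; 0 until calibrate_elimination fills it in
    clint_additional_ul_min_mg: float = 0.0
    renal_cl_l_h: float = 0.0

    def __post_init__(self) -> None:
        if self.clint_additional_ul_min_mg < 0 or self.renal_cl_l_h < 0:
            raise CompoundValidationError("clearances must be >= 0")
        if not self.pathways and self.clint_additional_ul_min_mg == 0:
            raise CompoundValidationError("need at least one elimination route")

    def pathway(self, enzyme: str = "CYP2D6") -> EnzymePathway:
        for p in self.pathways:
            if p.enzyme == enzyme:
                return p
        raise KeyError(enzyme)


@dataclass(frozen=True)
class CompoundModel:
    name: str = "fluvoxamine"
    mw_g_mol: float = 318.3
    logp: float = 3.0
    pka: float = 8.7
    fup: float = 0.14
    bp_ratio: float = 1.5
    absorption: AbsorptionParams = field(default_factory=AbsorptionParams)
    distribution: DistributionParams = field(default_factory=DistributionParams)
    elimination: EliminationParams = field(default_factory=EliminationParams)

    def __post_init__(self) -> None:
        if not (0 < self.fup <= 1):
            raise CompoundValidationError("fup must lie in (0, 1]")
        if self.bp_ratio <= 0 or self.mw_g_mol <= 0:
            raise CompoundValidationError("bp_ratio and mw must be positive")

    @property
    def fu_blood(self) -> float:
        return fu_blood(self)

    @property
    def km_ng_ml(self) -> float:
        """Km expressed as an unbound concentration in ng/mL."""
        return self.elimination.pathway().km_um * self.mw_g_mol

    def replace(self, **kw) -> "CompoundModel":
        return dataclasses.replace(self, **kw)


def fu_blood(compound: CompoundModel) -> float:
    """Unbound fraction referenced to whole blood, fu_B = fup/(B:P)."""
    return compound.fup / compound.bp_ratio


def default_fluvoxamine() -> CompoundModel:
    """The fluvoxamine parameter set used throughout the package.

    The non-CYP2D6 clearance and the CYP2D6 activity scalar are left at
    their uncalibrated defaults; run
    :func:`fluvopbpk.ivive.calibrate_elimination` before simulating.
    """
    absorption = AbsorptionParams(
        ka_per_h=ka_from_peff(5.67e-4, radius_cm=1.75),
    )
    return CompoundModel(absorption=absorption)


# ---------------------------------------------------------------------------
# serialization


def to_dict(compound: CompoundModel) -> dict:
    d = dataclasses.asdict(compound)
    d["elimination"]["pathways"] = [
        dataclasses.asdict(p) for p in compound.elimination.pathways
    ]
    return d


def from_dict(d: dict) -> CompoundModel:
    d = dict(d)
    absorption = AbsorptionParams(**d.pop("absorption"))
    distribution = DistributionParams(**d.pop("distribution"))
    elim = dict(d.pop("elimination"))
    elim["pathways"] = tuple(EnzymePathway(**p) for p in elim["pathways"])
    elimination = EliminationParams(**elim)
    return CompoundModel(
        absorption=absorption,
        distribution=distribution,
        elimination=elimination,
        **d,
    )


def save_yaml(compound: CompoundModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(compound), fh, sort_keys=False)


def load_yaml(path) -> CompoundModel:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))
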