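"""Tissue material library.

All moduli are stored in GPa, Poisson ratios dimensionless, permeabilities in
m^4/(N s) (intrinsic permeability over fluid viscosity).  Conversion to SI
happens only inside the mechanics module.

The default table covers every phenotype the mechano-regulation classifier can
emit plus every region material of the bone--implant model: titanium implant,
natural tooth, prosthesis crown, bone graft (elastic only, used by the
conventional-comparison model), cortical and cancellous bone, and the soft
tissue phenotypes (granulation, fibrous, cartilage, immature and mature bone).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "TissueProperties",
    "TissueLibrary",
    "BONE_PHENOTYPES",
    "POROUS_PHENOTYPES",
    "DEFAULT_POROSITY",
]

#: phenotypes whose modulus scales with the bone-quality multiplier
BONE_PHENOTYPES = frozenset({"cortical", "cancellous", "immature_bone", "mature_bone"})

#: materials with pore fluid (everything with a permeability entry)
POROUS_PHENOTYPES = frozenset(
    {
        "cortical",
        "cancellous",
        "granulation",
        "fibrous",
        "cartilage",
        "immature_bone",
        "mature_bone",
        "resorbed",
    }
)

#: pore volume fractions used by the consolidation solver (soft tissue vs bone)
DEFAULT_POROSITY = {
    "granulation": 0.8,
    "fibrous": 0.8,
    "cartilage": 0.8,
    "resorbed": 0.8,
    "immature_bone": 0.3,
    "mature_bone": 0.3,
    "cortical": 0.3,
    "cancellous": 0.3,
}


@dataclass(frozen=True)
class TissueProperties:
    """Linear-elastic (and optionally poroelastic) constants of one tissue.

    Parameters
    ----------
    young_modulus : float
        Young's modulus in GPa; must be positive.
    poisson_ratio : float
        Poisson ratio, in [0, 0.5).
    permeability : float or None
        Darcy permeability in m^4/(N s); ``None`` for non-porous materials
        (implant, tooth, prosthesis, bone graft) which are modeled as purely
        elastic inside the consolidation solve.
    """

    young_modulus: float
    poisson_ratio: float
    permeability: float | None = None

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ValueError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError(f"poisson_ratio must be in [0, 0.5), got {self.poisson_ratio}")
        if self.permeability is not None and not self.permeability > 0:
            raise ValueError(f"permeability must be > 0 when present, got {self.permeability}")

    @property
    def is_porous(self) -> bool:
        return self.permeability is not None


def _default_table() -> dict[str, TissueProperties]:
    return {
        "implant": TissueProperties(113.8, 0.34, None),  # Ti6Al4V
        "tooth": TissueProperties(20.0, 0.3, None),
        "prosthesis": TissueProperties(80.0, 0.3, None),
        "bone_graft": TissueProperties(2.0, 0.3, None),
        "cortical": TissueProperties(13.7, 0.3, 1e-17),
        "cancellous": TissueProperties(2.0, 0.3, 3.7e-13),
        "granulation": TissueProperties(0.001, 0.17, 1e-14),
        "fibrous": TissueProperties(0.002, 0.17, 1e-14),
        "cartilage": TissueProperties(0.01, 0.17, 5e-15),
        "immature_bone": TissueProperties(1.0, 0.3, 1e-13),
        "mature_bone": TissueProperties(6.0, 0.3, 3.7e-13),
        # "initial resorption" has no tabulated properties; resorbed elements
        # keep granulation-tissue values and stay classifiable in later days
        "resorbed": TissueProperties(0.001, 0.17, 1e-14),
    }


@dataclass
class TissueLibrary:
    """Phenotype -> property map with an optional bone-quality multiplier.

    ``bone_modulus_multiplier`` scales the Young's modulus of cortical,
    cancellous, immature and mature bone (e.g. 1.4 for a higher-bone-strength
    patient); soft tissues and non-bone materials are unaffected.
    """

    table: dict[str, TissueProperties] = field(default_factory=_default_table)
    bone_modulus_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not self.bone_modulus_multiplier > 0:
            raise ValueError("bone_modulus_multiplier must be > 0")

    def lookup(self, phenotype: str) -> TissueProperties:
        """Return the (possibly bone-quality-scaled) properties of a phenotype."""
        try:
            props = self.table[phenotype]
        except KeyError:
            raise KeyError(
                f"unknown phenotype {phenotype!r}; known: {sorted(self.table)}"
            ) from None
        if phenotype in BONE_PHENOTYPES and self.bone_modulus_multiplier != 1.0:
            props = replace(
                props, young_modulus=props.young_modulus * self.bone_modulus_multiplier
            )
        return props

    def __contains__(self, phenotype: str) -> bool:
        return phenotype in self.table

    def porosity(self, phenotype: str) -> float:
        return DEFAULT_POROSITY.get(phenotype, 0.3)


def lookup_properties(lib: TissueLibrary, phenotype: str) -> TissueProperties:
    """Functional wrapper around :meth:`TissueLibrary.lookup`."""
    return lib.lookup(phenotype)
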