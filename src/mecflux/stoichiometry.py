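"""Compounds, electron equivalents, and oxidation half-reactions.

The electron ledger counts everything in electron equivalents (e⁻ eq): the
moles of electrons released by complete oxidation of one mole of a compound
to HCO₃⁻, H₂O and NH₄⁺.  For a compound C_c H_h O_o N_n with formal charge z
the degree of reduction is

    γ = 4c + h − 2o − 3n − z

which is the same number obtained by balancing the oxidation half-reaction
explicitly; both routes are implemented and cross-checked in the test suite.
Formation free energies follow the Thauer pH-7 convention (H⁺ at
−39.87 kJ/mol) so that full-reaction ΔG°′ values come out on the standard
biochemical scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Compound",
    "HalfReaction",
    "InvalidCompoundError",
    "REGISTRY",
    "electron_equivalents",
    "oxidation_half_reaction",
    "parse_formula",
]

#: Faraday constant, C per mol electrons.
FARADAY = 96485.0

_ELEMENTS = ("C", "H", "O", "N")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidCompoundError(ValueError):
    """Raised for compositions that cannot act as an electron donor or sink."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an element-count string such as ``"C3H5O2"`` into counts.

    Only C, H, O and N are accepted; anything else is an error.
    """
    counts: dict[str, int] = {el: 0 for el in _ELEMENTS}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise InvalidCompoundError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in _ELEMENTS:
            raise InvalidCompoundError(
                f"unsupported element {el!r} in formula {formula!r}"
            )
        counts[el] += int(num) if num else 1
    if pos != len(formula):
        raise InvalidCompoundError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Compound:
    """A chemical species in the electron ledger.

    Parameters
    ----------
    name
        Identifier used in registries and reports.
    composition
        Counts of C, H, O, N atoms (non-negative integers).
    charge
        Formal charge (the anion formula is conventional for organic acids;
        the γ formula makes acid and anion agree).
    dGf
        Standard formation free energy at pH 7 (kJ/mol), Thauer convention;
        optional, needed only for reaction ΔG°′.
    phase
        ``"aqueous"`` or ``"gas"``; informational, never affects γ.
    """

    name: str
    composition: dict[str, int] = field(hash=False)
    charge: int = 0
    dGf: float | None = None
    phase: str = "aqueous"

    def __post_init__(self) -> None:
        comp = {el: int(self.composition.get(el, 0)) for el in _ELEMENTS}
        if any(v < 0 for v in comp.values()):
            raise InvalidCompoundError(
                f"{self.name}: composition counts must be non-negative"
            )
        object.__setattr__(self, "composition", comp)
        if self.phase not in ("aqueous", "gas"):
            raise InvalidCompoundError(f"{self.name}: unknown phase {self.phase!r}")

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: str,
        charge: int = 0,
        dGf: float | None = None,
        phase: str = "aqueous",
    ) -> "Compound":
        return cls(name, parse_formula(formula), charge, dGf, phase)

    @property
    def gamma(self) -> int:
        """Electron equivalents per mole (degree of reduction)."""
        return electron_equivalents(self)


def electron_equivalents(compound: Compound) -> int:
    """Electrons released by complete oxidation of one mole of *compound*.

    γ = 4C + H − 2O − 3N − charge, referenced to the HCO₃⁻ / H₂O / NH₄⁺
    end products.  Independent of phase.  A negative result signals a
    composition typo and raises :class:`InvalidCompoundError`.
    """
    c = compound.composition
    gamma = 4 * c["C"] + c["H"] - 2 * c["O"] - 3 * c["N"] - compound.charge
    if gamma < 0:
        raise InvalidCompoundError(
            f"{compound.name}: negative electron equivalents ({gamma}); "
            "check the composition and charge"
        )
    return gamma


@dataclass(frozen=True)
class HalfReaction:
    """Oxidation half-reaction of a donor to HCO₃⁻ + H⁺ + e⁻ (+ H₂O, NH₄⁺).

    ``coefficients`` maps species name → signed stoichiometric coefficient
    (products positive, the donor −1); ``electrons`` is e⁻ released per mole
    donor and always equals the donor's γ.
    """

    donor: Compound
    electrons: int
    coefficients: dict[str, float] = field(hash=False)

    def element_charge_residuals(self) -> dict[str, float]:
        """Element (C,H,O,N) and charge residuals; all zero when balanced."""
        species = {
            "HCO3-": ({"C": 1, "H": 1, "O": 3}, -1),
            "H+": ({"H": 1}, +1),
            "H2O": ({"H": 2, "O": 1}, 0),
            "NH4+": ({"N": 1, "H": 4}, +1),
            self.donor.name: (self.donor.composition, self.donor.charge),
        }
        res = {el: 0.0 for el in _ELEMENTS}
        charge = 0.0
        for name, nu in self.coefficients.items():
            comp, z = species[name]
            for el in _ELEMENTS:
                res[el] += nu * comp.get(el, 0)
            charge += nu * z
        charge -= self.electrons  # e⁻ are products with charge −1
        res["charge"] = charge
        return res


def oxidation_half_reaction(compound: Compound) -> HalfReaction:
    """Balance the oxidation of *compound* to HCO₃⁻ + H⁺ + e⁻ (+ H₂O, NH₄⁺).

    For C_c H_h O_o N_n^z:

        donor + (3c − o) H₂O → c HCO₃⁻ + n NH₄⁺ + p H⁺ + γ e⁻

    with proton count p fixed by hydrogen balance and γ by charge balance.
    The returned half-reaction is verified element- and charge-balanced.
    """
    comp = compound.composition
    c, h, o, n = comp["C"], comp["H"], comp["O"], comp["N"]
    gamma = electron_equivalents(compound)
    water = 3 * c - o
    protons = h + 2 * water - c - 4 * n
    coeffs: dict[str, float] = {compound.name: -1.0}
    if water:
        # consumed when positive, released (oxygen-rich donors) when negative
        coeffs["H2O"] = -float(water)
    if c:
        coeffs["HCO3-"] = float(c)
    if n:
        coeffs["NH4+"] = float(n)
    coeffs["H+"] = float(protons)
    rxn = HalfReaction(donor=compound, electrons=gamma, coefficients=coeffs)
    residuals = rxn.element_charge_residuals()
    if any(abs(v) > 1e-9 for v in residuals.values()):
        raise InvalidCompoundError(
            f"{compound.name}: oxidation half-reaction does not balance "
            f"(residuals {residuals})"
        )
    return rxn


def _build_registry() -> dict[str, Compound]:
    # Thauer-convention ΔGf°′ at pH 7 (kJ/mol); H⁺ carries −39.87 so that
    # pH-7 reaction free energies come out directly.
    spec = [
        ("propionate", "C3H5O2", -1, -361.08, "aqueous"),
        ("acetate", "C2H3O2", -1, -369.41, "aqueous"),
        ("formate", "CHO2", -1, -351.04, "aqueous"),
        ("hydrogen", "H2", 0, 0.0, "gas"),
        ("methane", "CH4", 0, -50.75, "gas"),
        ("carbon_dioxide", "CO2", 0, -394.36, "gas"),
        ("bicarbonate", "HCO3", -1, -586.85, "aqueous"),
        ("water", "H2O", 0, -237.18, "aqueous"),
        ("proton", "H", 1, -39.87, "aqueous"),
    ]
    return {
        name: Compound.from_formula(name, formula, charge, dGf, phase)
        for name, formula, charge, dGf, phase in spec
    }


#: Built-in compounds covering every species the propionate ledger touches.
REGISTRY: dict[str, Compound] = _build_registry()


def dump_registry(registry: dict[str, Compound], path) -> None:
    """Serialize a compound registry to a YAML config file."""
    import yaml

    entries = [
        {
            "name": c.name,
            "formula": "".join(
                f"{el}{n if n > 1 else ''}"
                for el, n in c.composition.items()
                if n > 0
            ),
            "charge": c.charge,
            "dGf": c.dGf,
            "phase": c.phase,
        }
        for c in registry.values()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def load_registry(path) -> dict[str, Compound]:
    """Load a compound registry from a YAML config file.

    Each entry needs ``name`` and ``formula`` (element-count string, e.g.
    ``"C3H5O2"``); ``charge``, ``dGf`` and ``phase`` are optional.
    """
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    registry = {}
    for e in entries:
        registry[e["name"]] = Compound.from_formula(
            e["name"],
            e["formula"],
            charge=int(e.get("charge", 0)),
            dGf=e.get("dGf"),
            phase=e.get("phase", "aqueous"),
        )
    return registry
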