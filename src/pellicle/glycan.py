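"""Glycan composition masses and genotype-to-structure feature prediction.

Masses are computed additively from dehydrated residue masses plus one water
for the free reducing end, with HPO3 (phosphate monoester) and C2H2O
(O-acetyl) increments.  Borohydride reduction of the reducing end opens the
ring and adds two hydrogens; NaBD4 reduction replaces one of them with
deuterium per label.  The headline check: a phosphorylated hexasaccharide
reduced with NaBD4 (Hex6 P1 red+D) has a nearest-integer monoisotopic
neutral mass of 1073 u.

Structure features are precursor-level predictions from a typed locus: the
dTDP-rhamnose pathway, its talose branch (the 4-dehydrogenase interconverts
dTDP-6-deoxy-L-talose with the rhamnose pathway intermediate, so 6dTal
requires the Rha pathway), UDP-Glc/Gal interconversion by an NAD-dependent
epimerase, and O-acetylation by an acetylase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

# monoisotopic / average residue and increment masses (u)
MONO = {
    "hex": 162.0528, "dhex": 146.0579, "hexnac": 203.0794,
    "water": 18.0106, "phosphate": 79.9663, "acetyl": 42.0106,
    "H": 1.00783, "D": 2.01410,
}
AVG = {
    "hex": 162.1406, "dhex": 146.1412, "hexnac": 203.1925,
    "water": 18.0153, "phosphate": 79.9799, "acetyl": 42.0367,
    "H": 1.00794, "D": 2.01410,
}


class GlycanError(ValueError):
    pass


@dataclass
class GlycanComposition:
    hex: int = 0
    dhex: int = 0
    hexnac: int = 0
    phosphate: int = 0
    acetyl: int = 0
    reduced: bool = False
    deuterium_labels: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "dhex", "hexnac", "phosphate", "acetyl", "deuterium_labels"):
            if getattr(self, name) < 0:
                raise GlycanError(f"{name} must be >= 0")
        if self.deuterium_labels and not self.reduced:
            raise GlycanError("deuterium labels require a reduced composition")

    @property
    def residues(self) -> int:
        return self.hex + self.dhex + self.hexnac


def composition_mass(comp: GlycanComposition) -> tuple[float, float]:
    """(monoisotopic, average) neutral mass in u.  Deterministic."""
    if comp.residues < 1:
        raise GlycanError("composition needs at least one residue")

    def total(m: dict) -> float:
        mass = (comp.hex * m["hex"] + comp.dhex * m["dhex"]
                + comp.hexnac * m["hexnac"] + m["water"]
                + comp.phosphate * m["phosphate"] + comp.acetyl * m["acetyl"])
        if comp.reduced:
            mass += 2 * m["H"] + comp.deuterium_labels * (m["D"] - m["H"])
        return mass

    return total(MONO), total(AVG)


_TOKEN_RE = re.compile(
    r"^(?:(?P<res>Hex|dHex|HexNAc|P|Ac)(?P<count>\d*)|(?P<red>red)(?P<label>(\+D)*))$",
    re.IGNORECASE,
)
_RES_FIELD = {"hex": "hex", "dhex": "dhex", "hexnac": "hexnac", "p": "phosphate", "ac": "acetyl"}


def parse_composition(text: str) -> GlycanComposition:
    """Parse the compact composition grammar, e.g. ``"Hex6 P1 red+D"``.

    Tokens are whitespace-separated: ``Hex``/``dHex``/``HexNAc``/``P``/``Ac``
    with an optional count (default 1), and ``red`` optionally followed by
    one ``+D`` per deuterium label.
    """
    fields: dict = {}
    for token in text.split():
        m = _TOKEN_RE.match(token)
        if not m:
            raise GlycanError(f"cannot parse composition token {token!r}")
        if m.group("res"):
            name = _RES_FIELD[m.group("res").lower()]
            fields[name] = fields.get(name, 0) + int(m.group("count") or 1)
        else:
            fields["reduced"] = True
            fields["deuterium_labels"] = fields.get("deuterium_labels", 0) + \
                (m.group("label") or "").count("+D")
    return GlycanComposition(**fields)


@dataclass
class StructureFeatureSet:
    precursors: set[str] = field(default_factory=set)
    modifications: set[str] = field(default_factory=set)
    organization_note: str = ""


_TALOSE_RE = re.compile(r"talose 4-dehydrogenase", re.IGNORECASE)
_PHOSPHO_RE = re.compile(r"phosphotransferase|kinase", re.IGNORECASE)


def predict_structure_features(typed) -> StructureFeatureSet:
    """Sugar precursors and modifications implied by a typed locus.

    UDP-Glc is always listed as the baseline precursor.  dTDP-6dTal is only
    predicted on top of an intact dTDP-Rha pathway.
    """
    features = StructureFeatureSet(precursors={"UDP-Glc"})
    roles = {c.role for c in typed.roles}
    products = " | ".join(c.gene.product for c in typed.roles)
    has_rml = any(r.startswith("precursor_rml") for r in roles)
    if has_rml:
        features.precursors.add("dTDP-Rha")
        if _TALOSE_RE.search(products):
            features.precursors.add("dTDP-6dTal")
    if "modification_epimerase" in roles:
        features.precursors.add("UDP-Gal")
    if "modification_acetylase" in roles:
        features.modifications.add("O-acetylation")
    if _PHOSPHO_RE.search(products):
        features.modifications.add("phosphorylation_candidate")
    notes = {
        "canonical_rhamnan_psp": "canonical rhamnan-PSP dual-chain organization",
        "non_canonical": "non-canonical organization (no priming GT/flippase: "
                         "rhamnan and side chain likely assembled and exported together)",
        "oligomeric": "priming GT without polymerase/co-polymerase: "
                      "side chain likely an oligomer",
    }
    features.organization_note = notes.get(typed.organization, typed.organization)
    return features
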