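"""SNFG vocabulary: monosaccharide classes, substituents, symbols.

The Symbol Nomenclature for Glycans maps monosaccharide classes to
(shape, color) pairs and defines how decorated residues collapse to named
classes — e.g. glucose carrying an N-acetyl group on carbon 2 *is*
N-acetylglucosamine (GlcNAc, blue square). This module holds that closed
dictionary and the matching logic used both by document normalization and
by symbol assignment during rendering.

Internal token conventions (shared across the package):

* anomer: ``a`` (alpha), ``b`` (beta), ``o`` (open chain), ``x`` (unknown)
* configuration: ``d``, ``l``, ``x`` (unknown)
* backbone modifications: ``deoxy``, ``acid``, ``ketone``, ``aldehyde``,
  ``en`` with 1-based carbon positions; ``-1`` is the unknown position
  sentinel everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import VocabularyError

UNKNOWN = -1

SUPERCLASS_LENGTH = {
    "TRI": 3,
    "TET": 4,
    "PEN": 5,
    "HEX": 6,
    "HEP": 7,
    "OCT": 8,
    "NON": 9,
}

MOD_KINDS = ("deoxy", "acid", "ketone", "aldehyde", "en")

# SNFG color palette (name -> hex) as published.
PALETTE = {
    "white": "#FFFFFF",
    "blue": "#0090BC",
    "green": "#00A651",
    "yellow": "#FFD400",
    "orange": "#F47920",
    "pink": "#F69EA1",
    "purple": "#A54399",
    "lightblue": "#8FCCE9",
    "brown": "#A17A4D",
    "red": "#ED1C24",
}


@dataclass(frozen=True)
class SubstituentClass:
    """A non-sugar decoration from the SNFG substituent vocabulary."""

    name: str
    #: GlycoCT linkage-type letter on the parent side: ``d`` for
    #: N-replacement substituents (the amine replaces the hydroxyl),
    #: ``o`` for O-linked ones.
    parent_link: str
    #: WURCS MAP expression (without position prefix).
    wurcs_map: str
    #: short text used when annotating symbols ("2S" etc.)
    short: str


_SUBSTITUENTS = [
    SubstituentClass("n-acetyl", "d", "*NCC/3=O", "NAc"),
    SubstituentClass("n-glycolyl", "d", "*NCCO/3=O", "NGc"),
    SubstituentClass("n-sulfate", "d", "*NSO/3=O/3=O", "NS"),
    SubstituentClass("n-methyl", "d", "*NC", "NMe"),
    SubstituentClass("amino", "d", "*N", "N"),
    SubstituentClass("acetyl", "o", "*OCC/3=O", "Ac"),
    SubstituentClass("methyl", "o", "*OC", "Me"),
    SubstituentClass("sulfate", "o", "*OSO/3=O/3=O", "S"),
    SubstituentClass("phosphate", "o", "*OPO/3O/3=O", "P"),
]

SUBSTITUENT_CLASSES = {s.name: s for s in _SUBSTITUENTS}


def substituent_class(name: str) -> SubstituentClass:
    try:
        return SUBSTITUENT_CLASSES[name]
    except KeyError:
        raise VocabularyError(
            f"unknown substituent {name!r}; known: "
            + ", ".join(sorted(SUBSTITUENT_CLASSES))
        ) from None


@dataclass(frozen=True)
class SNFGSymbol:
    """Shape/color/label triple assigned to a residue for depiction."""

    shape: str
    color: str          # palette name
    label: str
    color_hex: str = ""

    def __post_init__(self):
        if not self.color_hex:
            object.__setattr__(
                self, "color_hex", PALETTE.get(self.color, "#FFFFFF")
            )


@dataclass(frozen=True)
class MonosaccharideClass:
    """One named SNFG monosaccharide class.

    ``stems``/``configs`` are parallel tuples (Neu-type residues have the
    composite d-gro/d-gal stem pair); ``mods`` are backbone modifications;
    ``subs`` are the substituents that are *part of the name* (the 2-NAc of
    GlcNAc) — extra substituents on a residue do not prevent a match.
    """

    name: str
    stems: tuple[str, ...]
    configs: tuple[str, ...]
    superclass: str
    mods: frozenset[tuple[int, str]]
    subs: tuple[tuple[int, str], ...]
    shape: str
    color: str

    @property
    def symbol(self) -> SNFGSymbol:
        return SNFGSymbol(self.shape, self.color, self.name)


def _mono(name, stems, configs, superclass, mods, subs, shape, color):
    return MonosaccharideClass(
        name=name,
        stems=tuple(stems),
        configs=tuple(configs),
        superclass=superclass,
        mods=frozenset(mods),
        subs=tuple(subs),
        shape=shape,
        color=color,
    )


_NEU_MODS = [(1, "acid"), (2, "ketone"), (3, "deoxy")]

_MONOSACCHARIDES = [
    # hexoses
    _mono("Glc", ["glc"], ["d"], "HEX", [], [], "circle", "blue"),
    _mono("Man", ["man"], ["d"], "HEX", [], [], "circle", "green"),
    _mono("Gal", ["gal"], ["d"], "HEX", [], [], "circle", "yellow"),
    _mono("All", ["all"], ["d"], "HEX", [], [], "circle", "purple"),
    # hexosamines
    _mono("GlcN", ["glc"], ["d"], "HEX", [], [(2, "amino")],
          "crossed_square", "blue"),
    _mono("ManN", ["man"], ["d"], "HEX", [], [(2, "amino")],
          "crossed_square", "green"),
    _mono("GalN", ["gal"], ["d"], "HEX", [], [(2, "amino")],
          "crossed_square", "yellow"),
    # N-acetylhexosamines
    _mono("GlcNAc", ["glc"], ["d"], "HEX", [], [(2, "n-acetyl")],
          "square", "blue"),
    _mono("ManNAc", ["man"], ["d"], "HEX", [], [(2, "n-acetyl")],
          "square", "green"),
    _mono("GalNAc", ["gal"], ["d"], "HEX", [], [(2, "n-acetyl")],
          "square", "yellow"),
    # hexuronates
    _mono("GlcA", ["glc"], ["d"], "HEX", [(6, "acid")], [],
          "divided_diamond", "blue"),
    _mono("ManA", ["man"], ["d"], "HEX", [(6, "acid")], [],
          "divided_diamond", "green"),
    _mono("GalA", ["gal"], ["d"], "HEX", [(6, "acid")], [],
          "divided_diamond", "yellow"),
    # deoxyhexoses
    _mono("Fuc", ["gal"], ["l"], "HEX", [(6, "deoxy")], [],
          "triangle", "red"),
    _mono("Rha", ["man"], ["l"], "HEX", [(6, "deoxy")], [],
          "triangle", "green"),
    _mono("Qui", ["glc"], ["d"], "HEX", [(6, "deoxy")], [],
          "triangle", "blue"),
    # deoxyhexNAc
    _mono("FucNAc", ["gal"], ["l"], "HEX", [(6, "deoxy")],
          [(2, "n-acetyl")], "divided_triangle", "red"),
    _mono("QuiNAc", ["glc"], ["d"], "HEX", [(6, "deoxy")],
          [(2, "n-acetyl")], "divided_triangle", "blue"),
    # pentoses
    _mono("Xyl", ["xyl"], ["d"], "PEN", [], [], "star", "orange"),
    _mono("Ara", ["ara"], ["l"], "PEN", [], [], "star", "green"),
    _mono("Rib", ["rib"], ["d"], "PEN", [], [], "star", "pink"),
    _mono("Lyx", ["lyx"], ["d"], "PEN", [], [], "star", "yellow"),
    # nonulosonates (sialic acids and Kdn)
    _mono("Neu5Ac", ["gro", "gal"], ["d", "d"], "NON", _NEU_MODS,
          [(5, "n-acetyl")], "diamond", "purple"),
    _mono("Neu5Gc", ["gro", "gal"], ["d", "d"], "NON", _NEU_MODS,
          [(5, "n-glycolyl")], "diamond", "lightblue"),
    _mono("Kdn", ["gro", "gal"], ["d", "d"], "NON", _NEU_MODS, [],
          "diamond", "green"),
]

MONOSACCHARIDE_CLASSES = {m.name: m for m in _MONOSACCHARIDES}

# Generic fallbacks keyed by superclass: white version of the class shape.
_GENERIC_SHAPES = {
    "TRI": ("triangle", "Tri"),
    "TET": ("rectangle", "Tet"),
    "PEN": ("star", "Pen"),
    "HEX": ("circle", "Hex"),
    "HEP": ("circle", "Hep"),
    "OCT": ("circle", "Oct"),
    "NON": ("diamond", "Non"),
}


def monosaccharide_class(name: str) -> MonosaccharideClass:
    try:
        return MONOSACCHARIDE_CLASSES[name]
    except KeyError:
        raise VocabularyError(
            f"unknown monosaccharide {name!r}; known: "
            + ", ".join(sorted(MONOSACCHARIDE_CLASSES))
        ) from None


def match_class(
    stems: tuple[str, ...],
    configs: tuple[str, ...],
    superclass: str,
    mods: frozenset[tuple[int, str]],
    substituents: list[tuple[int, str]],
) -> Optional[MonosaccharideClass]:
    """Best-matching SNFG class for a residue signature, or None.

    A class matches when stems, configurations, superclass and backbone
    modifications agree exactly and every substituent named by the class is
    present on the residue at the stated position. Among matches the one
    consuming the most substituents wins (GlcNAc beats Glc when a 2-NAc is
    present), ties broken by dictionary order for determinism.
    """
    have = set(substituents)
    best: Optional[MonosaccharideClass] = None
    for m in _MONOSACCHARIDES:
        if m.stems != stems or m.configs != configs:
            continue
        if m.superclass != superclass or m.mods != mods:
            continue
        if not set(m.subs) <= have:
            continue
        if best is None or len(m.subs) > len(best.subs):
            best = m
    return best


def generic_symbol(superclass: str) -> SNFGSymbol:
    shape, label = _GENERIC_SHAPES.get(superclass, ("circle", superclass))
    return SNFGSymbol(shape, "white", label)
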