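"""WURCS 2.0 writer and dictionary-limited reader.

WURCS (Web3 Unique Representation of Carbohydrate Structures) is the
linear notation used as the primary key of the GlyTouCan repository::

    WURCS=2.0/<u>,<r>,<l>/[code][code].../<sequence>/<linkages>

* ``u`` unique residue codes, ``r`` residue instances, ``l`` linkage
  descriptors; the body must be consistent with the counts.
* a residue code is a backbone *skeleton* (one character per carbon:
  stereo digit, ``a`` anomeric, ``d`` deoxy, ``A`` acid, ``h``/``m``
  terminal CH2OH/CH3), an anomeric descriptor (``-1b``), a ring bridge
  (``_1-5``) and MAP substituent expressions (``_2*NCC/3=O``).
* linkage descriptors index residue instances by letter (``a4-b1``);
  ``?`` marks unknown positions, ``|`` separates alternatives, and a
  closing ``}`` on the parent side marks an undetermined fragment
  attachment (``a?|b?}-c1``).

Encoding is dictionary-driven: skeleton codes for the SNFG monosaccharide
set are shipped as a static table (D-form stereo digits; L forms by the
mirror rule, digit 1<->2). Residues outside the table raise
:class:`UnsupportedResidueError`. Residue order follows the same
depth-first order as the GlycoCT writer, which makes writer output
canonical for equal documents.
"""

from __future__ import annotations

import re
import string
from typing import Optional

from .errors import (
    EmptyDocumentError,
    UnsupportedResidueError,
    WurcsParseError,
    WurcsVersionError,
)
from .model import (
    FragmentPart,
    GlycanDocument,
    GlycanTree,
    Linkage,
    Residue,
    Substituent,
)
from .snfg import UNKNOWN, SUBSTITUENT_CLASSES

# ---------------------------------------------------------------------------
# skeleton dictionary

#: D-form stereo digits per stem (digit 2 = OH right / 1 = OH left in the
#: Fischer projection, anomeric and terminal carbons excluded).
_D_DIGITS = {
    # hexoses: C2..C5
    ("glc",): ("HEX", "2122"),
    ("man",): ("HEX", "1122"),
    ("gal",): ("HEX", "2112"),
    ("all",): ("HEX", "2222"),
    # pentoses: C2..C4
    ("xyl",): ("PEN", "212"),
    ("rib",): ("PEN", "222"),
    ("ara",): ("PEN", "122"),
    ("lyx",): ("PEN", "112"),
}

_NEU_KEY = (("gro", "gal"), ("d", "d"), "NON",
            frozenset({(1, "acid"), (2, "ketone"), (3, "deoxy")}))

_HEX_MOD_TAILS = {
    frozenset(): "h",
    frozenset({(6, "deoxy")}): "m",
    frozenset({(6, "acid")}): "A",
}
_PEN_TAIL = "h"


def _mirror(digits: str) -> str:
    return digits.translate(str.maketrans("12", "21"))


def _skeleton_table() -> dict[tuple, tuple[str, int]]:
    """signature -> (skeleton, anomeric position).

    signature = (stems, configs, superclass, mods frozenset)
    """
    table: dict[tuple, tuple[str, int]] = {}
    for stems, (superclass, digits) in _D_DIGITS.items():
        tails = _HEX_MOD_TAILS if superclass == "HEX" else {frozenset(): _PEN_TAIL}
        for mods, tail in tails.items():
            for config in ("d", "l"):
                dd = digits if config == "d" else _mirror(digits)
                key = (stems, (config,) * len(stems), superclass, mods)
                table[key] = ("a" + dd + tail, 1)
    table[_NEU_KEY] = ("Aad21122h", 2)
    return table


_SKELETONS = _skeleton_table()
_SKELETON_REVERSE = {
    skeleton: (key, apos) for key, (skeleton, apos) in _SKELETONS.items()
}

_MAP_BY_NAME = {name: cls.wurcs_map for name, cls in SUBSTITUENT_CLASSES.items()}
_NAME_BY_MAP = {cls.wurcs_map: name for name, cls in SUBSTITUENT_CLASSES.items()}

_LETTERS = string.ascii_lowercase + string.ascii_uppercase


def _letter(index: int) -> str:
    if index >= len(_LETTERS):
        raise UnsupportedResidueError(
            "more than 52 residue instances in one WURCS string"
        )
    return _LETTERS[index]


# ---------------------------------------------------------------------------
# writer

def residue_code(res: Residue) -> str:
    """The unique-residue code for one residue, e.g.
    ``a2122h-1x_1-5_2*NCC/3=O``."""
    key = (res.stems, res.configs, res.superclass, res.modifications)
    entry = _SKELETONS.get(key)
    if entry is None or res.anomer == "o":
        raise UnsupportedResidueError(
            f"no WURCS dictionary entry for residue "
            f"{'-'.join(res.stems)}/{''.join(res.configs)}/{res.superclass}"
            f" mods={sorted(res.modifications)} anomer={res.anomer}"
        )
    skeleton, apos = entry
    code = f"{skeleton}-{apos}{res.anomer}"
    if res.ring[0] == UNKNOWN or res.ring[1] == UNKNOWN:
        code += "_?-?"
    else:
        code += f"_{res.ring[0]}-{res.ring[1]}"
    for sub in res.sorted_substituents():
        pos = "?" if sub.position == UNKNOWN else str(sub.position)
        code += f"_{pos}{_MAP_BY_NAME[sub.name]}"
    return code


def _pos_str(p: int) -> str:
    return "?" if p == UNKNOWN else str(p)


class _Writer:
    def __init__(self, doc: GlycanDocument):
        self.doc = doc
        self.order: list[tuple[GlycanTree, int]] = []  # (tree, residue id)
        self.letter_of: dict[int, str] = {}

    def _collect(self, tree: GlycanTree) -> None:
        for rid in tree.preorder():
            self.letter_of[rid] = _letter(len(self.order))
            self.order.append((tree, rid))

    def write(self) -> str:
        doc = self.doc
        if doc.is_empty:
            raise EmptyDocumentError("cannot serialize an empty document")
        frags = sorted(doc.fragments, key=lambda f: f.index)
        self._collect(doc.core)
        for frag in frags:
            self._collect(frag.tree)

        codes: list[str] = []
        code_index: dict[str, int] = {}
        seq: list[int] = []
        for tree, rid in self.order:
            code = residue_code(tree.residues[rid])
            if code not in code_index:
                code_index[code] = len(codes) + 1
                codes.append(code)
            seq.append(code_index[code])

        links: list[str] = []
        for tree, rid in self.order:
            ln = tree.parent_linkage(rid)
            if ln is None:
                continue
            parent = self.letter_of[ln.parent_id]
            alts = "|".join(
                f"{parent}{_pos_str(p)}" for p in ln.parent_positions
            )
            links.append(
                f"{alts}-{self.letter_of[rid]}{_pos_str(ln.child_position)}"
            )
        for frag in frags:
            li = frag.linkage_info
            sites = sorted(
                frag.attachment_sites,
                key=lambda s: _LETTERS.index(self.letter_of[s]),
            )
            alts = "|".join(
                f"{self.letter_of[s]}{_pos_str(p)}"
                for s in sites for p in li.parent_positions
            )
            links.append(
                f"{alts}}}-{self.letter_of[frag.tree.root_id]}"
                f"{_pos_str(li.child_position)}"
            )

        counts = f"{len(codes)},{len(seq)},{len(links)}"
        body = "".join(f"[{c}]" for c in codes)
        return (
            f"WURCS=2.0/{counts}/{body}/"
            + "-".join(map(str, seq))
            + "/"
            + "_".join(links)
        )


def write_wurcs(doc: GlycanDocument) -> str:
    """Serialize a document to a canonical WURCS 2.0 string."""
    return _Writer(doc).write()


# ---------------------------------------------------------------------------
# reader

_HEADER_RE = re.compile(r"^WURCS=([0-9.]+)/(\d+),(\d+),(\d+)/")
_CODE_SECTION_RE = re.compile(r"^((?:\[[^\[\]]+\])+)/")
_LINK_SIDE_RE = re.compile(r"^([A-Za-z])(\?|\d+)$")


def _decode_code(code: str) -> Residue:
    """Invert :func:`residue_code` (template residue, id 0)."""
    parts = code.split("_")
    head = parts[0]
    m = re.fullmatch(r"([A-Za-z0-9]+)-(\d)([abx])", head)
    if not m:
        raise WurcsParseError(f"bad residue code {code!r}")
    skeleton, apos, anomer = m.group(1), int(m.group(2)), m.group(3)
    entry = _SKELETON_REVERSE.get(skeleton)
    if entry is None:
        raise UnsupportedResidueError(
            f"unknown WURCS skeleton {skeleton!r}"
        )
    (stems, configs, superclass, mods), expected_apos = entry
    if apos != expected_apos:
        raise WurcsParseError(
            f"anomeric position {apos} does not match skeleton {skeleton!r}"
        )
    ring = (UNKNOWN, UNKNOWN)
    subs: list[Substituent] = []
    rest = parts[1:]
    if rest:
        rm = re.fullmatch(r"(\?|\d+)-(\?|\d+)", rest[0])
        if rm:
            if rm.group(1) != "?" and rm.group(2) != "?":
                ring = (int(rm.group(1)), int(rm.group(2)))
            rest = rest[1:]
    for tok in rest:
        mm = re.fullmatch(r"(\?|\d+)(\*.+)", tok)
        if not mm:
            raise WurcsParseError(f"bad MAP token {tok!r} in {code!r}")
        name = _NAME_BY_MAP.get(mm.group(2))
        if name is None:
            raise UnsupportedResidueError(
                f"unknown MAP expression {mm.group(2)!r}"
            )
        pos = UNKNOWN if mm.group(1) == "?" else int(mm.group(1))
        subs.append(Substituent(name=name, position=pos))
    res = Residue(
        id=0,
        stems=stems,
        configs=configs,
        superclass=superclass,
        anomer=anomer,
        ring=ring,
        modifications=mods,
    )
    res.substituents = subs
    return res


def _parse_link_side(side: str) -> list[tuple[str, int]]:
    out = []
    for alt in side.split("|"):
        m = _LINK_SIDE_RE.match(alt)
        if not m:
            raise WurcsParseError(f"bad linkage token {alt!r}")
        out.append((
            m.group(1),
            UNKNOWN if m.group(2) == "?" else int(m.group(2)),
        ))
    return out


def parse_wurcs(text: str) -> GlycanDocument:
    """Parse a WURCS 2.0 string (dictionary-limited subset)."""
    text = text.strip()
    m = _HEADER_RE.match(text)
    if not m:
        raise WurcsParseError("not a WURCS string")
    if m.group(1) != "2.0":
        raise WurcsVersionError(f"unsupported WURCS version {m.group(1)}")
    n_unique, n_res, n_links = (int(m.group(i)) for i in (2, 3, 4))
    rest = text[m.end():]
    cm = _CODE_SECTION_RE.match(rest)
    if not cm:
        raise WurcsParseError("missing residue-code section")
    codes = re.findall(r"\[([^\[\]]+)\]", cm.group(1))
    rest = rest[cm.end():]
    if "/" not in rest:
        raise WurcsParseError("missing linkage section")
    seq_part, _, link_part = rest.partition("/")
    if len(codes) != n_unique:
        raise WurcsParseError(
            f"count mismatch: {n_unique} unique codes declared, "
            f"{len(codes)} present"
        )
    try:
        seq = [int(tok) for tok in seq_part.split("-")] if seq_part else []
    except ValueError:
        raise WurcsParseError(f"bad residue sequence {seq_part!r}") from None
    if len(seq) != n_res:
        raise WurcsParseError(
            f"count mismatch: {n_res} instances declared, {len(seq)} present"
        )
    if any(not 1 <= i <= len(codes) for i in seq):
        raise WurcsParseError("residue sequence index out of range")
    templates = [_decode_code(c) for c in codes]

    doc = GlycanDocument()
    instances: list[Residue] = []
    import copy as _copy
    for idx in seq:
        res = _copy.deepcopy(templates[idx - 1])
        res.id = doc._next_id
        doc._next_id += 1
        instances.append(res)
    by_letter = {_letter(i): res for i, res in enumerate(instances)}

    link_tokens = [tok for tok in link_part.split("_") if tok] if link_part else []
    if len(link_tokens) != n_links:
        raise WurcsParseError(
            f"count mismatch: {n_links} linkages declared, "
            f"{len(link_tokens)} present"
        )

    edges: list[tuple[str, tuple[int, ...], str, int]] = []
    frag_marks: list[tuple[list[tuple[str, int]], str, int]] = []
    for tok in link_tokens:
        if "-" not in tok:
            raise WurcsParseError(f"bad linkage descriptor {tok!r}")
        left, _, right = tok.partition("-")
        fragment = left.endswith("}")
        if fragment:
            left = left[:-1]
        rights = _parse_link_side(right)
        if len(rights) != 1:
            raise WurcsParseError(
                f"multiple child alternatives unsupported: {tok!r}"
            )
        child_letter, child_pos = rights[0]
        lefts = _parse_link_side(left)
        letters = {l for l, _ in lefts}
        if fragment:
            frag_marks.append((lefts, child_letter, child_pos))
        else:
            if len(letters) != 1:
                raise WurcsParseError(
                    f"plain linkage with several parents: {tok!r}"
                )
            positions = tuple(p for _, p in lefts)
            edges.append((lefts[0][0], positions, child_letter, child_pos))

    for letter in set(
        [l for l, *_ in edges] + [c for _, _, c, _ in edges]
    ):
        if letter not in by_letter:
            raise WurcsParseError(f"linkage references residue {letter!r}")

    # connected components over plain edges
    comp: dict[str, set[str]] = {
        _letter(i): {_letter(i)} for i in range(len(instances))
    }
    for parent, _, child, _ in edges:
        merged = comp[parent] | comp[child]
        for l in merged:
            comp[l] = merged
    children_of_edges = {child for _, _, child, _ in edges}

    def build_tree(letters: set[str]) -> GlycanTree:
        tree = GlycanTree(residues={
            by_letter[l].id: by_letter[l] for l in letters
        })
        roots = [l for l in letters if l not in children_of_edges]
        if len(roots) != 1:
            raise WurcsParseError("component is not a rooted tree")
        tree.root_id = by_letter[roots[0]].id
        for parent, positions, child, cpos in edges:
            if parent in letters:
                tree.linkages.append(Linkage(
                    child_id=by_letter[child].id,
                    parent_id=by_letter[parent].id,
                    parent_positions=positions,
                    child_position=cpos,
                ))
        tree.validate()
        return tree

    if not instances:
        raise WurcsParseError("WURCS string encodes no residues")
    core_letters = comp["a"]
    frag_roots = {child for _, child, _ in frag_marks}
    claimed = set(core_letters)
    doc.core = build_tree(core_letters)
    for n, (lefts, child_letter, child_pos) in enumerate(frag_marks, start=1):
        if child_letter not in by_letter:
            raise WurcsParseError(
                f"fragment references residue {child_letter!r}")
        letters = comp[child_letter]
        if letters & set(core_letters):
            raise WurcsParseError(
                "fragment root belongs to the core component")
        claimed |= letters
        tree = build_tree(letters)
        sites = set()
        positions = []
        for letter, pos in lefts:
            if letter not in core_letters:
                raise WurcsParseError(
                    f"fragment parent {letter!r} is not a core residue")
            sites.add(by_letter[letter].id)
            positions.append(pos)
        uniq_positions = tuple(dict.fromkeys(positions)) or (UNKNOWN,)
        doc.fragments.append(FragmentPart(
            tree=tree,
            linkage_info=Linkage(
                child_id=tree.root_id,
                parent_id=UNKNOWN,
                parent_positions=uniq_positions,
                child_position=child_pos,
            ),
            attachment_sites=frozenset(sites),
            index=n,
        ))
    unclaimed = set(by_letter) - claimed
    if unclaimed:
        raise WurcsParseError(
            f"disconnected residues {sorted(unclaimed)} "
            "(neither core nor marked fragment)"
        )
    doc.validate()
    return doc
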