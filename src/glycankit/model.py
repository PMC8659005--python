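"""Editable in-memory glycan documents.

A :class:`GlycanDocument` holds one *core* tree plus an ordered list of
*fragment parts* — subtrees whose attachment site on the core is only
partially determined (a set of candidate core residues, with possibly
unknown linkage positions). This is the data model behind bracket notation
in SNFG drawings: the core is fully drawn, fragments sit left of a bracket
with "*n" numbering when their candidate sites are restricted.

All editing operations snapshot the document into an undo/redo history.
Clearing the document purges the history as well: a cleared structure
cannot be recovered by undo.
"""

from __future__ import annotations

import copy
import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from . import snfg
from .errors import (
    ConflictError,
    DependencyError,
    MissingResidueError,
    NoParentError,
    OrderingError,
    TruncationError,
    ValidationError,
    VocabularyError,
)
from .snfg import UNKNOWN

ANOMERS = ("a", "b", "o", "x")
CONFIGS = ("d", "l", "x")

#: API-friendly spellings accepted wherever an anomer is expected.
_ANOMER_ALIASES = {
    "alpha": "a", "beta": "b", "open": "o", "unknown": "x",
    "a": "a", "b": "b", "o": "o", "x": "x",
}
_CONFIG_ALIASES = {
    "d": "d", "l": "l", "unknown": "x", "x": "x", "D": "d", "L": "l",
}


def _coerce_anomer(value: str) -> str:
    try:
        return _ANOMER_ALIASES[value]
    except KeyError:
        raise ValidationError(f"invalid anomer {value!r}") from None


def _coerce_config(value: str) -> str:
    try:
        return _CONFIG_ALIASES[value]
    except KeyError:
        raise ValidationError(f"invalid configuration {value!r}") from None


@dataclass
class Substituent:
    """A non-sugar decoration attached to a residue carbon."""

    name: str
    position: int = UNKNOWN  # 1..9, or -1 for unknown

    def __post_init__(self):
        snfg.substituent_class(self.name)  # vocabulary check
        if self.position != UNKNOWN and not 1 <= self.position <= 9:
            raise ValidationError(
                f"substituent position {self.position} outside 1..9"
            )

    @property
    def parent_link(self) -> str:
        """GlycoCT parent linkage-type letter ('d' N-replacement, 'o')."""
        return snfg.substituent_class(self.name).parent_link


@dataclass
class Residue:
    """One monosaccharide.

    ``stems``/``configs`` are parallel tuples of stereocode stems and their
    D/L configurations; ``ring`` is the (start, end) carbon pair of the ring
    closure or (-1, -1) when unknown / open-chain.
    """

    id: int
    stems: tuple[str, ...] = ("glc",)
    configs: tuple[str, ...] = ("x",)
    superclass: str = "HEX"
    anomer: str = "x"
    ring: tuple[int, int] = (UNKNOWN, UNKNOWN)
    modifications: frozenset[tuple[int, str]] = frozenset()
    substituents: list[Substituent] = field(default_factory=list)
    #: SNFG display name assigned by normalize(); never serialized.
    display_name: Optional[str] = None

    def __post_init__(self):
        self.validate()

    @property
    def backbone_length(self) -> int:
        return snfg.SUPERCLASS_LENGTH[self.superclass]

    def validate(self) -> None:
        if self.superclass not in snfg.SUPERCLASS_LENGTH:
            raise ValidationError(f"invalid superclass {self.superclass!r}")
        if self.anomer not in ANOMERS:
            raise ValidationError(f"invalid anomer {self.anomer!r}")
        if len(self.stems) != len(self.configs) or not self.stems:
            raise ValidationError("stems and configs must be parallel")
        for c in self.configs:
            if c not in CONFIGS:
                raise ValidationError(f"invalid configuration {c!r}")
        start, end = self.ring
        if start != UNKNOWN and end != UNKNOWN:
            if self.anomer == "o":
                raise ValidationError("open-chain residue cannot have a ring")
            if not start < end:
                raise ValidationError(
                    f"ring start {start} must be < ring end {end}"
                )
        n = self.backbone_length
        for pos, kind in self.modifications:
            if kind not in snfg.MOD_KINDS:
                raise ValidationError(f"invalid modification kind {kind!r}")
            if not 1 <= pos <= n:
                raise ValidationError(
                    f"modification position {pos} outside 1..{n}"
                )

    def sorted_substituents(self) -> list[Substituent]:
        """Substituents in canonical order: known positions ascending,
        unknown last, ties by name."""
        return sorted(
            self.substituents,
            key=lambda s: (s.position == UNKNOWN, s.position, s.name),
        )

    def sorted_modifications(self) -> list[tuple[int, str]]:
        return sorted(self.modifications)

    def signature(self) -> tuple:
        """Id-free chemical signature (used by isomorphism checks)."""
        return (
            self.stems,
            self.configs,
            self.superclass,
            self.anomer,
            self.ring,
            tuple(self.sorted_modifications()),
            tuple((s.position, s.name) for s in self.sorted_substituents()),
        )


@dataclass
class Linkage:
    """A glycosidic bond from a child residue's anomeric carbon to one of a
    set of candidate positions on its parent.

    Multiple ``parent_positions`` encode "one of these" ambiguity, never
    multi-attachment.
    """

    child_id: int
    parent_id: int
    parent_positions: tuple[int, ...] = (UNKNOWN,)
    child_position: int = 1

    def __post_init__(self):
        if not self.parent_positions:
            raise ValidationError("parent_positions must be non-empty")
        cleaned = []
        for p in self.parent_positions:
            if p != UNKNOWN and not 1 <= p <= 9:
                raise ValidationError(f"parent position {p} outside 1..9")
            cleaned.append(p)
        # canonical: known ascending, unknown (-1) last, deduplicated
        uniq = sorted(set(cleaned), key=lambda p: (p == UNKNOWN, p))
        self.parent_positions = tuple(uniq)
        if self.child_position != UNKNOWN and not 1 <= self.child_position <= 9:
            raise ValidationError(
                f"child position {self.child_position} outside 1..9"
            )


@dataclass
class GlycanTree:
    """Rooted tree of residues; the root is the reducing end."""

    residues: dict[int, Residue] = field(default_factory=dict)
    linkages: list[Linkage] = field(default_factory=list)
    root_id: Optional[int] = None

    def __bool__(self) -> bool:
        return bool(self.residues)

    def parent_linkage(self, child_id: int) -> Optional[Linkage]:
        for ln in self.linkages:
            if ln.child_id == child_id:
                return ln
        return None

    def child_linkages(self, parent_id: int) -> list[Linkage]:
        return [ln for ln in self.linkages if ln.parent_id == parent_id]

    def ordered_children(self, parent_id: int) -> list[Linkage]:
        """Child linkages in canonical order: ascending known parent
        position, unknown positions last, ties by child creation order."""
        def key(ln: Linkage):
            known = [p for p in ln.parent_positions if p != UNKNOWN]
            return (not known, min(known) if known else 0, ln.child_id)
        return sorted(self.child_linkages(parent_id), key=key)

    def descendants(self, residue_id: int) -> set[int]:
        """residue_id plus all residues below it."""
        out = {residue_id}
        frontier = [residue_id]
        while frontier:
            rid = frontier.pop()
            for ln in self.child_linkages(rid):
                if ln.child_id not in out:
                    out.add(ln.child_id)
                    frontier.append(ln.child_id)
        return out

    def preorder(self) -> Iterator[int]:
        """Depth-first pre-order over residue ids in canonical child
        order; empty for an empty tree."""
        if self.root_id is None:
            return
        stack = [self.root_id]
        while stack:
            rid = stack.pop()
            yield rid
            for ln in reversed(self.ordered_children(rid)):
                stack.append(ln.child_id)

    def validate(self) -> None:
        """Check connectivity, acyclicity and single-parenthood."""
        if not self.residues:
            if self.root_id is not None or self.linkages:
                raise ValidationError("empty tree with root or linkages")
            return
        if self.root_id not in self.residues:
            raise ValidationError("root_id not among residues")
        parents: dict[int, int] = {}
        for ln in self.linkages:
            if ln.child_id not in self.residues or ln.parent_id not in self.residues:
                raise ValidationError("linkage references missing residue")
            if ln.child_id in parents:
                raise ValidationError(
                    f"residue {ln.child_id} has multiple parents"
                )
            parents[ln.child_id] = ln.parent_id
        if self.root_id in parents:
            raise ValidationError("root has a parent")
        reached = self.descendants(self.root_id)
        if reached != set(self.residues):
            raise ValidationError("tree is not connected")
        for rid in self.residues:
            if rid != self.root_id and rid not in parents:
                raise ValidationError(f"residue {rid} has no parent")

    def signature(self) -> tuple:
        """Recursive id-free signature; equal signatures <=> isomorphic
        trees with identical chemistry and linkage position sets."""
        def sig(rid: int) -> tuple:
            children = []
            for ln in self.ordered_children(rid):
                children.append(
                    (ln.parent_positions, ln.child_position, sig(ln.child_id))
                )
            return (self.residues[rid].signature(), tuple(children))
        if self.root_id is None:
            return ()
        return sig(self.root_id)


@dataclass
class FragmentPart:
    """A fragment subtree plus where it may attach on the core."""

    tree: GlycanTree
    linkage_info: Linkage
    attachment_sites: frozenset[int]
    index: int
    #: UND statistics from parsed GlycoCT; informational only.
    stats: tuple[float, float] = (100.0, 100.0)

    def sites_complete(self, core: GlycanTree) -> bool:
        """True when every core residue is a candidate attachment site —
        the "*n" annotations are suppressed in that case."""
        return self.attachment_sites == set(core.residues)

    def signature(self, core: GlycanTree) -> tuple:
        site_sigs = tuple(sorted(
            core.residues[rid].signature() for rid in self.attachment_sites
        ))
        return (
            self.tree.signature(),
            self.linkage_info.parent_positions,
            self.linkage_info.child_position,
            self.sites_complete(core),
            site_sigs,
        )


_STEREOCODE_RE = re.compile(r"^[abox]-(?:[dlx][a-z]{3}-)+(?:TRI|TET|PEN|HEX|HEP|OCT|NON)-")


def residue_from_spec(spec: str, next_id: int) -> Residue:
    """Build a Residue from an SNFG name ("GlcNAc") or a raw GlycoCT
    basetype stereocode ("b-dglc-HEX-1:5")."""
    if _STEREOCODE_RE.match(spec):
        from . import glycoct  # cycle-free: glycoct imports model lazily here
        return glycoct.parse_basetype(spec, next_id)
    cls = snfg.monosaccharide_class(spec)
    ring = (UNKNOWN, UNKNOWN)
    if cls.superclass == "NON":
        ring = (2, 6)
    elif cls.superclass in ("HEX", "PEN"):
        ring = (1, 5) if cls.superclass == "HEX" else (1, 5)
    res = Residue(
        id=next_id,
        stems=cls.stems,
        configs=cls.configs,
        superclass=cls.superclass,
        anomer="x",
        ring=ring,
        modifications=cls.mods,
    )
    for pos, name in cls.subs:
        res.substituents.append(Substituent(name=name, position=pos))
    return res


def anomeric_position(residue: Residue) -> int:
    """Default anomeric carbon: ring start when known, else 2 for
    keto-sugars (Neu chains), else 1."""
    if residue.ring[0] != UNKNOWN:
        return residue.ring[0]
    if (2, "ketone") in residue.modifications:
        return 2
    return 1


class GlycanDocument:
    """Core tree + ordered fragment parts + undo/redo history."""

    def __init__(self):
        self.core = GlycanTree()
        self.fragments: list[FragmentPart] = []
        self._next_id = 1
        self._undo: list[tuple] = []
        self._redo: list[tuple] = []

    # -- state & history -------------------------------------------------

    def _state(self) -> tuple:
        return copy.deepcopy((self.core, self.fragments, self._next_id))

    def _restore(self, state: tuple) -> None:
        self.core, self.fragments, self._next_id = copy.deepcopy(state)

    def _record(self) -> None:
        self._undo.append(self._state())
        self._redo.clear()

    def undo(self) -> bool:
        """Restore the previous snapshot; False (no-op) on empty history."""
        if not self._undo:
            return False
        self._redo.append(self._state())
        self._restore(self._undo.pop())
        return True

    def redo(self) -> bool:
        if not self._redo:
            return False
        self._undo.append(self._state())
        self._restore(self._redo.pop())
        return True

    def clear(self) -> None:
        """Empty the document AND the history: a cleared structure cannot
        be brought back by undo."""
        self.core = GlycanTree()
        self.fragments = []
        self._next_id = 1
        self._undo.clear()
        self._redo.clear()

    # -- lookup ----------------------------------------------------------

    def _find_tree(self, residue_id: int) -> GlycanTree:
        if residue_id in self.core.residues:
            return self.core
        for frag in self.fragments:
            if residue_id in frag.tree.residues:
                return frag.tree
        raise MissingResidueError(f"no residue with id {residue_id}")

    def residue(self, residue_id: int) -> Residue:
        return self._find_tree(residue_id).residues[residue_id]

    @property
    def is_empty(self) -> bool:
        return not self.core and not self.fragments

    @property
    def is_simple(self) -> bool:
        """True when the document has no fragment parts."""
        return not self.fragments

    def all_trees(self) -> list[GlycanTree]:
        return [self.core] + [f.tree for f in self.fragments]

    # -- editing operations ----------------------------------------------

    def add_monosaccharide(
        self,
        residue_spec: str,
        parent_id: Optional[int] = None,
        anomer: Optional[str] = None,
        parent_positions: Optional[Sequence[int]] = None,
        child_position: Optional[int] = None,
    ) -> int:
        """Add a residue; the first residue of an empty document becomes
        the core root, later ones attach under ``parent_id``."""
        if self.core and parent_id is None:
            raise MissingResidueError(
                "document is non-empty: parent_id is required"
            )
        if parent_id is not None:
            tree = self._find_tree(parent_id)
        else:
            tree = self.core
        res = residue_from_spec(residue_spec, self._next_id)  # may raise
        self._record()
        self._next_id += 1
        if anomer is not None:
            res.anomer = _coerce_anomer(anomer)
            if res.anomer == "o":
                res.ring = (UNKNOWN, UNKNOWN)
        tree.residues[res.id] = res
        if parent_id is None:
            tree.root_id = res.id
        else:
            tree.linkages.append(Linkage(
                child_id=res.id,
                parent_id=parent_id,
                parent_positions=tuple(parent_positions or (UNKNOWN,)),
                child_position=(
                    child_position if child_position is not None
                    else anomeric_position(res)
                ),
            ))
        return res.id

    def add_substituent(self, residue_id: int, name: str,
                        position: int = UNKNOWN) -> None:
        res = self.residue(residue_id)
        cls = snfg.substituent_class(name)
        if position != UNKNOWN and not 1 <= position <= res.backbone_length:
            raise ValidationError(
                f"position {position} outside 1..{res.backbone_length}"
            )
        for existing in res.substituents:
            if existing.position == position and position != UNKNOWN:
                if existing.name == name:
                    raise ConflictError(
                        f"duplicate substituent {name} at position {position}"
                    )
                ex_cls = snfg.substituent_class(existing.name)
                if ex_cls.parent_link == cls.parent_link:
                    raise ConflictError(
                        f"position {position} already carries "
                        f"{existing.name} on the same linkage atom"
                    )
        self._record()
        res.substituents.append(Substituent(name=name, position=position))

    def set_linkage(self, child_id: int, anomer: Optional[str] = None,
                    parent_positions: Optional[Sequence[int]] = None,
                    child_position: Optional[int] = None) -> None:
        tree = self._find_tree(child_id)
        ln = tree.parent_linkage(child_id)
        if ln is None:
            raise NoParentError(f"residue {child_id} has no parent linkage")
        self._record()
        if anomer is not None:
            tree.residues[child_id].anomer = _coerce_anomer(anomer)
        if parent_positions is not None:
            ln2 = Linkage(
                child_id=ln.child_id,
                parent_id=ln.parent_id,
                parent_positions=tuple(parent_positions),
                child_position=(
                    child_position if child_position is not None
                    else ln.child_position
                ),
            )
            tree.linkages[tree.linkages.index(ln)] = ln2
        elif child_position is not None:
            ln2 = Linkage(
                child_id=ln.child_id,
                parent_id=ln.parent_id,
                parent_positions=ln.parent_positions,
                child_position=child_position,
            )
            tree.linkages[tree.linkages.index(ln)] = ln2

    def set_residue_properties(self, residue_id: int,
                               configuration: Optional[str | Sequence[str]] = None,
                               ring: Optional[tuple[int, int]] = None,
                               anomer: Optional[str] = None) -> None:
        """Update only the supplied fields; others are preserved."""
        res = self.residue(residue_id)
        new = copy.deepcopy(res)
        if configuration is not None:
            if isinstance(configuration, str):
                configs = tuple(
                    _coerce_config(configuration) for _ in res.stems
                )
            else:
                if len(configuration) != len(res.stems):
                    raise ValidationError(
                        "configuration tuple length must match stems"
                    )
                configs = tuple(_coerce_config(c) for c in configuration)
            new.configs = configs
        if anomer is not None:
            new.anomer = _coerce_anomer(anomer)
            if new.anomer == "o":
                new.ring = (UNKNOWN, UNKNOWN)
        if ring is not None:
            new.ring = tuple(ring)  # type: ignore[assignment]
        new.validate()  # raises before any mutation
        self._record()
        self._find_tree(residue_id).residues[residue_id] = new

    def delete_residue(self, residue_id: int) -> None:
        """Remove a residue and its whole descendant subtree.

        Deleting the core root while fragments exist is refused; deleting a
        fragment root removes the fragment part. Core deletions prune the
        deleted residues from fragment attachment-site sets and refuse to
        leave any fragment without sites.
        """
        tree = self._find_tree(residue_id)
        if tree is self.core:
            doomed = tree.descendants(residue_id)
            if residue_id == self.core.root_id and self.fragments:
                raise DependencyError(
                    "cannot delete the core root while fragment parts exist"
                )
            for frag in self.fragments:
                if frag.attachment_sites and not (frag.attachment_sites - doomed):
                    raise DependencyError(
                        f"delete would leave fragment *{frag.index} "
                        "without attachment sites"
                    )
            self._record()
            for frag in self.fragments:
                frag.attachment_sites = frozenset(
                    frag.attachment_sites - doomed
                )
            for rid in doomed:
                del self.core.residues[rid]
            self.core.linkages = [
                ln for ln in self.core.linkages
                if ln.child_id not in doomed and ln.parent_id not in doomed
            ]
            if residue_id == self.core.root_id:
                self.core.root_id = None
        else:
            frag = next(f for f in self.fragments
                        if residue_id in f.tree.residues)
            self._record()
            if residue_id == frag.tree.root_id:
                self.fragments.remove(frag)
            else:
                doomed = frag.tree.descendants(residue_id)
                for rid in doomed:
                    del frag.tree.residues[rid]
                frag.tree.linkages = [
                    ln for ln in frag.tree.linkages
                    if ln.child_id not in doomed and ln.parent_id not in doomed
                ]

    def replace_residue(self, residue_id: int, residue_spec: str) -> None:
        """Swap the monosaccharide class, preserving the linkages, the
        children, and substituents whose positions remain valid."""
        tree = self._find_tree(residue_id)
        old = tree.residues[residue_id]
        new = residue_from_spec(residue_spec, residue_id)  # may raise
        self._record()
        new.anomer = old.anomer
        if new.superclass == old.superclass:
            new.ring = old.ring
        fused = {(s.position, s.name) for s in new.substituents}
        for sub in old.substituents:
            key = (sub.position, sub.name)
            if key in fused:
                continue
            if sub.position == UNKNOWN or sub.position <= new.backbone_length:
                new.substituents.append(copy.deepcopy(sub))
        tree.residues[residue_id] = new

    # -- fragments ---------------------------------------------------------

    def add_fragment(self, residue_spec: str,
                     anomer: str = "x",
                     parent_positions: Sequence[int] = (UNKNOWN,),
                     child_position: Optional[int] = None) -> int:
        """Append a single-residue fragment part; candidate attachment
        sites default to every core residue. Returns the 1-based fragment
        index (the "*n" label)."""
        if not self.core:
            raise OrderingError(
                "the core part must be drawn before adding fragment parts"
            )
        res = residue_from_spec(residue_spec, self._next_id)  # may raise
        self._record()
        self._next_id += 1
        res.anomer = _coerce_anomer(anomer)
        tree = GlycanTree(residues={res.id: res}, root_id=res.id)
        index = max((f.index for f in self.fragments), default=0) + 1
        self.fragments.append(FragmentPart(
            tree=tree,
            linkage_info=Linkage(
                child_id=res.id,
                parent_id=UNKNOWN,
                parent_positions=tuple(parent_positions),
                child_position=(
                    child_position if child_position is not None
                    else anomeric_position(res)
                ),
            ),
            attachment_sites=frozenset(self.core.residues),
            index=index,
        ))
        return index

    def fragment(self, index: int) -> FragmentPart:
        for frag in self.fragments:
            if frag.index == index:
                return frag
        raise MissingResidueError(f"no fragment with index {index}")

    def set_attachment_sites(self, fragment_index: int,
                             site_ids: Sequence[int]) -> None:
        frag = self.fragment(fragment_index)
        sites = frozenset(site_ids)
        if not sites:
            raise ValidationError("attachment sites must be non-empty")
        bad = sites - set(self.core.residues)
        if bad:
            raise ValidationError(
                f"not core residues: {sorted(bad)}"
            )
        self._record()
        frag.attachment_sites = sites

    def set_fragment_linkage(self, fragment_index: int,
                             parent_positions: Optional[Sequence[int]] = None,
                             child_position: Optional[int] = None) -> None:
        frag = self.fragment(fragment_index)
        self._record()
        li = frag.linkage_info
        frag.linkage_info = Linkage(
            child_id=li.child_id,
            parent_id=li.parent_id,
            parent_positions=(
                tuple(parent_positions) if parent_positions is not None
                else li.parent_positions
            ),
            child_position=(
                child_position if child_position is not None
                else li.child_position
            ),
        )

    # -- normalization -----------------------------------------------------

    def normalize(self) -> "GlycanDocument":
        """Recompute every residue's SNFG display name from its chemistry.

        Pure relabeling: the chemical content (and hence the GlycoCT
        serialization) is unchanged. Residues with no dictionary match get
        a generic superclass label.
        """
        self._record()
        for tree in self.all_trees():
            for res in tree.residues.values():
                cls = snfg.match_class(
                    res.stems, res.configs, res.superclass,
                    res.modifications,
                    [(s.position, s.name) for s in res.substituents],
                )
                if cls is not None:
                    res.display_name = cls.name
                else:
                    res.display_name = snfg.generic_symbol(res.superclass).label
        return self

    # -- validation / comparison -------------------------------------------

    def validate(self) -> None:
        self.core.validate()
        seen: set[int] = set(self.core.residues)
        indices = set()
        for frag in self.fragments:
            frag.tree.validate()
            if not frag.tree:
                raise ValidationError("empty fragment tree")
            overlap = seen & set(frag.tree.residues)
            if overlap:
                raise ValidationError(f"duplicate residue ids {overlap}")
            seen |= set(frag.tree.residues)
            if not frag.attachment_sites:
                raise ValidationError("fragment with no attachment sites")
            if not frag.attachment_sites <= set(self.core.residues):
                raise ValidationError(
                    "attachment sites outside the core part"
                )
            if frag.index in indices:
                raise ValidationError(f"duplicate fragment index {frag.index}")
            indices.add(frag.index)
        if self.fragments and not self.core:
            raise ValidationError("fragments without a core part")

    def signature(self) -> tuple:
        """Id-free structural signature of the whole document."""
        return (
            self.core.signature(),
            tuple(f.signature(self.core) for f in
                  sorted(self.fragments, key=lambda f: f.index)),
        )


def documents_equivalent(a: GlycanDocument, b: GlycanDocument) -> bool:
    """Graph-isomorphism check: equal id-free signatures."""
    return a.signature() == b.signature()


def _clone_core_only(doc: GlycanDocument) -> GlycanDocument:
    out = GlycanDocument()
    out.core = copy.deepcopy(doc.core)
    out._next_id = doc._next_id
    return out


def enumerate_concrete(doc: GlycanDocument,
                       max_results: Optional[int] = None
                       ) -> list[GlycanDocument]:
    """Expand fragment ambiguity into concrete (fragment-free) documents.

    Each fragment is grafted onto exactly one of its candidate attachment
    sites. A fragment assigned to site *s* occupies the pairs (s, p) for
    every *known* parent position p of its linkage; two fragments may not
    occupy the same pair — unknown positions never collide. Output order is
    lexicographic over (fragment index, site id).
    """
    doc.validate()
    frags = sorted(doc.fragments, key=lambda f: f.index)
    site_lists = [sorted(f.attachment_sites) for f in frags]
    out: list[GlycanDocument] = []
    for assignment in itertools.product(*site_lists):
        occupied: set[tuple[int, int]] = set()
        ok = True
        for frag, site in zip(frags, assignment):
            pairs = {
                (site, p) for p in frag.linkage_info.parent_positions
                if p != UNKNOWN
            }
            if pairs & occupied:
                ok = False
                break
            occupied |= pairs
        if not ok:
            continue
        concrete = _clone_core_only(doc)
        for frag, site in zip(frags, assignment):
            sub = copy.deepcopy(frag.tree)
            concrete.core.residues.update(sub.residues)
            concrete.core.linkages.extend(sub.linkages)
            concrete.core.linkages.append(Linkage(
                child_id=sub.root_id,
                parent_id=site,
                parent_positions=frag.linkage_info.parent_positions,
                child_position=frag.linkage_info.child_position,
            ))
        concrete.validate()
        out.append(concrete)
        if max_results is not None and len(out) > max_results:
            raise TruncationError(
                f"more than {max_results} concrete structures"
            )
    return out
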