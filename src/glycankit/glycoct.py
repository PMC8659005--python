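"""GlycoCT condensed reader and writer, including UND fragment blocks.

GlycoCT condensed is the line-oriented sequence format used by glycan
databases: a ``RES`` section of basetype (``b``) and substituent (``s``)
records, a ``LIN`` section of linkage records, and optional ``UND`` blocks
for underdetermined subunits. Each UND block carries a statistics header,
a ``ParentIDs`` line naming the candidate attachment residues on the core,
a ``SubtreeLinkageID`` line describing the (possibly unknown) linkage, and
the fragment's own nested RES/LIN.

The writer is canonical: residues are renumbered in depth-first pre-order
(children by ascending known parent position, unknown last, ties by
creation order), substituent lines follow their residue, fragments are
emitted in index order and their ids continue the global sequence. Hence
``write(parse(write(d))) == write(d)`` byte-for-byte.

REP (repeat) and ALT (alternative) sections are out of scope and rejected
with :class:`UnsupportedFeatureError`.
"""

from __future__ import annotations

import re
from typing import Optional

from .errors import (
    EmptyDocumentError,
    GlycoCTParseError,
    UnsupportedFeatureError,
)
from .model import (
    FragmentPart,
    GlycanDocument,
    GlycanTree,
    Linkage,
    Residue,
    Substituent,
)
from .snfg import UNKNOWN, SUPERCLASS_LENGTH, substituent_class

# GlycoCT tokens for backbone modifications <-> model kinds
_MOD_TO_TOKEN = {
    "deoxy": "d",
    "acid": "a",
    "ketone": "keto",
    "aldehyde": "aldi",
    "en": "en",
}
_TOKEN_TO_MOD = {v: k for k, v in _MOD_TO_TOKEN.items()}

_SUPERCLASSES = set(SUPERCLASS_LENGTH)


# ---------------------------------------------------------------------------
# basetype strings

def write_basetype(res: Residue) -> str:
    """Serialize a residue to its basetype stereocode, e.g.
    ``b-dglc-HEX-1:5`` or ``a-dgro-dgal-NON-2:6|1:a|2:keto|3:d``."""
    parts = [res.anomer]
    for config, stem in zip(res.configs, res.stems):
        parts.append(f"{config}{stem}")
    parts.append(res.superclass)
    if res.anomer == "o":
        ring = "0:0"
    elif res.ring[0] == UNKNOWN or res.ring[1] == UNKNOWN:
        ring = "x:x"
    else:
        ring = f"{res.ring[0]}:{res.ring[1]}"
    out = "-".join(parts) + "-" + ring
    for pos, kind in res.sorted_modifications():
        out += f"|{pos}:{_MOD_TO_TOKEN[kind]}"
    return out


def parse_basetype(text: str, residue_id: int,
                   line: Optional[int] = None) -> Residue:
    """Parse a basetype stereocode into a Residue."""
    body, _, modpart = text.partition("|")
    modifications = set()
    if modpart:
        for clause in modpart.split("|"):
            m = re.fullmatch(r"(\d+):([a-z0-9]+)", clause)
            if not m or m.group(2) not in _TOKEN_TO_MOD:
                raise GlycoCTParseError(
                    f"bad modification {clause!r}", line
                )
            modifications.add((int(m.group(1)), _TOKEN_TO_MOD[m.group(2)]))
    tokens = body.split("-")
    if len(tokens) < 4:
        raise GlycoCTParseError(f"bad basetype {text!r}", line)
    anomer = tokens[0]
    if anomer not in ("a", "b", "o", "x"):
        raise GlycoCTParseError(f"bad anomer {anomer!r}", line)
    ring_token = tokens[-1]
    superclass = tokens[-2]
    if superclass not in _SUPERCLASSES:
        raise GlycoCTParseError(f"bad superclass {superclass!r}", line)
    stems, configs = [], []
    for tok in tokens[1:-2]:
        m = re.fullmatch(r"([dlx])([a-z]{3})", tok)
        if not m:
            raise GlycoCTParseError(f"bad stem token {tok!r}", line)
        configs.append(m.group(1))
        stems.append(m.group(2))
    if not stems:
        raise GlycoCTParseError(f"no stem in {text!r}", line)
    if ring_token in ("x:x", "0:0"):
        ring = (UNKNOWN, UNKNOWN)
    else:
        m = re.fullmatch(r"(\d+):(\d+)", ring_token)
        if not m:
            raise GlycoCTParseError(f"bad ring {ring_token!r}", line)
        ring = (int(m.group(1)), int(m.group(2)))
    try:
        return Residue(
            id=residue_id,
            stems=tuple(stems),
            configs=tuple(configs),
            superclass=superclass,
            anomer=anomer,
            ring=ring,
            modifications=frozenset(modifications),
        )
    except Exception as exc:
        raise GlycoCTParseError(str(exc), line) from exc


def _positions_token(positions: tuple[int, ...]) -> str:
    return "|".join(str(p) for p in positions)


# ---------------------------------------------------------------------------
# writer

class _Writer:
    def __init__(self, doc: GlycanDocument):
        self.doc = doc
        self.res_lines: list[str] = []
        self.lin_lines: list[str] = []
        self.next_res = 1
        self.next_lin = 1
        self.core_ids: dict[int, int] = {}  # internal id -> written id

    def _emit_res(self, line_body: str) -> int:
        rid = self.next_res
        self.next_res += 1
        self.res_lines.append(f"{rid}{line_body}")
        return rid

    def _emit_lin(self, body: str) -> None:
        self.lin_lines.append(f"{self.next_lin}:{body}")
        self.next_lin += 1

    def _emit_tree(self, tree: GlycanTree,
                   id_map: Optional[dict[int, int]] = None) -> int:
        """Emit RES/LIN for one tree, returning the written root id."""
        root_written = None

        def visit(rid: int, parent_written: Optional[int],
                  link: Optional[Linkage]) -> None:
            nonlocal root_written
            res = tree.residues[rid]
            written = self._emit_res("b:" + write_basetype(res))
            if id_map is not None:
                id_map[rid] = written
            if root_written is None:
                root_written = written
            if link is not None and parent_written is not None:
                self._emit_lin(
                    f"{parent_written}o"
                    f"({_positions_token(link.parent_positions)}"
                    f"+{link.child_position}){written}d"
                )
            for sub in res.sorted_substituents():
                sid = self._emit_res(f"s:{sub.name}")
                self._emit_lin(
                    f"{written}{sub.parent_link}"
                    f"({sub.position}+1){sid}n"
                )
            for child_link in tree.ordered_children(rid):
                visit(child_link.child_id, written, child_link)

        assert tree.root_id is not None
        visit(tree.root_id, None, None)
        assert root_written is not None
        return root_written

    def write(self) -> str:
        doc = self.doc
        if doc.is_empty:
            raise EmptyDocumentError("cannot serialize an empty document")
        lines = []
        self._emit_tree(doc.core, self.core_ids)
        und_chunks: list[list[str]] = []
        for n, frag in enumerate(
                sorted(doc.fragments, key=lambda f: f.index), start=1):
            chunk = [f"UND{n}:100.0:100.0"]
            parent_ids = sorted(
                self.core_ids[rid] for rid in frag.attachment_sites
            )
            chunk.append("ParentIDs:" + "|".join(map(str, parent_ids)))
            li = frag.linkage_info
            chunk.append(
                f"SubtreeLinkageID{n}:o"
                f"({_positions_token(li.parent_positions)}"
                f"+{li.child_position})d"
            )
            res_start = len(self.res_lines)
            lin_start = len(self.lin_lines)
            self._emit_tree(frag.tree)
            chunk.append("RES")
            chunk.extend(self.res_lines[res_start:])
            del self.res_lines[res_start:]
            if len(self.lin_lines) > lin_start:
                chunk.append("LIN")
                chunk.extend(self.lin_lines[lin_start:])
                del self.lin_lines[lin_start:]
            und_chunks.append(chunk)
        lines.append("RES")
        lines.extend(self.res_lines)
        if self.lin_lines:
            lines.append("LIN")
            lines.extend(self.lin_lines)
        if und_chunks:
            lines.append("UND")
            for chunk in und_chunks:
                lines.extend(chunk)
        return "\n".join(lines) + "\n"


def write_glycoct(doc: GlycanDocument) -> str:
    """Serialize a document to canonical GlycoCT condensed text."""
    return _Writer(doc).write()


# ---------------------------------------------------------------------------
# parser

_RES_RE = re.compile(r"^(\d+)([bs]):(.+)$")
_LIN_RE = re.compile(
    r"^(\d+):(\d+)([odn])\((-1|\d+(?:\|(?:-1|\d+))*)\+(-1|\d+)\)(\d+)([odn])$"
)
_UND_HDR_RE = re.compile(r"^UND(\d+):([0-9.]+):([0-9.]+)$")
_SUBTREE_RE = re.compile(
    r"^SubtreeLinkageID(\d+):([odn])\((-1|\d+(?:\|(?:-1|\d+))*)"
    r"\+(-1|\d+)\)([odn])$"
)


class _Section:
    """One RES/LIN pair (the main section or a UND block body)."""

    def __init__(self):
        self.basetypes: dict[int, str] = {}   # file id -> stereocode
        self.substituents: dict[int, str] = {}
        self.links: list[tuple] = []          # (parent, ptype, positions, cpos, child, ctype, line)


def _parse_positions(token: str, line: int) -> tuple[int, ...]:
    out = []
    for part in token.split("|"):
        out.append(int(part))
    return tuple(out)


def _build_tree(section: _Section, doc: GlycanDocument,
                file_to_internal: dict[int, int]) -> GlycanTree:
    """Materialize one section into a GlycanTree using document ids."""
    tree = GlycanTree()
    for fid in sorted(section.basetypes):
        res = parse_basetype(section.basetypes[fid], doc._next_id)
        doc._next_id += 1
        file_to_internal[fid] = res.id
        tree.residues[res.id] = res
    parented: set[int] = set()
    for parent, ptype, positions, cpos, child, ctype, line in section.links:
        if child in section.substituents:
            if parent not in section.basetypes or parent not in file_to_internal:
                raise GlycoCTParseError(
                    f"substituent {child} attached to unknown residue "
                    f"{parent}", line)
            name = section.substituents[child]
            try:
                substituent_class(name)
            except Exception as exc:
                raise GlycoCTParseError(str(exc), line) from exc
            pos = positions[0] if positions else UNKNOWN
            res = tree.residues[file_to_internal[parent]]
            res.substituents.append(Substituent(name=name, position=pos))
        elif child in section.basetypes:
            if parent not in section.basetypes:
                raise GlycoCTParseError(
                    f"linkage references undeclared residue {parent}", line)
            try:
                tree.linkages.append(Linkage(
                    child_id=file_to_internal[child],
                    parent_id=file_to_internal[parent],
                    parent_positions=positions,
                    child_position=cpos,
                ))
            except Exception as exc:
                raise GlycoCTParseError(str(exc), line) from exc
            parented.add(file_to_internal[child])
        else:
            raise GlycoCTParseError(
                f"linkage references undeclared id {child}", line)
    roots = [rid for rid in tree.residues if rid not in parented]
    if tree.residues:
        if len(roots) != 1:
            raise GlycoCTParseError(
                f"section has {len(roots)} roots; expected exactly 1")
        tree.root_id = roots[0]
        tree.validate()
    return tree


def parse_glycoct(text: str) -> GlycanDocument:
    """Parse GlycoCT condensed text (RES/LIN + optional UND blocks).

    ``\\r\\n`` line endings are tolerated. REP/ALT sections raise
    :class:`UnsupportedFeatureError`.
    """
    lines = text.replace("\r\n", "\n").split("\n")
    main = _Section()
    # each UND block: (stats, parent_file_ids, linkage tuple, section)
    blocks: list[dict] = []
    state = "start"
    current: Optional[_Section] = None
    block: Optional[dict] = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line in ("REP", "ALT", "ISO"):
            raise UnsupportedFeatureError(
                f"GlycoCT {line} sections are not supported"
            )
        if line == "RES":
            if state == "start":
                current, state = main, "res"
            elif state in ("und", "und-linkage"):
                if block is None or "linkage" not in block:
                    raise GlycoCTParseError(
                        "RES inside UND before SubtreeLinkageID", lineno)
                current = block["section"]
                state = "und-res"
            else:
                raise GlycoCTParseError("unexpected RES", lineno)
            continue
        if line == "LIN":
            if state == "res":
                state = "lin"
            elif state == "und-res":
                state = "und-lin"
            else:
                raise GlycoCTParseError("unexpected LIN", lineno)
            continue
        if line == "UND":
            if state not in ("res", "lin", "und-res", "und-lin"):
                raise GlycoCTParseError("unexpected UND", lineno)
            state = "und-start"
            continue
        m = _UND_HDR_RE.match(line)
        if m and state in ("und-start", "und-res", "und-lin"):
            block = {
                "stats": (float(m.group(2)), float(m.group(3))),
                "section": _Section(),
                "line": lineno,
            }
            blocks.append(block)
            state = "und"
            continue
        if line.startswith("ParentIDs:"):
            if block is None or state != "und":
                raise GlycoCTParseError("stray ParentIDs line", lineno)
            try:
                block["parents"] = [
                    int(tok) for tok in line[len("ParentIDs:"):].split("|")
                ]
            except ValueError:
                raise GlycoCTParseError("bad ParentIDs line", lineno) from None
            continue
        m = _SUBTREE_RE.match(line)
        if m:
            if block is None or state != "und":
                raise GlycoCTParseError("stray SubtreeLinkageID line", lineno)
            block["linkage"] = (
                _parse_positions(m.group(3), lineno),
                int(m.group(4)),
            )
            state = "und-linkage"
            continue
        m = _RES_RE.match(line)
        if m and state in ("res", "und-res"):
            assert current is not None
            fid, kind, body = int(m.group(1)), m.group(2), m.group(3)
            if fid in current.basetypes or fid in current.substituents:
                raise GlycoCTParseError(f"duplicate RES id {fid}", lineno)
            if kind == "b":
                current.basetypes[fid] = body
            else:
                current.substituents[fid] = body
            continue
        m = _LIN_RE.match(line)
        if m and state in ("lin", "und-lin"):
            assert current is not None
            current.links.append((
                int(m.group(2)), m.group(3),
                _parse_positions(m.group(4), lineno),
                int(m.group(5)), int(m.group(6)), m.group(7), lineno,
            ))
            continue
        raise GlycoCTParseError(f"unrecognized line {line!r}", lineno)

    doc = GlycanDocument()
    if not main.basetypes:
        raise GlycoCTParseError("no RES section / no residues")
    core_map: dict[int, int] = {}
    doc.core = _build_tree(main, doc, core_map)
    for n, blk in enumerate(blocks, start=1):
        if "parents" not in blk or "linkage" not in blk:
            raise GlycoCTParseError(
                "UND block missing ParentIDs or SubtreeLinkageID",
                blk["line"])
        frag_map: dict[int, int] = {}
        tree = _build_tree(blk["section"], doc, frag_map)
        if not tree:
            raise GlycoCTParseError("UND block with empty RES", blk["line"])
        sites = set()
        for fid in blk["parents"]:
            if fid not in core_map:
                raise GlycoCTParseError(
                    f"ParentIDs references non-core id {fid}", blk["line"])
            sites.add(core_map[fid])
        positions, cpos = blk["linkage"]
        doc.fragments.append(FragmentPart(
            tree=tree,
            linkage_info=Linkage(
                child_id=tree.root_id,
                parent_id=UNKNOWN,
                parent_positions=positions,
                child_position=cpos,
            ),
            attachment_sites=frozenset(sites),
            index=n,
            stats=blk["stats"],
        ))
    doc.validate()
    return doc
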