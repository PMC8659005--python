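# Methods

## Document model

A `GlycanDocument` is an ordered collection of rooted residue trees: one
core plus zero or more fragment parts (`FragmentPart`). A document with
no fragment parts is a simple glycan. Invariants enforced by
`validate()`:

* every tree is connected and acyclic, every non-root residue has
  exactly one parent; the core root is the reducing end;
* fragment attachment sites are non-empty subsets of the core residue
  set; fragment indices (`*n` labels) are unique and assigned in
  creation order;
* a single unknown sentinel (`-1` for positions and ring bounds, `x`
  for anomer and configuration) is used uniformly;
* open-chain residues (`anomer = o`) cannot carry a ring.

Editing operations (`add_monosaccharide`, `add_substituent`,
`set_linkage`, `set_residue_properties`, `delete_residue`,
`replace_residue`, `add_fragment`, `set_attachment_sites`, `normalize`)
snapshot the document before mutating; `undo`/`redo` restore adjacent
snapshots (value copies — later edits never mutate history entries), and
`clear` purges both the structure and the history, so a cleared document
cannot be recovered. Operations that can fail validate their inputs
before the snapshot is taken, so a refused edit leaves both the document
and the history untouched.

Design choices where the behaviour was genuinely open:

* **Delete semantics.** Deleting a residue removes its whole descendant
  subtree; re-parenting heuristics would silently invent linkages.
  Deleting the core root is refused while fragments exist, and a core
  deletion that would leave some fragment without any candidate site is
  refused; otherwise deleted residues are pruned from site sets.
* **Replace semantics.** `replace_residue` swaps the monosaccharide
  class (stems, configuration, superclass, modifications) and preserves
  the anomer, the linkages, the children and any substituent whose
  position is still within the new backbone.
* **Fragment collisions.** In `enumerate_concrete`, a fragment assigned
  to site *s* occupies the pairs (s, p) for each *known* parent position
  p; assignments whose occupied pairs intersect are excluded. Unknown
  positions occupy nothing and never collide. Output order is
  lexicographic over (fragment index, site id), making the expansion
  deterministic.
* **Attachment-site default.** A new fragment is attachable to every
  core residue; the `*n` annotations only appear once the user restricts
  the set (matching how site selection works in SNFG drawings).

## GlycoCT condensed

The writer is canonical: internal ids never leak — residues are
renumbered in depth-first pre-order, visiting children by ascending known
parent position, unknown positions last, ties by creation order;
substituent lines directly follow their residue; fragments are written as
`UND` blocks in index order, with ids continuing the global sequence,
`ParentIDs` ascending, and statistics always `100.0:100.0` (the
conventional "unknown" values; parsed statistics are retained in memory
but not interpreted). Linkage-type letters follow standard usage:
glycosidic bonds are `o…d`, N-replacement substituents (N-acetyl,
N-sulfate, amino…) are `d…n`, O-linked substituents `o…n`. Because the
parser assigns creation order from file order, `write ∘ parse` is a byte
fixpoint of the writer's output.

Scope: GlycoCT condensed only; `REP`/`ALT`/`ISO` sections raise an
unsupported-feature error naming the section. `\r\n` input is tolerated;
output uses `\n`.

## WURCS 2.0

Encoding is dictionary-driven rather than derived from first-principles
stereochemistry: a static table maps residue signatures
(stems, configurations, superclass, backbone modifications) to backbone
skeleton codes. The table stores D-form stereo digit strings
(glc 2122, man 1122, gal 2112, all 2222; xyl 212, rib 222, ara 122,
lyx 112 — digit 2 = hydroxyl right, 1 = left in the Fischer projection)
and derives L forms by the mirror rule (1↔2), which reproduces the
published codes for L-Fuc (`a1221m`) and L-Rha (`a2211m`). Hexose
variants map 6-deoxy to terminal `m` and 6-acid to `A`; the
Neu/Kdn backbone is the fixed skeleton `Aad21122h` with anomeric
position 2. Substituents map to MAP expressions (`*NCC/3=O` N-acetyl,
`*OSO/3=O/3=O` sulfate, …). Residues outside the table — including
open-chain forms and unknown configurations — raise an
unsupported-residue error listing the residue.

Residue instances are ordered by the same depth-first traversal as the
GlycoCT writer (an approximation of WURCS canonical ordering; exact
canonicalization is out of scope). Core bonds render as `a4-b1` with `?`
for unknowns and `a3|a6` for position alternatives; each fragment renders
one alternative-parent descriptor `a?|b?}-c1` over the cross product of
its sites and positions. The counts triple is (unique codes, instances,
linkage descriptors including fragment descriptors). The reader inverts
the writer on this subset and cross-checks all three counts against the
body.

## SNFG normalization and symbols

The monosaccharide dictionary covers the common SNFG classes (hexoses,
HexN, HexNAc, HexA, deoxyhexoses and their NAc forms, pentoses,
Neu5Ac/Neu5Gc/Kdn) with their shape/color pairs from the published
palette. A class matches a residue when stems, configurations,
superclass and modifications agree exactly and the class's defining
substituents are present at their positions; among matches the class
consuming the most substituents wins, so Glc + 2NAc normalizes to GlcNAc
while a 6-sulfate on the same residue neither blocks the match nor
disappears (it is rendered as adjacent text, `6S`). `normalize()` only
rewrites display names: serialization before and after is byte-identical.
Unmatched residues fall back to a white generic shape labelled by size
class (Hex, Pen, …).

## Layout and SVG

Grid layout with the reducing end rightmost: column = depth (growing
leftward), leaf rows assigned top-down, internal rows the mean of their
children. Among siblings the larger known parent position is drawn on
the upper row, unknown positions below known ones, ties by creation
order. Fragments stack left of a single right-facing square bracket
spanning the drawing's vertical extent, which sits one grid unit left of
the core's bounding box; each fragment root has a dashed pending edge
toward the bracket. Defaults: 50 px unit spacing, 18 px symbol radius,
both configurable via `RenderOptions`. Rendering is pure string
building over sorted traversals, so equal inputs give byte-identical
SVG; shapes carry `class="snfg-symbol"`, bonds `linkage`, the bracket
`bracket` and `*n` marks `annotation`, which is what the rendering
tests count after XML parsing. Substituents are drawn as short text
next to their residue, not as grid nodes. Exact pixel aesthetics are not
contractual; the tested properties are the topological/ordering ones
above.

## Search client

`search_glytoucan` validates the WURCS shape *before* any network
activity, then issues one GET to the configured endpoint (default: the
GlyCosmos WURCS→GlyTouCan-id service) with a 30 s timeout and no
retries. Transport failures, non-2xx responses and unparseable bodies
all return `status="error"` results instead of raising. Because the
response schema is not formally documented, accession extraction is
tolerant: conventional keys first (`id`, `accession`), then any
accession-shaped string (`G` + 7 alphanumerics, advisory only). Entry
and image URLs are pure string assembly from the configured bases
(entry default `https://glycosmos.org/glycans/show/`). The transport is
an injectable callable; the whole test suite runs offline against stubs.

## Fixtures: templates and the random generator

Templates ship as GlycoCT files loaded through the package's own parser:
the Man3GlcNAc2 N-glycan core pentasaccharide, mucin O-glycan cores 1
and 2, the lactose unit of lactosylceramide-type glycolipids, and a
chondroitin-style GlcA β1-3 GalNAc GAG stub. The category list is the
conventional one; the contents are fixed from standard glycobiology.

`random_document(GeneratorConfig)` emulates what a user draws in such an
editor: 2–8 residues by default (up to 10 in the round-trip suites),
30 % branching, 0–2 fragment parts, a 50 % chance that a fragment's
sites are restricted to a proper subset, 20 % unknown linkages, 10 %
ambiguous two-position linkages, 20 % extra substituents — all drawn
from the SNFG dictionary with ring-form anomers (α/β/unknown), since
that is what symbol-based editors produce. The generator is seeded and
deterministic (equal configs give byte-identical canonical GlycoCT) and
builds documents through the editing API, so every generated document
also exercises the history machinery. What it does **not** emulate:
biological plausibility of linkage chemistry (a generated "Gal α2-Xyl"
is chemically writable but biologically meaningless), repeat units,
cyclic glycans, glycoconjugate anchors, and open-chain forms — passing
round-trip and rendering tests therefore demonstrates format and
geometry correctness over the representable space, not biological
realism of the corpus.

## Problem sizes and numerical conventions

The acceptance checks use 500 documents for GlycoCT round-trips, 200 for
WURCS commutation, 100 each for enumeration agreement and rendering
contracts — large enough to cover the generator's branch/fragment/
unknown combinations many times over while keeping the whole run in
seconds. All checks are exact (byte equality, integer counts); there are
no numerical tolerances anywhere in the package. Ties and orderings are
resolved deterministically as described above, which is what makes byte
equality a usable contract.

## Known limitations

* WURCS coverage is the shipped dictionary, not the full skeleton
  algebra; unknown-configuration and open-chain residues serialize to
  GlycoCT but not to WURCS.
* WURCS residue ordering approximates, not reproduces, the official
  canonicalization, so strings for multi-branch glycans may be
  letter-permuted relative to GlyTouCan's registered form (the β-D-Glc,
  LacNAc and N-glycan-core outputs do match the registered strings).
* GlycoCT `REP`/`ALT`, cyclic glycans and glycoconjugate anchors are out
  of scope.
* The live GlyCosmos endpoint's schema is assumed only loosely (tolerant
  extraction); the client is written to be reconfigured per deployment.
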