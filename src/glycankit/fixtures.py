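"""Template structures and a seeded random-glycan generator.

Templates mirror the "Load Structure" categories of interactive glycan
editors: N-linked glycan, O-linked glycan, glycolipid, glycosaminoglycan
(GAG). The category list is standard; the concrete contents are fixed
from textbook glycobiology — the Man3GlcNAc2 N-glycan core
pentasaccharide, mucin O-glycan cores 1 and 2, the lactose unit of
lactosylceramide-type glycolipids, and a chondroitin-style GAG
disaccharide stub. Templates ship as GlycoCT files in the package data
directory and are loaded through the package's own parser.

The random generator is the repository's stand-in for interactive
drawing: seeded, fully deterministic, and restricted to the SNFG
dictionary, it drives the property tests (round-trips, enumeration,
rendering contracts).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from .errors import ValidationError, VocabularyError
from .glycoct import parse_glycoct
from .model import GlycanDocument
from .snfg import MONOSACCHARIDE_CLASSES, UNKNOWN

TEMPLATE_ALIASES = {
    "n-glycan": "n-glycan",
    "o-glycan": "o-glycan-core1",
    "o-glycan-core1": "o-glycan-core1",
    "o-glycan-core2": "o-glycan-core2",
    "glycolipid": "glycolipid",
    "gag": "gag",
}


def template_names() -> list[str]:
    return sorted(TEMPLATE_ALIASES)


def load_template(name: str) -> GlycanDocument:
    """Load a named template structure (parsed from its GlycoCT file)."""
    key = TEMPLATE_ALIASES.get(name.lower())
    if key is None:
        raise VocabularyError(
            f"unknown template {name!r}; known: "
            + ", ".join(template_names())
        )
    text = (
        resources.files("glycankit") / "templates" / f"{key}.glycoct"
    ).read_text(encoding="utf-8")
    return parse_glycoct(text)


@dataclass(frozen=True)
class GeneratorConfig:
    """Distribution parameters for :func:`random_document`.

    Defaults describe the glycans such editors typically hold: a handful
    of residues, occasional branching, up to two underdetermined
    fragments, and a realistic share of unknown linkage information.
    """

    seed: int = 0
    min_residues: int = 2
    max_residues: int = 8
    branch_probability: float = 0.3
    min_fragments: int = 0
    max_fragments: int = 2
    site_subset_probability: float = 0.5
    unknown_linkage_probability: float = 0.2
    ambiguous_position_probability: float = 0.1
    substituent_probability: float = 0.2

    def validate(self) -> None:
        if not 1 <= self.min_residues <= self.max_residues:
            raise ValidationError("need 1 <= min_residues <= max_residues")
        if not 0 <= self.min_fragments <= self.max_fragments:
            raise ValidationError("need 0 <= min_fragments <= max_fragments")
        if self.min_residues < 1 and self.max_fragments > 0:
            raise ValidationError("fragments require a non-empty core")
        for p in (self.branch_probability, self.site_subset_probability,
                  self.unknown_linkage_probability,
                  self.ambiguous_position_probability,
                  self.substituent_probability):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")


_NAMES = sorted(MONOSACCHARIDE_CLASSES)
_EXTRA_SUBSTITUENTS = ["sulfate", "methyl", "acetyl", "phosphate"]


def _random_linkage(rng: random.Random, cfg: GeneratorConfig,
                    parent_len: int) -> tuple[str, tuple[int, ...]]:
    anomer = rng.choice(["a", "a", "b", "b", "x"])
    if rng.random() < cfg.unknown_linkage_probability:
        return anomer, (UNKNOWN,)
    hi = max(2, parent_len)
    if rng.random() < cfg.ambiguous_position_probability and hi > 2:
        p1 = rng.randint(2, hi)
        p2 = rng.randint(2, hi)
        if p1 != p2:
            return anomer, (p1, p2)
    return anomer, (rng.randint(2, hi),)


def random_document(config: GeneratorConfig) -> GlycanDocument:
    """Draw one well-formed document from the configured distribution.

    Deterministic: equal configs produce byte-identical canonical
    GlycoCT. Residues are built through the editing API so every
    generated document also exercises the history machinery.
    """
    config.validate()
    rng = random.Random(config.seed)
    doc = GlycanDocument()
    n_residues = rng.randint(config.min_residues, config.max_residues)

    root = doc.add_monosaccharide(rng.choice(_NAMES))
    chain_tip = root
    ids = [root]
    for _ in range(n_residues - 1):
        if rng.random() < config.branch_probability:
            parent = rng.choice(ids)
        else:
            parent = chain_tip
        parent_len = doc.residue(parent).backbone_length
        anomer, positions = _random_linkage(rng, config, parent_len)
        rid = doc.add_monosaccharide(
            rng.choice(_NAMES), parent_id=parent,
            anomer=anomer, parent_positions=positions,
        )
        ids.append(rid)
        chain_tip = rid

    for rid in list(ids):
        if rng.random() < config.substituent_probability:
            res = doc.residue(rid)
            name = rng.choice(_EXTRA_SUBSTITUENTS)
            pos = rng.randint(2, res.backbone_length)
            try:
                doc.add_substituent(rid, name, pos)
            except Exception:
                pass  # occupied position: skip, keep determinism

    n_fragments = rng.randint(config.min_fragments, config.max_fragments)
    for _ in range(n_fragments):
        anomer, positions = _random_linkage(rng, config, 6)
        index = doc.add_fragment(
            rng.choice(_NAMES), anomer=anomer, parent_positions=positions,
        )
        if rng.random() < config.site_subset_probability and len(ids) > 1:
            k = rng.randint(1, len(ids) - 1)
            sites = rng.sample(sorted(ids), k)
            doc.set_attachment_sites(index, sites)

    doc.validate()
    return doc
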