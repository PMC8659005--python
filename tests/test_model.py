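"""Core document model: editing operations, fragments, history."""

import pytest

from glycankit import (
    ConflictError,
    DependencyError,
    GlycanDocument,
    MissingResidueError,
    NoParentError,
    OrderingError,
    TruncationError,
    ValidationError,
    VocabularyError,
    documents_equivalent,
    enumerate_concrete,
)
from glycankit.glycoct import write_glycoct
from glycankit.snfg import UNKNOWN

from conftest import brute_force_assignments, build_lacnac


class TestAddMonosaccharide:
    def test_first_residue_becomes_root(self):
        doc = GlycanDocument()
        rid = doc.add_monosaccharide("GlcNAc")
        assert doc.core.root_id == rid
        assert len(doc.core.residues) == 1
        assert doc.residue(rid).anomer == "x"

    def test_attach_with_linkage(self, lacnac):
        doc, root, gal = lacnac
        assert len(doc.core.residues) == 2
        ln = doc.core.parent_linkage(gal)
        assert ln.parent_positions == (4,)
        assert ln.child_position == 1
        assert doc.residue(gal).anomer == "b"

    def test_unknown_parent_is_reference_error(self, lacnac):
        doc, *_ = lacnac
        with pytest.raises(MissingResidueError):
            doc.add_monosaccharide("Gal", parent_id=999)

    def test_unknown_name_is_vocabulary_error(self):
        doc = GlycanDocument()
        with pytest.raises(VocabularyError):
            doc.add_monosaccharide("NotASugar")

    def test_nonempty_doc_requires_parent(self, lacnac):
        doc, *_ = lacnac
        with pytest.raises(MissingResidueError):
            doc.add_monosaccharide("Gal")

    def test_raw_stereocode_spec(self):
        doc = GlycanDocument()
        rid = doc.add_monosaccharide("b-dglc-HEX-1:5")
        res = doc.residue(rid)
        assert res.stems == ("glc",) and res.anomer == "b"


class TestSubstituents:
    def test_add_known_position(self):
        doc = GlycanDocument()
        rid = doc.add_monosaccharide("Glc")
        doc.add_substituent(rid, "n-acetyl", 2)
        subs = doc.residue(rid).substituents
        assert [(s.name, s.position) for s in subs] == [("n-acetyl", 2)]

    def test_unknown_position_round_trips(self):
        doc = GlycanDocument()
        rid = doc.add_monosaccharide("Gal")
        doc.add_substituent(rid, "sulfate")
        assert doc.residue(rid).substituents[0].position == UNKNOWN
        assert "(-1+1)" in write_glycoct(doc)

    def test_duplicate_is_conflict(self):
        doc = GlycanDocument()
        rid = doc.add_monosaccharide("Glc")
        doc.add_substituent(rid, "n-acetyl", 2)
        with pytest.raises(ConflictError):
            doc.add_substituent(rid, "n-acetyl", 2)

    def test_bad_name_is_vocabulary_error(self):
        doc = GlycanDocument()
        rid = doc.add_monosaccharide("Glc")
        with pytest.raises(VocabularyError):
            doc.add_substituent(rid, "plutonium", 2)


class TestSetLinkage:
    def test_ambiguous_positions_stored_and_serialized(self, lacnac):
        doc, root, gal = lacnac
        doc.set_linkage(gal, anomer="a", parent_positions=[3, 6])
        assert doc.core.parent_linkage(gal).parent_positions == (3, 6)
        assert "(3|6+1)" in write_glycoct(doc)

    def test_fully_undetermined_bond(self, lacnac):
        doc, root, gal = lacnac
        doc.set_linkage(gal, anomer="unknown", parent_positions=[UNKNOWN])
        ln = doc.core.parent_linkage(gal)
        assert ln.parent_positions == (UNKNOWN,)
        assert doc.residue(gal).anomer == "x"

    def test_root_has_no_parent(self, lacnac):
        doc, root, _ = lacnac
        with pytest.raises(NoParentError):
            doc.set_linkage(root, anomer="a", parent_positions=[2])


class TestResidueProperties:
    def test_configuration_only_changes_configuration(self, lacnac):
        doc, root, gal = lacnac
        before = doc.residue(gal)
        anomer, ring = before.anomer, before.ring
        doc.set_residue_properties(gal, configuration="L")
        after = doc.residue(gal)
        assert after.configs == ("l",)
        assert after.anomer == anomer and after.ring == ring

    def test_furanose_ring_descriptor(self):
        doc = GlycanDocument()
        rid = doc.add_monosaccharide("Gal", anomer="b")
        doc.set_residue_properties(rid, ring=(1, 4))
        assert "b-dgal-HEX-1:4" in write_glycoct(doc)

    def test_inverted_ring_is_validation_error(self, lacnac):
        doc, root, _ = lacnac
        with pytest.raises(ValidationError):
            doc.set_residue_properties(root, ring=(5, 2))
        # failed edit must not half-apply
        assert doc.residue(root).ring == (1, 5)


class TestDeleteReplace:
    def test_delete_leaf(self, lacnac):
        doc, root, gal = lacnac
        doc.delete_residue(gal)
        assert set(doc.core.residues) == {root}
        assert doc.core.linkages == []

    def test_delete_internal_removes_subtree(self):
        doc = GlycanDocument()
        a = doc.add_monosaccharide("GlcNAc")
        b = doc.add_monosaccharide("Man", a, anomer="b", parent_positions=[4])
        c = doc.add_monosaccharide("Man", b, anomer="a", parent_positions=[3])
        d_ = doc.add_monosaccharide("Man", b, anomer="a", parent_positions=[6])
        assert doc.core.descendants(b) == {b, c, d_}
        doc.delete_residue(b)
        assert set(doc.core.residues) == {a}

    def test_delete_core_root_with_fragments_refused(self, lacnac_fuc):
        doc, root, gal, idx = lacnac_fuc
        with pytest.raises(DependencyError):
            doc.delete_residue(root)

    def test_delete_prunes_attachment_sites(self, lacnac_fuc):
        doc, root, gal, idx = lacnac_fuc
        doc.delete_residue(gal)
        assert doc.fragment(idx).attachment_sites == {root}

    def test_replace_preserves_topology(self):
        doc = GlycanDocument()
        a = doc.add_monosaccharide("Glc")
        b = doc.add_monosaccharide("Glc", a, anomer="b", parent_positions=[4])
        c = doc.add_monosaccharide("Glc", b, anomer="a", parent_positions=[3])
        shape_before = doc.core.signature()
        doc.replace_residue(b, "Man")
        assert doc.residue(b).stems == ("man",)
        ln = doc.core.parent_linkage(c)
        assert ln.parent_id == b and ln.parent_positions == (3,)
        # same topology: signatures equal once stems are ignored
        def strip(sig):
            chem, children = sig
            return (tuple(strip(s) for (_, _, s) in children),)
        assert strip(doc.core.signature()) == strip(shape_before)

    def test_replace_preserves_valid_substituents(self):
        doc = GlycanDocument()
        a = doc.add_monosaccharide("Glc")
        doc.add_substituent(a, "sulfate", 6)
        doc.replace_residue(a, "Man")
        assert [(s.name, s.position) for s in doc.residue(a).substituents] \
            == [("sulfate", 6)]


class TestFragments:
    def test_default_sites_are_all_core_residues(self, lacnac_fuc):
        doc, root, gal, idx = lacnac_fuc
        assert idx == 1
        assert doc.fragment(idx).attachment_sites == {root, gal}
        assert doc.fragment(idx).sites_complete(doc.core)

    def test_fragment_requires_core(self):
        doc = GlycanDocument()
        with pytest.raises(OrderingError):
            doc.add_fragment("Fuc")

    def test_indices_assigned_in_order(self, lacnac):
        doc, *_ = lacnac
        assert doc.add_fragment("Fuc") == 1
        assert doc.add_fragment("Xyl") == 2

    def test_restrict_sites(self, lacnac_fuc):
        doc, root, gal, idx = lacnac_fuc
        doc.set_attachment_sites(idx, [root])
        frag = doc.fragment(idx)
        assert frag.attachment_sites == {root}
        assert not frag.sites_complete(doc.core)

    def test_empty_or_foreign_sites_rejected(self, lacnac_fuc):
        doc, root, gal, idx = lacnac_fuc
        with pytest.raises(ValidationError):
            doc.set_attachment_sites(idx, [])
        with pytest.raises(ValidationError):
            doc.set_attachment_sites(idx, [999])


class TestEnumerate:
    def test_one_fragment_two_sites(self, lacnac_fuc):
        doc, *_ = lacnac_fuc
        concrete = enumerate_concrete(doc)
        assert len(concrete) == 2
        for c in concrete:
            assert not c.fragments
            assert len(c.core.residues) == 3
            c.validate()

    def test_two_fragments_unknown_positions_never_collide(self, lacnac):
        doc, *_ = lacnac
        doc.add_fragment("Fuc")
        doc.add_fragment("Xyl")
        assert len(enumerate_concrete(doc)) == 4

    def test_known_position_collisions_excluded(self, lacnac):
        doc, *_ = lacnac
        i1 = doc.add_fragment("Fuc", parent_positions=[3])
        i2 = doc.add_fragment("Xyl", parent_positions=[3])
        # same known position: the two fragments cannot share a site
        assert len(enumerate_concrete(doc)) == 2

    def test_no_fragments_yields_core_only(self, lacnac):
        doc, *_ = lacnac
        out = enumerate_concrete(doc)
        assert len(out) == 1
        assert documents_equivalent(out[0], doc)

    def test_truncation(self, lacnac_fuc):
        doc, *_ = lacnac_fuc
        with pytest.raises(TruncationError):
            enumerate_concrete(doc, max_results=1)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force(self, seed):
        from glycankit.fixtures import GeneratorConfig, random_document
        doc = random_document(GeneratorConfig(
            seed=seed, min_residues=2, max_residues=5,
            min_fragments=1, max_fragments=3,
        ))
        assert len(enumerate_concrete(doc)) == len(
            brute_force_assignments(doc))


class TestHistory:
    def test_add_then_undo(self):
        doc = GlycanDocument()
        doc.add_monosaccharide("Glc")
        assert doc.undo()
        assert doc.is_empty

    def test_undo_redo_roundtrip(self):
        doc = GlycanDocument()
        doc.add_monosaccharide("Glc")
        sig = doc.signature()
        doc.undo()
        assert doc.redo()
        assert doc.signature() == sig

    def test_clear_purges_history(self):
        doc = GlycanDocument()
        doc.add_monosaccharide("Glc")
        doc.clear()
        assert not doc.undo()
        assert doc.is_empty

    def test_undo_on_empty_history_signals_noop(self):
        assert GlycanDocument().undo() is False

    def test_snapshots_are_value_copies(self, lacnac):
        doc, root, gal = lacnac
        doc.set_linkage(gal, parent_positions=[3])
        doc.set_linkage(gal, parent_positions=[6])
        doc.undo()
        assert doc.core.parent_linkage(gal).parent_positions == (3,)
        doc.undo()
        assert doc.core.parent_linkage(gal).parent_positions == (4,)


def test_tree_invariant_after_random_edit_sequences():
    """Any sequence of editing operations leaves every tree connected and
    acyclic (validate() traverses and checks)."""
    import random

    rng = random.Random(7)
    doc = GlycanDocument()
    names = ["Glc", "Gal", "Man", "Fuc", "GlcNAc", "Neu5Ac"]
    for step in range(200):
        op = rng.random()
        ids = [rid for t in doc.all_trees() for rid in t.residues]
        try:
            if op < 0.45 or not ids:
                if doc.core:
                    doc.add_monosaccharide(
                        rng.choice(names), parent_id=rng.choice(ids),
                        anomer=rng.choice(["a", "b", "x"]),
                        parent_positions=[rng.randint(2, 6)])
                else:
                    doc.add_monosaccharide(rng.choice(names))
            elif op < 0.6:
                doc.delete_residue(rng.choice(ids))
            elif op < 0.7:
                doc.replace_residue(rng.choice(ids), rng.choice(names))
            elif op < 0.8 and doc.core:
                doc.add_fragment(rng.choice(names))
            elif op < 0.9:
                doc.undo()
            else:
                doc.redo()
        except Exception:
            pass  # refused edits must leave the document valid too
        doc.validate()
        for tree in doc.all_trees():
            tree.validate()
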