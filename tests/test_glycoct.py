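"""GlycoCT condensed reader/writer, including UND fragment blocks."""

import pytest
from hypothesis import given, settings, strategies as st

from glycankit import (
    EmptyDocumentError,
    GlycanDocument,
    GlycoCTParseError,
    UnsupportedFeatureError,
    documents_equivalent,
)
from glycankit.fixtures import GeneratorConfig, random_document
from glycankit.glycoct import parse_glycoct, write_glycoct
from glycankit.snfg import UNKNOWN

from conftest import (
    LACNAC_FUC_UND_GLYCOCT,
    LACNAC_GLYCOCT,
    build_lacnac,
    build_lacnac_with_fuc_fragment,
)


class TestParse:
    def test_minimal_single_residue(self):
        doc = parse_glycoct("RES\n1b:b-dglc-HEX-1:5\n")
        assert len(doc.core.residues) == 1
        res = doc.residue(doc.core.root_id)
        assert (res.stems, res.configs, res.anomer) == (("glc",), ("d",), "b")
        assert res.ring == (1, 5)

    def test_lacnac(self):
        doc = parse_glycoct(LACNAC_GLYCOCT)
        root = doc.residue(doc.core.root_id)
        assert root.anomer == "x"
        assert [(s.name, s.position) for s in root.substituents] \
            == [("n-acetyl", 2)]
        (ln,) = doc.core.linkages
        assert ln.parent_positions == (4,) and ln.child_position == 1
        child = doc.residue(ln.child_id)
        assert child.stems == ("gal",) and child.anomer == "b"

    def test_und_block_becomes_fragment(self):
        doc = parse_glycoct(LACNAC_FUC_UND_GLYCOCT)
        assert len(doc.fragments) == 1
        frag = doc.fragments[0]
        assert frag.attachment_sites == set(doc.core.residues)
        assert frag.linkage_info.parent_positions == (UNKNOWN,)
        fuc = frag.tree.residues[frag.tree.root_id]
        assert fuc.stems == ("gal",) and fuc.configs == ("l",)
        assert fuc.modifications == {(6, "deoxy")}

    def test_crlf_tolerated(self):
        doc = parse_glycoct(LACNAC_GLYCOCT.replace("\n", "\r\n"))
        assert len(doc.core.residues) == 2

    def test_rep_section_unsupported(self):
        text = LACNAC_GLYCOCT + "REP\nREP1:5o(4+1)5d=-1--1\n"
        with pytest.raises(UnsupportedFeatureError, match="REP"):
            parse_glycoct(text)

    def test_alt_section_unsupported(self):
        with pytest.raises(UnsupportedFeatureError, match="ALT"):
            parse_glycoct("RES\n1b:b-dglc-HEX-1:5\nALT\n")

    def test_dangling_id_reports_line(self):
        text = "RES\n1b:b-dglc-HEX-1:5\nLIN\n1:1o(4+1)9d\n"
        with pytest.raises(GlycoCTParseError) as exc:
            parse_glycoct(text)
        assert exc.value.line == 4

    def test_garbage_line_rejected(self):
        with pytest.raises(GlycoCTParseError):
            parse_glycoct("RES\n1b:b-dglc-HEX-1:5\nwhat is this\n")

    def test_neu5ac_stereocode(self):
        doc = parse_glycoct(
            "RES\n1b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d\n2s:n-acetyl\n"
            "LIN\n1:1d(5+1)2n\n")
        res = doc.residue(doc.core.root_id)
        assert res.stems == ("gro", "gal")
        assert res.modifications == {(1, "acid"), (2, "ketone"), (3, "deoxy")}
        assert res.ring == (2, 6)


class TestWrite:
    def test_lacnac_is_canonical(self):
        doc, *_ = build_lacnac()
        assert write_glycoct(doc) == LACNAC_GLYCOCT

    def test_fragment_doc_matches_reference_text(self):
        doc, *_ = build_lacnac_with_fuc_fragment()
        assert write_glycoct(doc) == LACNAC_FUC_UND_GLYCOCT

    def test_empty_document_rejected(self):
        with pytest.raises(EmptyDocumentError):
            write_glycoct(GlycanDocument())

    def test_default_sites_list_every_core_basetype(self):
        doc, *_ = build_lacnac_with_fuc_fragment()
        assert "ParentIDs:1|3" in write_glycoct(doc)

    def test_children_ordered_by_known_parent_position(self):
        doc = GlycanDocument()
        root = doc.add_monosaccharide("Man", anomer="b")
        doc.add_monosaccharide("Man", root, anomer="a", parent_positions=[6])
        doc.add_monosaccharide("Man", root, anomer="a", parent_positions=[3])
        doc.add_monosaccharide(
            "Man", root, anomer="a", parent_positions=[UNKNOWN])
        lines = write_glycoct(doc).splitlines()
        lin = [l for l in lines if "o(" in l]
        assert "(3+1)" in lin[0] and "(6+1)" in lin[1] and "(-1+1)" in lin[2]


class TestRoundTrip:
    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=100000))
    def test_parse_write_isomorphism_and_fixpoint(self, seed):
        doc = random_document(GeneratorConfig(seed=seed, max_residues=10))
        text = write_glycoct(doc)
        parsed = parse_glycoct(text)
        assert documents_equivalent(doc, parsed)
        assert write_glycoct(parsed) == text

    def test_und_block_count_equals_fragment_count(self):
        doc = random_document(GeneratorConfig(
            seed=11, min_fragments=2, max_fragments=2))
        text = write_glycoct(doc)
        assert text.count("UND", text.index("UND")) >= 2
        assert text.count("ParentIDs:") == 2
        assert text.count("SubtreeLinkageID") == 2
        assert documents_equivalent(doc, parse_glycoct(text))

    def test_determinism_identical_edit_sequences(self):
        a = write_glycoct(build_lacnac_with_fuc_fragment()[0])
        b = write_glycoct(build_lacnac_with_fuc_fragment()[0])
        assert a == b
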