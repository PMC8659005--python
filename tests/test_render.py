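"""Layout geometry and SVG rendering contracts."""

import xml.etree.ElementTree as ET

import pytest

from glycankit import GlycanDocument, layout, render_svg
from glycankit.fixtures import GeneratorConfig, random_document

from conftest import build_lacnac, build_lacnac_with_fuc_fragment


def svg_root(doc, **kw):
    return ET.fromstring(render_svg(doc, **kw))


def by_class(root, cls):
    return [el for el in root.iter() if el.get("class") == cls]


class TestLayout:
    def test_single_residue_at_origin_column(self):
        doc = GlycanDocument()
        doc.add_monosaccharide("Glc")
        (node,) = layout(doc)
        assert (node.col, node.row) == (0.0, 0.0)

    def test_linear_trisaccharide_collinear(self):
        doc = GlycanDocument()
        a = doc.add_monosaccharide("Glc")
        b = doc.add_monosaccharide("Gal", a, anomer="b", parent_positions=[4])
        doc.add_monosaccharide("Fuc", b, anomer="a", parent_positions=[2])
        nodes = layout(doc)
        assert sorted(n.col for n in nodes) == [0.0, 1.0, 2.0]
        assert len({n.row for n in nodes}) == 1

    def test_root_is_rightmost_parent_right_of_child(self):
        doc = random_document(GeneratorConfig(seed=3, max_fragments=0))
        nodes = {n.residue_id: n for n in layout(doc)}
        root = nodes[doc.core.root_id]
        assert root.x == max(n.x for n in nodes.values())
        for ln in doc.core.linkages:
            assert nodes[ln.parent_id].x > nodes[ln.child_id].x

    def test_higher_known_position_on_upper_row(self):
        doc = GlycanDocument()
        root = doc.add_monosaccharide("Man", anomer="b")
        lo = doc.add_monosaccharide("Man", root, anomer="a",
                                    parent_positions=[3])
        hi = doc.add_monosaccharide("Man", root, anomer="a",
                                    parent_positions=[6])
        nodes = {n.residue_id: n for n in layout(doc)}
        assert nodes[hi].y < nodes[lo].y

    def test_fragment_left_of_bracket_left_of_core(self):
        doc, root, gal, idx = build_lacnac_with_fuc_fragment()
        doc.set_attachment_sites(idx, [root])
        nodes = layout(doc)
        core_x = [n.x for n in nodes if n.part_index == 0]
        frag_x = [n.x for n in nodes if n.part_index == idx]
        svg = ET.fromstring(render_svg(doc))
        (bracket,) = by_class(svg, "bracket")
        bx = float(bracket.get("d").split()[1])
        assert max(frag_x) < bx < min(core_x)

    def test_no_two_nodes_share_a_pixel(self):
        doc = random_document(GeneratorConfig(seed=5, min_fragments=1))
        pts = [(n.x, n.y) for n in layout(doc)]
        assert len(pts) == len(set(pts))


class TestRenderSvg:
    def test_empty_document_is_valid_svg_with_no_shapes(self):
        root = svg_root(GlycanDocument())
        assert root.tag.endswith("svg")
        assert by_class(root, "snfg-symbol") == []

    @pytest.mark.parametrize("seed", range(10))
    def test_one_symbol_per_residue_edges_drawn(self, seed):
        doc = random_document(GeneratorConfig(seed=seed))
        root = svg_root(doc)
        n_res = sum(len(t.residues) for t in doc.all_trees())
        n_edges = sum(len(t.linkages) for t in doc.all_trees())
        assert len(by_class(root, "snfg-symbol")) == n_res
        assert len(by_class(root, "linkage")) >= n_edges

    def test_one_bracket_per_fragment_bearing_document(self):
        simple, *_ = build_lacnac()
        assert by_class(svg_root(simple), "bracket") == []
        doc, *_ = build_lacnac_with_fuc_fragment()
        doc.add_fragment("Xyl")
        assert len(by_class(svg_root(doc), "bracket")) == 1

    def test_annotations_iff_proper_subset_of_sites(self):
        # all sites selected: no *n anywhere
        doc, root, gal, idx = build_lacnac_with_fuc_fragment()
        texts = [t.text for t in by_class(svg_root(doc), "annotation")]
        assert texts == []
        # restricted: *1 on the selected core residue and the fragment root
        doc.set_attachment_sites(idx, [gal])
        texts = [t.text for t in by_class(svg_root(doc), "annotation")]
        assert texts.count("*1") == 2

    def test_unknown_linkage_rendered_with_question_marks(self):
        doc = GlycanDocument()
        a = doc.add_monosaccharide("Glc")
        doc.add_monosaccharide("Gal", a)  # anomer and position unknown
        labels = [t.text for t in by_class(svg_root(doc), "linkage-label")]
        assert "??" in labels

    def test_beta4_label(self):
        doc, *_ = build_lacnac()
        labels = [t.text for t in by_class(svg_root(doc), "linkage-label")]
        assert "β4" in labels

    def test_byte_deterministic(self):
        a = render_svg(build_lacnac_with_fuc_fragment()[0])
        b = render_svg(build_lacnac_with_fuc_fragment()[0])
        assert a == b
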