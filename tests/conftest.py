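import itertools

import pytest

from glycankit import GlycanDocument
from glycankit.snfg import UNKNOWN

LACNAC_GLYCOCT = """RES
1b:x-dglc-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
LIN
1:1d(2+1)2n
2:1o(4+1)3d
"""

LACNAC_FUC_UND_GLYCOCT = LACNAC_GLYCOCT + """UND
UND1:100.0:100.0
ParentIDs:1|3
SubtreeLinkageID1:o(-1+1)d
RES
4b:a-lgal-HEX-1:5|6:d
"""

# frozen from GlyTouCan during development
BETA_D_GLC_WURCS = "WURCS=2.0/1,1,0/[a2122h-1b_1-5]/1/"
LACNAC_WURCS = (
    "WURCS=2.0/2,2,1/[a2122h-1x_1-5_2*NCC/3=O][a2112h-1b_1-5]/1-2/a4-b1"
)


def build_lacnac() -> tuple[GlycanDocument, int, int]:
    """GlcNAc (reducing end, anomer unknown) + Gal beta1-4."""
    doc = GlycanDocument()
    root = doc.add_monosaccharide("GlcNAc")
    gal = doc.add_monosaccharide(
        "Gal", parent_id=root, anomer="beta", parent_positions=[4]
    )
    return doc, root, gal


def build_lacnac_with_fuc_fragment() -> tuple[GlycanDocument, int, int, int]:
    doc, root, gal = build_lacnac()
    idx = doc.add_fragment("Fuc", anomer="a")
    return doc, root, gal, idx


def brute_force_assignments(doc: GlycanDocument) -> list[tuple[int, ...]]:
    """Independent enumeration oracle: all fragment->site assignments such
    that no two fragments occupy the same (site, known position) pair."""
    frags = sorted(doc.fragments, key=lambda f: f.index)
    valid = []
    for combo in itertools.product(
            *[sorted(f.attachment_sites) for f in frags]):
        pairs = []
        for frag, site in zip(frags, combo):
            pairs.extend(
                (site, p) for p in frag.linkage_info.parent_positions
                if p != UNKNOWN
            )
        if len(pairs) == len(set(pairs)):
            valid.append(combo)
    return valid


@pytest.fixture
def lacnac():
    return build_lacnac()


@pytest.fixture
def lacnac_fuc():
    return build_lacnac_with_fuc_fragment()
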