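# glycankit

A headless glycan-structure toolkit: editable glycan documents with
underdetermined fragment parts, GlycoCT-condensed and WURCS 2.0
interconversion, SNFG normalization, deterministic 2D depiction to SVG,
and a WURCS-keyed GlyTouCan search client.

## Who this is for

Glycoinformatics developers and glycoscientists who need the *engine*
behind a glycan drawing/search tool without a browser: building glycans
programmatically, validating and canonicalizing database records,
expanding ambiguous structures, generating SNFG figures, and looking
structures up in the GlyTouCan repository.

## The model

A glycan is a rooted tree of monosaccharides: the **reducing end** is the
root (drawn rightmost under SNFG convention), and each glycosidic bond
links a child's anomeric carbon (α/β/unknown) to one of a set of candidate
carbon positions on its parent — a multi-position set encodes "one of
these" ambiguity, never multi-attachment. A **glycan fragment** is a fully
drawn *core* plus one or more *fragment parts*, each a subtree whose
attachment site on the core is only partially determined: a non-empty set
of candidate core residues plus a (possibly unknown) linkage description.
Fragment parts are drawn left of a bracket and numbered `*n` when their
candidate sites are a proper subset of the core.

Three text encodings of the same object:

* **GlycoCT condensed** — `RES` (basetypes `b:` and substituents `s:`),
  `LIN` (`1:1o(4+1)2d`), and one `UND` block per fragment part carrying
  `ParentIDs` (candidate attachment residues) and `SubtreeLinkageID`
  (the fragment linkage).
* **WURCS 2.0** — the canonical linear notation keying GlyTouCan:
  `WURCS=2.0/u,r,l/[codes]/sequence/linkages`, with `?` for unknown
  positions, `|` for alternatives and a closing `}` marking undetermined
  fragment attachment.
* **SNFG symbols** — the community shape/color nomenclature; normalization
  collapses decorated residues into named classes (Glc + 2-NAc → GlcNAc).

## Worked example

```python
from glycankit import GlycanDocument, enumerate_concrete
from glycankit.glycoct import write_glycoct
from glycankit.wurcs import write_wurcs

doc = GlycanDocument()
glcnac = doc.add_monosaccharide("GlcNAc")              # reducing end
doc.add_monosaccharide("Gal", parent_id=glcnac,
                       anomer="beta", parent_positions=[4])
doc.add_fragment("Fuc", anomer="a")                    # site unknown
print(write_glycoct(doc))
print(write_wurcs(doc))
print(len(enumerate_concrete(doc)), "concrete structures")
```

prints

```
RES
1b:x-dglc-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
LIN
1:1d(2+1)2n
2:1o(4+1)3d
UND
UND1:100.0:100.0
ParentIDs:1|3
SubtreeLinkageID1:o(-1+1)d
RES
4b:a-lgal-HEX-1:5|6:d

WURCS=2.0/3,3,2/[a2122h-1x_1-5_2*NCC/3=O][a2112h-1b_1-5][a1221m-1a_1-5]/1-2-3/a4-b1_a?|b?}-c1
2 concrete structures
```

That is N-acetyllactosamine (Gal β1–4 GlcNAc, reducing anomer unknown)
with an α-fucose fragment that may sit on either core residue: the UND
block lists both candidate parents (`ParentIDs:1|3`) with an unknown
position (`-1`), the WURCS linkage `a?|b?}-c1` says the same, and
expanding the ambiguity yields the two possible concrete trisaccharides.

The same operations are available from a shell:

```sh
glycankit template n-glycan | glycankit convert - --to wurcs
# WURCS=2.0/4,5,4/[a2122h-1x_1-5_2*NCC/3=O][a2122h-1b_1-5_2*NCC/3=O][a1122h-1b_1-5][a1122h-1a_1-5]/1-2-3-4-4/a4-b1_b4-c1_c3-d1_c6-e1
glycankit render - --out glycan.svg < structure.glycoct
glycankit search - < structure.glycoct      # queries GlyTouCan (network)
```

Commands: `convert`, `render`, `normalize`, `enumerate`, `template`,
`search`; all read a file path or `-` for stdin and exit non-zero on
failure (2 parse error, 3 unsupported feature, 4 network failure).

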