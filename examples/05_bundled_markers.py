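"""Inspect the bundled consensus marker gene set.

The package ships the consensus tumor marker genes (TMGs) and non-tumor
marker genes (NMGs) derived from five labeled cancer single-cell datasets
(renal cell carcinoma, head-and-neck squamous, melanoma, lung
adenocarcinoma, breast cancer). These 259 genes are the default feature
space for prediction against user-supplied references.
"""

from precancell import load_bundled_markers

markers = load_bundled_markers()
print(f"provenance: {markers.provenance}")
print(f"{len(markers.tmg)} tumor marker genes, first ten: {', '.join(markers.tmg[:10])}")
print(f"{len(markers.nmg)} non-tumor marker genes, first ten: {', '.join(markers.nmg[:10])}")
print("-> TMGs are up in malignant cells in every training dataset; NMGs mark")
print("   immune/stromal programs (note CD3D, PTPRC, HLA class I/II among them)")
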