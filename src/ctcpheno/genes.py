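"""Mapping from panel protein markers to representative gene symbols.

Used to project bulk differential-expression results onto the mass-cytometry
panel. Some antibody targets have no single-gene counterpart:
pan-cytokeratin recognises many keratins and is mapped to KRT19 as a
representative (flagged), HLA-ABC is mapped to HLA-A, and phospho-epitopes
are post-translational states with no transcript of their own, so they are
left unmapped by default.
"""

from __future__ import annotations

#: marker -> (gene symbol or None, representative-mapping flag)
MARKER_GENE_MAP: dict[str, tuple[str | None, bool]] = {
    "EpCAM": ("EPCAM", False),
    "Pan-cytokeratin": ("KRT19", True),
    "E-cadherin": ("CDH1", False),
    "EGFR": ("EGFR", False),
    "CD3": ("CD3E", True),
    "CD4": ("CD4", False),
    "CD8": ("CD8A", True),
    "CD25": ("IL2RA", False),
    "CD14": ("CD14", False),
    "CD86": ("CD86", False),
    "CD163": ("CD163", False),
    "CD19": ("CD19", False),
    "CD56": ("NCAM1", False),
    "CD66b": ("CEACAM8", False),
    "HLA-ABC": ("HLA-A", True),
    "HLA-DR": ("HLA-DRA", True),
    "CD45": ("PTPRC", False),
    "CD31": ("PECAM1", False),
    "Vimentin": ("VIM", False),
    "Snail1": ("SNAI1", False),
    "Twist": ("TWIST1", False),
    "CD133": ("PROM1", False),
    "CD24": ("CD24", False),
    "CD44": ("CD44", False),
    "Ki67": ("MKI67", False),
    "CD47": ("CD47", False),
    "PD-1": ("PDCD1", False),
    "PD-L1": ("CD274", False),
    "PD-L2": ("PDCD1LG2", False),
    "CTLA4": ("CTLA4", False),
    "CD39": ("ENTPD1", False),
    "CD73": ("NT5E", False),
    # phospho-epitopes: no transcript counterpart, unmapped by default
    "pSTAT1": (None, False),
    "pSTAT3": (None, False),
    "pSTAT5": (None, False),
    "pPARP": (None, False),
    "pAKT": (None, False),
    "pERK": (None, False),
    "pCREB": (None, False),
    "p38": (None, False),
}


def mapped_markers() -> dict[str, str]:
    """Return {marker: gene} for markers with a gene counterpart."""
    return {m: g for m, (g, _) in MARKER_GENE_MAP.items() if g is not None}


def gene_to_marker() -> dict[str, str]:
    return {g: m for m, (g, _) in MARKER_GENE_MAP.items() if g is not None}
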