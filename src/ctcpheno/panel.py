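"""Antibody panel definition for CTC mass cytometry.

The default panel covers 40 analytical protein targets chosen to (a) identify
CTCs and immune cells by lineage and (b) phenotype them: epithelial and
immune lineage, epithelial-mesenchymal transition (EMT), stemness and
proliferation, immune evasion/checkpoint molecules, and phosphorylated
signalling proteins.  Counting the Cd-106 carrier-barcode reagent the panel
comprises 41 antibody targets.  Two non-antibody channels are carried
alongside: the Cd-106 barcode that marks autologous PBMC carrier cells and
the osmium label on the stimulated positive-control PBMCs.  Per-event
acquisition quality channels (Event_length and the Gaussian discrimination
parameters Center, Offset, Width, Residual) are part of every event table
but are never ArcSinh-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class MarkerCategory(str, Enum):
    EPITHELIAL_LINEAGE = "epithelial_lineage"
    IMMUNE_LINEAGE = "immune_lineage"
    EMT = "emt"
    STEMNESS_PROLIFERATION = "stemness_proliferation"
    IMMUNE_EVASION = "immune_evasion"
    PHOSPHO = "phospho"
    BARCODE = "barcode"
    CONTROL_LABEL = "control_label"
    ACQUISITION = "acquisition"


#: categories of channels that carry antibody signal to be analysed
ANALYTICAL_CATEGORIES = frozenset(
    {
        MarkerCategory.EPITHELIAL_LINEAGE,
        MarkerCategory.IMMUNE_LINEAGE,
        MarkerCategory.EMT,
        MarkerCategory.STEMNESS_PROLIFERATION,
        MarkerCategory.IMMUNE_EVASION,
        MarkerCategory.PHOSPHO,
    }
)

#: acquisition channels used by Gaussian-parameter event clean-up
ACQUISITION_CHANNELS = ("Event_length", "Center", "Offset", "Width", "Residual")

#: CD45 plus the immune lineage markers used for CTC exclusion gating
CTC_EXCLUSION_MARKERS = ("CD45", "CD3", "CD4", "CD8", "CD19", "CD14", "CD56", "CD66b")

#: the epithelial inclusion marker of the CTC rule
CTC_INCLUSION_MARKER = "Pan-cytokeratin"


@dataclass(frozen=True)
class PanelEntry:
    marker: str
    channel: str
    category: MarkerCategory


@dataclass
class PanelDefinition:
    """Marker <-> channel map with category tags."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.marker for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("marker names must be unique")
        if sum(e.category is MarkerCategory.BARCODE for e in self.entries) > 1:
            raise ValueError("at most one barcode channel")
        if sum(e.category is MarkerCategory.CONTROL_LABEL for e in self.entries) > 1:
            raise ValueError("at most one control-label channel")

    # -- lookups ----------------------------------------------------------
    def markers(self, category: MarkerCategory | None = None) -> list[str]:
        if category is None:
            return [e.marker for e in self.entries]
        return [e.marker for e in self.entries if e.category is category]

    @property
    def analytical_markers(self) -> list[str]:
        return [e.marker for e in self.entries if e.category in ANALYTICAL_CATEGORIES]

    @property
    def barcode_marker(self) -> str:
        return self._single(MarkerCategory.BARCODE)

    @property
    def control_marker(self) -> str:
        return self._single(MarkerCategory.CONTROL_LABEL)

    def _single(self, cat: MarkerCategory) -> str:
        found = self.markers(cat)
        if len(found) != 1:
            raise ValueError(f"panel must contain exactly one {cat.value} channel")
        return found[0]

    def category_of(self, marker: str) -> MarkerCategory:
        for e in self.entries:
            if e.marker == marker:
                return e.category
        raise KeyError(marker)

    def channel_of(self, marker: str) -> str:
        for e in self.entries:
            if e.marker == marker:
                return e.channel
        raise KeyError(marker)

    def require(self, markers: list[str] | tuple[str, ...]) -> None:
        known = set(self.markers())
        missing = [m for m in markers if m not in known]
        if missing:
            raise KeyError(f"panel is missing markers: {missing}")


# marker, metal channel, category — order follows the panel's sub-groups
_DEFAULT_PANEL: list[tuple[str, str, MarkerCategory]] = [
    # epithelial lineage
    ("EpCAM", "Y89Di", MarkerCategory.EPITHELIAL_LINEAGE),
    ("Pan-cytokeratin", "In113Di", MarkerCategory.EPITHELIAL_LINEAGE),
    ("E-cadherin", "In115Di", MarkerCategory.EPITHELIAL_LINEAGE),
    ("EGFR", "La139Di", MarkerCategory.EPITHELIAL_LINEAGE),
    # immune / endothelial lineage
    ("CD3", "Pr141Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD4", "Nd142Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD8", "Nd143Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD25", "Nd144Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD14", "Nd145Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD86", "Nd146Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD163", "Sm147Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD19", "Nd148Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD56", "Sm149Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD66b", "Nd150Di", MarkerCategory.IMMUNE_LINEAGE),
    ("HLA-ABC", "Eu151Di", MarkerCategory.IMMUNE_LINEAGE),
    ("HLA-DR", "Sm152Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD45", "Eu153Di", MarkerCategory.IMMUNE_LINEAGE),
    ("CD31", "Sm154Di", MarkerCategory.IMMUNE_LINEAGE),
    # EMT
    ("Vimentin", "Gd155Di", MarkerCategory.EMT),
    ("Snail1", "Gd156Di", MarkerCategory.EMT),
    ("Twist", "Gd158Di", MarkerCategory.EMT),
    # stemness / proliferation
    ("CD133", "Tb159Di", MarkerCategory.STEMNESS_PROLIFERATION),
    ("CD24", "Gd160Di", MarkerCategory.STEMNESS_PROLIFERATION),
    ("CD44", "Dy161Di", MarkerCategory.STEMNESS_PROLIFERATION),
    ("Ki67", "Dy162Di", MarkerCategory.STEMNESS_PROLIFERATION),
    # immune evasion / checkpoint
    ("CD47", "Dy163Di", MarkerCategory.IMMUNE_EVASION),
    ("PD-1", "Dy164Di", MarkerCategory.IMMUNE_EVASION),
    ("PD-L1", "Ho165Di", MarkerCategory.IMMUNE_EVASION),
    ("PD-L2", "Er166Di", MarkerCategory.IMMUNE_EVASION),
    ("CTLA4", "Er167Di", MarkerCategory.IMMUNE_EVASION),
    ("CD39", "Er168Di", MarkerCategory.IMMUNE_EVASION),
    ("CD73", "Tm169Di", MarkerCategory.IMMUNE_EVASION),
    # phosphorylated signalling proteins
    ("pSTAT1", "Er170Di", MarkerCategory.PHOSPHO),
    ("pSTAT3", "Yb171Di", MarkerCategory.PHOSPHO),
    ("pSTAT5", "Yb172Di", MarkerCategory.PHOSPHO),
    ("pPARP", "Yb173Di", MarkerCategory.PHOSPHO),
    ("pAKT", "Yb174Di", MarkerCategory.PHOSPHO),
    ("pERK", "Lu175Di", MarkerCategory.PHOSPHO),
    ("pCREB", "Yb176Di", MarkerCategory.PHOSPHO),
    ("p38", "Bi209Di", MarkerCategory.PHOSPHO),
    # carrier barcode (B2M + ATPase/CD298 mixture on Cd-106) and osmium control
    ("B2M-ATPase-barcode", "Cd106Di", MarkerCategory.BARCODE),
    ("Osmium", "Os189Di", MarkerCategory.CONTROL_LABEL),
]


def make_default_panel() -> PanelDefinition:
    """Build the default CTC/PBMC antibody panel.

    Returns the 40 analytical markers with their category tags, the Cd-106
    carrier barcode, the osmium control label, and the acquisition channels.
    """
    entries = [PanelEntry(m, c, cat) for m, c, cat in _DEFAULT_PANEL]
    entries += [
        PanelEntry(name, name, MarkerCategory.ACQUISITION) for name in ACQUISITION_CHANNELS
    ]
    return PanelDefinition(entries)
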