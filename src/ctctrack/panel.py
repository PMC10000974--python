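"""The 22-gene qRT-PCR panel used to characterize enriched CTCs.

The panel covers epithelial, EMT and cancer-stem-cell lineage markers plus
signaling genes commonly perturbed in breast cancer, together with a white
blood cell control (PTPRC/CD45), a nucleated red blood cell control (GYPA)
and three housekeeping genes. A fixed 4+4 subset of the panel defines the
epithelial-mesenchymal (EM) score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeneRecord",
    "GenePanel",
    "default_panel",
    "CT_MAX",
]

#: Assay detection limit in PCR cycles; Ct == CT_MAX encodes "undetected".
CT_MAX = 40.0

GENE_CLASSES = (
    "epithelial",
    "emt",
    "csc",
    "signaling",
    "wbc_control",
    "rbc_control",
    "housekeeping",
)

#: Classes whose genes count as "CTC-related" for scores and positive-gene counts.
CTC_CLASSES = frozenset({"epithelial", "emt", "csc", "signaling"})


@dataclass(frozen=True)
class GeneRecord:
    """One panel member: symbol, lineage class and EM-score membership."""

    symbol: str
    gene_class: str
    em_epi: bool = False
    em_mes: bool = False

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.em_epi and self.em_mes:
            raise ValueError(f"{self.symbol}: a gene cannot be both EM-epi and EM-mes")


@dataclass(frozen=True)
class GenePanel:
    """An ordered collection of :class:`GeneRecord` with convenience views."""

    genes: tuple[GeneRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            raise ValueError("duplicate gene symbols in panel")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes)

    def by_class(self, *classes: str) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes if g.gene_class in classes)

    @property
    def ctc_genes(self) -> tuple[str, ...]:
        """The 17 tumor-facing genes; controls and housekeeping excluded."""
        return self.by_class(*CTC_CLASSES)

    @property
    def control_genes(self) -> tuple[str, ...]:
        return self.by_class("wbc_control", "rbc_control", "housekeeping")

    @property
    def housekeeping_genes(self) -> tuple[str, ...]:
        return self.by_class("housekeeping")

    @property
    def em_epi_genes(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes if g.em_epi)

    @property
    def em_mes_genes(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes if g.em_mes)

    @property
    def em_genes(self) -> tuple[str, ...]:
        return self.em_epi_genes + self.em_mes_genes

    def record(self, symbol: str) -> GeneRecord:
        sym = symbol.upper()
        for g in self.genes:
            if g.symbol == sym:
                return g
        raise KeyError(f"gene {symbol!r} not in panel")


# EM-score membership: 4 epithelial vs 4 mesenchymal/stem genes. MUC1 and
# EGFR are epithelial markers but are not part of the EM-score subset;
# genes of ambiguous polarity (e.g. FGFR1) are likewise excluded.
_EM_EPI = {"CDH1", "EPCAM", "KRT7", "KRT18"}
_EM_MES = {"ALDH1A1", "CDH2", "FN1", "ZEB2"}

_DEFAULT_MEMBERS = [
    ("CDH1", "epithelial"),
    ("EGFR", "epithelial"),
    ("EPCAM", "epithelial"),
    ("KRT7", "epithelial"),
    ("KRT18", "epithelial"),
    ("MUC1", "epithelial"),
    ("AXL", "emt"),
    ("CDH2", "emt"),
    ("FN1", "emt"),
    ("SNAI2", "emt"),
    ("ZEB2", "emt"),
    ("ALDH1A1", "csc"),
    ("BCL2", "signaling"),
    ("CD274", "signaling"),
    ("ERBB2", "signaling"),
    ("FGFR1", "signaling"),
    ("MET", "signaling"),
    ("PTPRC", "wbc_control"),
    ("GYPA", "rbc_control"),
    ("B2M", "housekeeping"),
    ("GAPDH", "housekeeping"),
    ("HPRT1", "housekeeping"),
]


def default_panel() -> GenePanel:
    """Build the default 22-gene panel (17 CTC-related + 5 controls)."""
    return GenePanel(
        tuple(
            GeneRecord(sym, cls, em_epi=sym in _EM_EPI, em_mes=sym in _EM_MES)
            for sym, cls in _DEFAULT_MEMBERS
        )
    )
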