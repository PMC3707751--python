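"""Gene panels for the breast-cancer prognostic signature analysis.

The default panel holds the 32 candidate genes assayed by qRT-PCR in the
study cohort (literature-derived candidates plus PGR). Two signature
subsets are the final prognostic models: a five-gene set for overall
survival (disease mortality) and a six-gene set for disease-free survival
(recurrence) that additionally carries NAT1.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: 32 candidate genes, ordered by their univariate mortality p-value.
DEFAULT_GENES: tuple[str, ...] = (
    "RABEP1", "PGR", "NAT1", "PTP4A2", "SLC39A6", "ESR1", "EVL", "TBC1D9",
    "FUT8", "SCUBE2", "GATA3", "MELK", "TCEAL1", "XBP1", "PLK1", "IL6ST",
    "DSC2", "CX3CL1", "ATAD2", "BUB1", "CENPA", "CKS2", "GABRP", "GMPS",
    "LRBA", "MAPRE2", "MCM6", "PFKP", "ST8SIA1", "TPBG", "TRIM29", "YBX1",
)

#: Final signature for overall survival (breast-cancer mortality).
OS_SIGNATURE: tuple[str, ...] = ("PGR", "GABRP", "TBC1D9", "SLC39A6", "LRBA")

#: Final signature for disease-free survival (recurrence): OS set + NAT1.
DFS_SIGNATURE: tuple[str, ...] = OS_SIGNATURE + ("NAT1",)

#: Positively intercorrelated, estrogen-receptor-associated gene block.
ER_BLOCK: tuple[str, ...] = ("PGR", "ESR1", "NAT1", "SLC39A6", "TBC1D9", "LRBA")

#: Gene negatively correlated with the ER block (up in ER- tumors).
ANTI_GENE: str = "GABRP"


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene list with named signature subsets.

    Parameters
    ----------
    genes : ordered gene symbols (unique).
    os_signature, dfs_signature : subsets of ``genes`` used as the fixed
        mortality / recurrence signatures in downstream model comparison.
    """

    genes: tuple[str, ...] = DEFAULT_GENES
    os_signature: tuple[str, ...] = OS_SIGNATURE
    dfs_signature: tuple[str, ...] = DFS_SIGNATURE

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ValueError(f"duplicate genes in panel: {dupes}")
        for name, subset in (("os_signature", self.os_signature),
                             ("dfs_signature", self.dfs_signature)):
            missing = set(subset) - set(self.genes)
            if missing:
                raise ValueError(f"{name} genes not in panel: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def signature(self, outcome: str) -> tuple[str, ...]:
        """Signature subset for outcome ``"os"`` or ``"dfs"``."""
        if outcome == "os":
            return self.os_signature
        if outcome == "dfs":
            return self.dfs_signature
        raise ValueError(f"unknown outcome {outcome!r}; expected 'os' or 'dfs'")
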