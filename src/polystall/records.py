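"""Core record types shared across the package.

Coordinate convention, fixed package-wide: 1-based, inclusive, CDS-relative.
Codon *k* spans nucleotides ``3k-2 .. 3k``. Protein-level hits use amino-acid
coordinates, poly(A) hits nucleotide coordinates, and inhibitory-codon-pair
hits codon indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional

import numpy as np

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Architecture labels: (a) dense K/R window, (b) consecutive K/R run,
#: (c) poly(A) tract, (d) high net-charge 30-aa window, plus the ICP control.
CATEGORIES = ("a", "b", "c", "d")

HIT_KINDS = frozenset(
    {"net_charge_window", "kr_window_stretch", "consecutive_kr", "polyA", "icp"}
)


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (trailing stop marker stripped)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().rstrip("*")
        if not seq:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        for i, aa in enumerate(seq, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"{self.gene_id}: invalid residue {aa!r} at position {i}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """A coding nucleotide sequence over {A,C,G,T}."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.gene_id}: empty CDS")
        for i, nt in enumerate(seq, start=1):
            if nt not in NUCLEOTIDES:
                raise ValueError(
                    f"{self.gene_id}: invalid nucleotide {nt!r} at position {i}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def in_frame(self) -> bool:
        return len(self.sequence) % 3 == 0

    def codons(self) -> List[str]:
        """In-frame codons; a trailing partial codon is dropped."""
        seq = self.sequence
        return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


@dataclass(frozen=True)
class ArchitectureHit:
    """One detected feature on one gene.

    ``value`` is kind-specific: window net charge, K/R count, run length,
    merged-region length, or 1 per ICP occurrence.
    """

    gene_id: str
    kind: str
    start: int
    end: int
    value: int

    def __post_init__(self) -> None:
        if self.kind not in HIT_KINDS:
            raise ValueError(f"unknown hit kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: bad hit coordinates {self.start}..{self.end}"
            )


@dataclass
class ArchitectureSummary:
    """Gene-level classification over the four polybasic architectures."""

    flags: "object"  # pandas.DataFrame: gene_id index, boolean columns a..d
    venn: Dict[FrozenSet[str], int]
    hits: List[ArchitectureHit]

    @property
    def union_count(self) -> int:
        return int(self.flags[list(CATEGORIES)].any(axis=1).sum())

    @property
    def multi_category_count(self) -> int:
        return int((self.flags[list(CATEGORIES)].sum(axis=1) > 1).sum())


@dataclass(frozen=True)
class FootprintRead:
    """An aligned ribosome footprint reduced to (gene, 5' position, length)."""

    gene_id: str
    five_prime: int
    length: int

    def __post_init__(self) -> None:
        if self.five_prime < 1:
            raise ValueError(f"{self.gene_id}: five_prime must be >= 1")
        if self.length < 1:
            raise ValueError(f"{self.gene_id}: non-positive read length")


@dataclass
class Profile:
    """Per-nucleotide (or per-codon) footprint count vector for one gene."""

    gene_id: str
    counts: np.ndarray
    resolution: str = "nt"  # "nt" or "codon"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError(f"{self.gene_id}: negative counts")
        if self.resolution not in ("nt", "codon"):
            raise ValueError(f"bad resolution {self.resolution!r}")


@dataclass
class MetageneResult:
    """Mean normalized coverage aligned on feature anchors, per group.

    ``adjusted_p`` maps each non-control group to per-offset Holm-Sidak
    adjusted p-values from Welch t-tests against the control group.
    """

    offsets: np.ndarray
    group_means: Dict[str, np.ndarray]
    adjusted_p: Dict[str, np.ndarray] = field(default_factory=dict)
    n_genes: Dict[str, int] = field(default_factory=dict)
    control: Optional[str] = None


@dataclass(frozen=True)
class AnchorRecord:
    """Start of a stretch of interest, CDS-relative, 1-based nt."""

    gene_id: str
    anchor: int
    kind: str = ""

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise ValueError(f"{self.gene_id}: anchor must be >= 1")
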