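"""Detection of polybasic architectures and inhibitory codon pairs.

Four architectures of polybasic sequence are scanned for, mirroring the
arrangements used in ribosome-stalling reporters:

(a) eight or more lysines/arginines (K/R) within a 10-amino-acid window;
(b) six or more consecutive K/R residues;
(c) ten or more consecutive adenines in the CDS (poly(A) tract);
(d) net charge >= +12 within a 30-amino-acid window (the approximate
    stretch of nascent peptide enclosed by the ribosome exit tunnel).

Net charge counts K and R as +1, D and E as -1, every other residue 0;
terminal amino/carboxyl charges are disregarded. In addition, in-frame
inhibitory codon pairs (ICPs, e.g. CGA-CGA) are located as an endogenous
positive control for stalling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import (
    ArchitectureHit,
    ArchitectureSummary,
    CATEGORIES,
    CdsRecord,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

#: The two inhibitory codon pairs named in the main text; the full published
#: list is supplied by the user as configuration.
DEFAULT_ICP_PAIRS = ("CGACGA", "CGACCG")


@dataclass(frozen=True)
class Thresholds:
    """Category thresholds; defaults follow the architecture definitions."""

    kr_window_count: int = 8
    kr_window_size: int = 10
    consecutive_kr: int = 6
    polya_len: int = 10
    charge_threshold: int = 12
    charge_window: int = 30


def _charge_vector(protein: ProteinRecord) -> np.ndarray:
    seq = protein.sequence
    charges = np.zeros(len(seq), dtype=np.int64)
    for i, aa in enumerate(seq):
        if aa in POSITIVE:
            charges[i] = 1
        elif aa in NEGATIVE:
            charges[i] = -1
    return charges


def _window_sums(values: np.ndarray, window: int) -> np.ndarray:
    cumsum = np.concatenate(([0], np.cumsum(values)))
    return cumsum[window:] - cumsum[:-window]


def net_charge_profile(
    protein: ProteinRecord, window: int = 30
) -> List[Tuple[int, int]]:
    """Net charge in every consecutive ``window``-residue frame.

    Returns one ``(start, charge)`` pair per window start 1..L-window+1.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(protein) < window:
        raise ValueError(
            f"{protein.gene_id}: protein length {len(protein)} < window {window}"
        )
    sums = _window_sums(_charge_vector(protein), window)
    return [(i + 1, int(s)) for i, s in enumerate(sums)]


def max_net_charge(protein: ProteinRecord, window: int = 30) -> Tuple[int, int]:
    """Maximum window net charge and its (earliest) 1-based start."""
    profile = net_charge_profile(protein, window)
    start, charge = max(profile, key=lambda sc: (sc[1], -sc[0]))
    return charge, start


def _kr_runs(sequence: str) -> Iterable[Tuple[int, int]]:
    """Maximal runs of K/R as (start, end), 1-based inclusive."""
    start = None
    for i, aa in enumerate(sequence):
        if aa in POSITIVE:
            if start is None:
                start = i
        elif start is not None:
            yield start + 1, i
            start = None
    if start is not None:
        yield start + 1, len(sequence)


def find_consecutive_kr(
    protein: ProteinRecord, min_len: int = 6
) -> List[ArchitectureHit]:
    """Maximal runs of consecutive K/R with length >= ``min_len``."""
    hits = []
    for start, end in _kr_runs(protein.sequence):
        length = end - start + 1
        if length >= min_len:
            hits.append(
                ArchitectureHit(protein.gene_id, "consecutive_kr", start, end, length)
            )
    return hits


def find_kr_window_stretch(
    protein: ProteinRecord,
    min_count: int = 8,
    window: int = 10,
    merged: bool = False,
) -> List[ArchitectureHit]:
    """Windows of ``window`` residues holding >= ``min_count`` K/R.

    With ``merged=False`` every qualifying window start is reported
    (value = K/R count in the window). With ``merged=True`` overlapping or
    touching qualifying windows are unioned into maximal regions
    (value = region length), the representation under which the longest
    yeast polybasic regions measure 42 and 44 residues.
    """
    if len(protein) < window:
        return []
    is_kr = np.array([aa in POSITIVE for aa in protein.sequence], dtype=np.int64)
    counts = _window_sums(is_kr, window)
    raw = [
        ArchitectureHit(
            protein.gene_id, "kr_window_stretch", i + 1, i + window, int(c)
        )
        for i, c in enumerate(counts)
        if c >= min_count
    ]
    if not merged:
        return raw
    return merge_window_hits(raw)


def merge_window_hits(hits: Sequence[ArchitectureHit]) -> List[ArchitectureHit]:
    """Union overlapping/adjacent window hits into maximal regions."""
    merged: List[ArchitectureHit] = []
    for hit in sorted(hits, key=lambda h: (h.gene_id, h.start)):
        if (
            merged
            and merged[-1].gene_id == hit.gene_id
            and hit.start <= merged[-1].end + 1
        ):
            prev = merged[-1]
            end = max(prev.end, hit.end)
            merged[-1] = ArchitectureHit(
                prev.gene_id, prev.kind, prev.start, end, end - prev.start + 1
            )
        else:
            merged.append(
                ArchitectureHit(
                    hit.gene_id, hit.kind, hit.start, hit.end,
                    hit.end - hit.start + 1,
                )
            )
    return merged


def find_polyA(cds: CdsRecord, min_len: int = 10) -> List[ArchitectureHit]:
    """Maximal adenine runs of length >= ``min_len``; nt coordinates."""
    hits = []
    seq = cds.sequence
    i = 0
    while i < len(seq):
        if seq[i] == "A":
            j = i
            while j < len(seq) and seq[j] == "A":
                j += 1
            if j - i >= min_len:
                hits.append(
                    ArchitectureHit(cds.gene_id, "polyA", i + 1, j, j - i)
                )
            i = j
        else:
            i += 1
    return hits


def find_icp(
    cds: CdsRecord, icp_pairs: Sequence[str] = DEFAULT_ICP_PAIRS
) -> List[ArchitectureHit]:
    """In-frame adjacent codon pairs matching the inhibitory-pair list.

    Matching is strictly frame 0 of the annotated CDS: a pair at codons
    (k, k+1), never an arbitrary hexamer. Coordinates are codon indices.
    """
    pairs = {p.upper() for p in icp_pairs}
    for p in pairs:
        if len(p) != 6 or any(nt not in "ACGT" for nt in p):
            raise ValueError(f"ICP entries must be 6-nt codon pairs, got {p!r}")
    if not cds.in_frame:
        logger.warning(
            "%s: CDS length %d not divisible by 3; truncating to last full codon",
            cds.gene_id, len(cds),
        )
    codons = cds.codons()
    hits = []
    for k in range(len(codons) - 1):
        if codons[k] + codons[k + 1] in pairs:
            hits.append(ArchitectureHit(cds.gene_id, "icp", k + 1, k + 2, 1))
    return hits


def classify_proteome(
    proteins: Sequence[ProteinRecord],
    cdss: Sequence[CdsRecord],
    thresholds: Thresholds = Thresholds(),
    icp_pairs: Optional[Sequence[str]] = None,
    exclude: Optional[Iterable[str]] = None,
) -> ArchitectureSummary:
    """Per-gene flags for architectures (a)-(d), Venn counts, and all hits.

    Genes present in only one of the protein/CDS sets are excluded from the
    categories needing the missing sequence (logged). ``exclude`` is the
    dubious-ORF list supplied as configuration. ICP hits are collected when
    ``icp_pairs`` is given and reported as a separate ``icp`` flag column,
    outside the four-way Venn.
    """
    exclude_set = set(exclude) if exclude else set()
    prot_by_id = {p.gene_id: p for p in proteins if p.gene_id not in exclude_set}
    cds_by_id = {c.gene_id: c for c in cdss if c.gene_id not in exclude_set}
    if len(prot_by_id) != len([p for p in proteins if p.gene_id not in exclude_set]):
        raise ValueError("duplicate gene_id in protein set")
    only_prot = set(prot_by_id) - set(cds_by_id)
    only_cds = set(cds_by_id) - set(prot_by_id)
    for gid in sorted(only_prot):
        logger.warning("%s: no CDS record; skipping nucleotide categories", gid)
    for gid in sorted(only_cds):
        logger.warning("%s: no protein record; skipping protein categories", gid)

    gene_ids = sorted(set(prot_by_id) | set(cds_by_id))
    columns = list(CATEGORIES) + (["icp"] if icp_pairs is not None else [])
    flags = pd.DataFrame(False, index=pd.Index(gene_ids, name="gene_id"),
                         columns=columns)
    all_hits: List[ArchitectureHit] = []
    t = thresholds
    for gid in gene_ids:
        protein = prot_by_id.get(gid)
        cds = cds_by_id.get(gid)
        if protein is not None:
            wins = find_kr_window_stretch(
                protein, t.kr_window_count, t.kr_window_size, merged=True
            )
            runs = find_consecutive_kr(protein, t.consecutive_kr)
            flags.loc[gid, "a"] = bool(wins)
            flags.loc[gid, "b"] = bool(runs)
            all_hits.extend(wins)
            all_hits.extend(runs)
            if len(protein) >= t.charge_window:
                charge, start = max_net_charge(protein, t.charge_window)
                if charge >= t.charge_threshold:
                    flags.loc[gid, "d"] = True
                    all_hits.append(
                        ArchitectureHit(
                            gid, "net_charge_window", start,
                            start + t.charge_window - 1, charge,
                        )
                    )
            else:
                logger.warning(
                    "%s: protein shorter than %d aa; excluded from net-charge "
                    "category", gid, t.charge_window,
                )
        if cds is not None:
            pa = find_polyA(cds, t.polya_len)
            flags.loc[gid, "c"] = bool(pa)
            all_hits.extend(pa)
            if icp_pairs is not None:
                icps = find_icp(cds, icp_pairs)
                flags.loc[gid, "icp"] = bool(icps)
                all_hits.extend(icps)

    venn = venn_counts(flags)
    return ArchitectureSummary(flags=flags, venn=venn, hits=all_hits)


def venn_counts(flags: pd.DataFrame) -> Dict[FrozenSet[str], int]:
    """Counts of the 15 disjoint Venn regions over categories a-d."""
    venn: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(CATEGORIES) + 1):
        for combo in combinations(CATEGORIES, r):
            region = frozenset(combo)
            in_region = np.ones(len(flags), dtype=bool)
            for cat in CATEGORIES:
                col = flags[cat].to_numpy(dtype=bool)
                in_region &= col if cat in region else ~col
            venn[region] = int(in_region.sum())
    return venn


def relative_positions(
    hits: Sequence[ArchitectureHit], gene_lengths: Dict[str, int]
) -> Dict[str, List[float]]:
    """Hit start / gene length, in (0, 1], grouped per hit kind.

    ``gene_lengths`` must be in the coordinate unit of each hit's kind
    (aa for protein kinds, nt for polyA, codons for icp).
    """
    out: Dict[str, List[float]] = {}
    for hit in hits:
        length = gene_lengths[hit.gene_id]
        if length <= 0:
            raise ValueError(f"{hit.gene_id}: non-positive gene length")
        if hit.start > length:
            raise ValueError(
                f"{hit.gene_id}: hit start {hit.start} beyond gene length {length}"
            )
        out.setdefault(hit.kind, []).append(hit.start / length)
    return out
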