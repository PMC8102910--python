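"""Disome (collided-ribosome) footprint processing.

Disome fragments protect ~60 nt, spanning two stacked ribosomes. Two
published processing dialects are supported:

* ``broad``  — accept any read of 50-80 nt, no trimming;
* ``narrow`` — trim 2 nt from the 5' end and 5 nt from the 3' end of each
  read (the low-quality ends), then accept 57-63 nt.

Trimming precedes length filtering; the accepted ranges are quoted
post-trim. The A site of the leading ribosome (the one at the 3' portion
of the fragment) is the codon containing the 46th nucleotide of the
processed read. Collision geometry is summarized as the offset, in codons,
of the disome metagene maximum relative to a feature anchor: polybasic
stretches produce a broad peak 9-10 codons downstream, inhibitory codon
pairs a sharp peak immediately after the pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .records import FootprintRead

logger = logging.getLogger(__name__)

#: nt offset (1-based within the read) of the leading ribosome's A site.
LEADING_A_SITE_OFFSET = 46


@dataclass(frozen=True)
class DisomeDialect:
    name: str
    trim5: int
    trim3: int
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trims must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")


BROAD = DisomeDialect("broad", trim5=0, trim3=0, min_len=50, max_len=80)
NARROW = DisomeDialect("narrow", trim5=2, trim3=5, min_len=57, max_len=63)
DIALECTS = {d.name: d for d in (BROAD, NARROW)}


def preprocess_disome(
    reads: Sequence[FootprintRead], dialect: DisomeDialect
) -> List[FootprintRead]:
    """Trim read ends per dialect, then keep reads in the accepted range.

    The order matters: lengths are reduced by the trims first and the
    [min_len, max_len] filter applies to the trimmed length. Reads shorter
    than the trims are dropped (logged).
    """
    kept: List[FootprintRead] = []
    dropped = 0
    for read in reads:
        if read.length <= dialect.trim5 + dialect.trim3:
            dropped += 1
            continue
        length = read.length - dialect.trim5 - dialect.trim3
        if dialect.min_len <= length <= dialect.max_len:
            kept.append(
                FootprintRead(
                    read.gene_id, read.five_prime + dialect.trim5, length
                )
            )
    if dropped:
        logger.warning("dropped %d read(s) shorter than the trims", dropped)
    return kept


def disome_a_site(
    read: FootprintRead, cds_length: Optional[int] = None
) -> Optional[int]:
    """A-site codon of the leading (3') ribosome: codon with the 46th nt."""
    if read.length < LEADING_A_SITE_OFFSET:
        raise ValueError(
            f"{read.gene_id}: read length {read.length} < {LEADING_A_SITE_OFFSET}"
        )
    nt = read.five_prime + LEADING_A_SITE_OFFSET - 1
    if cds_length is not None and nt > cds_length:
        logger.warning("%s: disome A site nt %d beyond CDS", read.gene_id, nt)
        return None
    return math.ceil(nt / 3)


@dataclass
class CollisionPeak:
    offset: int  # codons relative to anchor
    height: float
    width: int  # number of offsets at or above half-maximum


def collision_peak_offset(
    metagene_values: np.ndarray,
    offsets: np.ndarray,
    search: Tuple[int, int] = (-25, 25),
) -> Optional[CollisionPeak]:
    """Locate the disome density maximum near an anchor, in codons.

    Searches ``offsets`` within ``search`` (inclusive); ties break toward
    the smaller offset. A flat profile has no peak (None, flagged). The
    reported width is the count of in-search offsets at or above the
    half-maximum (baseline-subtracted), distinguishing the sharp post-ICP
    peak from the broad polybasic one.
    """
    offsets = np.asarray(offsets)
    values = np.asarray(metagene_values, dtype=float)
    mask = (offsets >= search[0]) & (offsets <= search[1]) & ~np.isnan(values)
    if not mask.any():
        raise ValueError("no finite metagene values in the search window")
    sub_off = offsets[mask]
    sub_val = values[mask]
    vmax, vmin = sub_val.max(), sub_val.min()
    if vmax == vmin:
        logger.warning("flat disome profile in search window; no peak")
        return None
    j = int(np.argmax(sub_val))  # first index wins: smaller offset on ties
    half = vmin + (vmax - vmin) / 2
    width = int((sub_val >= half).sum())
    return CollisionPeak(offset=int(sub_off[j]), height=float(vmax), width=width)


def peak_spacings(
    metagene_values: np.ndarray, offsets: np.ndarray, min_height_frac: float = 0.5
) -> List[int]:
    """Raw spacings (in offset units) between local maxima above a height cut.

    Descriptive only — queued-ribosome patterns show up as ~10-codon
    spacings, but no formal periodicity test is applied.
    """
    values = np.asarray(metagene_values, dtype=float)
    offsets = np.asarray(offsets)
    finite = ~np.isnan(values)
    v, o = values[finite], offsets[finite]
    if len(v) < 3:
        return []
    cut = v.min() + min_height_frac * (v.max() - v.min())
    peaks = [
        i for i in range(1, len(v) - 1)
        if v[i] >= cut and v[i] > v[i - 1] and v[i] >= v[i + 1]
    ]
    return [int(o[b] - o[a]) for a, b in zip(peaks, peaks[1:])]
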