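"""Monosome footprint processing: A-site estimation, coverage profiles,
window normalization and metagene aggregation.

The ribosomal A site is estimated from footprint geometry, counting the
first nucleotide of the read as 1: the A site is the codon containing the
16th nt for 28-nt reads, the 17th nt for 29-31 nt reads, and the 18th nt
for 32-nt reads. Short footprints (20-23 nt, the empty-A-site class) carry
no published offset rule; the midpoint nucleotide is used by default and
this choice is flagged in output metadata.

Coverage around a feature anchor is normalized per gene by dividing each
nucleotide's count by the summed counts in a +/-150 nt window around the
anchor, so that sequencing depth cancels and genes average on equal
footing. Group differences are tested per offset with Welch t-tests and
Holm-Sidak family-wise adjustment across offsets.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import FootprintRead, MetageneResult, Profile

logger = logging.getLogger(__name__)

#: A-site offset (1-based nt within the read) by monosome read length.
A_SITE_OFFSETS = {28: 16, 29: 17, 30: 17, 31: 17, 32: 18}

#: Inclusive read-length classes used throughout the analyses.
LENGTH_CLASSES = {
    "27-29": (27, 29),
    "20-22": (20, 22),
    "28-32": (28, 32),
    "21-23": (21, 23),
}

SHORT_READ_MIN, SHORT_READ_MAX = 20, 23


def a_site_nt(read: FootprintRead) -> Optional[int]:
    """1-based CDS nt position of the A site, or None for ineligible lengths.

    Lengths 28-32 use the calibrated offset rule; short reads 20-23 nt fall
    back to the read midpoint (package convention, no published rule).
    """
    offset = A_SITE_OFFSETS.get(read.length)
    if offset is None:
        if SHORT_READ_MIN <= read.length <= SHORT_READ_MAX:
            offset = (read.length + 1) // 2
        else:
            return None
    return read.five_prime + offset - 1


def estimate_a_site(
    read: FootprintRead, cds_length: Optional[int] = None
) -> Optional[int]:
    """A-site codon index for a 28-32 nt read (codon k spans nt 3k-2..3k)."""
    if read.length not in A_SITE_OFFSETS:
        return None
    nt = read.five_prime + A_SITE_OFFSETS[read.length] - 1
    if cds_length is not None and nt > cds_length:
        logger.warning("%s: A site nt %d beyond CDS", read.gene_id, nt)
        return None
    return math.ceil(nt / 3)


def filter_length_class(
    reads: Sequence[FootprintRead], length_class: str
) -> List[FootprintRead]:
    """Inclusive length filter by named class (e.g. ``"27-29"``)."""
    if length_class not in LENGTH_CLASSES:
        raise KeyError(
            f"unknown length class {length_class!r}; "
            f"expected one of {sorted(LENGTH_CLASSES)}"
        )
    lo, hi = LENGTH_CLASSES[length_class]
    kept = [r for r in reads if lo <= r.length <= hi]
    logger.info("length class %s: kept %d/%d reads", length_class, len(kept), len(reads))
    return kept


def read_length_distribution(reads: Sequence[FootprintRead]) -> Dict[int, int]:
    """Exact integer histogram of read lengths."""
    return dict(sorted(Counter(r.length for r in reads).items()))


def build_profile(
    reads: Sequence[FootprintRead],
    cds_length: int,
    mode: str = "full_read",
    gene_id: str = "",
) -> Profile:
    """Per-nucleotide coverage for one gene.

    ``full_read`` increments every nucleotide covered by the read;
    ``a_site`` increments only the estimated A-site nucleotide (reads with
    no eligible A-site rule, or an A site off the CDS, are skipped).
    Reads extending past the CDS are dropped and logged.
    """
    if mode not in ("full_read", "a_site"):
        raise ValueError(f"unknown profile mode {mode!r}")
    counts = np.zeros(cds_length, dtype=float)
    dropped = 0
    for read in reads:
        if read.five_prime + read.length - 1 > cds_length:
            dropped += 1
            continue
        if mode == "full_read":
            counts[read.five_prime - 1 : read.five_prime + read.length - 1] += 1
        else:
            nt = a_site_nt(read)
            if nt is None or nt > cds_length:
                continue
            counts[nt - 1] += 1
    if dropped:
        logger.warning("%s: dropped %d read(s) extending past CDS", gene_id, dropped)
    return Profile(gene_id=gene_id, counts=counts, resolution="nt")


def normalize_window(
    profile: Profile,
    anchor: int,
    halfwidth: int = 150,
    min_coverage_frac: float = 0.5,
) -> Optional[np.ndarray]:
    """Depth-normalized coverage in a +/-halfwidth window around ``anchor``.

    Returns a vector over offsets -halfwidth..+halfwidth in which each
    in-CDS position holds count / window-sum (the vector sums to 1) and
    positions clipped off the CDS hold NaN. Genes whose window sum is zero,
    or whose window retains less than ``min_coverage_frac`` of its span
    after clipping, are excluded (None, logged).
    """
    n = len(profile.counts)
    if not 1 <= anchor <= n:
        raise ValueError(
            f"{profile.gene_id}: anchor {anchor} outside CDS of length {n}"
        )
    width = 2 * halfwidth + 1
    window = np.full(width, np.nan)
    lo = max(1, anchor - halfwidth)
    hi = min(n, anchor + halfwidth)
    window[lo - anchor + halfwidth : hi - anchor + halfwidth + 1] = (
        profile.counts[lo - 1 : hi]
    )
    valid = ~np.isnan(window)
    if valid.sum() < min_coverage_frac * width:
        logger.warning(
            "%s: window at %d retains %d/%d positions; excluded",
            profile.gene_id, anchor, int(valid.sum()), width,
        )
        return None
    total = np.nansum(window)
    if total <= 0:
        logger.warning("%s: zero coverage in window at %d; excluded",
                       profile.gene_id, anchor)
        return None
    return window / total


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value, NaNs omitted.

    Degenerate zero-variance columns: identical means give p = 1 (no
    evidence of difference), differing constant groups give p = 0.
    """
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def holm_sidak(pvalues: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="holm-sidak")[1]
    return out


def metagene(
    windows_by_group: Dict[str, Sequence[np.ndarray]],
    control: Optional[str] = None,
    halfwidth: int = 150,
) -> MetageneResult:
    """Average normalized windows per group and test against a control.

    Each group's metagene is the per-offset mean of its genes' normalized
    windows (NaN-aware at clipped edges). When ``control`` names one group,
    every other group is compared to it per offset with Welch t-tests,
    adjusted across offsets by the Holm-Sidak method.
    """
    if not windows_by_group:
        raise ValueError("no groups supplied")
    offsets = np.arange(-halfwidth, halfwidth + 1)
    stacks: Dict[str, np.ndarray] = {}
    for name, windows in windows_by_group.items():
        windows = [w for w in windows if w is not None]
        if not windows:
            raise ValueError(f"group {name!r}: all genes excluded")
        stack = np.vstack(windows)
        if stack.shape[1] != len(offsets):
            raise ValueError(
                f"group {name!r}: window width {stack.shape[1]} != {len(offsets)}"
            )
        stacks[name] = stack

    means = {name: np.nanmean(stack, axis=0) for name, stack in stacks.items()}
    result = MetageneResult(
        offsets=offsets,
        group_means=means,
        n_genes={name: stack.shape[0] for name, stack in stacks.items()},
        control=control,
    )
    if control is not None:
        if control not in stacks:
            raise KeyError(f"control group {control!r} not supplied")
        ctrl = stacks[control]
        for name, stack in stacks.items():
            if name == control:
                continue
            if stack.shape[0] < 2 or ctrl.shape[0] < 2:
                raise ValueError("need >= 2 genes per group for testing")
            raw = np.array(
                [_welch_p(stack[:, j], ctrl[:, j]) for j in range(len(offsets))]
            )
            result.adjusted_p[name] = holm_sidak(raw)
    return result


def plot_metagene(result: MetageneResult, path: str, anchor_label: str = "feature start") -> None:
    """Metagene profile per group with the anchor marked; saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for name, mean in result.group_means.items():
        ax.plot(result.offsets, mean, label=f"{name} (n={result.n_genes[name]})")
    ax.axvline(0, color="gold", linestyle=":", label=anchor_label)
    ax.set_xlabel("offset from anchor (nt)")
    ax.set_ylabel("mean normalized coverage")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def peak_offset(result: MetageneResult, group: str) -> Tuple[int, float]:
    """Offset of the metagene maximum for ``group`` (earliest on ties)."""
    mean = result.group_means[group]
    j = int(np.nanargmax(mean))
    return int(result.offsets[j]), float(mean[j])
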