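"""Independent brute-force oracles used to check the scanners and statistics.

These deliberately re-derive every quantity by exhaustive enumeration and
stay independent of the implementation paths they check.
"""

from typing import Dict, List, Sequence, Tuple

import numpy as np

CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


def brute_net_charge_windows(seq: str, window: int) -> List[Tuple[int, int]]:
    out = []
    for start in range(len(seq) - window + 1):
        charge = sum(CHARGE.get(aa, 0) for aa in seq[start : start + window])
        out.append((start + 1, charge))
    return out


def brute_kr_runs(seq: str, min_len: int) -> List[Tuple[int, int, int]]:
    """(start, end, length) of maximal K/R runs >= min_len, 1-based."""
    out = []
    i = 0
    while i < len(seq):
        if seq[i] in "KR":
            j = i
            while j < len(seq) and seq[j] in "KR":
                j += 1
            if j - i >= min_len:
                out.append((i + 1, j, j - i))
            i = j
        else:
            i += 1
    return out


def brute_kr_windows(seq: str, min_count: int, window: int) -> List[Tuple[int, int]]:
    """(start, count) for every qualifying window."""
    out = []
    for start in range(len(seq) - window + 1):
        count = sum(1 for aa in seq[start : start + window] if aa in "KR")
        if count >= min_count:
            out.append((start + 1, count))
    return out


def brute_polya(seq: str, min_len: int) -> List[Tuple[int, int, int]]:
    out = []
    i = 0
    while i < len(seq):
        if seq[i] == "A":
            j = i
            while j < len(seq) and seq[j] == "A":
                j += 1
            if j - i >= min_len:
                out.append((i + 1, j, j - i))
            i = j
        else:
            i += 1
    return out


def brute_icp(cds: str, pairs: Sequence[str]) -> List[int]:
    """1-based first-codon indices of in-frame inhibitory pairs."""
    pairs = set(pairs)
    n = len(cds) // 3
    return [
        k + 1
        for k in range(n - 1)
        if cds[3 * k : 3 * k + 6] in pairs
    ]


def brute_ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS D by exhaustive ECDF comparison at all data points."""
    points = np.concatenate([a, b])
    d = 0.0
    for x in points:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, abs(fa - fb))
    return d


def brute_holm_sidak(pvalues: Sequence[float]) -> np.ndarray:
    """Step-down Sidak adjustment: p_(i) -> max_{j<=i} 1-(1-p_(j))^(m-j)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, min(1.0, adj))
        adjusted[idx] = running
    return adjusted


GENETIC_CODE: Dict[str, str] = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            GENETIC_CODE[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]


def translate(cds: str) -> str:
    """Standard-code translation, stops as '*'; independent of biopython."""
    return "".join(
        GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )
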