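"""Per-gene translatability metrics and group statistics.

Covers the codon stabilization coefficient (CSC: per-codon Pearson
correlation between codon frequency and mRNA half-life, and its gene-level
mean CSCg), translation efficiency (TE: footprint reads / mRNA reads),
the decile-banded normalization used to place initiation metrics on a
common 0-1 scale, Kolmogorov-Smirnov / Welch-t group comparisons, and
Euclidean hierarchical clustering of the normalized score matrix.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .records import CdsRecord, STOP_CODONS

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("te", "cscg", "init_time", "kozak5", "kozak50", "ssu_density")

#: Initiation-oriented metrics where a *low* raw value means efficient
#: initiation; the normalized score inverts these so 1 is always "best".
LOWER_IS_BETTER = frozenset({"init_time", "ssu_density"})


def compute_csc(
    codon_freqs: pd.DataFrame, half_lives: pd.Series
) -> pd.Series:
    """Per-codon Pearson r between codon frequency and mRNA half-life.

    ``codon_freqs`` is genes x codons (frequency of occurrence of each codon
    in each mRNA); ``half_lives`` is indexed by gene. Codons whose frequency
    has zero variance across genes get NaN (flagged by a warning).
    """
    common = codon_freqs.index.intersection(half_lives.dropna().index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes with both codon frequencies and half-lives")
    X = codon_freqs.loc[common].to_numpy(dtype=float)
    y = half_lives.loc[common].to_numpy(dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    if sy == 0:
        r[:] = np.nan
    csc = pd.Series(r, index=codon_freqs.columns, name="csc")
    undefined = csc.index[csc.isna()]
    if len(undefined):
        logger.warning("CSC undefined for codons: %s", ", ".join(undefined))
    return csc


def compute_cscg(cds: CdsRecord, table: pd.Series) -> float:
    """Gene-level CSC: mean CSC over the gene's sense codons.

    Every codon occurrence counts once; stop codons are excluded.
    """
    codons = [c for c in cds.codons() if c not in STOP_CODONS]
    if not codons:
        raise ValueError(f"{cds.gene_id}: no sense codons")
    missing = sorted({c for c in codons if c not in table.index or pd.isna(table[c])})
    if missing:
        raise KeyError(
            f"{cds.gene_id}: no CSC value for codon(s) {', '.join(missing)}"
        )
    return float(np.mean([table[c] for c in codons]))


def compute_te(rpf_counts: pd.Series, mrna_counts: pd.Series) -> pd.Series:
    """Translation efficiency: footprint reads / mRNA reads per gene.

    Genes with zero mRNA reads get NaN (flagged), never a silent zero.
    """
    rpf, mrna = rpf_counts.align(mrna_counts, join="inner")
    if (rpf < 0).any() or (mrna < 0).any():
        raise ValueError("negative read counts")
    te = pd.Series(np.nan, index=rpf.index, name="te", dtype=float)
    ok = mrna > 0
    te[ok] = rpf[ok] / mrna[ok]
    n_undef = int((~ok).sum())
    if n_undef:
        logger.warning("TE undefined (zero mRNA reads) for %d gene(s)", n_undef)
    return te


def normalized_decile_score(
    values: pd.Series, higher_is_better: bool = True
) -> pd.Series:
    """Decile-banded min-max normalization onto [0, 1].

    The genome is split into eight equal-count groups by value, and the two
    extreme groups are each split again at their median, giving ten groups.
    Each group is min-max normalized internally, then mapped into its
    genome-wide band: the lowest group occupies [0, 0.0625], the highest
    [0.9375, 1], and the middle eight groups equal consecutive bands in
    between. This caps the influence of a few extreme genes on the scale.

    ``higher_is_better=False`` inverts the metric first, so a score of 1
    always denotes the best (most efficient) end.
    """
    finite = values.dropna()
    if len(finite) < 10:
        raise ValueError("need >= 10 finite values")
    x = finite.to_numpy(dtype=float)
    if not higher_is_better:
        x = -x
    scores = np.empty_like(x)

    if x.max() == x.min():  # degenerate: every gene identical
        scores[:] = 0.5
    else:
        order = np.argsort(x, kind="stable")
        if len(np.unique(x)) < len(x):
            logger.warning(
                "ties present; group assignment follows stable sort order"
            )
        octiles = np.array_split(order, 8)
        groups = (
            list(np.array_split(octiles[0], 2))
            + octiles[1:7]
            + list(np.array_split(octiles[7], 2))
        )
        lows = [0.0, 1 / 16] + [1 / 16 + i * (7 / 8) / 8 for i in range(1, 8)] + [15 / 16]
        highs = lows[1:] + [1.0]
        for idx, lo, hi in zip(groups, lows, highs):
            g = x[idx]
            frac = np.full(len(g), 0.5) if g.max() == g.min() else (
                (g - g.min()) / (g.max() - g.min())
            )
            scores[idx] = lo + frac * (hi - lo)

    out = pd.Series(np.nan, index=values.index, dtype=float, name=values.name)
    out[finite.index] = scores
    return out


def compare_groups(
    values: pd.Series,
    groups: Dict[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Each gene group versus the rest of the genome: KS and Welch t tests.

    Returns one row per group with the two-sample KS statistic ``D`` and
    two-sided p-value, the Welch t-test p-value, and a significance mask at
    ``alpha`` (non-significant cells mirror the blank cells of a p-value
    heat map). Missing metric values are excluded pairwise.
    """
    rows = []
    clean = values.dropna()
    for name, members in groups.items():
        members = set(members)
        sample = clean[clean.index.isin(members)].to_numpy()
        rest = clean[~clean.index.isin(members)].to_numpy()
        if len(sample) == 0 or len(rest) == 0:
            raise ValueError(f"group {name!r}: empty sample after NaN removal")
        if len(sample) < 3:
            raise ValueError(f"group {name!r}: need n >= 3, got {len(sample)}")
        ks = stats.ks_2samp(sample, rest, method="auto")
        tt = stats.ttest_ind(sample, rest, equal_var=False)
        rows.append(
            {
                "group": name,
                "n": len(sample),
                "ks_D": float(ks.statistic),
                "ks_p": float(ks.pvalue),
                "t_p": float(tt.pvalue),
                "significant": bool(ks.pvalue <= alpha),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def cluster_genes(
    scores: pd.DataFrame, method: str = "average"
) -> Tuple[List[str], np.ndarray, pd.DataFrame]:
    """Hierarchical clustering of genes by Euclidean distance.

    Rows with all metrics missing are excluded (logged); remaining missing
    values are median-imputed per column (flagged). Returns the deterministic
    leaf order (gene ids), the linkage matrix, and the imputed matrix.
    """
    all_missing = scores.isna().all(axis=1)
    if all_missing.any():
        logger.warning(
            "excluding %d gene(s) with all metrics missing", int(all_missing.sum())
        )
    mat = scores.loc[~all_missing].copy()
    if mat.isna().any().any():
        logger.warning(
            "median-imputing %d missing value(s) for clustering",
            int(mat.isna().sum().sum()),
        )
        mat = mat.fillna(mat.median())
    if len(mat) < 2:
        raise ValueError("need >= 2 genes to cluster")
    Z = linkage(mat.to_numpy(dtype=float), method=method, metric="euclidean")
    order = [mat.index[i] for i in leaves_list(Z)]
    return order, Z, mat


def score_matrix(
    metrics: pd.DataFrame,
    columns: Sequence[str] = ("init_time", "kozak5", "kozak50", "ssu_density", "te"),
    orientation: Optional[Dict[str, bool]] = None,
) -> pd.DataFrame:
    """Normalized decile scores for several metrics side by side.

    Orientation defaults to higher-is-better except for the metrics in
    ``LOWER_IS_BETTER``; 1 always means efficient initiation/translation.
    """
    orientation = orientation or {}
    out = {}
    for col in columns:
        hib = orientation.get(col, col not in LOWER_IS_BETTER)
        out[col] = normalized_decile_score(metrics[col], higher_is_better=hib)
    return pd.DataFrame(out, index=metrics.index)
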