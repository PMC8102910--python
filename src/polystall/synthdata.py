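"""Seeded synthetic-data generators with planted ground truth.

Everything the analysis modules consume can be generated here without any
download: proteomes/CDS sets with planted polybasic architectures,
monosome footprints with configurable pause sites, disome reads with a
planted leading-ribosome A site, and per-gene translatability metric
tables with a chosen correlation structure.

Planted genes provably satisfy exactly their intended architectures and
background genes none — both are verified with the scanners at generation
time, so round-trip tests have exact truth. All randomness flows through
one ``numpy.random.Generator`` derived from the config seed; reruns with
the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import seqscan
from .records import CdsRecord, FootprintRead, ProteinRecord
from .riboprof import A_SITE_OFFSETS
from .disome import LEADING_A_SITE_OFFSET, DisomeDialect, BROAD

AA20 = sorted("ACDEFGHIKLMNPQRSTVWY")
UNCHARGED = sorted(set(AA20) - set("KRDE"))

#: Synonymous codons per amino acid (standard code).
BACK_TABLE: Dict[str, List[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    BACK_TABLE.setdefault(_aa, []).append(_codon)
for _aa in BACK_TABLE:
    BACK_TABLE[_aa].sort()

#: Poly(A)-free codon choices used when a planted K/R motif must carry
#: charge without creating an adenine tract (or an inhibitory pair).
SAFE_CODON = {"K": "AAG", "R": "CGT"}

METRIC_NAMES = ("te", "cscg", "init_time", "kozak5", "kozak50", "ssu_density")

#: Single-factor loadings reproducing the expected sign structure: TE
#: correlates positively with CSCg and the Kozak scores, negatively with
#: initiation time and 40S 5'UTR density. corr(te, cscg) = 0.5.
DEFAULT_LOADINGS = {
    "te": np.sqrt(0.5),
    "cscg": np.sqrt(0.5),
    "init_time": -0.6,
    "kozak5": 0.5,
    "kozak50": 0.5,
    "ssu_density": -0.5,
}

#: Planted motifs per architecture, chosen so each satisfies exactly its
#: own category: (a) nine K/R in ten residues but runs of at most five;
#: (b) a six-residue K/R run; (d) twelve K/R spread over 24 residues
#: (charge +12 in a 30-aa window, no dense 10-aa window, no long run).
MOTIFS = {
    "a": "KRKRKAKRKR",
    "b": "KKKKKK",
    "d": "KA" * 12,
}
#: (c) is planted at the CDS level: three AAA lysines followed by an
#: A-initial threonine codon give a ten-adenine tract from only three K.
POLYA_PEPTIDE = "KKKT"
POLYA_CODONS = ("AAA", "AAA", "AAA", "ACA")
#: A twelve-lysine run encoded AAA satisfies all four architectures at once.
ALL_FOUR_MOTIF = "K" * 12

BUFFER = 30  # charge-free flanking residues around every planted motif


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the conditions exercised throughout the analyses:
    200 genes of 150-400 aa, 50 footprints per gene, a 3-fold density
    increase over the 9 nt downstream of a stall anchor, and a disome
    leading-ribosome A site planted 9 codons past the anchor.
    """

    seed: int = 0
    n_genes: int = 200
    gene_length: Tuple[int, int] = (150, 400)  # aa, inclusive
    planted: Dict[str, int] = field(
        default_factory=lambda: {"a": 3, "b": 3, "c": 3, "d": 3, "icp": 3}
    )
    planted_multi: Sequence[Tuple[str, ...]] = ()
    icp_pairs: Tuple[str, ...] = seqscan.DEFAULT_ICP_PAIRS
    lysine_codon: str = "AAG"  # "AAA" turns planted K runs into poly(A)
    reads_per_gene: int = 50
    pause_factor: float = 3.0
    pause_width_nt: int = 9
    short_read_fraction: float = 0.0  # 20-22 nt reads at stalls
    disomes_per_gene: int = 30
    disome_offset_codons: int = 9
    disome_background_fraction: float = 0.5
    n_metric_genes: int = 2000
    metric_loadings: Optional[Dict[str, float]] = None
    target_corr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.pause_factor < 1:
            raise ValueError("pause factor must be >= 1")
        for frac in (self.short_read_fraction, self.disome_background_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if any(v < 0 for v in self.planted.values()):
            raise ValueError("planted counts must be >= 0")
        if self.n_genes < sum(self.planted.values()) + len(self.planted_multi):
            raise ValueError("more planted genes than n_genes")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _longest_a_run(codons: Sequence[Optional[str]]) -> int:
    """Longest adenine run in the concatenated planted codons."""
    joined = "".join(c if c else "NNN" for c in codons)
    best = run = 0
    for ch in joined:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    return best


def _random_background(
    rng: np.random.Generator, length: int, thresholds: seqscan.Thresholds
) -> str:
    """A protein sequence provably free of all four architectures."""
    for _ in range(1000):
        seq = "".join(rng.choice(AA20, size=length))
        protein = ProteinRecord("_bg", seq)
        if seqscan.find_kr_window_stretch(
            protein, thresholds.kr_window_count, thresholds.kr_window_size
        ):
            continue
        if seqscan.find_consecutive_kr(protein, thresholds.consecutive_kr):
            continue
        if length >= thresholds.charge_window:
            charge, _ = seqscan.max_net_charge(protein, thresholds.charge_window)
            if charge >= thresholds.charge_threshold:
                continue
        return seq
    raise RuntimeError("could not sample an architecture-free background")


def _back_translate(
    rng: np.random.Generator,
    peptide: str,
    forced: Dict[int, str],
    icp_pairs: Sequence[str],
    expect_polya: int,
    min_polya: int,
) -> str:
    """CDS for ``peptide`` (+TAA stop) with forced codons at given indices.

    Background codon choice is rejection-sampled so that, outside the
    planted positions, the CDS carries no adenine tract >= ``min_polya``
    and no inhibitory pair; ``expect_polya`` planted tract(s) are expected.
    """
    for _ in range(1000):
        codons = [
            forced.get(i, rng.choice(BACK_TABLE[aa]))
            for i, aa in enumerate(peptide)
        ] + ["TAA"]
        cds = CdsRecord("_bg", "".join(codons))
        icp_expected = sum(1 for i in forced if forced.get(i, "") + forced.get(i + 1, "") in icp_pairs)
        if len(seqscan.find_icp(cds, icp_pairs)) != icp_expected:
            continue
        if len(seqscan.find_polyA(cds, min_polya)) != expect_polya:
            continue
        return cds.sequence
    raise RuntimeError("could not back-translate without stray architectures")


def generate_proteome(
    config: SimConfig,
    thresholds: seqscan.Thresholds = seqscan.Thresholds(),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[ProteinRecord], List[CdsRecord], pd.DataFrame]:
    """Proteome + CDS set with planted architectures and a truth table.

    One gene per planted count carries exactly one architecture (or one
    ICP); entries of ``planted_multi`` carry the given category
    combination. The truth table records per-gene planted flags and the
    motif anchor (1-based aa and nt start), and every record is verified
    with the scanners before being returned.
    """
    rng = rng if rng is not None else config.rng()
    plan: List[Tuple[str, ...]] = []
    for cat, count in sorted(config.planted.items()):
        plan.extend([(cat,)] * count)
    plan.extend(tuple(sorted(m)) for m in config.planted_multi)
    plan.extend([()] * (config.n_genes - len(plan)))

    k_codon = config.lysine_codon
    proteins, cdss, rows = [], [], []
    for idx, categories in enumerate(plan):
        gene_id = f"SYN{idx + 1:04d}"
        lo, hi = config.gene_length
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_background(rng, length, thresholds))
        forced: Dict[int, str] = {}
        anchor_aa: Optional[int] = None
        expect_polya = 0

        motifs: List[Tuple[str, str, Optional[Tuple[str, ...]]]] = []
        if set(categories) >= {"a", "b", "c", "d"}:
            motifs.append(("abcd", ALL_FOUR_MOTIF, ("AAA",) * len(ALL_FOUR_MOTIF)))
        else:
            for cat in categories:
                if cat == "c":
                    motifs.append(("c", POLYA_PEPTIDE, POLYA_CODONS))
                elif cat == "icp":
                    pair = config.icp_pairs[0]
                    aa1 = standard_dna_table.forward_table[pair[:3]]
                    aa2 = standard_dna_table.forward_table[pair[3:]]
                    motifs.append(("icp", aa1 + aa2, (pair[:3], pair[3:])))
                else:
                    motif = MOTIFS[cat]
                    codons = tuple(
                        k_codon if aa == "K" else SAFE_CODON.get(aa)
                        for aa in motif
                    )
                    motifs.append((cat, motif, codons))

        # Place motifs left to right at random positions, each wrapped in a
        # charge-free buffer so neighbouring background cannot tip a
        # scanning window.
        needed = sum(len(m[1]) + BUFFER for m in motifs) + BUFFER
        if needed > length:
            raise ValueError(
                f"{gene_id}: planted motifs need {needed} aa, gene has {length}"
            )
        slack = length - needed
        extras = (
            rng.multinomial(slack, np.full(len(motifs) + 1, 1 / (len(motifs) + 1)))
            if motifs else np.zeros(1, dtype=int)
        )
        cursor = BUFFER + int(extras[0])
        for m_idx, (_, motif, codons) in enumerate(motifs):
            # A planted K run coded AAA becomes an adenine tract of 3x the
            # run length, which the poly(A) scanner will (correctly) flag.
            if codons is not None and _longest_a_run(codons) >= thresholds.polya_len:
                expect_polya += 1
            start = cursor
            for j in range(-BUFFER, len(motif) + BUFFER):
                pos = start + j
                if 0 <= pos < length and (j < 0 or j >= len(motif)):
                    if seq[pos] in "KRDE":
                        seq[pos] = rng.choice(UNCHARGED)
            for j, aa in enumerate(motif):
                seq[start + j] = aa
                if codons is not None and codons[j] is not None:
                    forced[start + j] = codons[j]
            # keep an adenine-initial codon off the end of a planted AAA run
            if codons and any(c and c.startswith("AA") for c in codons):
                tail = start + len(motif)
                if tail < length:
                    forced.setdefault(tail, "GGT" if seq[tail] != "G" else "GGT")
                    seq[tail] = "G"
                if start > 0:
                    forced.setdefault(start - 1, "GGT")
                    seq[start - 1] = "G"
            if anchor_aa is None:
                anchor_aa = start + 1
            cursor = start + len(motif) + BUFFER + int(extras[m_idx + 1])

        peptide = "".join(seq)
        cds_seq = _back_translate(
            rng, peptide, forced, config.icp_pairs, expect_polya,
            thresholds.polya_len,
        )
        expected = set(categories) - {"icp"}
        if set(categories) >= {"a", "b", "c", "d"}:
            expected = {"a", "b", "c", "d"}
        if expect_polya:
            expected.add("c")
        protein = ProteinRecord(gene_id, peptide)
        cds = CdsRecord(gene_id, cds_seq)
        _verify_planted(
            protein, cds, expected, "icp" in categories, thresholds,
            config.icp_pairs,
        )
        proteins.append(protein)
        cdss.append(cds)
        rows.append(
            {
                "gene_id": gene_id,
                "length_aa": length,
                **{c: c in expected for c in ("a", "b", "c", "d")},
                "icp": "icp" in categories,
                "anchor_aa": anchor_aa if anchor_aa is not None else pd.NA,
                "anchor_nt": 3 * (anchor_aa - 1) + 1 if anchor_aa else pd.NA,
            }
        )
    truth = pd.DataFrame(rows).set_index("gene_id")
    return proteins, cdss, truth


def _verify_planted(
    protein: ProteinRecord,
    cds: CdsRecord,
    expected: set,
    expect_icp: bool,
    thresholds: seqscan.Thresholds,
    icp_pairs: Sequence[str],
) -> None:
    summary = seqscan.classify_proteome(
        [protein], [cds], thresholds, icp_pairs=icp_pairs
    )
    found = {c for c in ("a", "b", "c", "d") if summary.flags.iloc[0][c]}
    found_icp = bool(summary.flags.iloc[0]["icp"])
    if found != expected or found_icp != expect_icp:
        raise RuntimeError(
            f"{protein.gene_id}: planted {sorted(expected)} but scanners "
            f"found {sorted(found) + (['icp'] if found_icp else [])}"
        )


def simulate_footprints(
    config: SimConfig,
    cds_lengths: Dict[str, int],
    stall_anchors: Optional[Dict[str, int]] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[FootprintRead]:
    """Monosome footprints with uniform background and optional stalls.

    A-site nucleotides are sampled per gene from a uniform density;
    positions within ``pause_width_nt`` downstream of a gene's stall anchor
    (inclusive) are upweighted by ``pause_factor``. Read lengths are drawn
    uniformly from 28-32 nt and the 5' end back-computed by inverting the
    A-site offset rule, so A-site estimation recovers the sampled codon
    exactly. At stall positions a ``short_read_fraction`` of reads instead
    emulates the empty-A-site class (20-22 nt, midpoint placement).
    """
    rng = rng if rng is not None else config.rng()
    stall_anchors = stall_anchors or {}
    lengths = np.array(sorted(A_SITE_OFFSETS))
    reads: List[FootprintRead] = []
    for gene_id in sorted(cds_lengths):
        L = cds_lengths[gene_id]
        lo, hi = 19, L - 15  # feasible A-site range for every 28-32 nt read
        if hi < lo:
            continue
        weights = np.ones(L)
        weights[: lo - 1] = 0.0
        weights[hi:] = 0.0
        anchor = stall_anchors.get(gene_id)
        if anchor is not None and config.pause_factor != 1.0:
            a0, a1 = anchor, min(L, anchor + config.pause_width_nt - 1)
            weights[a0 - 1 : a1] *= config.pause_factor
        weights /= weights.sum()
        nts = rng.choice(np.arange(1, L + 1), size=config.reads_per_gene, p=weights)
        for nt in nts:
            in_stall = (
                anchor is not None
                and anchor <= nt <= anchor + config.pause_width_nt - 1
            )
            if in_stall and rng.random() < config.short_read_fraction:
                length = int(rng.integers(20, 23))
                five_prime = int(nt) - (length + 1) // 2 + 1
            else:
                length = int(rng.choice(lengths))
                five_prime = int(nt) - A_SITE_OFFSETS[length] + 1
            reads.append(FootprintRead(gene_id, five_prime, length))
    return reads


def simulate_disomes(
    config: SimConfig,
    anchor_codons: Dict[str, int],
    cds_lengths: Dict[str, int],
    dialect: DisomeDialect = BROAD,
    rng: Optional[np.random.Generator] = None,
) -> List[FootprintRead]:
    """Raw disome reads whose leading-ribosome A site is planted.

    A fraction ``1 - disome_background_fraction`` of each gene's reads puts
    the leading ribosome's A site exactly ``disome_offset_codons`` codons
    after the anchor codon; the rest are uniform background. Raw lengths
    are emitted per dialect (including the to-be-trimmed ends), so running
    ``preprocess_disome`` then ``disome_a_site`` recovers the planted codon
    exactly.
    """
    rng = rng if rng is not None else config.rng()
    reads: List[FootprintRead] = []
    post_lo = max(dialect.min_len, LEADING_A_SITE_OFFSET)
    for gene_id in sorted(anchor_codons):
        L = cds_lengths[gene_id]
        c_min = (LEADING_A_SITE_OFFSET + 2 + dialect.trim5 + 2) // 3 + 1
        c_max = (L + 48 - dialect.max_len - dialect.trim3) // 3
        planted = anchor_codons[gene_id] + config.disome_offset_codons
        if not c_min <= planted <= c_max:
            raise ValueError(
                f"{gene_id}: planted disome codon {planted} infeasible "
                f"(allowed {c_min}..{c_max})"
            )
        for _ in range(config.disomes_per_gene):
            if rng.random() < config.disome_background_fraction:
                codon = int(rng.integers(c_min, c_max + 1))
            else:
                codon = planted
            post_len = int(rng.integers(post_lo, dialect.max_len + 1))
            a_nt = 3 * codon - 2
            five_prime = a_nt - (LEADING_A_SITE_OFFSET - 1) - dialect.trim5
            raw_len = post_len + dialect.trim5 + dialect.trim3
            reads.append(FootprintRead(gene_id, five_prime, raw_len))
    return reads


def generate_metrics(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene metric table with a controlled correlation structure.

    Latent values are multivariate normal with either the given full target
    correlation matrix or a single-factor structure from ``metric_loadings``
    (default: corr(TE, CSCg) = +0.5, positive Kozak loadings, negative
    initiation-time and 40S-density loadings). Returns ``(metrics, latent)``
    where ``metrics`` holds observable scales (TE, initiation seconds and
    40S density are log-normal, hence positive) and ``latent`` the true
    Gaussian values for recovery tests.
    """
    rng = rng if rng is not None else config.rng()
    names = list(METRIC_NAMES)
    if config.target_corr is not None:
        corr = np.asarray(config.target_corr, dtype=float)
    else:
        lam = np.array(
            [(config.metric_loadings or DEFAULT_LOADINGS)[n] for n in names]
        )
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    z = rng.standard_normal((config.n_metric_genes, len(names))) @ chol.T
    index = pd.Index(
        [f"SYN{i + 1:04d}" for i in range(config.n_metric_genes)], name="gene_id"
    )
    latent = pd.DataFrame(z, columns=names, index=index)
    metrics = pd.DataFrame(
        {
            "te": np.exp(0.6 * latent["te"]),
            "cscg": 0.05 * latent["cscg"],
            "init_time": np.exp(np.log(30.0) + 0.5 * latent["init_time"]),
            "kozak5": latent["kozak5"],
            "kozak50": latent["kozak50"],
            "ssu_density": np.exp(0.5 * latent["ssu_density"]),
        },
        index=index,
    )
    return metrics, latent
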