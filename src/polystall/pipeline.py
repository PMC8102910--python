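"""End-to-end driver: simulate -> scan -> scores -> metagene -> disome.

``run_pipeline`` exercises the whole analysis on synthetic data (or on
user-supplied files) and writes a report bundle of TSV tables plus a
provenance log recording the package version, seed, thresholds and input
digests. Outputs are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__, disome, io, riboprof, seqscan, synthdata, translatability

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: synthdata.SimConfig,
    out_dir: str,
    thresholds: seqscan.Thresholds = seqscan.Thresholds(),
    halfwidth: int = 150,
) -> Dict[str, pd.DataFrame]:
    """Full synthetic run; returns the tables it also writes to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    # 1. synthetic proteome with planted truth
    proteins, cdss, truth = synthdata.generate_proteome(config, thresholds, rng)
    io.write_fasta(proteins, out / "proteins.fasta")
    io.write_fasta(cdss, out / "cds.fasta")
    io.write_tsv(truth, out / "planted_truth.tsv")

    # 2. architecture scan
    summary = seqscan.classify_proteome(
        proteins, cdss, thresholds, icp_pairs=config.icp_pairs
    )
    io.write_tsv(summary.flags, out / "flags.tsv")
    io.write_tsv(io.hits_table(summary.hits), out / "hits.tsv", index=False)
    io.write_tsv(io.venn_table(summary.venn), out / "venn.tsv", index=False)

    # 3. translatability scores on a synthetic metric table
    metrics, _ = synthdata.generate_metrics(config, rng)
    scores = translatability.score_matrix(metrics)
    io.write_tsv(scores, out / "normalized_scores.tsv")
    flagged = truth.index[truth[list("abcd")].any(axis=1)]
    group = [g for g in flagged if g in metrics.index]
    tests = {}
    if len(group) >= 3:
        for col in ("te", "cscg"):
            tests[col] = translatability.compare_groups(
                metrics[col], {"polybasic": group}
            )
        io.write_tsv(pd.concat(tests, names=["metric"]), out / "group_tests.tsv")

    # 4. monosome metagene around planted anchors
    cds_lengths = {c.gene_id: len(c) for c in cdss}
    anchors = {
        g: int(truth.loc[g, "anchor_nt"])
        for g in truth.index
        if pd.notna(truth.loc[g, "anchor_nt"])
    }
    background = [g for g in truth.index if g not in anchors]
    pseudo = {  # control group: windows around matched positions, no stall
        g: min(200, cds_lengths[g] - halfwidth // 2) for g in background
    }
    reads = synthdata.simulate_footprints(config, cds_lengths, anchors, rng)
    by_gene: Dict[str, list] = {}
    for r in reads:
        by_gene.setdefault(r.gene_id, []).append(r)
    windows: Dict[str, list] = {"polybasic": [], "background": []}
    for g, anchor in anchors.items():
        profile = riboprof.build_profile(
            by_gene.get(g, []), cds_lengths[g], mode="a_site", gene_id=g
        )
        w = riboprof.normalize_window(profile, anchor, halfwidth)
        if w is not None:
            windows["polybasic"].append(w)
    for g, anchor in pseudo.items():
        profile = riboprof.build_profile(
            by_gene.get(g, []), cds_lengths[g], mode="a_site", gene_id=g
        )
        w = riboprof.normalize_window(profile, anchor, halfwidth)
        if w is not None:
            windows["background"].append(w)
    meta = riboprof.metagene(windows, control="background", halfwidth=halfwidth)
    meta_df = pd.DataFrame(
        {
            "offset": meta.offsets,
            **{f"mean_{k}": v for k, v in meta.group_means.items()},
            **{f"adj_p_{k}": v for k, v in meta.adjusted_p.items()},
        }
    )
    io.write_tsv(meta_df, out / "metagene.tsv", index=False)
    riboprof.plot_metagene(meta, str(out / "metagene.png"))

    # 5. disome geometry around the same anchors (codon resolution)
    anchor_codons = {g: (a - 1) // 3 + 1 for g, a in anchors.items()}
    feasible = {
        g: c
        for g, c in anchor_codons.items()
        if c + config.disome_offset_codons >= 20
        and 3 * (c + config.disome_offset_codons) + 60 <= cds_lengths[g]
    }
    disome_rows = []
    if feasible:
        for name, dialect in disome.DIALECTS.items():
            raw = synthdata.simulate_disomes(
                config, feasible, cds_lengths, dialect, rng
            )
            processed = disome.preprocess_disome(raw, dialect)
            halfw_codons = 25
            per_gene: Dict[str, np.ndarray] = {}
            for r in processed:
                codon = disome.disome_a_site(r, cds_lengths[r.gene_id])
                if codon is None:
                    continue
                vec = per_gene.setdefault(
                    r.gene_id, np.zeros(2 * halfw_codons + 1)
                )
                off = codon - feasible[r.gene_id]
                if -halfw_codons <= off <= halfw_codons:
                    vec[off + halfw_codons] += 1
            mats = [v / v.sum() for v in per_gene.values() if v.sum() > 0]
            mean = np.nanmean(np.vstack(mats), axis=0)
            offsets = np.arange(-halfw_codons, halfw_codons + 1)
            peak = disome.collision_peak_offset(mean, offsets)
            disome_rows.append(
                {
                    "dialect": name,
                    "n_genes": len(mats),
                    "peak_offset_codons": peak.offset if peak else pd.NA,
                    "peak_width": peak.width if peak else pd.NA,
                }
            )
        io.write_tsv(pd.DataFrame(disome_rows), out / "disome_peaks.tsv", index=False)

    provenance = {
        "package": "polystall",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "target_corr"},
        "thresholds": asdict(thresholds),
        "short_read_a_site_rule": "midpoint (no published offset rule)",
        "inputs": {
            p.name: _digest(p)
            for p in sorted(out.glob("*.fasta"))
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    tables = {
        "truth": truth,
        "flags": summary.flags,
        "scores": scores,
        "metagene": meta_df,
        "disome": pd.DataFrame(disome_rows),
    }
    return tables
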