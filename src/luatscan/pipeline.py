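"""End-to-end orchestration: simulate -> call -> assemble -> summarize.

One reproducible run driven by a single YAML config (per-stage sections
mirroring the SimConfig fields plus a ``calling`` section), writing every
stage output plus a manifest and a machine-readable summary.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import classify_gene_sets, dedupe_tss, first_exon_length, select_candidate_promoters
from .assembly import assemble_luat
from .caller import (
    call_luats,
    calls_to_frame,
    candidate_antisense_scores,
    empirical_threshold,
    null_distribution_from_regions,
    sample_intergenic_regions,
)
from .expranalysis import splicing_index_from_reads
from .signal import coverage_from_reads
from .synthio import SimConfig, simulate_dataset
from . import io as lio

logger = logging.getLogger("luatscan.pipeline")

DEFAULT_CALLING = {
    "alpha": 0.005,
    "null_m": 10000,
    "null_length": 5000,
    "null_buffer": 1000,
    "flank": 5000,
    "bin_bp": 100,
    "transform": "log2p1",
    "seed_window": 1500,
    "max_gap": 800,
    "min_frag_len": 200,
    "min_cov": 1,
}


def load_config(path) -> tuple[SimConfig, dict]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    calling = dict(DEFAULT_CALLING)
    calling.update(raw.pop("calling", {}))
    sim = SimConfig.from_dict(raw)
    return sim, calling


def _stamp(seed: int, cmd: str) -> str:
    return f"luatscan v{__version__} | seed={seed} | cmd={cmd}"


def run_end_to_end(config_path, outdir, cmd: str = "run", write_fasta: bool = False) -> dict:
    """Run the full pipeline on a simulated dataset; returns the summary.

    Writes annotation, reads, truth, calls, assembled LUAT models, the
    gene-set partition, the summary (JSON + TSV) and a manifest capturing
    inputs, parameters, seed and package version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "config"
    try:
        sim_cfg, calling = load_config(config_path)
        seed = sim_cfg.seed
        stamp = _stamp(seed, cmd)

        stage = "simulate"
        logger.info("simulating dataset (seed=%d)", seed)
        data = simulate_dataset(sim_cfg)
        genome = data["genome"]
        annotation = data["annotation"]
        truth = data["truth"]
        reads = data["reads"]

        lio.write_gtf(outdir / "annotation.gtf", annotation)
        lio.write_bed6_reads(outdir / "reads.bed", reads)
        lio.write_tsv(outdir / "truth.tsv", truth, stamp)
        lio.write_bed_features(outdir / "cpg_islands_planted.bed", data["cpg_islands"])
        if write_fasta:
            lio.write_fasta(outdir / "genome.fa", genome)

        stage = "candidates"
        deduped = dedupe_tss(annotation)
        candidates = select_candidate_promoters(deduped, genome)
        logger.info("%d candidate promoters (of %d transcripts)", len(candidates), len(deduped))

        stage = "coverage"
        cov = coverage_from_reads(reads, genome)

        stage = "null"
        null_regions = sample_intergenic_regions(
            annotation, genome, m=calling["null_m"], length=calling["null_length"],
            buffer=calling["null_buffer"], seed=seed,
        )
        null = null_distribution_from_regions(
            cov, null_regions, length=calling["null_length"],
            bin_bp=calling["bin_bp"], transform=calling["transform"],
        )
        threshold = empirical_threshold(null, calling["alpha"])
        logger.info("empirical threshold %.3f (alpha=%.4g)", threshold, calling["alpha"])

        stage = "call"
        scores = candidate_antisense_scores(
            cov, candidates, flank=calling["flank"], bin_bp=calling["bin_bp"],
            transform=calling["transform"],
        )
        calls = call_luats(candidates, scores, threshold)
        called = [c for c in calls if c.called]

        stage = "assemble"
        by_gene = {t.gene_id: t for t in candidates}
        luat_models = []
        offsets = []
        for c in called:
            res = assemble_luat(
                cov, reads, by_gene[c.gene_id], sim_cfg.expression.library_size,
                seed_window=calling["seed_window"], min_len=calling["min_frag_len"],
                max_gap=calling["max_gap"], min_cov=calling["min_cov"],
            )
            if res is None:
                continue
            interval, offset, fpkm = res
            c.luat_interval, c.luat_offset_bp, c.luat_fpkm = interval, offset, fpkm
            offsets.append(offset)
            from .types import TranscriptModel

            luat_models.append(
                TranscriptModel(
                    f"LUAT_{c.gene_id}", f"LUAT_{c.gene_id}", interval[0], interval[3],
                    ((interval[1], interval[2]),), is_coding=False,
                )
            )
        lio.write_gtf(outdir / "luats.gtf", luat_models)
        lio.write_tsv(outdir / "calls.tsv", calls_to_frame(calls), stamp)

        stage = "genesets"
        call_map = {c.gene_id: c.called for c in calls}
        partition = classify_gene_sets(deduped, call_map, annotation)
        lio.write_tsv(outdir / "gene_sets.tsv", partition.to_frame(), stamp)

        stage = "summarize"
        hist_edges = list(range(-1500, 1, 100))
        hist, _ = np.histogram(offsets, bins=hist_edges) if offsets else (np.zeros(15, int), None)
        set_summaries = {}
        by_gene_all = {t.gene_id: t for t in deduped}
        for label in ("luat_associated", "coding_coding", "unidirectional"):
            genes = [by_gene_all[g] for g in partition.genes(label) if g in by_gene_all]
            fe = [first_exon_length(t) for t in genes]
            si5 = []
            for t in genes[:50]:
                try:
                    si5.append(
                        splicing_index_from_reads(
                            reads, t, sim_cfg.expression.library_size
                        ).si_5prime
                    )
                except ValueError:
                    pass
            set_summaries[label] = {
                "n_genes": len(genes),
                "median_first_exon_bp": float(np.median(fe)) if fe else None,
                "median_si_5prime": float(np.median(si5)) if si5 else None,
            }

        summary = {
            "version": __version__,
            "seed": seed,
            "n_transcripts": len(annotation),
            "n_candidates": len(candidates),
            "n_called": len(called),
            "called_fraction": (len(called) / len(candidates)) if candidates else 0.0,
            "threshold": threshold,
            "n_assembled": len(luat_models),
            "offset_histogram": {
                "edges_bp": hist_edges,
                "counts": [int(x) for x in hist],
            },
            "median_luat_fpkm": float(np.median([c.luat_fpkm for c in called
                                                 if c.luat_fpkm is not None]))
            if any(c.luat_fpkm is not None for c in called) else None,
            "gene_sets": set_summaries,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        flat = pd.DataFrame(
            [
                {"metric": "n_candidates", "value": summary["n_candidates"]},
                {"metric": "n_called", "value": summary["n_called"]},
                {"metric": "called_fraction", "value": summary["called_fraction"]},
                {"metric": "threshold", "value": summary["threshold"]},
                {"metric": "n_assembled", "value": summary["n_assembled"]},
            ]
        )
        lio.write_tsv(outdir / "summary.tsv", flat, stamp)

        manifest = {
            "package_version": __version__,
            "seed": seed,
            "command": cmd,
            "config": {"simulation": sim_cfg.to_dict(), "calling": calling},
            "outputs": sorted(
                p.name for p in outdir.iterdir() if p.name not in ("run.log", "manifest.json")
            ),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("run complete: %d called of %d candidates", len(called), len(candidates))
        return summary
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        print(f"luatscan: pipeline failed at stage {stage!r}", file=sys.stderr)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
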