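"""End-to-end enrichment report: scan -> associate -> bootstrap -> classify.

``run_report`` takes one configuration mapping (typically loaded from YAML),
validates every input up front, then runs per contrast x feature the
bootstrap enrichment, the multi-TF partition per contrast, and the rescue
summary when a disease and a corrected contrast are both supplied. All
outputs are TSV/JSON plus a manifest with a checksum per written file;
deterministic stages reproduce byte-identical outputs under the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .enrichment_bootstrap import GeneUniverse, run_enrichment
from .genomic_features import associate_peaks_to_genes, unique_target_genes
from .io_formats import (
    PWM,
    DEGRecord,
    read_annotation,
    read_bed,
    read_deg_table,
    read_fasta,
    read_pwm,
    chrom_sizes as fasta_chrom_sizes,
)
from .motif_scan import genes_with_feature, promoter_windows, scan_promoters
from .synthetic_data import (
    SimulationConfig,
    plant_motifs,
    simulate_annotation_and_sequence,
    simulate_peak_sets,
)
from .tf_classification import classify_degs, rescue_calls

logger = logging.getLogger("regboot")


class ConfigError(ValueError):
    """Raised when the run configuration is invalid (before any stage runs)."""


def consensus_pwm(consensus: str, certainty: float = 0.97) -> PWM:
    """High-information PWM putting ``certainty`` on each consensus base."""
    base_index = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(consensus), 4), (1 - certainty) / 3)
    for i, b in enumerate(consensus.upper()):
        probs[i, base_index[b]] = certainty
    return PWM(probs=probs, name=f"consensus:{consensus}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_inputs(config: Mapping) -> tuple:
    """Resolve synthetic or file-based inputs into in-memory stage inputs."""
    seed = int(config.get("seed", 0))
    window_size = int(config.get("window_size", 1000))
    if "synthetic" in config:
        sim = SimulationConfig(seed=seed, **dict(config["synthetic"]))
        sim = replace(sim, window_size=window_size)
        genes, sequences, sizes = simulate_annotation_and_sequence(sim)
        rng = np.random.default_rng(seed + 10)
        gene_ids = [g.gene_id for g in genes]
        deg_ids = set(gene_ids[: sim.n_deg])
        windows = promoter_windows(genes, sizes, window_size)
        sequences, _ = plant_motifs(sequences, windows, deg_ids, sim)
        # two contrasts: the disease contrast has the planted DEGs; in the
        # corrected contrast a configurable fraction of them is rescued
        rescue_frac = float(config.get("synthetic_rescue_fraction", 0.7))
        rescued = set(
            rng.choice(sorted(deg_ids), size=int(rescue_frac * len(deg_ids)), replace=False)
        )
        lfc = {g: float(rng.normal(0, 1)) for g in gene_ids}
        deg_tables = {
            "disease": pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "log2fc": [lfc[g] for g in gene_ids],
                    "padj": [0.001 if g in deg_ids else 0.5 for g in gene_ids],
                }
            ),
            "corrected": pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "log2fc": [lfc[g] / 2 for g in gene_ids],
                    "padj": [
                        0.001 if (g in deg_ids and g not in rescued) else 0.5
                        for g in gene_ids
                    ],
                }
            ),
        }
        pwms = {"planted": consensus_pwm(sim.consensus)}
        # a calibration motif planted at the same frequency in DEGs and
        # non-DEGs: its enrichment p-value should be unremarkable
        null_consensus = "".join("ACGT"[(i + 1) % 4] for i in range(len(sim.consensus)))
        null_sim = replace(
            sim,
            seed=seed + 101,
            consensus=null_consensus,
            plant_freq_deg=sim.plant_freq_nondeg,
        )
        sequences, _ = plant_motifs(sequences, windows, deg_ids, null_sim)
        pwms["null"] = consensus_pwm(null_consensus)
        peak_gene_sets, _ = simulate_peak_sets(gene_ids, sim)
        return genes, sequences, sizes, deg_tables, pwms, peak_gene_sets, window_size, seed
    if "inputs" not in config:
        raise ConfigError("config must contain either 'synthetic' or 'inputs'")
    inputs = config["inputs"]
    for key in ("annotation", "fasta", "deg_tables"):
        if key not in inputs:
            raise ConfigError(f"inputs.{key} is required")
    if not inputs.get("pwms") and not inputs.get("peak_beds"):
        raise ConfigError("at least one PWM or one peak set is required")
    for key in ("annotation", "fasta"):
        if not Path(inputs[key]).exists():
            raise ConfigError(f"inputs.{key}: no such file {inputs[key]}")
    genes = read_annotation(inputs["annotation"])
    sequences = read_fasta(inputs["fasta"])
    sizes = fasta_chrom_sizes(sequences)
    deg_tables = {}
    for contrast, path in inputs["deg_tables"].items():
        if not Path(path).exists():
            raise ConfigError(f"deg table {contrast}: no such file {path}")
        records = read_deg_table(path)
        deg_tables[contrast] = pd.DataFrame(
            [(r.gene_id, r.log2fc, r.padj) for r in records],
            columns=["gene_id", "log2fc", "padj"],
        )
    pwms = {}
    for name, spec in (inputs.get("pwms") or {}).items():
        if isinstance(spec, str):
            spec = {"path": spec}
        if not Path(spec["path"]).exists():
            raise ConfigError(f"pwm {name}: no such file {spec['path']}")
        pwms[name] = read_pwm(spec["path"], format=spec.get("format", "jaspar"))
    peak_gene_sets = {}
    proximal_bp = int(config.get("proximal_bp", 5000))
    for name, path in (inputs.get("peak_beds") or {}).items():
        if not Path(path).exists():
            raise ConfigError(f"peak bed {name}: no such file {path}")
        peaks = read_bed(path)
        assignments = associate_peaks_to_genes(peaks, genes, proximal_bp)
        peak_gene_sets[name] = unique_target_genes(assignments)
    return genes, sequences, sizes, deg_tables, pwms, peak_gene_sets, window_size, seed


def run_report(config: Mapping, outdir: str | Path) -> dict:
    """Run the full enrichment report; returns the manifest dictionary."""
    t0 = time.time()
    loaded = _load_inputs(config)
    genes, sequences, sizes, deg_tables, pwms, peak_gene_sets, window_size, seed = loaded
    if not pwms and not peak_gene_sets:
        raise ConfigError("no features configured: supply at least one PWM or peak set")
    if not deg_tables:
        raise ConfigError("no DEG contrasts configured")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reps = int(config.get("reps", 10_000))
    alpha = float(config.get("alpha", 1e-4))
    written: list[Path] = []

    logger.info("scanning %d promoter windows with %d PWM(s)", len(genes), len(pwms))
    windows = promoter_windows(genes, sizes, window_size)
    feature_sets: dict[str, set[str]] = {}
    for name, pwm in pwms.items():
        t = time.time()
        hits = scan_promoters(windows, sequences, pwm, alpha=alpha)
        feature_sets[f"motif:{name}"] = genes_with_feature(hits)
        logger.info("scan %s: %d hits in %.1fs", name, len(hits), time.time() - t)
    for name, gene_set in peak_gene_sets.items():
        feature_sets[f"peak:{name}"] = set(gene_set)

    def to_records(df: pd.DataFrame) -> list[DEGRecord]:
        return [
            DEGRecord(r.gene_id, float(r.log2fc), None if pd.isna(r.padj) else float(r.padj))
            for r in df.itertuples()
        ]

    report: dict = {"enrichment": {}, "partition": {}, "rescue": None}
    for contrast, table in deg_tables.items():
        records = to_records(table)
        universe = GeneUniverse.from_deg_records(records)
        for feat_name, feat_genes in feature_sets.items():
            result = run_enrichment(universe, feat_genes, reps=reps, seed=seed)
            key = f"{contrast}__{feat_name.replace(':', '_')}"
            _write_json(result.summary(), outdir / f"enrichment_{key}.json")
            pd.DataFrame({"null_freq": result.null_freqs}).to_csv(
                outdir / f"null_{key}.tsv", sep="\t", index=False
            )
            written += [outdir / f"enrichment_{key}.json", outdir / f"null_{key}.tsv"]
            report["enrichment"][key] = result.summary()
        tf_sets = {
            name.split(":", 1)[1]: genes
            for name, genes in feature_sets.items()
            if name.startswith("peak:")
        } or {name.split(":", 1)[1]: genes for name, genes in feature_sets.items()}
        partition = classify_degs(universe.deg, tf_sets)
        part_payload = {"counts": partition.counts, "proportions": partition.proportions}
        _write_json(part_payload, outdir / f"partition_{contrast}.json")
        written.append(outdir / f"partition_{contrast}.json")
        report["partition"][contrast] = part_payload

    if len(deg_tables) >= 2:
        names = list(deg_tables)
        rescue = rescue_calls(to_records(deg_tables[names[0]]), to_records(deg_tables[names[1]]))
        payload = {
            "disease_contrast": names[0],
            "corrected_contrast": names[1],
            "n_rescued": rescue.n_rescued,
            "n_not_rescued": rescue.n_not_rescued,
            "n_indeterminate": rescue.n_indeterminate,
            "rescue_fraction": rescue.fraction,
        }
        _write_json(payload, outdir / "rescue.json")
        written.append(outdir / "rescue.json")
        report["rescue"] = payload

    manifest = {
        "version": __version__,
        "rng": "numpy-PCG64",
        "seed": seed,
        "reps": reps,
        "alpha": alpha,
        "window_size": window_size,
        "config": {k: v for k, v in config.items()},
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": {p.name: _checksum(p) for p in written},
    }
    _write_json(manifest, outdir / "manifest.json")
    report["manifest"] = manifest
    return report
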