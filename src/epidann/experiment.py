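"""End-to-end experiment orchestration.

An experiment is described by a validated configuration (YAML on disk or a
dict in memory): where the data comes from (synthetic generator or
genome+BED+pair files per cell line), the model/training hyperparameters,
and an output directory.  ``run_experiment`` executes
prepare -> train -> evaluate (-> motifs) and writes every artifact with a
provenance record sufficient to regenerate the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import MetricsReport, evaluate, feature_domain_probe
from .genomic import extract_window, load_genome, one_hot_encode, read_pairs, read_regions
from .model import ModelConfig
from .pairs import (
    EPIPair,
    assign_quantile_bins,
    build_domains,
    dedupe_pairs,
    filter_by_distance,
    generate_negative_candidates,
    subsample_negatives,
)
from .synthetic import SynthConfig, benchmark_domains
from .training import TrainConfig, train

#: Desk-scale hyperparameters: a configuration small enough to train on one
#: CPU core in tens of seconds while keeping every mechanism of the
#: full-scale model (two branches, pooling, recurrent fusion, both heads).
#: The learning rate is raised to 0.2 because plain SGD at the full-scale
#: 0.001 barely moves a small network within 10 epochs.
DESK_SCALE = dict(
    n_kernels=32,
    kernel_len=12,
    n_conv_layers=1,
    lstm_dim=25,
    epi_dense_dim=32,
    domain_dense_dim=16,
    epochs=10,
    batch_size=64,
    learning_rate=0.2,
)


def run_transfer_benchmark(
    synth_config,
    variant: str = "dann",
    seed: int = 0,
    reverse_gradient: bool = True,
    probe: bool = False,
):
    """Train one desk-scale model on a synthetic benchmark and evaluate it.

    Returns a dict with the trained network, its target-test AUC, and (when
    ``probe=True``) the held-out domain-probe accuracy of its features.
    Used by the repeated-seed transfer experiments; ``variant`` may be any
    architecture variant, and ``reverse_gradient=False`` gives the
    no-reversal (cooperative) control.
    """
    source, target_train, target_test = benchmark_domains(synth_config)
    model_kwargs = {k: DESK_SCALE[k] for k in ("n_kernels", "kernel_len", "n_conv_layers", "lstm_dim", "epi_dense_dim", "domain_dense_dim")}
    model_config = ModelConfig(
        variant=variant,
        enh_len=synth_config.enh_len,
        prom_len=synth_config.prom_len,
        lambda_grl=1.0,
        reverse_gradient=reverse_gradient,
        **model_kwargs,
    )
    train_config = TrainConfig(
        epochs=DESK_SCALE["epochs"],
        batch_size=DESK_SCALE["batch_size"],
        learning_rate=DESK_SCALE["learning_rate"],
        seed=seed,
    )
    use_target = target_train if model_config.has_domain_head else None
    network, history = train(source, use_target, model_config, train_config)
    report = evaluate(network, target_test)
    out = {"network": network, "auc": report.auc, "report": report, "history": history}
    if probe:
        out["probe_accuracy"] = feature_domain_probe(network, source, target_test, seed=seed)
    return out


@dataclass
class ExperimentConfig:
    """Validated experiment description; unknown keys are rejected."""

    out_dir: str
    seed: int = 0
    # synthetic data source (used when cell_lines is empty)
    synthetic: Optional[dict] = None
    # file-based source: genome path + per-cell-line element/pair files
    genome: Optional[str] = None
    cell_lines: dict = field(default_factory=dict)  # name -> {enhancers, promoters, pairs}
    target_cell: Optional[str] = None
    min_distance: int = 10_000
    max_distance: int = 2_000_000
    n_bins: int = 5
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    extract_motifs: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# file-based corpus preparation
# ---------------------------------------------------------------------------


def prepare_cell_line(
    genome,
    enhancer_bed,
    promoter_bed,
    pairs_tsv,
    min_distance: int = 10_000,
    max_distance: int = 2_000_000,
    n_bins: int = 5,
    seed: int = 0,
    cell_line: str = "",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Build a balanced, distance-matched, encoded corpus for one cell line.

    Returns (enh, prom, labels) arrays plus a summary dict (pair counts and
    bin edges).  Positives come from the labeled pair table; negatives are
    subsampled per distance bin from all non-interacting annotated pairs.
    """
    enhancers = read_regions(enhancer_bed, kind="enhancer")
    promoters = read_regions(promoter_bed, kind="promoter")
    raw = read_pairs(pairs_tsv)
    pairs = [EPIPair(e, p, label, cell_line=cell_line) for e, p, label in raw]
    pairs = dedupe_pairs(pairs)
    kept = filter_by_distance(pairs, min_distance, max_distance)
    positives = [p for p in kept if p.epi_label == 1]
    binned_pos, edges = assign_quantile_bins(positives, n_bins)
    candidates = generate_negative_candidates(
        enhancers, promoters, positives, min_distance, max_distance, cell_line
    )
    negatives = subsample_negatives(binned_pos, candidates, edges, seed)
    corpus = binned_pos + negatives
    enh = np.stack([one_hot_encode(extract_window(p.enhancer, 3000, genome).seq) for p in corpus])
    prom = np.stack([one_hot_encode(extract_window(p.promoter, 2000, genome).seq) for p in corpus])
    labels = np.array([p.epi_label for p in corpus], dtype=np.int8)
    summary = {
        "cell_line": cell_line,
        "n_input_pairs": len(raw),
        "n_after_dedupe": len(pairs),
        "n_after_distance_filter": len(kept),
        "n_positives": len(binned_pos),
        "n_negatives": len(negatives),
        "bin_edges": [float(e) for e in edges],
    }
    return enh, prom, labels, summary


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _synthetic_domains(config: ExperimentConfig):
    synth_kwargs = dict(config.synthetic or {})
    synth_kwargs.setdefault("seed", config.seed)
    sc = SynthConfig(**synth_kwargs)
    source, target_train, target_test = benchmark_domains(sc)
    return source, target_train, target_test, sc


def _file_domains(config: ExperimentConfig):
    genome = load_genome(config.genome)
    tables = {}
    summaries = {}
    for name, files in config.cell_lines.items():
        enh, prom, labels, summary = prepare_cell_line(
            genome,
            files["enhancers"],
            files["promoters"],
            files["pairs"],
            config.min_distance,
            config.max_distance,
            config.n_bins,
            seed=config.seed,
            cell_line=name,
        )
        tables[name] = (enh, prom, labels)
        summaries[name] = summary
    source, target_train, target_test = build_domains(tables, config.target_cell, config.seed)
    return source, target_train, target_test, summaries


def run_experiment(config: ExperimentConfig) -> MetricsReport:
    """Execute prepare -> train -> evaluate (-> motifs); returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "prepare"
    try:
        if config.cell_lines:
            source, target_train, target_test, extra = _file_domains(config)
        else:
            source, target_train, target_test, extra = _synthetic_domains(config)

        stage = "train"
        model_kwargs = dict(config.model)
        model_kwargs.setdefault("enh_len", source.enh.shape[1])
        model_kwargs.setdefault("prom_len", source.prom.shape[1])
        model_config = ModelConfig(**model_kwargs)
        train_kwargs = dict(config.train)
        train_kwargs.setdefault("seed", config.seed)
        train_config = TrainConfig(**train_kwargs)
        use_target = target_train if model_config.has_domain_head else None
        network, history = train(source, use_target, model_config, train_config)
        network.save(out / "model.npz")
        pd.DataFrame(history.to_records()).to_csv(out / "history.csv", index=False)

        stage = "evaluate"
        report = evaluate(network, target_test)
        (out / "metrics.json").write_text(report.to_json())

        if config.extract_motifs:
            stage = "motifs"
            from .genomic import one_hot_decode
            from .motifs import extract_kernel_pfms, write_meme

            seqs = [one_hot_decode(m) for m in target_test.enh[:200]]
            pfms = extract_kernel_pfms(network, seqs, branch="enhancer")
            write_meme(pfms, out / "motifs.meme")

        provenance = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_source": source.n,
            "n_target_train": target_train.n,
            "n_target_test": target_test.n,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
        return report
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc


def aggregate_runs(reports: list[MetricsReport], conditions: Optional[list] = None) -> pd.DataFrame:
    """Mean and standard deviation of each metric, grouped by condition.

    ``conditions`` (optional) labels each report — e.g. a variant name or
    target cell line; the repeated-seed protocol averages ~10 runs per
    condition at full scale.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for i, r in enumerate(reports):
        row = {
            "condition": conditions[i] if conditions else "all",
            "accuracy": r.accuracy,
            "precision": r.precision,
            "recall": r.recall,
            "f1": r.f1,
            "auc": r.auc,
            "aupr": r.aupr,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.groupby("condition").agg(["mean", "std", "count"])
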