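"""End-to-end orchestration: data → features → evaluation → reports.

One :class:`PipelineConfig` (YAML/JSON-loadable) drives the full
experiment: generate or load a cohort, derive CPSD features per
surrogate variant and interaction context, run the repeated
cross-validated evaluation, compare variants, and emit the sub-band
coupling and variance-correlation reports together with figures and a
run manifest.

All randomness flows from one master seed through
:func:`derive_seeds`, so any stage (or any single variant) can be
re-run in isolation and reproduce bit-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import plots
from .evaluate import (
    EvalConfig,
    PerformanceDistribution,
    compare_variants,
    repeated_kfold_eval,
)
from .report import group_histograms, subband_summaries, variance_outcome_table
from .spectral import DEFAULT_BANDS_CPM, extract_features, feature_matrix
from .surrogates import VARIANT_ORDER, SurrogateSpec, apply_surrogate
from .synthetic import Cohort, GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


def derive_seeds(master_seed: int, labels: Sequence[str]) -> dict[str, int]:
    """Deterministic per-stage seeds from one master seed.

    Each stage seed is the first 4 bytes of SHA-256 over
    ``"<master_seed>:<label>"``, reduced modulo 2**31 — independent of
    call order and collision-free in practice.
    """
    out = {}
    for label in labels:
        digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
        out[label] = int.from_bytes(digest[:4], "big") % (2**31)
    return out


def stage_seed(master_seed: int, label: str) -> int:
    return derive_seeds(master_seed, [label])[label]


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) the experiment."""

    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    series_path: str | None = None  # long-format CSV, alternative to generator
    labels_path: str | None = None
    contexts: tuple[str, ...] | None = None  # None = all available
    eval_config: EvalConfig = field(default_factory=EvalConfig)
    variants: tuple[str, ...] = VARIANT_ORDER
    bands_cpm: tuple[tuple[float, float], ...] = DEFAULT_BANDS_CPM
    include_phase: bool = False
    n_boot: int = 1000
    out_dir: str = "dyadsync_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        synthetic = self.generator is not None
        from_files = self.series_path is not None
        if synthetic == from_files:
            raise ValueError(
                "exactly one data source: a generator config or input CSV paths"
            )
        if from_files and self.labels_path is None:
            raise ValueError("series_path requires labels_path")
        unknown = set(self.variants) - set(VARIANT_ORDER)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "generator" in raw and raw["generator"] is not None:
            g = dict(raw["generator"])
            for key in ("shared_band", "mean_range", "sd_range", "contexts"):
                if key in g and g[key] is not None:
                    g[key] = tuple(g[key])
            raw["generator"] = GeneratorConfig(**g)
        elif raw.get("series_path"):
            raw["generator"] = None
        if "eval_config" in raw:
            raw["eval_config"] = EvalConfig(**raw["eval_config"])
        for key in ("contexts", "variants"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "bands_cpm" in raw:
            raw["bands_cpm"] = tuple(tuple(b) for b in raw["bands_cpm"])
        return cls(**raw)


class _JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        return json.dumps(
            {
                "time": self.formatTime(record),
                "level": record.levelname,
                "logger": record.name,
                "message": record.getMessage(),
            }
        )


def _setup_logging(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(_JsonLineFormatter())
    root = logging.getLogger("dyadsync")
    root.addHandler(handler)
    root.setLevel(level.upper())
    return handler


def variant_feature_source(
    dyads: Sequence[dio.DyadSeries],
    labels: dict[str, bool],
    spec: SurrogateSpec,
    include_phase: bool = False,
):
    """Feature source for one surrogate variant.

    Deterministic variants are transformed once and return a fixed
    ``(X, y)``; time-randomized variants return a callable drawing fresh
    permutations (hence fresh features) inside every evaluation
    repetition.
    """
    if not spec.time_permute:
        feats = [
            extract_features(apply_surrogate(d, spec)) for d in dyads
        ]
        X, y, _ = feature_matrix(feats, labels, include_phase)
        return X, y

    def regenerate(rng: np.random.Generator):
        feats = [
            extract_features(apply_surrogate(d, spec, rng)) for d in dyads
        ]
        X, y, _ = feature_matrix(feats, labels, include_phase)
        return X, y

    return regenerate


def _load_data(
    config: PipelineConfig, out_dir: Path
) -> tuple[dict[str, list[dio.DyadSeries]], dict[str, bool], dict]:
    if config.generator is not None:
        cohort: Cohort = generate_cohort(
            config.generator,
            np.random.default_rng(stage_seed(config.seed, "cohort")),
        )
        series_path = out_dir / "cohort_series.csv"
        labels_path = out_dir / "cohort_labels.csv"
        dio.write_dyads(
            [d for ds in cohort.dyads.values() for d in ds], series_path
        )
        dio.write_labels(cohort.labels, labels_path)
        info = {
            "source": "synthetic",
            "series_path": str(series_path),
            "labels_path": str(labels_path),
            "n_couples": config.generator.n_couples,
            "n_values": cohort.n_values,
            "validation": None,
        }
        return cohort.dyads, cohort.label_map(), info
    dyads, validation = dio.read_dyads(config.series_path)
    labels_list = dio.read_labels(config.labels_path)
    retained, summary = dio.apply_exclusions(labels_list)
    label_map = {l.couple_id: l.separated for l in retained}
    by_context: dict[str, list[dio.DyadSeries]] = {}
    for d in dyads:
        if d.couple_id in label_map:
            by_context.setdefault(d.context, []).append(d)
    info = {
        "source": "files",
        "series_path": config.series_path,
        "labels_path": config.labels_path,
        "n_couples": summary["n_retained"],
        "n_values": sum(2 * d.n_samples for ds in by_context.values() for d in ds),
        "validation": validation.to_dict(),
        "exclusions": summary,
    }
    return by_context, label_map, info


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full experiment; returns (and writes) the run manifest.

    A stage failure still writes the manifest, marking completed stages,
    and re-raises; partial outputs are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir, config.log_level)
    manifest: dict = {
        "config": _config_dict(config),
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": config.seed,
        "versions": _versions(),
        "stages": [],
        "outputs": {},
        "completed": False,
    }
    t_start = time.time()
    try:
        _run_stages(config, out_dir, manifest)
        manifest["completed"] = True
    finally:
        manifest["elapsed_s"] = round(time.time() - t_start, 3)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logging.getLogger("dyadsync").removeHandler(handler)
        handler.close()
    return manifest


def _run_stages(config: PipelineConfig, out_dir: Path, manifest: dict) -> None:
    def record(stage: str, t0: float) -> None:
        manifest["stages"].append(
            {"stage": stage, "status": "ok", "elapsed_s": round(time.time() - t0, 3)}
        )

    t0 = time.time()
    dyads_by_context, label_map, data_info = _load_data(config, out_dir)
    manifest["data"] = data_info
    record("load", t0)

    contexts = config.contexts or tuple(sorted(dyads_by_context))
    summary: dict[str, dict] = {}
    dists_by_context: dict[str, list[PerformanceDistribution]] = {}
    for context in contexts:
        dyads = dyads_by_context[context]
        rows = []
        dists = []
        for variant in config.variants:
            t0 = time.time()
            spec = SurrogateSpec.from_variant_id(variant)
            source = variant_feature_source(
                dyads, label_map, spec, config.include_phase
            )
            rng = np.random.default_rng(
                stage_seed(config.seed, f"eval:{context}:{variant}")
            )
            dist = repeated_kfold_eval(
                source, config.eval_config, rng, variant_id=variant, context=context
            )
            dists.append(dist)
            for rep, v in enumerate(dist.mcc_values):
                rows.append(
                    {
                        "variant": variant,
                        "context": context,
                        "repetition": rep,
                        "mcc": v,
                    }
                )
            summary.setdefault(context, {})[variant] = {
                "mean_mcc": dist.mean_mcc,
                "se_mcc": dist.se_mcc,
            }
            record(f"eval:{context}:{variant}", t0)
        dists_by_context[context] = dists
        perf_path = out_dir / f"performance_{context}.csv"
        pd.DataFrame(rows).to_csv(perf_path, index=False)
        manifest["outputs"][f"performance_{context}"] = str(perf_path)

        t0 = time.time()
        comparison = compare_variants(dists)
        for name, df in (
            (f"comparison_{context}", comparison.pairwise),
            (f"vs_zero_{context}", comparison.vs_zero),
        ):
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False)
            manifest["outputs"][name] = str(path)
        plots.variant_bar_chart(
            dists,
            out_dir / f"fig_variants_{context}.png",
            title=f"{context} interaction",
        )
        manifest["outputs"][f"fig_variants_{context}"] = str(
            out_dir / f"fig_variants_{context}.png"
        )
        record(f"compare:{context}", t0)

        t0 = time.time()
        feats = [extract_features(d) for d in dyads]
        summaries = subband_summaries(feats, label_map, config.bands_cpm)
        hist = group_histograms(
            summaries,
            n_boot=config.n_boot,
            rng=np.random.default_rng(stage_seed(config.seed, f"boot:{context}")),
        )
        for name, df in (
            (f"subband_summaries_{context}", summaries),
            (f"subband_histograms_{context}", hist.histograms),
            (f"subband_differences_{context}", hist.differences),
        ):
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False)
            manifest["outputs"][name] = str(path)
        plots.subband_histograms(
            hist.histograms, out_dir / f"fig_subbands_{context}.png"
        )
        manifest["outputs"][f"fig_subbands_{context}"] = str(
            out_dir / f"fig_subbands_{context}.png"
        )
        record(f"report:{context}", t0)

    t0 = time.time()
    table = variance_outcome_table(
        {c: dyads_by_context[c] for c in contexts}, label_map
    )
    path = out_dir / "variance_table.csv"
    table.to_csv(path, index=False)
    manifest["outputs"]["variance_table"] = str(path)
    record("variance_table", t0)

    summary_path = out_dir / "performance_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest["outputs"]["performance_summary"] = str(summary_path)
    manifest["seeds"] = derive_seeds(
        config.seed,
        ["cohort"]
        + [f"eval:{c}:{v}" for c in contexts for v in config.variants]
        + [f"boot:{c}" for c in contexts],
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=str))


def _versions() -> dict:
    import scipy
    import sklearn

    from . import __version__

    return {
        "dyadsync": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
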