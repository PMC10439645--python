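"""Repeated-experiment engine: settings -> models -> metrics -> summaries.

One repetition = fresh cohorts for every setting, fresh model fits on the
training cohort, metrics in the internal and every external setting, and
internal-minus-external deltas.  Every repetition's randomness derives only
from (master seed, repetition index), so runs are deterministic, resumable
and embarrassingly parallel without changing results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .generate import ExogenousSource, InterventionSpec, build_study_settings
from .graph import CausalGraph, parse_graph
from .metrics import (PerformanceRecord, TransportRecord, aggregate,
                      evaluate_predictions, records_to_frame, transport_delta)
from .models import ModelConfig, predict_probabilities, train_model
from .sem import SemParameterSet, read_parameters

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a full experiment."""

    dag_path: str | None = None
    params_path: str | None = None
    exogenous_csv: str | None = None       # bootstrap table (z-scale)
    exogenous_parametric: dict = field(default_factory=dict)
    n: int = 10_000
    repetitions: int = 200
    master_seed: int = 0
    settings: dict[str, list] = field(default_factory=dict)
    algorithms: list[str] = field(default_factory=lambda: ["logistic"])
    schemes: list[str] = field(
        default_factory=lambda: ["all", "parents", "children", "exogenous"])
    train_label: str = "train"
    internal_label: str = "internal"
    output_dir: str | None = None
    ici_span: float = 0.75
    brier_bins: int = 10
    # in-memory alternatives to the path fields
    graph: CausalGraph | None = None
    params: SemParameterSet | None = None
    exogenous: ExogenousSource | None = None

    def __post_init__(self):
        if self.repetitions < 1:
            raise PipelineError("repetitions must be >= 1")
        if self.n < 100:
            raise PipelineError("cohort size n must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        settings = {}
        for label, ivs in raw.pop("settings", {}).items():
            settings[label] = [InterventionSpec(**iv) for iv in (ivs or [])]
        return cls(settings=settings, **raw)

    def resolve(self):
        graph = self.graph or parse_graph(Path(self.dag_path).read_text())
        params = self.params or read_parameters(self.params_path, graph)
        if self.exogenous is not None:
            exo = self.exogenous
        elif self.exogenous_csv:
            exo = ExogenousSource(table=pd.read_csv(self.exogenous_csv),
                                  parametric=self.exogenous_parametric)
        else:
            exo = ExogenousSource(parametric=self.exogenous_parametric)
        if self.train_label not in self.settings:
            raise PipelineError(f"settings must include {self.train_label!r}")
        if self.internal_label not in self.settings:
            raise PipelineError(f"settings must include {self.internal_label!r}")
        return graph, params, exo


@dataclass
class ResultBundle:
    performance: pd.DataFrame
    transport: pd.DataFrame
    performance_summary: pd.DataFrame
    transport_summary: pd.DataFrame
    n_failures: int
    config: ExperimentConfig
    params_hash: str
    version: str = __version__


def _one_repetition(rep, graph, params, exo, config) -> tuple[list, list]:
    cohorts = build_study_settings(graph, params, exo, config.settings,
                                   n=config.n, master_seed=config.master_seed,
                                   repetition=rep)
    train = cohorts[config.train_label]
    eval_labels = [l for l in config.settings if l != config.train_label]
    perf: list[PerformanceRecord] = []
    trans: list[TransportRecord] = []
    seed_root = np.random.SeedSequence(config.master_seed,
                                       spawn_key=(rep, 1_000_003))
    model_seeds = seed_root.generate_state(
        len(config.algorithms) * len(config.schemes)) % (2**31)
    i = 0
    for algorithm in config.algorithms:
        for scheme in config.schemes:
            mc = ModelConfig(algorithm, scheme, seed=int(model_seeds[i]))
            i += 1
            model = train_model(mc, train, graph)
            by_setting = {}
            for label in eval_labels:
                pred = predict_probabilities(model, cohorts[label])
                by_setting[label] = evaluate_predictions(
                    pred, algorithm, scheme, rep, span=config.ici_span,
                    n_bins=config.brier_bins)
            perf.extend(by_setting.values())
            internal = by_setting[config.internal_label]
            for label in eval_labels:
                if label != config.internal_label:
                    trans.append(transport_delta(internal, by_setting[label]))
    return perf, trans


def run_experiment(config: ExperimentConfig) -> ResultBundle:
    """Run all repetitions; flush partial results so interrupted runs resume."""
    graph, params, exo = config.resolve()
    params.validate_against(graph)
    params_before = params.copy()
    outdir = Path(config.output_dir) if config.output_dir else None
    perf_path = trans_path = None
    done: set[int] = set()
    perf_frames: list[pd.DataFrame] = []
    trans_frames: list[pd.DataFrame] = []
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        perf_path = outdir / "performance.csv"
        trans_path = outdir / "transport.csv"
        if perf_path.exists():
            prev = pd.read_csv(perf_path)
            done = set(prev["repetition"].astype(int))
            perf_frames.append(prev)
            log.info("resuming: %d repetitions already on disk", len(done))
        if trans_path.exists():
            trans_frames.append(pd.read_csv(trans_path))

    n_failures = 0
    max_failures = max(1, int(0.01 * config.repetitions))
    for rep in range(config.repetitions):
        if rep in done:
            continue
        try:
            perf, trans = _one_repetition(rep, graph, params, exo, config)
        except Exception as exc:
            n_failures += 1
            log.warning("repetition %d failed: %s", rep, exc)
            if n_failures > max_failures:
                raise PipelineError(
                    f"aborting: {n_failures} repetition failures (> 1%)")
            continue
        pf = records_to_frame(perf)
        tf = records_to_frame(trans)
        perf_frames.append(pf)
        trans_frames.append(tf)
        if perf_path is not None:
            pf.to_csv(perf_path, mode="a", header=not perf_path.exists(),
                      index=False)
            tf.to_csv(trans_path, mode="a", header=not trans_path.exists(),
                      index=False)
        if (rep + 1) % 25 == 0:
            log.info("repetition %d/%d done", rep + 1, config.repetitions)

    assert params.equations == params_before.equations  # interventions never leak
    performance = pd.concat(perf_frames, ignore_index=True)
    transport = pd.concat(trans_frames, ignore_index=True)
    bundle = ResultBundle(performance, transport, aggregate(performance),
                          aggregate(transport), n_failures, config,
                          params_hash=params.graph_hash)
    if outdir is not None:
        bundle.performance_summary.to_csv(outdir / "performance_summary.csv",
                                          index=False)
        bundle.transport_summary.to_csv(outdir / "transport_summary.csv",
                                        index=False)
        echo = {k: v for k, v in dataclasses.asdict(config).items()
                if isinstance(v, (str, int, float, list, type(None)))}
        (outdir / "run_info.json").write_text(json.dumps(
            {"config": echo, "params_hash": bundle.params_hash,
             "version": __version__, "n_failures": n_failures}, indent=2,
            default=str))
    return bundle


def expected_record_counts(config: ExperimentConfig) -> tuple[int, int]:
    """(performance, transport) record counts implied by the configuration."""
    n_models = len(config.algorithms) * len(config.schemes)
    eval_settings = len(config.settings) - 1          # all but train
    external = eval_settings - 1                      # all but internal
    return (config.repetitions * n_models * eval_settings,
            config.repetitions * n_models * external)


# -- reporting -------------------------------------------------------------

def report(bundle: ResultBundle, outdir, plots: bool = True) -> pd.DataFrame:
    """Summary tables (median [p2.5, p97.5] per cell) and density plots."""
    if len(bundle.performance) == 0:
        raise PipelineError("empty result bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = pd.concat([bundle.performance_summary,
                         bundle.transport_summary], ignore_index=True)
    summary.to_csv(outdir / "summary.csv", index=False)
    if plots:
        _density_plots(bundle.performance, outdir, "performance")
        _density_plots(bundle.transport, outdir, "transport")
    return summary


def _density_plots(df: pd.DataFrame, outdir: Path, stem: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    metrics = [c for c in df.columns
               if c not in ("algorithm", "scheme", "setting", "repetition")]
    settings = list(dict.fromkeys(df["setting"]))
    for metric in metrics:
        fig, axes = plt.subplots(1, len(settings),
                                 figsize=(3.2 * len(settings), 3.0),
                                 sharex=True, squeeze=False)
        for ax, setting in zip(axes[0], settings):
            sub = df[df["setting"] == setting]
            for (algorithm, scheme), grp in sub.groupby(["algorithm", "scheme"]):
                vals = grp[metric].to_numpy(dtype=float)
                med = np.median(vals)
                if len(vals) > 2 and np.ptp(vals) > 0:
                    kde = gaussian_kde(vals)
                    xs = np.linspace(vals.min(), vals.max(), 200)
                    ax.plot(xs, kde(xs), label=f"{algorithm}/{scheme}", lw=1)
                ax.plot([med], [0], marker="D", ms=4, clip_on=False)
            ax.set_title(setting, fontsize=9)
            ax.set_xlabel(metric, fontsize=8)
        axes[0, 0].set_ylabel("density", fontsize=8)
        if axes[0, -1].get_legend_handles_labels()[0]:
            axes[0, -1].legend(fontsize=6, frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / f"{stem}_{metric}.png", dpi=120)
        plt.close(fig)
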