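"""Semi-synthetic cohort generation: exogenous sampling + forward simulation.

Exogenous variables are drawn either by bootstrapping rows of a source table
(preserving their joint distribution) or from parametric marginals.
Endogenous variables are then simulated in topological order from the
structural equations.  External settings are declared as interventions:

* ``replace_exogenous`` — redraw one exogenous variable from a normal
  distribution (natural-scale specs are converted to the z-scale with the
  parameter set's normalization info);
* ``set_prevalence`` — redraw one binary exogenous variable from a Bernoulli;
* ``override_mechanism`` — swap intercept/coefficients of one structural
  equation before simulation (the parameter set itself is never mutated).

Seeding: every cohort draws from ``numpy.random.default_rng`` seeded by a
``SeedSequence``; the experiment engine derives per-setting, per-repetition
sub-seeds as ``SeedSequence(master, spawn_key=(repetition, setting_index))``
so any single cohort is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, as_frame
from .graph import CausalGraph
from .sem import SemParameterSet


class GenerationError(ValueError):
    pass


class InterventionError(GenerationError):
    pass


# -- exogenous sources -----------------------------------------------------

@dataclass
class ExogenousSource:
    """Bootstrap table and/or parametric marginals for exogenous variables.

    ``table`` rows are resampled with replacement (jointly by default,
    per-column when ``joint=False``).  ``parametric`` maps variable ->
    ``{"dist": "normal", "mean": m, "sd": s}`` or
    ``{"dist": "bernoulli", "p": p}`` and overrides the table column.
    """

    table: pd.DataFrame | None = None
    parametric: dict[str, dict] = field(default_factory=dict)
    joint: bool = True

    def __post_init__(self):
        if self.table is not None:
            self.table = as_frame(self.table)
            if len(self.table) == 0:
                raise GenerationError("bootstrap table is empty")
        for var, spec in self.parametric.items():
            _check_parametric(var, spec)
        if self.table is None and not self.parametric:
            raise GenerationError("exogenous source is empty")

    @property
    def variables(self) -> list[str]:
        cols = list(self.table.columns) if self.table is not None else []
        cols += [v for v in self.parametric if v not in cols]
        return cols


def _check_parametric(var: str, spec: dict) -> None:
    dist = spec.get("dist")
    if dist == "normal":
        if not spec.get("sd", 0) > 0:
            raise GenerationError(f"{var!r}: normal sd must be > 0")
    elif dist == "bernoulli":
        if not 0 < spec.get("p", -1) < 1:
            raise GenerationError(f"{var!r}: prevalence must be in (0,1)")
    else:
        raise GenerationError(f"{var!r}: unknown distribution {dist!r}")


def _draw_parametric(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec["dist"] == "normal":
        return rng.normal(spec["mean"], spec["sd"], size=n)
    return (rng.random(n) < spec["p"]).astype(float)


def sample_exogenous(source: ExogenousSource, n: int, seed) -> CohortTable:
    """Draw n exogenous rows; reproducible given the seed."""
    if n <= 0:
        raise GenerationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    if source.table is not None:
        if source.joint:
            idx = rng.integers(0, len(source.table), size=n)
            boot = source.table.iloc[idx].reset_index(drop=True)
            for c in source.table.columns:
                cols[c] = boot[c].to_numpy(dtype=float)
        else:
            for c in source.table.columns:
                idx = rng.integers(0, len(source.table), size=n)
                cols[c] = source.table[c].to_numpy(dtype=float)[idx]
    for var, spec in source.parametric.items():
        cols[var] = _draw_parametric(spec, n, rng)
    return CohortTable(pd.DataFrame(cols), scale="z")


# -- interventions ---------------------------------------------------------

@dataclass
class InterventionSpec:
    """Declarative description of how an external setting differs.

    kind="replace_exogenous": variable, mean, sd, scale ("natural" or "z")
    kind="set_prevalence":    variable, p
    kind="override_mechanism": target, intercept (optional), coefficients
        (optional partial mapping parent -> new value)
    """

    kind: str
    variable: str | None = None
    mean: float | None = None
    sd: float | None = None
    scale: str = "natural"
    p: float | None = None
    target: str | None = None
    intercept: float | None = None
    coefficients: dict[str, float] = field(default_factory=dict)

    def validate(self, graph: CausalGraph) -> None:
        if self.kind == "replace_exogenous":
            if self.variable not in graph.node_names:
                raise InterventionError(f"unknown variable {self.variable!r}")
            if graph.role(self.variable) != "exogenous":
                raise InterventionError(
                    f"replace_exogenous targets non-exogenous {self.variable!r}")
            if self.sd is None or not self.sd > 0:
                raise InterventionError("replace_exogenous needs sd > 0")
            if self.scale not in ("natural", "z"):
                raise InterventionError(f"unknown scale {self.scale!r}")
        elif self.kind == "set_prevalence":
            if self.variable not in graph.node_names:
                raise InterventionError(f"unknown variable {self.variable!r}")
            if graph.role(self.variable) != "exogenous":
                raise InterventionError(
                    f"set_prevalence targets non-exogenous {self.variable!r}")
            if self.p is None or not 0 < self.p < 1:
                raise InterventionError("prevalence must be in (0,1)")
        elif self.kind == "override_mechanism":
            if self.target not in graph.node_names:
                raise InterventionError(f"unknown target {self.target!r}")
            if graph.role(self.target) != "endogenous":
                raise InterventionError(
                    f"override_mechanism targets exogenous {self.target!r}")
            parents = set(graph.parents(self.target))
            bad = set(self.coefficients) - parents
            if bad:
                raise InterventionError(
                    f"override of non-parent coefficients {sorted(bad)} "
                    f"for {self.target!r}")
        else:
            raise InterventionError(f"unknown intervention kind {self.kind!r}")


def replace_exogenous(variable, mean, sd, scale="natural") -> InterventionSpec:
    return InterventionSpec("replace_exogenous", variable=variable,
                            mean=mean, sd=sd, scale=scale)


def set_prevalence(variable, p) -> InterventionSpec:
    return InterventionSpec("set_prevalence", variable=variable, p=p)


def override_mechanism(target, intercept=None, coefficients=None) -> InterventionSpec:
    return InterventionSpec("override_mechanism", target=target,
                            intercept=intercept,
                            coefficients=dict(coefficients or {}))


# -- forward simulation ----------------------------------------------------

def generate_cohort(graph: CausalGraph, params: SemParameterSet,
                    exo: ExogenousSource, n: int, seed,
                    interventions=(), setting: str = "") -> CohortTable:
    """Simulate a full cohort on the z-scale.

    Exogenous columns come from :func:`sample_exogenous`; exogenous
    interventions substitute the named variable's draws; mechanism overrides
    act on a private copy of the equations.  Endogenous nodes are computed in
    topological order: continuous y = lp + N(0, residual_sd); binary y = 1 iff
    lp + e > 0 with standard-normal (or standard-logistic) e.
    """
    params.validate_against(graph)
    for iv in interventions:
        iv.validate(graph)
    equations = {t: eq.copy() for t, eq in params.equations.items()}
    rng = np.random.default_rng(seed)
    cohort = sample_exogenous(exo, n, rng)
    df = cohort.data
    missing = [v for v in graph.exogenous if v not in df.columns]
    if missing:
        raise GenerationError(f"exogenous source lacks variables {missing}")

    for iv in interventions:
        if iv.kind == "replace_exogenous":
            mean, sd = iv.mean, iv.sd
            if iv.scale == "natural":
                if iv.variable not in params.normalization:
                    raise InterventionError(
                        f"no normalization info for {iv.variable!r}; cannot "
                        "convert a natural-scale intervention to the z-scale")
                nat_mean, nat_sd = params.normalization.stats[iv.variable]
                mean = (mean - nat_mean) / nat_sd
                sd = sd / nat_sd
            df[iv.variable] = rng.normal(mean, sd, size=n)
        elif iv.kind == "set_prevalence":
            df[iv.variable] = (rng.random(n) < iv.p).astype(float)
        else:  # override_mechanism
            eq = equations[iv.target]
            if iv.intercept is not None:
                eq.intercept = iv.intercept
            eq.coefficients.update(iv.coefficients)

    for node in graph.topological_order():
        if graph.role(node) == "exogenous":
            continue
        eq = equations[node]
        lp = eq.linear_predictor(df)
        if eq.link == "identity":
            df[node] = lp + rng.normal(0.0, eq.residual_sd, size=n)
        elif eq.link == "latent_normal":
            df[node] = (lp + rng.standard_normal(n) > 0).astype(float)
        else:  # latent_logistic
            df[node] = (lp + rng.logistic(0.0, 1.0, size=n) > 0).astype(float)

    df = df[[v for v in graph.node_names if v in df.columns]
            + [c for c in df.columns if c not in graph.node_names]]
    return CohortTable(df, setting=setting,
                       seed=seed if isinstance(seed, int) else None, scale="z")


# -- the six study settings ------------------------------------------------

def setting_seed(master_seed: int, repetition: int, setting_index: int):
    """Counter-based sub-seed: SeedSequence(master, spawn_key=(rep, idx))."""
    return np.random.SeedSequence(master_seed,
                                  spawn_key=(repetition, setting_index))


def build_study_settings(graph: CausalGraph, params: SemParameterSet,
                         exo: ExogenousSource, settings: dict,
                         n: int = 10_000, master_seed: int = 0,
                         repetition: int = 0) -> dict[str, CohortTable]:
    """Generate one cohort per named setting with deterministic sub-seeds.

    ``settings`` maps label -> list of InterventionSpec (empty for train and
    internal validation, which share the mechanism but not random draws).
    """
    labels = list(settings)
    if len(set(labels)) != len(labels):
        raise GenerationError("duplicate setting labels")
    out: dict[str, CohortTable] = {}
    for idx, (label, interventions) in enumerate(settings.items()):
        seed = setting_seed(master_seed, repetition, idx)
        out[label] = generate_cohort(graph, params, exo, n, seed,
                                     interventions=interventions, setting=label)
    return out
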