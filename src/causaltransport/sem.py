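"""Structural-equation parameter sets: estimation, persistence, normalization.

One equation per endogenous node.  Continuous targets are linear-Gaussian
(least squares on the parents, residual standard deviation from the
residuals).  Binary targets use a latent-variable threshold link: the latent
score is intercept + sum(beta * parent) + e with e ~ N(0,1) (probit,
``latent_normal``) or standard-logistic e (``latent_logistic``), and the event
occurs when the latent score exceeds zero.  The estimator is equation-by-
equation, which for a recursive system with independent errors targets the
same structural coefficients as a system-wide fit.

All continuous variables are assumed z-normalized before estimation;
:class:`NormalizationInfo` carries the natural-unit means and standard
deviations so cohorts and intervention values can be mapped between scales.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as smapi

from .cohort import CohortTable, as_frame
from .graph import CausalGraph

LINKS = ("identity", "latent_normal", "latent_logistic")


class SemError(ValueError):
    pass


class ZeroVarianceError(SemError):
    pass


class EstimationError(SemError):
    pass


class ParameterFileError(SemError):
    """Schema violation in a parameter file; message carries the location."""


# -- normalization ---------------------------------------------------------

@dataclass
class NormalizationInfo:
    """Natural-unit mean and sd per continuous variable (sample-sd, ddof=1)."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for var, (_, sd) in self.stats.items():
            if not sd > 0:
                raise ZeroVarianceError(f"variable {var!r} has sd {sd} <= 0")

    def to_z(self, var: str, value):
        mean, sd = self.stats[var]
        return (np.asarray(value) - mean) / sd

    def from_z(self, var: str, value):
        mean, sd = self.stats[var]
        return np.asarray(value) * sd + mean

    def __contains__(self, var):
        return var in self.stats

    def __eq__(self, other):
        return isinstance(other, NormalizationInfo) and self.stats == other.stats


def _continuous_columns(df: pd.DataFrame, graph=None, binary=None) -> list[str]:
    if graph is not None:
        return [c for c in df.columns
                if c in graph.node_names and graph.kind(c) == "continuous"]
    if binary is not None:
        return [c for c in df.columns if c not in set(binary)]
    out = []
    for c in df.columns:
        vals = np.unique(np.asarray(df[c], dtype=float))
        if not np.isin(vals, (0.0, 1.0)).all():
            out.append(c)
    return out


def znormalize(data, graph=None, binary=None):
    """Z-transform continuous columns; returns (z-scale cohort, info).

    Continuous columns are identified from the graph's node kinds when one is
    given, from an explicit ``binary`` column list otherwise, or by falling
    back to "not 0/1-valued".  Binary columns are left untouched.
    """
    df = as_frame(data).copy()
    stats_map: dict[str, tuple[float, float]] = {}
    for c in _continuous_columns(df, graph, binary):
        col = np.asarray(df[c], dtype=float)
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        if sd == 0:
            raise ZeroVarianceError(f"column {c!r} has zero variance")
        df[c] = (col - mean) / sd
        stats_map[c] = (mean, sd)
    info = NormalizationInfo(stats_map)
    if isinstance(data, CohortTable):
        out = CohortTable(df, data.setting, data.seed, "z", dict(data.extra))
    else:
        out = CohortTable(df, scale="z")
    return out, info


def denormalize(data, info: NormalizationInfo):
    """Invert :func:`znormalize` for the variables recorded in ``info``."""
    df = as_frame(data).copy()
    for c in df.columns:
        if c in info:
            df[c] = info.from_z(c, np.asarray(df[c], dtype=float))
    if isinstance(data, CohortTable):
        return CohortTable(df, data.setting, data.seed, "natural", dict(data.extra))
    return CohortTable(df, scale="natural")


# -- equations -------------------------------------------------------------

@dataclass
class EquationSpec:
    """Structural equation for one endogenous node (z-scale)."""

    target: str
    intercept: float
    coefficients: dict[str, float]
    residual_sd: float | None = None   # continuous targets only
    link: str = "identity"             # identity | latent_normal | latent_logistic

    def __post_init__(self):
        if self.link not in LINKS:
            raise SemError(f"unknown link {self.link!r} for {self.target!r}")
        if self.link == "identity":
            if self.residual_sd is None or not self.residual_sd >= 0:
                raise SemError(
                    f"continuous equation for {self.target!r} needs residual_sd >= 0")
        elif self.residual_sd is not None:
            raise SemError(
                f"binary equation for {self.target!r} must not set residual_sd")

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(df), self.intercept, dtype=float)
        for parent, beta in self.coefficients.items():
            lp += beta * np.asarray(df[parent], dtype=float)
        return lp

    def copy(self) -> "EquationSpec":
        return replace(self, coefficients=dict(self.coefficients))


@dataclass
class SemParameterSet:
    """All structural equations for a DAG plus normalization metadata."""

    graph_hash: str
    equations: dict[str, EquationSpec]
    normalization: NormalizationInfo = field(default_factory=NormalizationInfo)
    provenance: str = "unspecified"

    def validate_against(self, graph: CausalGraph) -> None:
        if self.graph_hash != graph.graph_hash():
            raise SemError("parameter set was built for a different graph "
                           f"(hash {self.graph_hash} != {graph.graph_hash()})")
        endo = set(graph.endogenous)
        for target, eq in self.equations.items():
            loc = f"equations/{target}"
            if target != eq.target:
                raise ParameterFileError(f"{loc}: target mismatch")
            if target not in endo:
                raise ParameterFileError(
                    f"{loc}: equation for exogenous or unknown node {target!r}")
            parents = set(graph.parents(target))
            keys = set(eq.coefficients)
            if keys != parents:
                raise ParameterFileError(
                    f"{loc}/coefficients: keys {sorted(keys)} do not match "
                    f"parents {sorted(parents)}")
            want_binary = graph.kind(target) == "binary"
            if want_binary and eq.link == "identity":
                raise ParameterFileError(f"{loc}: binary node needs a latent link")
            if not want_binary and eq.link != "identity":
                raise ParameterFileError(f"{loc}: continuous node needs identity link")
        missing = endo - set(self.equations)
        if missing:
            raise ParameterFileError(f"equations: missing for {sorted(missing)}")

    def copy(self) -> "SemParameterSet":
        return SemParameterSet(self.graph_hash,
                               {t: eq.copy() for t, eq in self.equations.items()},
                               NormalizationInfo(dict(self.normalization.stats)),
                               self.provenance)

    def __eq__(self, other):
        if not isinstance(other, SemParameterSet):
            return NotImplemented
        return (self.graph_hash == other.graph_hash
                and self.equations == other.equations
                and self.normalization == other.normalization
                and self.provenance == other.provenance)


# -- estimation ------------------------------------------------------------

def fit_sem(data, graph: CausalGraph, binary_link: str = "latent_normal",
            normalization: NormalizationInfo | None = None) -> SemParameterSet:
    """Estimate one structural equation per endogenous node.

    ``data`` must be on the z-scale.  Continuous nodes: ordinary least
    squares; residual sd uses ddof = n - p - 1.  Binary nodes: probit
    (``latent_normal``) or logit (``latent_logistic``) maximum likelihood,
    matching the generator's latent-threshold convention.
    """
    df = as_frame(data)
    missing = [v for v in graph.node_names if v not in df.columns]
    if missing:
        raise SemError(f"data lacks graph variables {missing}")
    total_parents = sum(len(graph.parents(v)) for v in graph.endogenous)
    if len(df) <= total_parents + 10:
        raise SemError(f"need n > total parent count + 10 = {total_parents + 10}")
    equations: dict[str, EquationSpec] = {}
    for target in graph.endogenous:
        parents = graph.parents(target)
        y = np.asarray(df[target], dtype=float)
        X = df[parents].to_numpy(dtype=float)
        Xd = np.column_stack([np.ones(len(y)), X])
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise EstimationError(
                f"singular design for {target!r}; collinear parents among {parents}")
        if graph.kind(target) == "continuous":
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            resid = y - Xd @ beta
            dof = max(len(y) - Xd.shape[1], 1)
            sd = float(np.sqrt(np.sum(resid**2) / dof))
            equations[target] = EquationSpec(
                target, float(beta[0]),
                dict(zip(parents, map(float, beta[1:]))), residual_sd=sd)
        else:
            model_cls = smapi.Probit if binary_link == "latent_normal" else smapi.Logit
            try:
                res = model_cls(y, Xd).fit(disp=0, maxiter=200)
            except Exception as exc:  # separation, singular hessian, ...
                raise EstimationError(
                    f"latent-threshold fit failed for binary node {target!r}: {exc}")
            if not res.mle_retvals.get("converged", True):
                raise EstimationError(
                    f"latent-threshold fit did not converge for {target!r}")
            beta = np.asarray(res.params, dtype=float)
            equations[target] = EquationSpec(
                target, float(beta[0]),
                dict(zip(parents, map(float, beta[1:]))), link=binary_link)
    norm = normalization or NormalizationInfo()
    return SemParameterSet(graph.graph_hash(), equations, norm, provenance="fitted")


# -- persistence (JSON) ----------------------------------------------------

def write_parameters(params: SemParameterSet, path) -> None:
    payload = {
        "graph_hash": params.graph_hash,
        "provenance": params.provenance,
        "normalization": {v: {"mean": m, "sd": s}
                          for v, (m, s) in params.normalization.stats.items()},
        "equations": [
            {"target": eq.target, "intercept": eq.intercept,
             "coefficients": dict(eq.coefficients),
             **({"residual_sd": eq.residual_sd} if eq.link == "identity"
                else {"link": eq.link})}
            for eq in params.equations.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_parameters(path, graph: CausalGraph | None = None) -> SemParameterSet:
    """Load a parameter file, optionally validating it against a graph."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParameterFileError(f"/: not valid JSON ({exc})")
    for key in ("graph_hash", "equations"):
        if key not in payload:
            raise ParameterFileError(f"/{key}: missing")
    norm_stats = {}
    for var, entry in payload.get("normalization", {}).items():
        loc = f"/normalization/{var}"
        if not isinstance(entry, dict) or "mean" not in entry or "sd" not in entry:
            raise ParameterFileError(f"{loc}: needs mean and sd")
        if not entry["sd"] > 0:
            raise ParameterFileError(f"{loc}/sd: must be > 0")
        norm_stats[var] = (float(entry["mean"]), float(entry["sd"]))
    equations: dict[str, EquationSpec] = {}
    for i, entry in enumerate(payload["equations"]):
        loc = f"/equations/{i}"
        for key in ("target", "intercept", "coefficients"):
            if key not in entry:
                raise ParameterFileError(f"{loc}/{key}: missing")
        target = entry["target"]
        if target in equations:
            raise ParameterFileError(f"{loc}/target: duplicate equation for {target!r}")
        link = entry.get("link", "identity")
        try:
            equations[target] = EquationSpec(
                target, float(entry["intercept"]),
                {k: float(v) for k, v in entry["coefficients"].items()},
                residual_sd=entry.get("residual_sd"), link=link)
        except SemError as exc:
            raise ParameterFileError(f"{loc}: {exc}")
    params = SemParameterSet(payload["graph_hash"], equations,
                             NormalizationInfo(norm_stats),
                             payload.get("provenance", "unspecified"))
    if graph is not None:
        params.validate_against(graph)
    return params
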