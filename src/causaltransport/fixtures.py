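"""Shipped study system: canonical DAG, default parameters, baseline cohort.

The 17-node graph covers demographic (age, sex, education), genetic (APOE
ε4 carriage), behavioral (smoking, alcohol-abuse history), clinical (BMI,
hypertension, cardiovascular history), biomarker (CSF tau and amyloid-β,
FDG-PET, hippocampal/ventricular/intracranial volumes) and cognitive (MMSE)
variables around the binary outcome ``cogn`` (cognitive impairment).  Its
parent/children/exogenous partitions define the four predictor schemes.

The default structural parameters carry the published point estimates where
such estimates exist (age→tau 0.37, apoe4→tau 0.57, hypert→tau 0.14,
alc→tau 0.57, tau intercept -0.5, age→abeta -0.14, age→cogn -0.13,
age→hypert 0.11, age→cardio 0.13); every other number is an invented fixture
default (provenance="fixture") chosen so that the internal-setting outcome
prevalence is ~0.70 and z-scale variances stay near 1.

The baseline-cohort generator emulates the study's post-imputation baseline
table marginals (age median 73.9 IQR 69.2-78.9; APOE ε4 46.9%; male 55.1%;
outcome prevalence 69.9%; ...) with normal/Bernoulli marginals and optional
small Gaussian-copula dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .cohort import CohortTable
from .generate import (ExogenousSource, InterventionSpec, override_mechanism,
                       replace_exogenous, set_prevalence)
from .graph import CausalGraph, parse_graph
from .sem import EquationSpec, NormalizationInfo, SemParameterSet

#: plain-text canonical DAG; declaration order fixes every ordered query
CANONICAL_DAG_TEXT = """\
# Cognitive-impairment causal DAG (17 nodes).
# Node kinds
age : continuous
apoe4 : binary
sex : binary
educ : continuous
bmi : continuous
hypert : binary
alc : binary
smok : binary
cardio : binary
tau : continuous
abeta : continuous
cogn : binary
hippo : continuous
ventr : continuous
icv : continuous
fdg : continuous
mmse : continuous
outcome: cogn
# Demographics and behavior
age -> educ
sex -> educ
age -> smok
sex -> smok
age -> alc
sex -> alc
age -> bmi
sex -> bmi
educ -> bmi
# Vascular pathway
age -> hypert
bmi -> hypert
smok -> hypert
age -> cardio
hypert -> cardio
smok -> cardio
bmi -> cardio
# CSF biomarkers
age -> tau
apoe4 -> tau
hypert -> tau
alc -> tau
age -> abeta
apoe4 -> abeta
# Outcome and its direct causes
age -> cogn
apoe4 -> cogn
sex -> cogn
educ -> cogn
bmi -> cogn
cardio -> cogn
tau -> cogn
abeta -> cogn
# Consequences of cognitive status
cogn -> hippo
age -> hippo
icv -> hippo
cogn -> ventr
age -> ventr
icv -> ventr
cogn -> icv
sex -> icv
cogn -> fdg
age -> fdg
cogn -> mmse
age -> mmse
educ -> mmse
"""


def canonical_dag() -> CausalGraph:
    """The shipped 17-node DAG with outcome ``cogn``."""
    return parse_graph(CANONICAL_DAG_TEXT)


# -- baseline-table profile ------------------------------------------------

_IQR_TO_SD = 2 * spstats.norm.ppf(0.75)  # 1.349: normal IQR in sd units


@dataclass
class MarginalSpec:
    kind: str                        # continuous | binary
    median: float | None = None      # continuous, natural units
    iqr: tuple[float, float] | None = None
    mean: float | None = None        # alternative to median/iqr
    sd: float | None = None
    prevalence: float | None = None  # binary
    invented: bool = False           # not in the printed baseline table

    def moments(self) -> tuple[float, float]:
        if self.kind != "continuous":
            raise ValueError("moments only defined for continuous variables")
        mean = self.mean if self.mean is not None else self.median
        if self.sd is not None:
            sd = self.sd
        else:
            lo, hi = self.iqr
            if not hi > lo:
                raise ValueError("IQR bounds must be ordered")
            sd = (hi - lo) / _IQR_TO_SD
        return float(mean), float(sd)


@dataclass
class CohortProfile:
    """Marginal specs per variable plus optional pairwise dependence knobs."""

    variables: dict[str, MarginalSpec]
    dependence: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for name, spec in self.variables.items():
            if spec.kind == "binary" and not 0 < spec.prevalence < 1:
                raise ValueError(f"{name!r}: prevalence must be in (0,1)")


def default_profile() -> CohortProfile:
    """Baseline-table marginals; volumetric/FDG entries are invented."""
    v = {
        "age": MarginalSpec("continuous", median=73.9, iqr=(69.2, 78.9)),
        "apoe4": MarginalSpec("binary", prevalence=0.469),
        "sex": MarginalSpec("binary", prevalence=0.551),
        "educ": MarginalSpec("continuous", median=16.0, iqr=(14.0, 18.0)),
        "bmi": MarginalSpec("continuous", median=28.31, iqr=(25.5, 31.6)),
        "hypert": MarginalSpec("binary", prevalence=0.341),
        "alc": MarginalSpec("binary", prevalence=0.025),
        "smok": MarginalSpec("binary", prevalence=0.243),
        "cardio": MarginalSpec("binary", prevalence=0.678),
        "tau": MarginalSpec("continuous", median=257.8, iqr=(193.4, 349.7)),
        "abeta": MarginalSpec("continuous", median=854.2, iqr=(596.2, 1395.5)),
        "cogn": MarginalSpec("binary", prevalence=0.699),
        "hippo": MarginalSpec("continuous", mean=6700.0, sd=1050.0, invented=True),
        "ventr": MarginalSpec("continuous", mean=39000.0, sd=21000.0, invented=True),
        "icv": MarginalSpec("continuous", mean=1.53e6, sd=1.55e5, invented=True),
        "fdg": MarginalSpec("continuous", mean=1.21, sd=0.16, invented=True),
        "mmse": MarginalSpec("continuous", median=28.0, iqr=(25.0, 29.0)),
    }
    return CohortProfile(v)


def make_adni_like_cohort(profile: CohortProfile | None = None,
                          n: int = 1737, seed=0) -> CohortTable:
    """Synthetic baseline cohort (natural units) matching profile marginals.

    Continuous variables are normal (mean from the median, sd from IQR/1.349
    unless given directly); binaries are Bernoulli.  Dependence knobs induce
    Gaussian-copula correlation between the named latent pairs (default: all
    zero, i.e. independent marginals).  This emulates the analysis-ready
    baseline table only marginally -- it does not follow the causal graph.
    """
    profile = profile or default_profile()
    rng = np.random.default_rng(seed)
    names = list(profile.variables)
    k = len(names)
    corr = np.eye(k)
    for (a, b), rho in profile.dependence.items():
        ia, ib = names.index(a), names.index(b)
        corr[ia, ib] = corr[ib, ia] = rho
    if profile.dependence:
        latent = rng.multivariate_normal(np.zeros(k), corr, size=n,
                                         method="cholesky")
    else:
        latent = rng.standard_normal((n, k))
    cols = {}
    for j, name in enumerate(names):
        spec = profile.variables[name]
        if spec.kind == "continuous":
            mean, sd = spec.moments()
            cols[name] = mean + sd * latent[:, j]
        else:
            # event on high latent values, so dependence knobs keep their sign
            cols[name] = (latent[:, j] > spstats.norm.ppf(1 - spec.prevalence)
                          ).astype(float)
    return CohortTable(pd.DataFrame(cols), setting="baseline",
                       seed=seed if isinstance(seed, int) else None,
                       scale="natural")


# -- default structural parameters -----------------------------------------

def default_normalization(profile: CohortProfile | None = None) -> NormalizationInfo:
    profile = profile or default_profile()
    stats_map = {}
    for name, spec in profile.variables.items():
        if spec.kind == "continuous":
            stats_map[name] = spec.moments()
    return NormalizationInfo(stats_map)


def default_parameter_set(outcome_link: str = "latent_normal") -> SemParameterSet:
    """Complete z-scale parameter set for the canonical DAG.

    Published point estimates are used verbatim where they exist; every other
    value is an invented fixture default (see module docstring).

    ``outcome_link="latent_logistic"`` swaps the outcome equation to a
    standard-logistic latent residual with its coefficients rescaled by 1.7
    (the usual logit/probit scale factor), preserving the ~0.70 prevalence;
    useful when a correctly specified logistic-regression benchmark is
    wanted.
    """
    E = EquationSpec
    equations = {
        "educ": E("educ", 0.0, {"age": -0.10, "sex": 0.15}, residual_sd=0.95),
        "smok": E("smok", -0.72, {"age": -0.05, "sex": 0.15}, link="latent_normal"),
        "alc": E("alc", -2.00, {"age": -0.35, "sex": 0.10}, link="latent_normal"),
        "bmi": E("bmi", 0.0, {"age": -0.10, "sex": 0.10, "educ": -0.05},
                 residual_sd=0.98),
        "hypert": E("hypert", -0.45, {"age": 0.11, "bmi": 0.10, "smok": 0.10},
                    link="latent_normal"),
        "cardio": E("cardio", 0.35, {"age": 0.13, "hypert": 0.25, "smok": 0.10,
                                     "bmi": 0.05}, link="latent_normal"),
        "tau": E("tau", -0.50, {"age": 0.37, "apoe4": 0.57, "hypert": 0.14,
                                "alc": 0.57}, residual_sd=0.80),
        "abeta": E("abeta", 0.20, {"age": -0.14, "apoe4": -0.45},
                   residual_sd=0.90),
        "cogn": E("cogn", 0.48, {"age": -0.13, "apoe4": 0.60, "sex": 0.20,
                                 "educ": -0.20, "bmi": -0.10, "cardio": 0.15,
                                 "tau": 0.80, "abeta": -0.80},
                  link="latent_normal"),
        "icv": E("icv", 0.0, {"cogn": -0.10, "sex": 0.40}, residual_sd=0.90),
        "hippo": E("hippo", 0.0, {"cogn": -0.50, "age": -0.20, "icv": 0.30},
                   residual_sd=0.80),
        "ventr": E("ventr", 0.0, {"cogn": 0.40, "age": 0.30, "icv": 0.30},
                   residual_sd=0.85),
        "fdg": E("fdg", 0.0, {"cogn": -0.60, "age": -0.10}, residual_sd=0.80),
        "mmse": E("mmse", 0.0, {"cogn": -0.90, "age": -0.05, "educ": 0.10},
                  residual_sd=0.60),
    }
    if outcome_link == "latent_logistic":
        cogn = equations["cogn"]
        equations["cogn"] = E(
            "cogn", 1.7 * cogn.intercept,
            {k: 1.7 * v for k, v in cogn.coefficients.items()},
            link="latent_logistic")
    elif outcome_link != "latent_normal":
        raise ValueError(f"unknown outcome link {outcome_link!r}")
    return SemParameterSet(canonical_dag().graph_hash(), equations,
                           default_normalization(), provenance="fixture")


def default_exogenous_source(n: int = 1737, seed: int = 20230819,
                             params: SemParameterSet | None = None) -> ExogenousSource:
    """Bootstrap source: z-scored exogenous columns of a baseline cohort."""
    params = params or default_parameter_set()
    graph = canonical_dag()
    cohort = make_adni_like_cohort(n=n, seed=seed)
    df = cohort.data[graph.exogenous].copy()
    for c in df.columns:
        if c in params.normalization:
            df[c] = params.normalization.to_z(c, df[c].to_numpy())
    return ExogenousSource(table=df, joint=True)


# -- the four published external settings ----------------------------------

def standard_interventions() -> dict[str, list[InterventionSpec]]:
    """Interventions defining the six study settings.

    age: mean age 73.9 -> 35 (sd 10, natural scale); age2: -> 65; apoe4:
    carriage prevalence 46.9% -> 5%; tau: new tau mechanism (intercept
    -0.5 -> 0.9, age 0.37 -> 0.9, apoe4 0.57 -> 0.8, hypert 0.14 -> 0.9,
    alc 0.57 -> 0.001).
    """
    return {
        "train": [],
        "internal": [],
        "age": [replace_exogenous("age", 35.0, 10.0, scale="natural")],
        "age2": [replace_exogenous("age", 65.0, 10.0, scale="natural")],
        "apoe4": [set_prevalence("apoe4", 0.05)],
        "tau": [override_mechanism("tau", intercept=0.9,
                                   coefficients={"age": 0.9, "apoe4": 0.8,
                                                 "hypert": 0.9, "alc": 0.001})],
    }
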