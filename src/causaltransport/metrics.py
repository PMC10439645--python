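"""Transportability metrics: calibration (ICI, Brier decomposition), AUC,
internal-minus-external deltas, and percentile aggregation.

Sign conventions follow the transport-delta definition delta = internal -
external: a negative calibration delta (external ICI/reliability larger) and a
positive AUC delta (external AUC smaller) both mean degraded external
performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)


class MetricError(ValueError):
    pass


class UndefinedAUCError(MetricError):
    pass


@dataclass
class PredictionSet:
    """Predicted event probabilities with observed binary outcomes."""

    probabilities: np.ndarray
    outcomes: np.ndarray
    setting: str = ""

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if self.probabilities.shape != self.outcomes.shape:
            raise MetricError("probabilities and outcomes differ in length")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise MetricError("probabilities outside [0,1]")
        if not np.isin(np.unique(self.outcomes), (0.0, 1.0)).all():
            raise MetricError("outcomes must be 0/1")

    @property
    def n(self) -> int:
        return len(self.outcomes)

    def both_classes(self) -> bool:
        return 0.0 < self.outcomes.mean() < 1.0


def _unpack(pred) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pred, PredictionSet):
        return pred.probabilities, pred.outcomes
    p, y = pred
    return np.asarray(p, dtype=float), np.asarray(y, dtype=float)


# -- integrated calibration index ------------------------------------------

def ici(pred, span: float = 0.75) -> float:
    """Mean |predicted - smoothed observed frequency|.

    The smoother is local linear regression of the binary outcome on the
    predicted probability with tricube weights over a window containing
    ``span`` of the data; smoothed values are clipped to [0,1].  If all
    predictions coincide the smoother is degenerate and the ICI reduces to
    |mean prediction - event rate|.
    """
    p, y = _unpack(pred)
    if np.ptp(p) < 1e-12:
        return float(abs(p.mean() - y.mean()))
    # interpolation grid for the smoother at large n; the calibration curve
    # is smooth, so anchors every 1% of the range change the ICI by < 1e-5
    delta = 0.01 * np.ptp(p) if len(p) > 5000 else 0.0
    smoothed = lowess(y, p, frac=span, it=0, delta=delta, return_sorted=False)
    smoothed = np.clip(smoothed, 0.0, 1.0)
    return float(np.mean(np.abs(p - smoothed)))


# -- Brier score decomposition ---------------------------------------------

@dataclass
class BrierComponents:
    """Murphy decomposition with small-sample bias corrections.

    The decomposition applies to the binned forecasts (each forecast replaced
    by its bin mean): ``brier`` is the score of those binned forecasts, and
    the uncorrected components satisfy REL - RES + UNC = brier exactly.
    ``brier_raw`` is the unbinned mean squared error; it differs from
    ``brier`` by the within-bin forecast variance/covariance terms.  The
    corrected reliability may be slightly negative; it is reported as
    computed.
    """

    reliability: float
    resolution: float
    uncertainty: float
    brier: float
    reliability_uncorrected: float
    resolution_uncorrected: float
    uncertainty_uncorrected: float
    brier_raw: float
    n_bins: int
    n_merged: int


def quantile_bin_edges(p: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile bin edges of the predictions in 1/n_bins steps."""
    return np.quantile(p, np.linspace(0.0, 1.0, n_bins + 1))


def brier_decomposition(pred, n_bins: int = 10) -> BrierComponents:
    """Three-way Brier decomposition over quantile bins of the predictions.

    Forecasts are grouped into quantile bins (ties at a bin edge fall to the
    lower bin); bins left with <= 1 member are merged into their neighbor so
    the within-bin variance needed by the bias correction exists.
    """
    p, y = _unpack(pred)
    N = len(p)
    if N < n_bins:
        raise MetricError(f"need n >= {n_bins} observations, got {N}")
    edges = quantile_bin_edges(p, n_bins)
    inner = np.unique(edges[1:-1])
    idx = np.searchsorted(inner, p, side="left")  # == edge -> lower bin
    order = np.unique(idx)
    counts = np.array([(idx == b).sum() for b in order])
    pbar = np.array([p[idx == b].mean() for b in order])
    obar = np.array([y[idx == b].mean() for b in order])

    n_merged = 0
    while (counts <= 1).any() and len(counts) > 1:
        b = int(np.argmin(counts))
        nb = b - 1 if b > 0 else b + 1
        log.warning("merging singleton forecast bin %d into neighbor %d", b, nb)
        tot = counts[b] + counts[nb]
        pbar[nb] = (pbar[b] * counts[b] + pbar[nb] * counts[nb]) / tot
        obar[nb] = (obar[b] * counts[b] + obar[nb] * counts[nb]) / tot
        counts[nb] = tot
        counts = np.delete(counts, b)
        pbar = np.delete(pbar, b)
        obar = np.delete(obar, b)
        n_merged += 1

    obar_all = y.mean()
    rel = float(np.sum(counts * (pbar - obar) ** 2) / N)
    res = float(np.sum(counts * (obar - obar_all) ** 2) / N)
    unc = float(obar_all * (1.0 - obar_all))
    # score of the binned forecasts: the quantity the components decompose
    brier = float(np.sum(counts * (pbar - obar) ** 2
                         + counts * obar * (1.0 - obar)) / N)
    brier_raw = float(np.mean((p - y) ** 2))

    # within-bin sampling-noise corrections (each bin now has >= 2 members
    # unless the whole sample collapsed to one bin of size 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        within = np.where(counts > 1,
                          counts * obar * (1.0 - obar) / np.maximum(counts - 1, 1),
                          0.0)
    bin_term = float(np.sum(within) / N)
    global_term = unc / (N - 1) if N > 1 else 0.0
    rel_c = rel - bin_term
    res_c = res - bin_term + global_term
    unc_c = unc + global_term
    return BrierComponents(rel_c, res_c, unc_c, brier, rel, res, unc,
                           brier_raw, n_bins=len(counts), n_merged=n_merged)


# -- discrimination --------------------------------------------------------

def auc(pred) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied) / (n1 * n0)."""
    p, y = _unpack(pred)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC undefined with a single outcome class")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# -- records and deltas ----------------------------------------------------

@dataclass
class PerformanceRecord:
    algorithm: str
    scheme: str
    setting: str
    repetition: int
    ici: float
    brier_reliability: float
    brier_resolution: float
    brier_uncertainty: float
    brier: float
    auc: float


@dataclass
class TransportRecord:
    algorithm: str
    scheme: str
    setting: str           # the external setting
    repetition: int
    delta_ici: float
    delta_brier: float
    delta_auc: float


def evaluate_predictions(pred: PredictionSet, algorithm: str, scheme: str,
                         repetition: int, span: float = 0.75,
                         n_bins: int = 10) -> PerformanceRecord:
    """All metrics for one prediction set."""
    comp = brier_decomposition(pred, n_bins=n_bins)
    return PerformanceRecord(algorithm, scheme, pred.setting, repetition,
                             ici(pred, span=span), comp.reliability,
                             comp.resolution, comp.uncertainty, comp.brier,
                             auc(pred))


def transport_delta(internal: PerformanceRecord,
                    external: PerformanceRecord) -> TransportRecord:
    """internal - external for each metric (paired within a repetition)."""
    key_i = (internal.algorithm, internal.scheme, internal.repetition)
    key_e = (external.algorithm, external.scheme, external.repetition)
    if key_i != key_e:
        raise MetricError(f"cannot pair records {key_i} and {key_e}")
    if internal.setting == external.setting:
        raise MetricError("internal and external settings must differ")
    return TransportRecord(
        internal.algorithm, internal.scheme, external.setting,
        internal.repetition,
        delta_ici=internal.ici - external.ici,
        delta_brier=internal.brier_reliability - external.brier_reliability,
        delta_auc=internal.auc - external.auc)


# -- aggregation -----------------------------------------------------------

_GROUP_KEYS = ["algorithm", "scheme", "setting"]


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if not records:
        raise MetricError("no records to aggregate")
    cols = [f.name for f in dc_fields(records[0])]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records],
                        columns=cols)


def aggregate(records) -> pd.DataFrame:
    """Median and 2.5/97.5 empirical percentiles per group and metric.

    Quantiles use linear interpolation (numpy default, R type-7).  Returns a
    tidy frame: algorithm, scheme, setting, metric, median, p2_5, p97_5,
    n_reps.
    """
    df = records_to_frame(records)
    metric_cols = [c for c in df.columns
                   if c not in _GROUP_KEYS + ["repetition"]]
    long = df.melt(id_vars=[k for k in _GROUP_KEYS if k in df.columns],
                   value_vars=metric_cols, var_name="metric")
    keys = [k for k in _GROUP_KEYS if k in df.columns] + ["metric"]
    rows = []
    for group, sub in long.groupby(keys, sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        if len(vals) == 0:
            log.warning("empty group %s skipped", group)
            continue
        rows.append([*group, float(np.median(vals)),
                     float(np.quantile(vals, 0.025)),
                     float(np.quantile(vals, 0.975)), len(vals)])
    return pd.DataFrame(rows, columns=keys + ["median", "p2_5", "p97_5", "n_reps"])
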