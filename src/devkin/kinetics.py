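"""Sigmoidal activation model for zygotic genes and initiation-time estimation.

The activation curve of a zygotic gene is modelled on the log scale as

    log(mRNA(t)) = a - b / (1 + exp(c * (t - t_i)))

where ``a`` is the final log-expression level, ``b`` the total rise above the
basal level ``a - b``, ``c`` the slope and ``t_i`` the initiation (half-rise)
time: the curve passes through ``a - b/2`` at ``t = t_i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from devkin.io import MAX_NA_FRACTION, ExpressionMatrix

logger = logging.getLogger(__name__)

#: Minimum fitted rise (natural-log units, ~1.65-fold) to call a gene activated.
DEFAULT_RISE_THRESHOLD = 0.5

#: Slope starts of the deterministic initialization grid.
_C_STARTS = (0.3, 1.0, 3.0)
#: Window quantiles used as half-rise-time starts (3 slopes x 4 = 12 starts).
_TI_START_QUANTILES = (0.2, 0.4, 0.6, 0.8)

_RSS_TIE_TOL = 1e-9


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of one gene's activation curve in one species."""

    a: float
    b: float
    c: float
    t_i: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_i):
            raise ValueError("t_i must be finite")

    @property
    def basal(self) -> float:
        """The t -> -inf asymptote ``a - b``."""
        return self.a - self.b


@dataclass(frozen=True)
class FitReport:
    """Outcome of fitting one gene's time course.

    ``params`` is populated only for the ``activated`` classification.
    """

    params: SigmoidParams | None
    rss: float
    converged: bool
    classification: str  # activated | flat | decaying | unfit

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")
        if (self.classification == "activated") != (self.params is not None):
            raise ValueError("params must be present iff classification is 'activated'")


def sigmoid_eval(params: SigmoidParams, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the activation curve on the log scale. Total function of finite t."""
    t = np.asarray(t, dtype=float)
    z = np.clip(params.c * (t - params.t_i), -700.0, 700.0)
    out = params.a - params.b / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c, t_i = theta
    z = np.clip(c * (t - t_i), -700.0, 700.0)
    return a - b / (1.0 + np.exp(z)) - y


def _jacobian(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c, t_i = theta
    z = np.clip(c * (t - t_i), -700.0, 700.0)
    ez = np.exp(z)
    sig = 1.0 / (1.0 + ez)  # d(-b*sig)/dz = b*ez*sig^2
    bump = b * ez * sig * sig
    jac = np.empty((t.size, 4))
    jac[:, 0] = 1.0
    jac[:, 1] = -sig
    jac[:, 2] = bump * (t - t_i)
    jac[:, 3] = -bump * c
    return jac


def _multistart_fit(
    t: np.ndarray, y: np.ndarray, sign: float
) -> tuple[np.ndarray, float, bool]:
    """Best-of-12 bounded least-squares fit; ``sign`` constrains the slope sign.

    Deterministic: fixed start grid, lowest RSS wins, ties broken by smaller t_i.
    """
    t_lo, t_hi = float(t.min()), float(t.max())
    span = t_hi - t_lo
    a0 = float(y.max())
    b0 = max(float(np.ptp(y)), 1e-3)
    if sign > 0:
        c_bounds = (1e-6, np.inf)
        c_starts = _C_STARTS
    else:
        c_bounds = (-np.inf, -1e-6)
        c_starts = tuple(-c for c in _C_STARTS)
    lower = [-np.inf, 0.0, c_bounds[0], t_lo - 5.0 * max(span, 1.0)]
    upper = [np.inf, np.inf, c_bounds[1], t_hi + 5.0 * max(span, 1.0)]

    best_theta, best_rss, best_ok = None, np.inf, False
    for c0 in c_starts:
        for q in _TI_START_QUANTILES:
            ti0 = t_lo + q * span
            try:
                sol = least_squares(
                    _residuals,
                    x0=np.array([a0, b0, c0, ti0]),
                    jac=_jacobian,
                    bounds=(lower, upper),
                    args=(t, y),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            rss = float(2.0 * sol.cost)
            better = rss < best_rss - _RSS_TIE_TOL or (
                abs(rss - best_rss) <= _RSS_TIE_TOL
                and best_theta is not None
                and sol.x[3] < best_theta[3]
            )
            if best_theta is None or better:
                best_theta, best_rss, best_ok = sol.x, rss, bool(sol.success)
        if best_rss < 1e-14 * t.size:  # essentially exact fit; remaining starts moot
            break
    return best_theta, best_rss, best_ok


def fit_sigmoid(
    t: Sequence[float],
    y: Sequence[float],
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
) -> FitReport:
    """Fit the four-parameter activation curve to a log-expression time course.

    Replicates are passed as repeated ``(t, y)`` points. Requires at least 5
    distinct time points. Classification:

    - ``activated``: fitted rise >= ``rise_threshold``, positive slope, and
      half-rise time within the observed window extended by one sampling
      interval;
    - ``decaying``: a negative-slope fit with sufficient drop beats the
      activation fit (the decay fit is used for classification only);
    - ``flat``: no fit reaches the rise threshold;
    - ``unfit``: activation-shaped but the half-rise time falls outside the
      extended window, or the optimiser failed.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    distinct = np.unique(t)
    if distinct.size < 5:
        raise ValueError(f"need >= 5 distinct time points, got {distinct.size}")
    if np.ptp(y) == 0:
        return FitReport(params=None, rss=0.0, converged=True, classification="flat")

    theta_up, rss_up, ok_up = _multistart_fit(t, y, sign=+1.0)
    a, b, c, t_i = theta_up
    interval = float(np.median(np.diff(distinct)))
    in_window = (distinct.min() - interval) <= t_i <= (distinct.max() + interval)

    if b >= rise_threshold and c > 0 and in_window and ok_up:
        return FitReport(
            params=SigmoidParams(a=float(a), b=float(b), c=float(c), t_i=float(t_i)),
            rss=rss_up,
            converged=True,
            classification="activated",
        )

    # Activation fit did not qualify: allow a negative slope for classification.
    theta_dn, rss_dn, ok_dn = _multistart_fit(t, y, sign=-1.0)
    if ok_dn and theta_dn[1] >= rise_threshold and rss_dn < rss_up:
        return FitReport(params=None, rss=rss_dn, converged=True, classification="decaying")
    if max(theta_up[1], theta_dn[1] if ok_dn else 0.0) < rise_threshold:
        return FitReport(params=None, rss=min(rss_up, rss_dn), converged=ok_up or ok_dn, classification="flat")
    return FitReport(params=None, rss=rss_up, converged=ok_up, classification="unfit")


def log_transform(values: np.ndarray, pseudocount: float | None = None) -> np.ndarray:
    """Natural log of linear values with pseudocount.

    Default pseudocount: ``max(1e-6, smallest positive value / 10)``. The log
    base rescales ``a`` and ``b`` jointly and leaves ``t_i`` unchanged.
    """
    values = np.asarray(values, dtype=float)
    if pseudocount is None:
        positive = values[np.isfinite(values) & (values > 0)]
        pseudocount = max(1e-6, float(positive.min()) / 10.0) if positive.size else 1e-6
    return np.log(values + pseudocount)


def initiation_times_batch(
    matrix: ExpressionMatrix,
    gene_subset: Iterable[str] | None = None,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
) -> pd.DataFrame:
    """Fit every requested gene and tabulate initiation times.

    Linear values are log-transformed internally; replicate measurements enter
    the fit as repeated points. Genes exceeding the missing-data limit are
    reported ``unfit`` without fitting. Returns columns
    ``gene_id, a, b, c, t_i, classification, rss``.
    """
    genes = list(gene_subset) if gene_subset is not None else list(matrix.gene_ids)
    if not genes:
        raise ValueError("empty gene subset")
    log_values = log_transform(matrix.values)
    t_rep = np.repeat(matrix.timepoints, matrix.n_replicates)

    dense = matrix.dense_gene_mask()
    n_sparse = 0
    rows = []
    for gid in genes:
        i = matrix.gene_index(gid)
        if not dense[i]:
            n_sparse += 1
            rows.append((gid, np.nan, np.nan, np.nan, np.nan, "unfit", np.nan))
            continue
        y = log_values[i].reshape(-1)
        report = fit_sigmoid(t_rep, y, rise_threshold=rise_threshold)
        p = report.params
        rows.append(
            (
                gid,
                p.a if p else np.nan,
                p.b if p else np.nan,
                p.c if p else np.nan,
                p.t_i if p else np.nan,
                report.classification,
                report.rss,
            )
        )
    if n_sparse:
        logger.warning(
            "excluded %d gene(s) with > %.0f%% missing cells from fitting",
            n_sparse,
            100 * MAX_NA_FRACTION,
        )
    return pd.DataFrame(rows, columns=["gene_id", "a", "b", "c", "t_i", "classification", "rss"])


def select_clear_activations(
    table: pd.DataFrame,
    c_range: tuple[float, float] = (0.2, 4.0),
    rss_factor: float = 3.0,
) -> pd.Series:
    """Boolean mask of genes with a clear, well-determined activation fit.

    Keeps ``activated`` genes whose slope lies in a plausible per-hour band
    and whose RSS is below ``rss_factor`` times the median RSS of activated
    genes — the usual curation step before regressing initiation times
    between species.
    """
    activated = table["classification"] == "activated"
    if not activated.any():
        return activated
    rss_cap = rss_factor * float(table.loc[activated, "rss"].median())
    return activated & table["c"].between(*c_range) & (table["rss"] <= rss_cap)


def recommend_sampling_interval(total_duration_h: float) -> float:
    """Rule-of-thumb sampling interval: a tenth of the studied developmental window."""
    if total_duration_h <= 0:
        raise ValueError("total duration must be positive")
    return total_duration_h / 10.0
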