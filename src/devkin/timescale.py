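"""Linear developmental-time scaling between species and profile conditioning.

The map is ``T_target = shift + rate * T_reference``: the intercept captures
the offset of the maternal-to-zygotic transition and the slope the ratio of
developmental rates. It is estimated by regressing orthologue initiation
times in the target species on those in the reference species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from devkin.io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeScaling:
    """Linear map from reference-species time to target-species time."""

    shift: float
    rate: float
    r_squared: float = float("nan")
    n_genes: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate} (anti-scaling)")


def fit_time_scaling(
    pairs: Sequence[tuple[float, float]], method: str = "ols"
) -> TimeScaling:
    """Fit the scaling line from orthologue initiation-time pairs.

    ``pairs`` are ``(t_i_reference, t_i_target)``. ``method`` is ``"ols"``
    (default) or ``"theil-sen"`` for a robust slope when heterochronic
    outliers are suspected. The target is always regressed on the reference;
    use :func:`invert_scaling` for the other direction.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (reference, target) tuples")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct reference initiation times")

    if method == "ols":
        fit = stats.linregress(x, y)
        shift, rate = float(fit.intercept), float(fit.slope)
    elif method == "theil-sen":
        ts = stats.theilslopes(y, x)
        shift, rate = float(ts.intercept), float(ts.slope)
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = y - (shift + rate * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if rate <= 0:
        raise ValueError(f"fitted rate {rate:.4g} <= 0: anti-scaling")
    return TimeScaling(shift=shift, rate=rate, r_squared=r2, n_genes=int(len(x)))


def map_time(scaling: TimeScaling, t_reference: float | np.ndarray) -> float | np.ndarray:
    """Map reference-species time(s) to target-species time(s)."""
    t = np.asarray(t_reference, dtype=float)
    out = scaling.shift + scaling.rate * t
    return float(out) if out.ndim == 0 else out


def invert_scaling(scaling: TimeScaling) -> TimeScaling:
    """Algebraic inverse map; composition with the original is the identity."""
    return TimeScaling(
        shift=-scaling.shift / scaling.rate,
        rate=1.0 / scaling.rate,
        r_squared=scaling.r_squared,
        n_genes=scaling.n_genes,
    )


def normalize_to_max(profile: Sequence[float]) -> np.ndarray:
    """Percent-of-max normalisation of a linear expression profile.

    Each value is divided by the profile maximum and expressed as percent, so
    the maximum of the output is exactly 100. NaNs are ignored for the
    maximum and propagated.
    """
    profile = np.asarray(profile, dtype=float)
    peak = np.nanmax(profile) if profile.size else 0.0
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("profile must contain at least one positive value")
    # divide first so the peak maps to exactly 1.0, hence exactly 100.0
    return profile / peak * 100.0


def resample_profile(
    profile: Sequence[float],
    source_times: Sequence[float],
    target_times: Sequence[float],
) -> np.ndarray:
    """Linearly interpolate a profile onto ``target_times``.

    Values at shared time stamps are unchanged; extrapolation is an error.
    """
    profile = np.asarray(profile, dtype=float)
    src = np.asarray(source_times, dtype=float)
    dst = np.asarray(target_times, dtype=float)
    if profile.shape != src.shape:
        raise ValueError("profile and source_times must have equal length")
    if dst.size and (dst.min() < src.min() - 1e-9 or dst.max() > src.max() + 1e-9):
        raise ValueError(
            f"target times [{dst.min():g}, {dst.max():g}] extend beyond the measured "
            f"window [{src.min():g}, {src.max():g}]"
        )
    return np.interp(np.clip(dst, src.min(), src.max()), src, profile)


def normalized_profiles(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene percent-of-max profiles of replicate-mean linear values."""
    means = matrix.replicate_mean()
    out = np.empty_like(means)
    for i in range(means.shape[0]):
        out[i] = normalize_to_max(means[i])
    return out


def project_onto_reference_grid(
    matrix_target: ExpressionMatrix,
    scaling: TimeScaling,
    reference_times: Sequence[float],
) -> np.ndarray:
    """Target-species percent-of-max profiles sampled at the reference grid.

    Each reference time ``t`` is mapped to target time ``shift + rate * t``
    and the target profile is linearly interpolated there, after
    percent-of-max normalisation, giving profiles directly comparable to the
    reference species on equivalent developmental time points.
    """
    mapped = map_time(scaling, np.asarray(reference_times, dtype=float))
    profiles = normalized_profiles(matrix_target)
    return np.vstack(
        [resample_profile(p, matrix_target.timepoints, mapped) for p in profiles]
    )
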