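"""Stage-by-stage interspecies conservation analyses.

Given two orthologue-aligned expression matrices, this module computes
time-point x time-point correlation matrices (Pearson on log values,
Spearman on raw values), cross-species variance (divergence) profiles, PCA
sample grouping, and a summary that classifies the equivalent-stage
correlation series as hourglass, funnel, flat or mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from devkin.io import ExpressionMatrix, GeneClassLabels, OrthologMap, align_orthologs
from devkin.kinetics import log_transform
from devkin.timescale import TimeScaling, map_time

logger = logging.getLogger(__name__)

#: Correlation margin separating hourglass/flat shape calls.
DEFAULT_MARGIN = 0.05
#: Significance level of the monotone-trend test for the funnel call.
DEFAULT_TREND_ALPHA = 0.05


@dataclass
class StageCorrelation:
    """Interspecies correlation matrix over stage pairs for one gene set."""

    method: str  # pearson | spearman
    gene_set: str
    matrix: np.ndarray  # (stages A, stages B)
    times_a: np.ndarray
    times_b: np.ndarray
    n_genes: int


@dataclass
class DivergenceProfile:
    """Per-time-point cross-species expression variance, averaged over genes."""

    times: np.ndarray
    variance: np.ndarray
    n_species: int


@dataclass
class PatternSummary:
    """Shape summary of the equivalent-stage correlation series."""

    diagonality_index: float
    peak_stage: float
    equivalent_series: np.ndarray
    equivalent_times_a: np.ndarray
    trend_rho: float
    trend_pvalue: float
    shape: str  # hourglass | funnel | flat | mixed


def interspecies_correlation_matrix(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    ortholog_map: OrthologMap | None = None,
    method: str = "pearson",
    gene_set: Sequence[str] | None = None,
    gene_set_label: str = "all",
) -> StageCorrelation:
    """Correlate every stage of species A against every stage of species B.

    Entry ``(s, t)`` is the correlation, across orthologous genes, between
    A's expression column at stage ``s`` and B's at stage ``t``. Pearson is
    computed on log(value + pseudocount); Spearman on raw values with
    average ranks. ``gene_set`` restricts rows to reference-species gene ids
    (applied after orthologue alignment).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if ortholog_map is not None:
        matrix_a, matrix_b = align_orthologs(matrix_a, matrix_b, ortholog_map)
    elif matrix_a.n_genes != matrix_b.n_genes:
        raise ValueError("matrices must be orthologue-aligned (equal row counts)")

    keep = np.ones(matrix_a.n_genes, dtype=bool)
    if gene_set is not None:
        wanted = set(gene_set)
        keep &= np.array([g in wanted for g in matrix_a.gene_ids])
    keep &= matrix_a.dense_gene_mask() & matrix_b.dense_gene_mask()
    n_genes = int(keep.sum())
    if n_genes < 3:
        raise ValueError(f"need >= 3 genes after restriction, got {n_genes}")

    vals_a = matrix_a.replicate_mean()[keep]
    vals_b = matrix_b.replicate_mean()[keep]
    if method == "pearson":
        vals_a = log_transform(vals_a)
        vals_b = log_transform(vals_b)

    na, nb = vals_a.shape[1], vals_b.shape[1]
    out = np.empty((na, nb))
    for s in range(na):
        for t in range(nb):
            if method == "pearson":
                out[s, t] = stats.pearsonr(vals_a[:, s], vals_b[:, t]).statistic
            else:
                out[s, t] = stats.spearmanr(vals_a[:, s], vals_b[:, t]).statistic
    return StageCorrelation(
        method=method,
        gene_set=gene_set_label,
        matrix=out,
        times_a=matrix_a.timepoints.copy(),
        times_b=matrix_b.timepoints.copy(),
        n_genes=n_genes,
    )


def divergence_profile(
    profiles_per_species: Sequence[np.ndarray],
    times: Sequence[float],
) -> DivergenceProfile:
    """Cross-species variance of expression at each matched time point.

    ``profiles_per_species`` holds one orthologue-aligned (genes x stages)
    array per species, already resampled to the common scaled grid and
    per-gene normalised. The variance across species (ddof=1) is computed
    per gene per stage and averaged over genes.
    """
    if len(profiles_per_species) < 2:
        raise ValueError("need >= 2 species")
    stack = np.stack([np.asarray(p, dtype=float) for p in profiles_per_species])
    if stack.ndim != 3:
        raise ValueError("each species must contribute a (genes x stages) array")
    times = np.asarray(times, dtype=float)
    if times.size != stack.shape[2]:
        raise ValueError("times length does not match profiles")
    var = stack.var(axis=0, ddof=1).mean(axis=0)
    return DivergenceProfile(times=times, variance=var, n_species=stack.shape[0])


def pca_sample_projection(
    samples: np.ndarray,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Project stage samples (rows) onto leading principal components.

    ``samples`` stacks the per-stage expression vectors of both species
    (genes as features); rows are centred internally. Returns the
    coordinates on the first ``n_components`` components and the full
    variance-explained fractions (non-increasing, summing to 1).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 3:
        raise ValueError("need >= 3 stage samples")
    if n_components > samples.shape[0]:
        raise ValueError(
            f"requested {n_components} components from {samples.shape[0]} samples"
        )
    pca = PCA(n_components=None, svd_solver="full")
    coords = pca.fit_transform(samples)
    ratios = pca.explained_variance_ratio_
    return coords[:, :n_components], ratios


def equivalent_stage_pairs(
    times_a: Sequence[float],
    times_b: Sequence[float],
    scaling: TimeScaling | None = None,
) -> list[tuple[float, float]]:
    """Match each A stage to its developmentally equivalent B stage.

    With a scaling, each A time is mapped into B time and snapped to the
    nearest measured B stage (maximum snap distance logged); without one,
    stages are paired by index.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if scaling is None:
        if times_a.size != times_b.size:
            raise ValueError("without a scaling, stage grids must have equal length")
        return list(zip(times_a.tolist(), times_b.tolist()))
    mapped = map_time(scaling, times_a)
    idx = np.abs(times_b[None, :] - np.atleast_1d(mapped)[:, None]).argmin(axis=1)
    snap = np.abs(times_b[idx] - mapped)
    logger.info("equivalent-stage snapping: max |snap| = %.3g h", float(snap.max()))
    return list(zip(times_a.tolist(), times_b[idx].tolist()))


def pattern_summary(
    corr: StageCorrelation,
    equivalence: Sequence[tuple[float, float]],
    margin: float = DEFAULT_MARGIN,
    trend_alpha: float = DEFAULT_TREND_ALPHA,
    zygotic_start_index: int = 1,
) -> PatternSummary:
    """Classify the equivalent-stage correlation series as hourglass/funnel/flat/mixed.

    The series is the correlation at each matched (A, B) stage pair, ordered
    by A time. Calls, in order of precedence: ``flat`` if the series range
    is below ``margin``; ``hourglass`` if an interior stage exceeds both
    ends by ``margin``; ``funnel`` if the Spearman trend of the series over
    zygotic stages (from ``zygotic_start_index``) is positive and
    significant at ``trend_alpha``; otherwise ``mixed``.
    """
    if len(equivalence) < 3:
        raise ValueError("need >= 3 equivalence pairs")
    ia, ib = [], []
    for ta, tb in equivalence:
        sa = np.flatnonzero(np.isclose(corr.times_a, ta))
        sb = np.flatnonzero(np.isclose(corr.times_b, tb))
        if sa.size == 0 or sb.size == 0:
            raise ValueError(f"equivalence pair ({ta}, {tb}) is not on the correlation grid")
        ia.append(int(sa[0]))
        ib.append(int(sb[0]))
    order = np.argsort(corr.times_a[ia])
    ia = np.asarray(ia)[order]
    ib = np.asarray(ib)[order]

    series = corr.matrix[ia, ib]
    best_b = corr.matrix[ia, :].argmax(axis=1)
    diagonality = float(np.mean(best_b == ib))
    peak_pos = int(np.argmax(series))
    peak_stage = float(corr.times_a[ia][peak_pos])

    zyg = series[zygotic_start_index:]
    if zyg.size >= 3:
        trend = stats.spearmanr(np.arange(zyg.size), zyg)
        rho, pval = float(trend.statistic), float(trend.pvalue)
    else:
        rho, pval = float("nan"), float("nan")

    if float(np.ptp(series)) < margin:
        shape = "flat"
    elif (
        0 < peak_pos < len(series) - 1
        and series[peak_pos] >= series[0] + margin
        and series[peak_pos] >= series[-1] + margin
    ):
        shape = "hourglass"
    elif np.isfinite(rho) and rho > 0 and pval < trend_alpha:
        shape = "funnel"
    else:
        shape = "mixed"

    return PatternSummary(
        diagonality_index=diagonality,
        peak_stage=peak_stage,
        equivalent_series=series,
        equivalent_times_a=corr.times_a[ia].copy(),
        trend_rho=rho,
        trend_pvalue=pval,
        shape=shape,
    )


def class_resolved_patterns(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    ortholog_map: OrthologMap,
    labels: GeneClassLabels,
    scaling: TimeScaling | None = None,
    method: str = "pearson",
    **summary_kwargs,
) -> dict[str, tuple[StageCorrelation, PatternSummary]]:
    """Per-class correlation matrices and pattern summaries, plus "all"."""
    aligned_a, aligned_b = align_orthologs(matrix_a, matrix_b, ortholog_map)
    equivalence = equivalent_stage_pairs(aligned_a.timepoints, aligned_b.timepoints, scaling)
    out: dict[str, tuple[StageCorrelation, PatternSummary]] = {}
    gene_sets: dict[str, Sequence[str] | None] = {"all": None}
    for cls in labels.classes():
        gene_sets[cls] = labels.genes_of(cls)
    for name, gene_set in gene_sets.items():
        try:
            corr = interspecies_correlation_matrix(
                aligned_a, aligned_b, None, method=method, gene_set=gene_set, gene_set_label=name
            )
        except ValueError as exc:
            logger.warning("skipping class %r: %s", name, exc)
            continue
        out[name] = (corr, pattern_summary(corr, equivalence, **summary_kwargs))
    return out
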