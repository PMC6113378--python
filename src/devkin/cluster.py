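"""k-means temporal-profile clustering and orthologue conservation calls.

Genes are clustered by their (percent-of-max) temporal profiles in a
reference species with Lloyd's iteration seeded from randomly chosen gene
profiles. Orthologues in a second species, resampled onto the equivalent
time grid, are then labelled conserved or diverged either by their Euclidean
distance to the partner's cluster centroid against a per-cluster cutoff, or
by nearest-centroid membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from devkin.io import GeneClassLabels, OrthologMap

logger = logging.getLogger(__name__)

DEFAULT_N_RESTARTS = 20


@dataclass
class ClusteringResult:
    """Converged k-means partition of temporal profiles.

    ``centroids`` has shape ``(k, n_timepoints)`` over the common grid
    ``times``; ``assignments`` maps every clustered gene to one cluster
    index; ``member_distances[j]`` holds the Euclidean distances of cluster
    ``j``'s members to its centroid.
    """

    k: int
    times: np.ndarray
    centroids: np.ndarray
    assignments: dict[str, int]
    inertia: float
    per_cluster_max_dist: np.ndarray
    member_distances: list[np.ndarray]
    converged: bool
    inertia_history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ConservationCall:
    """Conserved/diverged label for one orthologue pair."""

    ref_id: str
    target_id: str
    cluster: int
    distance: float
    cutoff: float
    label: str  # conserved | diverged
    method: str  # distance | membership


def _assign(profiles: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((profiles[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _lloyd(
    profiles: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, bool, list[float]]:
    n = profiles.shape[0]
    centroids = profiles[rng.choice(n, size=k, replace=False)].copy()
    labels = _assign(profiles, centroids)
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        for j in range(k):
            members = profiles[labels == j]
            if len(members) == 0:
                # re-seed an empty cluster at the point farthest from its centroid
                dist = np.linalg.norm(profiles - centroids[labels], axis=1)
                far = int(np.argmax(dist))
                centroids[j] = profiles[far]
                labels[far] = j
                logger.debug("re-seeded empty cluster %d at farthest point %d", j, far)
            else:
                centroids[j] = members.mean(axis=0)
        new_labels = _assign(profiles, centroids)
        inertia = float(((profiles - centroids[new_labels]) ** 2).sum())
        history.append(inertia)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
    # final means consistent with the final assignment
    for j in range(k):
        members = profiles[labels == j]
        if len(members):
            centroids[j] = members.mean(axis=0)
    inertia = float(((profiles - centroids[labels]) ** 2).sum())
    return labels, centroids, inertia, converged, history


def kmeans_cluster(
    profiles: np.ndarray,
    gene_ids: Sequence[str],
    k: int,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    times: Sequence[float] | None = None,
    max_iter: int = 300,
) -> ClusteringResult:
    """Multi-restart Lloyd k-means of temporal profiles on a shared grid.

    Each restart initialises the k means at randomly chosen gene profiles
    (without replacement) using a sub-seed derived from ``seed``, iterates
    until no gene moves, and the lowest-inertia restart wins (ties broken by
    lexicographically smallest assignment vector).
    """
    profiles = np.asarray(profiles, dtype=float)
    gene_ids = list(gene_ids)
    n = profiles.shape[0]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must match profiles")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    best: tuple[float, tuple[int, ...]] | None = None
    best_out = None
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(child)
        labels, centroids, inertia, converged, history = _lloyd(profiles, k, rng, max_iter)
        key = (inertia, tuple(int(x) for x in labels))
        if best is None or key < best:
            best = key
            best_out = (labels, centroids, inertia, converged, history)

    labels, centroids, inertia, converged, history = best_out
    dists = np.linalg.norm(profiles - centroids[labels], axis=1)
    member_distances = [dists[labels == j] for j in range(k)]
    per_cluster_max = np.array(
        [d.max() if d.size else 0.0 for d in member_distances]
    )
    return ClusteringResult(
        k=k,
        times=np.arange(profiles.shape[1], dtype=float) if times is None else np.asarray(times, dtype=float),
        centroids=centroids,
        assignments={g: int(c) for g, c in zip(gene_ids, labels)},
        inertia=inertia,
        per_cluster_max_dist=per_cluster_max,
        member_distances=member_distances,
        converged=converged,
        inertia_history=history,
    )


def conservation_cutoff(result: ClusteringResult, rule: str = "max") -> np.ndarray:
    """Per-cluster conservation cutoffs from the reference-species distances.

    Rules: ``"max"`` (default) — each cluster's maximal member-to-centroid
    distance; ``"quantile:q"`` — the q-quantile of member distances;
    ``"global-max"`` — the overall maximal distance applied to every cluster.
    """
    if not result.converged:
        raise ValueError("clustering did not converge; cutoffs undefined")
    if rule == "max":
        return result.per_cluster_max_dist.copy()
    if rule == "global-max":
        return np.full(result.k, float(result.per_cluster_max_dist.max()))
    if rule.startswith("quantile:"):
        try:
            q = float(rule.split(":", 1)[1])
        except ValueError:
            raise ValueError(f"bad quantile in cutoff rule {rule!r}") from None
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quantile must be in [0, 1], got {q}")
        return np.array(
            [np.quantile(d, q) if d.size else 0.0 for d in result.member_distances]
        )
    raise ValueError(f"unknown cutoff rule {rule!r}")


def classify_conservation(
    result_a: ClusteringResult,
    profiles_b: np.ndarray,
    gene_ids_b: Sequence[str],
    ortholog_map: OrthologMap,
    method: str = "distance",
    cutoff_rule: str = "max",
) -> list[ConservationCall]:
    """Label each aligned orthologue pair conserved or diverged.

    ``profiles_b`` must be resampled onto the reference species' (scaled)
    time grid and percent-of-max normalised. Method ``"distance"`` compares
    the Euclidean distance of the B profile to its partner's A-cluster
    centroid against that cluster's cutoff; ``"membership"`` assigns the B
    profile to its nearest A centroid and requires it to coincide with the
    partner's cluster.
    """
    profiles_b = np.asarray(profiles_b, dtype=float)
    if profiles_b.shape[1] != result_a.centroids.shape[1]:
        raise ValueError(
            f"grid mismatch: B profiles have {profiles_b.shape[1]} time points, "
            f"centroids have {result_a.centroids.shape[1]}"
        )
    if method not in ("distance", "membership"):
        raise ValueError(f"unknown method {method!r}")
    index_b = {g: i for i, g in enumerate(gene_ids_b)}
    cutoffs = conservation_cutoff(result_a, cutoff_rule)

    calls: list[ConservationCall] = []
    for ref_id, target_id in ortholog_map.pairs:
        if ref_id not in result_a.assignments or target_id not in index_b:
            continue
        cluster = result_a.assignments[ref_id]
        profile = profiles_b[index_b[target_id]]
        distance = float(np.linalg.norm(profile - result_a.centroids[cluster]))
        if method == "distance":
            # tolerance absorbs summation-order rounding so that B == A
            # always calibrates to 100% conserved under the max rule
            conserved = distance <= cutoffs[cluster] * (1.0 + 1e-9) + 1e-12
        else:
            nearest = int(np.argmin(np.linalg.norm(result_a.centroids - profile, axis=1)))
            conserved = nearest == cluster
        calls.append(
            ConservationCall(
                ref_id=ref_id,
                target_id=target_id,
                cluster=cluster,
                distance=distance,
                cutoff=float(cutoffs[cluster]),
                label="conserved" if conserved else "diverged",
                method=method,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[ConservationCall]) -> pd.DataFrame:
    """Tabulate conservation calls, one row per orthologue pair."""
    return pd.DataFrame(
        [
            (c.ref_id, c.target_id, c.cluster, c.distance, c.cutoff, c.label, c.method)
            for c in calls
        ],
        columns=["ref_id", "target_id", "cluster", "distance", "cutoff", "label", "method"],
    )


def class_enrichment(
    target_genes: Sequence[str],
    background_genes: Sequence[str],
    labels: GeneClassLabels,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each class in a target gene set.

    For each class present in the labelled background, tests whether the
    target set (e.g. one cluster, or all diverged genes) contains more
    members of the class than expected by drawing uniformly from the
    background. P-values are Benjamini-Hochberg adjusted across classes.
    """
    background = list(dict.fromkeys(background_genes))
    if not background:
        raise ValueError("empty background gene set")
    target = [g for g in dict.fromkeys(target_genes) if g in set(background)]
    labelled_target = [g for g in target if g in labels.labels]
    if not labelled_target:
        logger.warning("no class labels available for any target gene; empty enrichment table")
        return pd.DataFrame(
            columns=["class", "n_target", "n_background", "target_size", "background_size", "p_value", "q_value"]
        )

    m_total = len(background)
    n_draw = len(target)
    rows = []
    for cls in sorted({labels.labels[g] for g in background if g in labels.labels}):
        members = {g for g in background if labels.labels.get(g) == cls}
        k_in = len(members.intersection(target))
        k_bg = len(members)
        p = float(hypergeom.sf(k_in - 1, m_total, k_bg, n_draw))
        rows.append((cls, k_in, k_bg, n_draw, m_total, p))
    df = pd.DataFrame(
        rows, columns=["class", "n_target", "n_background", "target_size", "background_size", "p_value"]
    )
    df["q_value"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df.sort_values("p_value", ignore_index=True)


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, pvals[i] * n / rank)
        adj[i] = running
    return adj
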