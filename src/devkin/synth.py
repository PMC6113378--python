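"""Synthetic two-species developmental expression datasets with ground truth.

Four gene classes are emulated on the log scale as continuous functions of
reference-species (A) developmental time:

- ``developmental``: sigmoidal zygotic activation, archetypes differing in
  half-rise time; species B follows the same curve at scaled times.
- ``housekeeping``: monotone rise from a maternal baseline after the
  zygotic transition.
- ``maternal``: high initial level decaying sigmoidally.
- ``environmental``: pulse archetypes peaking at different stages; with a
  configured probability the species-B profile is replaced (fully or
  partially, per the divergence magnitude) by a different archetype.

Within every class a configured fraction of genes diverges in species B by
per-stage log offsets whose magnitude profile is class-specific: largest at
early/late stages for developmental genes (hourglass-shaped correlation
dips), shrinking with time for housekeeping genes (funnel). Developmental
divergence is confined to plateau stages so activation timing stays
conserved. Any gene whose B profile was deliberately altered — stage
perturbation or archetype swap — carries ``diverged=True`` in the ground
truth; all remaining pairs differ by measurement noise only.

Species B is measured on the grid ``map_time(scaling, times_a)``, so stage
``j`` of B is developmentally equivalent to stage ``j`` of A; with zero
noise and zero divergence the B profile equals the A function evaluated at
the equivalent (inverse-scaled) times exactly. Replicates are independent
log-normal noise draws. All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from devkin.io import ExpressionMatrix, GeneClassLabels, OrthologMap, write_expression_table
from devkin.timescale import TimeScaling, map_time

CLASS_NAMES = ("developmental", "housekeeping", "maternal", "environmental")


def _default_times_a() -> np.ndarray:
    # 0..36 hpf at the recommended tenth-of-window interval
    return np.linspace(0.0, 36.0, 11)


def _default_stage_noise(n_stages: int) -> dict[str, np.ndarray]:
    """Per-stage divergence noise (log units) applied to a diverging B gene."""
    x = np.linspace(-1.0, 1.0, n_stages)
    return {
        # large at both ends, small at mid-development -> hourglass correlations
        "developmental": 0.20 + 0.90 * x**2,
        # shrinking with developmental progression -> funnel correlations
        "housekeeping": 2.0 * np.exp(-np.linspace(0.0, 3.2, n_stages)) + 0.08,
        "maternal": np.full(n_stages, 0.30),
        "environmental": np.full(n_stages, 0.60),
    }


def _default_divergence_prob() -> dict[str, float]:
    """Fraction of each class whose species-B profile actually diverges."""
    return {
        "developmental": 0.15,
        "housekeeping": 0.30,
        "maternal": 0.10,
        "environmental": 0.15,
    }


@dataclass
class SimulationConfig:
    """Knobs of the two-species simulation; all counts and noise levels >= 0."""

    n_developmental: int = 200
    n_housekeeping: int = 100
    n_maternal: int = 50
    n_environmental: int = 100
    times_a: np.ndarray = field(default_factory=_default_times_a)
    scaling: TimeScaling = field(default_factory=lambda: TimeScaling(shift=2.42, rate=1.037))
    n_archetypes: int = 5
    env_archetype_peaks: tuple[float, ...] = (6.0, 15.0, 24.0, 33.0)
    noise_sigma: float = 0.05
    env_divergence_prob: float = 0.5
    env_divergence_magnitude: float = 1.0
    replicates: int = 3
    stage_noise: dict[str, np.ndarray] | None = None
    stage_divergence_prob: dict[str, float] | None = None
    zygotic_transition_h: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.times_a = np.asarray(self.times_a, dtype=float)
        for name in ("n_developmental", "n_housekeeping", "n_maternal", "n_environmental"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.env_divergence_prob <= 1.0:
            raise ValueError("env_divergence_prob must be in [0, 1]")
        if not 0.0 <= self.env_divergence_magnitude <= 1.0:
            raise ValueError("env_divergence_magnitude must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if np.any(np.diff(self.times_a) <= 0):
            raise ValueError("times_a must be strictly increasing")

    @classmethod
    def noiseless(cls, **overrides) -> "SimulationConfig":
        """A configuration with no noise and no divergence of any kind."""
        cfg = cls(noise_sigma=0.0, env_divergence_prob=0.0, **overrides)
        cfg.stage_noise = {c: np.zeros(cfg.times_a.size) for c in CLASS_NAMES}
        cfg.stage_divergence_prob = {c: 0.0 for c in CLASS_NAMES}
        return cfg

    def resolved_stage_noise(self) -> dict[str, np.ndarray]:
        defaults = _default_stage_noise(self.times_a.size)
        if self.stage_noise is None:
            return defaults
        out = dict(defaults)
        for cls_name, arr in self.stage_noise.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size != self.times_a.size:
                raise ValueError(f"stage_noise[{cls_name!r}] must have {self.times_a.size} entries")
            out[cls_name] = arr
        return out

    def resolved_divergence_prob(self) -> dict[str, float]:
        out = _default_divergence_prob()
        if self.stage_divergence_prob is not None:
            out.update(self.stage_divergence_prob)
        for cls_name, p in out.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"stage_divergence_prob[{cls_name!r}] must be in [0, 1]")
        return out


def _sigmoid(t: np.ndarray, a: float, b: float, c: float, t_i: float) -> np.ndarray:
    return a - b / (1.0 + np.exp(np.clip(c * (t - t_i), -700, 700)))


@dataclass
class _Gene:
    gene_class: str
    archetype: int
    archetype_b: int
    curve_a: Callable[[np.ndarray], np.ndarray]
    curve_b: Callable[[np.ndarray], np.ndarray]
    t_i: float | None
    diverged: bool
    rise_halfwidth: float | None = None  # half-width of the activation rise, hours


def _draw_genes(config: SimulationConfig, rng: np.random.Generator) -> list[_Gene]:
    genes: list[_Gene] = []
    t_lo, t_hi = float(config.times_a.min()), float(config.times_a.max())

    ti_centers = np.linspace(t_lo + 0.25 * (t_hi - t_lo), t_lo + 0.7 * (t_hi - t_lo), config.n_archetypes)
    for _ in range(config.n_developmental):
        arch = int(rng.integers(config.n_archetypes))
        a = rng.uniform(1.5, 4.0)
        b = rng.uniform(1.0, 2.8)
        c = rng.uniform(0.6, 1.5)
        t_i = float(ti_centers[arch] + rng.uniform(-1.5, 1.5))
        curve = (lambda a=a, b=b, c=c, t_i=t_i: (lambda t: _sigmoid(t, a, b, c, t_i)))()
        genes.append(_Gene("developmental", arch, arch, curve, curve, t_i, False, rise_halfwidth=4.0 / c))

    for _ in range(config.n_housekeeping):
        base = rng.uniform(1.0, 2.0)
        slope = rng.uniform(0.03, 0.08)
        tz = config.zygotic_transition_h
        curve = (lambda base=base, slope=slope, tz=tz: (
            lambda t: base + slope * np.maximum(0.0, np.asarray(t, dtype=float) - tz)
        ))()
        genes.append(_Gene("housekeeping", 0, 0, curve, curve, None, False))

    for _ in range(config.n_maternal):
        low = rng.uniform(0.3, 1.0)
        drop = rng.uniform(1.0, 2.5)
        c = rng.uniform(0.3, 0.8)
        t_d = rng.uniform(6.0, 14.0)
        curve = (lambda low=low, drop=drop, c=c, t_d=t_d: (
            lambda t: low + drop / (1.0 + np.exp(np.clip(c * (np.asarray(t, dtype=float) - t_d), -700, 700)))
        ))()
        genes.append(_Gene("maternal", 0, 0, curve, curve, None, False))

    peaks = np.asarray(config.env_archetype_peaks, dtype=float)
    for _ in range(config.n_environmental):
        arch = int(rng.integers(peaks.size))
        base = rng.uniform(0.5, 1.5)
        amp = rng.uniform(1.5, 2.5)
        width = rng.uniform(4.0, 6.0)

        def pulse(mu: float, base=base, amp=amp, width=width) -> Callable[[np.ndarray], np.ndarray]:
            return lambda t: base + amp * np.exp(-((np.asarray(t, dtype=float) - mu) ** 2) / (2.0 * width**2))

        curve_a = pulse(float(peaks[arch]))
        diverged = bool(rng.random() < config.env_divergence_prob)
        arch_b = arch
        curve_b = curve_a
        if diverged:
            others = [i for i in range(peaks.size) if i != arch]
            arch_b = int(others[rng.integers(len(others))])
            m = config.env_divergence_magnitude
            alt = pulse(float(peaks[arch_b]))
            curve_b = (lambda ca=curve_a, cb=alt, m=m: (lambda t: (1.0 - m) * ca(t) + m * cb(t)))()
        genes.append(_Gene("environmental", arch, arch_b, curve_a, curve_b, None, diverged))
    return genes


def simulate_two_species_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologMap, GeneClassLabels, pd.DataFrame]:
    """Generate matched species-A/species-B matrices plus full ground truth.

    Returns ``(matrix_a, matrix_b, ortholog_map, class_labels, truth)``
    where ``truth`` has one row per orthologue pair with the gene class,
    archetype ids on both sides, the true half-rise times (developmental
    genes) and the conserved/diverged flag.
    """
    n_total = config.n_developmental + config.n_housekeeping + config.n_maternal + config.n_environmental
    if n_total == 0:
        raise ValueError("config requests zero genes")
    rng = np.random.default_rng(config.seed)
    genes = _draw_genes(config, rng)
    stage_noise = config.resolved_stage_noise()
    divergence_prob = config.resolved_divergence_prob()

    times_a = config.times_a
    times_b = np.asarray(map_time(config.scaling, times_a), dtype=float)
    n_stages = times_a.size
    n_rep = config.replicates

    ids_a = [f"gA_{i:05d}" for i in range(n_total)]
    ids_b = [f"gB_{i:05d}" for i in range(n_total)]

    log_a = np.empty((n_total, n_stages, n_rep))
    log_b = np.empty((n_total, n_stages, n_rep))
    truth_rows = []
    for i, gene in enumerate(genes):
        mean_a = gene.curve_a(times_a)
        # stage j of B is developmentally equivalent to stage j of A
        mean_b = gene.curve_b(times_a)
        # only a subset of each class diverges; those pairs are flagged in truth
        perturbed = bool(rng.random() < divergence_prob[gene.gene_class])
        divergence = rng.normal(0.0, 1.0, size=n_stages) * stage_noise[gene.gene_class]
        if gene.rise_halfwidth is not None and gene.t_i is not None:
            # plateau-level divergence only: activation timing stays conserved
            divergence = divergence * (np.abs(times_a - gene.t_i) > gene.rise_halfwidth)
        if perturbed:
            mean_b = mean_b + divergence
        dyn_range = max(float(np.ptp(mean_a)), 0.2)
        sigma = config.noise_sigma * dyn_range
        log_a[i] = mean_a[:, None] + sigma * rng.normal(size=(n_stages, n_rep))
        log_b[i] = mean_b[:, None] + sigma * rng.normal(size=(n_stages, n_rep))
        truth_rows.append(
            (
                ids_a[i],
                ids_b[i],
                gene.gene_class,
                gene.archetype,
                gene.archetype_b,
                gene.t_i if gene.t_i is not None else np.nan,
                map_time(config.scaling, gene.t_i) if gene.t_i is not None else np.nan,
                gene.diverged or perturbed,
            )
        )

    rep_ids = [str(r + 1) for r in range(n_rep)]
    matrix_a = ExpressionMatrix(
        species="species_A", gene_ids=ids_a, timepoints=times_a, values=np.exp(log_a), replicate_ids=rep_ids
    )
    matrix_b = ExpressionMatrix(
        species="species_B", gene_ids=ids_b, timepoints=times_b, values=np.exp(log_b), replicate_ids=rep_ids
    )
    omap = OrthologMap(list(zip(ids_a, ids_b)))
    labels = GeneClassLabels({gid: gene.gene_class for gid, gene in zip(ids_a, genes)})
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id_a", "gene_id_b", "gene_class", "archetype_a", "archetype_b", "t_i_a", "t_i_b", "diverged"],
    )
    return matrix_a, matrix_b, omap, labels, truth


def make_worked_example_fixtures(out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Deterministic worked-example tables used throughout the test suite.

    - ``sigmoid_example``: the reference activation curve (a=0.8, b=0.6,
      c=1, t_i=8 hpf) sampled at t = 0..20 hpf.
    - ``initiation_pairs``: 22 collinear initiation-time pairs under
      T_target = 2.42 + 1.037 x T_reference at T_reference = 5..26 h.
    - ``correlation_toy``: a 4-gene, 2-stage two-species toy table.

    When ``out_dir`` is given the tables are also written as TSV files.
    """
    t = np.arange(0.0, 21.0)
    sigmoid_example = pd.DataFrame(
        {"t_hpf": t, "log_expression": _sigmoid(t, a=0.8, b=0.6, c=1.0, t_i=8.0)}
    )

    t_ref = np.arange(5.0, 27.0)
    initiation_pairs = pd.DataFrame(
        {"t_i_reference": t_ref, "t_i_target": 2.42 + 1.037 * t_ref}
    )

    correlation_toy = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "a_s1": [1.0, 2.0, 3.0, 4.0],
            "a_s2": [4.0, 3.0, 2.0, 1.0],
            "b_s1": [2.0, 3.0, 5.0, 8.0],
            "b_s2": [9.0, 5.0, 3.0, 2.0],
        }
    )

    fixtures = {
        "sigmoid_example": sigmoid_example,
        "initiation_pairs": initiation_pairs,
        "correlation_toy": correlation_toy,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in fixtures.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    return fixtures


def write_dataset(
    out_dir: str | Path,
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    omap: OrthologMap,
    labels: GeneClassLabels,
    truth: pd.DataFrame,
) -> None:
    """Write the standard TSVs consumed by the CLI subcommands."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_expression_table(matrix_a, out_dir / "species_A.tsv")
    write_expression_table(matrix_b, out_dir / "species_B.tsv")
    omap.write_tsv(out_dir / "orthologs.tsv")
    labels.write_tsv(out_dir / "class_labels.tsv")
    truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
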