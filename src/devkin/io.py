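"""Expression-matrix, orthologue-map and class-label I/O.

Tables are plain delimited text. Expression columns follow the header
dialect ``t<hpf>`` or ``t<hpf>_r<rep>`` (hpf as decimal hours), with gene
identifiers in the first column. Missing cells are written ``NA``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fraction of missing cells above which a gene is excluded from fitting
#: and clustering.
MAX_NA_FRACTION = 0.25

_TIME_COL_PATTERN = r"^t(?P<hpf>\d+(?:\.\d+)?)(?:_r(?P<rep>\w+))?$"


@dataclass
class ExpressionMatrix:
    """Genes x (time points x replicates) linear-scale expression values.

    ``values`` has shape ``(n_genes, n_timepoints, n_replicates)``; missing
    measurements are NaN. ``replicate_ids`` is None when the source table
    carried a single unnamed measurement per time point.
    """

    species: str
    gene_ids: list[str]
    timepoints: np.ndarray
    values: np.ndarray
    replicate_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, np.newaxis]
        if self.values.ndim != 3:
            raise ValueError("values must be (genes, timepoints[, replicates])")
        dupes = [g for g, n in Counter(self.gene_ids).items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match values")
        if self.timepoints.size != self.values.shape[1]:
            raise ValueError("timepoints length does not match values")
        if self.timepoints.size and (
            np.any(self.timepoints < 0) or np.any(np.diff(self.timepoints) <= 0)
        ):
            raise ValueError("timepoints must be non-negative and strictly increasing")
        if self.replicate_ids is not None and len(self.replicate_ids) != self.values.shape[2]:
            raise ValueError("replicate_ids length does not match values")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return int(self.timepoints.size)

    @property
    def n_replicates(self) -> int:
        return int(self.values.shape[2])

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(gene_id) from None

    def replicate_mean(self) -> np.ndarray:
        """Per-gene profile averaged over replicates, shape (genes, timepoints)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=2)

    def na_fraction(self) -> np.ndarray:
        """Per-gene fraction of missing cells across all measurement columns."""
        return np.isnan(self.values).reshape(self.n_genes, -1).mean(axis=1)

    def dense_gene_mask(self, max_na_fraction: float = MAX_NA_FRACTION) -> np.ndarray:
        """Boolean mask of genes with an acceptable fraction of missing cells."""
        return self.na_fraction() <= max_na_fraction

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset (and reorder) to ``gene_ids``."""
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionMatrix(
            species=self.species,
            gene_ids=[self.gene_ids[i] for i in idx],
            timepoints=self.timepoints.copy(),
            values=self.values[idx].copy(),
            replicate_ids=None if self.replicate_ids is None else list(self.replicate_ids),
        )


def _column_header(t: float, rep: str | None) -> str:
    ts = f"{t:.10g}"
    return f"t{ts}" if rep is None else f"t{ts}_r{rep}"


def read_expression_table(
    path: str | Path, dialect: str | None = None, species: str | None = None
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The first column holds gene identifiers; remaining headers follow the
    ``t<hpf>`` / ``t<hpf>_r<rep>`` dialect. Unsorted time columns are
    auto-sorted with a logged warning. Duplicate gene ids and non-numeric
    cells (other than ``NA``) are errors.
    """
    path = Path(path)
    sep = dialect if dialect is not None else ("," if path.suffix.lower() == ".csv" else "\t")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene-id column plus measurement columns")

    gene_ids = df.iloc[:, 0].tolist()
    dupes = [g for g, n in Counter(gene_ids).items() if n > 1]
    if dupes:
        raise ValueError(f"{path}: duplicate gene id(s): {sorted(dupes)}")

    parsed = []
    for col in df.columns[1:]:
        m = pd.Series([col]).str.extract(_TIME_COL_PATTERN).iloc[0]
        if pd.isna(m["hpf"]):
            raise ValueError(f"{path}: column {col!r} does not match 't<hpf>' or 't<hpf>_r<rep>'")
        parsed.append((float(m["hpf"]), None if pd.isna(m["rep"]) else str(m["rep"]), col))

    times = sorted({t for t, _, _ in parsed})
    reps_per_time = {t: [r for tt, r, _ in parsed if tt == t] for t in times}
    rep_sets = {tuple(sorted(r, key=str)) for r in reps_per_time.values()}
    if len(rep_sets) != 1:
        raise ValueError(f"{path}: inconsistent replicate labels across time points")
    rep_labels = sorted(reps_per_time[times[0]], key=str)
    if len(rep_labels) != len(set(rep_labels)):
        raise ValueError(f"{path}: duplicated (timepoint, replicate) columns")
    has_reps = rep_labels != [None]

    header_times = [t for t, _, _ in parsed]
    if header_times != sorted(header_times):
        logger.warning("%s: time columns are not sorted; auto-sorting", path)

    col_of = {(t, r): c for t, r, c in parsed}
    values = np.empty((len(gene_ids), len(times), len(rep_labels)))
    for j, t in enumerate(times):
        for k, r in enumerate(rep_labels):
            raw = df[col_of[(t, r)]]
            for i, cell in enumerate(raw):
                text = cell.strip()
                if text in ("NA", ""):
                    values[i, j, k] = np.nan
                    continue
                try:
                    # exact strtod parse; pandas' fast parser can be 1 ulp off
                    values[i, j, k] = float(text)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at gene {gene_ids[i]!r}, "
                        f"column {col_of[(t, r)]!r}"
                    ) from None

    matrix = ExpressionMatrix(
        species=species or path.stem,
        gene_ids=gene_ids,
        timepoints=np.asarray(times),
        values=values,
        replicate_ids=[str(r) for r in rep_labels] if has_reps else None,
    )
    logger.info(
        "%s: parsed %d genes, %d time points, %d replicate(s)",
        path,
        matrix.n_genes,
        matrix.n_timepoints,
        matrix.n_replicates,
    )
    return matrix


def write_expression_table(matrix: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    """Write ``matrix`` so that :func:`read_expression_table` round-trips it bit-identically."""
    path = Path(path)
    sep = dialect if dialect is not None else ("," if path.suffix.lower() == ".csv" else "\t")
    reps = matrix.replicate_ids if matrix.replicate_ids is not None else [None]
    headers = ["gene_id"] + [
        _column_header(t, r) for t in matrix.timepoints for r in reps
    ]
    with path.open("w") as fh:
        fh.write(sep.join(headers) + "\n")
        flat = matrix.values.reshape(matrix.n_genes, -1)
        for gid, row in zip(matrix.gene_ids, flat):
            cells = ["NA" if np.isnan(v) else f"{v:.17g}" for v in row]
            fh.write(sep.join([gid] + cells) + "\n")


@dataclass
class OrthologMap:
    """One-to-one orthologue pairs ``(gene_id_species_A, gene_id_species_B)``."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def one_to_one(self) -> "OrthologMap":
        """Drop many-to-many entries: keep pairs whose both members occur exactly once."""
        count_a = Counter(a for a, _ in self.pairs)
        count_b = Counter(b for _, b in self.pairs)
        kept = [(a, b) for a, b in self.pairs if count_a[a] == 1 and count_b[b] == 1]
        n_dropped = len(self.pairs) - len(kept)
        if n_dropped:
            logger.warning("dropped %d many-to-many orthologue pair(s)", n_dropped)
        return OrthologMap(kept)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: orthologue map needs two columns")
        return cls([(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])])

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for a, b in self.pairs:
                fh.write(f"{a}\t{b}\n")


@dataclass
class GeneClassLabels:
    """Mapping gene id -> functional class label (stand-in for GO classes)."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, lab in self.labels.items():
            if not str(lab).strip():
                raise ValueError(f"empty class label for gene {gid!r}")

    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def genes_of(self, label: str) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == label]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneClassLabels":
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: class-label table needs two columns")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for g, lab in self.labels.items():
                fh.write(f"{g}\t{lab}\n")


def align_orthologs(
    matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix, ortholog_map: OrthologMap
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to mapped orthologue pairs, row-aligned.

    Row ``i`` of the first output is the orthologue of row ``i`` of the
    second. Pairs referencing absent gene ids are dropped with a warning;
    an empty intersection is an error.
    """
    omap = ortholog_map.one_to_one()
    genes_a = set(matrix_a.gene_ids)
    genes_b = set(matrix_b.gene_ids)
    kept = [(a, b) for a, b in omap.pairs if a in genes_a and b in genes_b]
    n_dropped = len(omap.pairs) - len(kept)
    if n_dropped:
        logger.warning("dropped %d orthologue pair(s) referencing absent gene ids", n_dropped)
    if not kept:
        raise ValueError("no orthologue pairs map into both matrices")
    logger.info(
        "aligned %d orthologue pairs (%d/%d genes unmapped in A/B)",
        len(kept),
        matrix_a.n_genes - len(kept),
        matrix_b.n_genes - len(kept),
    )
    sub_a = matrix_a.subset([a for a, _ in kept])
    sub_b = matrix_b.subset([b for _, b in kept])
    return sub_a, sub_b


def read_config(path: str | Path) -> dict:
    """Read a plain-text ``key: value`` run configuration (YAML subset)."""
    import yaml

    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be flat 'key: value' lines")
    return cfg
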