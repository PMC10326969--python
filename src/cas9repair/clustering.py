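"""Clustering of per-outcome knockout-response profiles.

Each retained (target, outcome) pair becomes a row of log2 fold changes
across the knockout lines; rows are embedded in 2D with UMAP (min_dist 0,
50 neighbours by default) and grouped with seeded k-means (7 clusters by
default).  Summaries report cluster x category composition, knockout
enrichment (column z-scores averaged within cluster), and per-cluster
deletion directionality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OutcomeProfile, ScreenDataset
from .outcomes import ClassifiedOutcome, Indel
from .profiling import LFC_PSEUDOCOUNT, classification_cache

__all__ = [
    "LFCMatrix",
    "EmbeddingResult",
    "select_outcomes",
    "build_lfc_matrix",
    "embed",
    "cluster",
    "composition",
    "ko_enrichment",
    "cluster_directionality",
]

logger = logging.getLogger(__name__)


@dataclass
class LFCMatrix:
    """Per-outcome log2 fold changes (rows: (target_id, outcome key);
    columns: knockout lines) plus row annotations (category, control
    frequency, deletion size, MH length, directionality)."""

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.annotations.index):
            raise ValueError("values and annotations must share a row index")
        if self.values.isna().any().any():
            raise ValueError("LFC matrix contains missing values")


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    index: pd.MultiIndex
    n_neighbors: int
    min_dist: float
    seed: int


def _profiles_by_line(dataset: ScreenDataset) -> dict[str, dict[str, OutcomeProfile]]:
    out: dict[str, dict[str, OutcomeProfile]] = {}
    for (key, tid), prof in dataset.profiles.items():
        out.setdefault(key.cell_line, {})[tid] = prof
    return out


def select_outcomes(
    dataset: ScreenDataset, min_lines: int = 10
) -> list[tuple[str, str]]:
    """Rows entering the matrix: (target, outcome) present in the control
    AND with nonzero count in at least ``min_lines`` knockout lines."""
    by_line = _profiles_by_line(dataset)
    ctrl = dataset.control_line_name
    if ctrl not in by_line:
        raise ValueError(f"control line {ctrl!r} absent")
    ko_lines = [ln for ln in by_line if ln != ctrl]
    rows = []
    for tid, ctrl_prof in sorted(by_line[ctrl].items()):
        for o, n in sorted(ctrl_prof.counts.items(), key=lambda kv: kv[0].key()):
            if n <= 0:
                continue
            present = sum(
                1
                for ln in ko_lines
                if by_line[ln].get(tid) is not None
                and by_line[ln][tid].counts.get(o, 0) > 0
            )
            if present >= min_lines:
                rows.append((tid, o.key()))
    return rows


def build_lfc_matrix(
    dataset: ScreenDataset,
    rows: list[tuple[str, str]] | None = None,
    pseudocount: float = LFC_PSEUDOCOUNT,
    min_lines: int = 10,
    cache: dict[tuple[str, Indel], ClassifiedOutcome] | None = None,
) -> LFCMatrix:
    """Assemble the clustering input from a pooled dataset."""
    if rows is None:
        rows = select_outcomes(dataset, min_lines=min_lines)
    if cache is None:
        cache = classification_cache(dataset)
    by_line = _profiles_by_line(dataset)
    ctrl = dataset.control_line_name
    ko_lines = sorted(ln for ln in by_line if ln != ctrl)
    freq_cache = {
        (ln, tid): prof.frequencies()
        for ln, profs in by_line.items()
        for tid, prof in profs.items()
    }
    data, ann = [], []
    for tid, okey in rows:
        o = Indel.from_key(okey)
        f_ctrl = freq_cache[(ctrl, tid)].get(o, 0.0)
        lfcs = [
            np.log2(
                (freq_cache[(ln, tid)].get(o, 0.0) + pseudocount)
                / (f_ctrl + pseudocount)
            )
            for ln in ko_lines
        ]
        co = cache.get((tid, o))
        if co is None:
            from .outcomes import classify

            co = classify(dataset.targets[tid], o)
        data.append(lfcs)
        ann.append(
            (
                co.category.name,
                f_ctrl,
                o.deletion_size,
                co.mh_len,
                co.directionality if co.directionality is not None else np.nan,
            )
        )
    index = pd.MultiIndex.from_tuples(rows, names=["target_id", "outcome"])
    values = pd.DataFrame(data, index=index, columns=ko_lines)
    annotations = pd.DataFrame(
        ann,
        index=index,
        columns=["category", "control_freq", "deletion_size", "mh_len", "directionality"],
    )
    return LFCMatrix(values, annotations)


def embed(
    matrix: LFCMatrix,
    n_neighbors: int = 50,
    min_dist: float = 0.0,
    seed: int = 0,
) -> EmbeddingResult:
    """2D UMAP of the fold-change rows; deterministic under a fixed seed
    (umap-learn runs single-threaded when random_state is set)."""
    n_rows = len(matrix.values)
    if n_rows < n_neighbors:
        raise ValueError(
            f"{n_rows} rows < n_neighbors={n_neighbors}; reduce n_neighbors"
        )
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        coords = reducer.fit_transform(matrix.values.to_numpy())
    return EmbeddingResult(
        np.asarray(coords), matrix.values.index, n_neighbors, min_dist, seed
    )


def cluster(
    embedding: EmbeddingResult | np.ndarray,
    k: int = 7,
    method: str = "kmeans",
    seed: int = 0,
) -> np.ndarray:
    """Group embedded rows into k clusters (labels 1..k).

    k-means on the 2D coordinates by default; a density-based alternative
    (DBSCAN, label 0 = noise) is available behind ``method='dbscan'``."""
    coords = embedding.coords if isinstance(embedding, EmbeddingResult) else embedding
    if method == "kmeans":
        if k > len(coords):
            raise ValueError(f"k={k} exceeds {len(coords)} rows")
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        return km.fit_predict(coords) + 1
    if method == "dbscan":
        from sklearn.cluster import DBSCAN

        labels = DBSCAN(eps=0.5, min_samples=10).fit_predict(coords)
        return np.where(labels < 0, 0, labels + 1)
    raise ValueError(f"unknown clustering method {method!r}")


def composition(
    labels: np.ndarray, categories: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two re-normalizations of the cluster x category contingency table:
    per-category distribution among clusters (columns sum to 100%) and
    per-cluster composition (rows sum to 100%)."""
    counts = pd.crosstab(
        pd.Series(labels, index=categories.index, name="cluster"), categories
    )
    among_clusters = counts.div(counts.sum(axis=0), axis=1) * 100.0
    within_cluster = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return among_clusters, within_cluster


def ko_enrichment(labels: np.ndarray, matrix: LFCMatrix) -> pd.DataFrame:
    """Mean column z-score per cluster: each knockout's fold changes are
    z-scored across all rows, then averaged within each cluster."""
    vals = matrix.values
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    z = vals.copy()
    for col in vals.columns:
        if sd[col] == 0:
            logger.warning("zero-variance LFC column %r; z-scores set to 0", col)
            z[col] = 0.0
        else:
            z[col] = (vals[col] - mu[col]) / sd[col]
    z["cluster"] = labels
    return z.groupby("cluster").mean().sort_index()


def cluster_directionality(
    labels: np.ndarray,
    matrix: LFCMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Mean directionality of non-homologous pure deletions per cluster,
    with a seeded percentile bootstrap CI.  Clusters with no qualifying
    rows report NaN."""
    ann = matrix.annotations
    rng = np.random.default_rng(seed)
    alpha = (1 - ci) / 2
    rows = []
    for lab in sorted(set(labels.tolist())):
        mask = (
            (labels == lab)
            & (ann["deletion_size"] > 0)
            & (ann["mh_len"] == 0)
            & ann["directionality"].notna()
        )
        vals = ann.loc[mask, "directionality"].to_numpy()
        if len(vals) == 0:
            rows.append((lab, 0, np.nan, np.nan, np.nan))
            continue
        mean = float(vals.mean())
        boot = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        bmeans = vals[boot].mean(axis=1)
        lo, hi = np.quantile(bmeans, [alpha, 1 - alpha])
        rows.append((lab, len(vals), mean, float(lo), float(hi)))
    return pd.DataFrame(
        rows, columns=["cluster", "n", "mean_directionality", "ci_low", "ci_high"]
    )
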