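"""Single-cell postanalysis pipeline.

Order is fixed and enforced through the matrix ``stage`` field:

    filter_missing -> impute_min -> log2_normalize -> embed / differential_expression

Missing values are assumed missing-not-at-random (low abundance), so proteins
absent from too many cells are dropped, the remainder min-imputed, and
quantities log2-transformed and standardized before embedding. Differential
expression runs a two-sided equal-variance (Student) t-test on the log2
values, corrects with Benjamini–Hochberg, and flags a protein upregulated
when its BH q-value clears alpha and its linear group-mean ratio exceeds 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import QuantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_missing",
    "impute_min",
    "log2_normalize",
    "embed",
    "EmbeddingResult",
    "differential_expression",
    "group_cv_summary",
    "cluster_order",
    "PipelineOrderError",
]


class PipelineOrderError(RuntimeError):
    """A pipeline step was invoked out of order (e.g. DE on non-imputed data)."""


def _nonblank_samples(matrix: QuantMatrix) -> list[str]:
    meta = matrix.sample_meta
    if "is_blank" in meta.columns:
        return list(meta.index[~meta["is_blank"].astype(bool)])
    return list(meta.index)


def filter_missing(matrix: QuantMatrix, max_missing_cells: int) -> QuantMatrix:
    """Drop proteins missing in more than ``max_missing_cells`` cells.

    The inequality is strict: a protein missing in exactly the threshold
    number of cells is kept. Blank samples do not count toward the threshold.
    """
    if max_missing_cells < 0:
        raise ValueError("max_missing_cells must be >= 0")
    cells = _nonblank_samples(matrix)
    n_missing = (~matrix.observed[cells]).sum(axis=1)
    keep = matrix.values.index[n_missing <= max_missing_cells]
    removed = matrix.values.shape[0] - len(keep)
    logger.info("filter_missing: removed %d of %d proteins", removed, matrix.values.shape[0])
    out = matrix.subset_proteins(keep, stage="filtered")
    return out


def impute_min(matrix: QuantMatrix) -> QuantMatrix:
    """Substitute every missing cell with the global minimum observed value.

    The observed mask is preserved unchanged for audit.
    """
    vals = matrix.values
    if not matrix.observed.to_numpy().any():
        raise ValueError("all-missing matrix: nothing to impute from")
    global_min = float(np.nanmin(vals.to_numpy()))
    filled = vals.fillna(global_min)
    return matrix.evolve(values=filled, stage="imputed", linear=filled)


def log2_normalize(matrix: QuantMatrix, mode: str = "zscore_per_protein") -> QuantMatrix:
    """Log2-transform and standardize toward a normal distribution.

    Modes: ``zscore_per_protein`` (each protein row to mean 0, sample SD 1),
    ``zscore_global`` (one mean/SD over the whole matrix), ``none`` (pure
    log2). Zero-variance rows become all-zero with a warning.
    """
    vals = matrix.values
    if vals.isna().to_numpy().any():
        raise PipelineOrderError("matrix has missing cells: run impute_min first")
    if (vals.to_numpy() <= 0).any():
        raise ValueError("nonpositive values: impute_min on positive quantities first")
    logged = np.log2(vals)
    if mode == "none":
        out = logged
    elif mode == "zscore_global":
        flat = logged.to_numpy()
        out = (logged - flat.mean()) / flat.std(ddof=1)
    elif mode == "zscore_per_protein":
        mean = logged.mean(axis=1)
        sd = logged.std(axis=1, ddof=1)
        zero_var = sd == 0
        if zero_var.any():
            warnings.warn(
                f"{int(zero_var.sum())} constant protein row(s) set to all-zero",
                RuntimeWarning,
                stacklevel=2,
            )
        sd = sd.replace(0.0, np.inf)  # constant rows -> 0 after centering
        out = logged.sub(mean, axis=0).div(sd, axis=0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return matrix.evolve(values=out, stage="log2", linear=matrix.linear)


@dataclass(frozen=True)
class EmbeddingResult:
    """Low-dimensional sample coordinates."""

    coordinates: pd.DataFrame            # samples x components
    method: str
    seed: int | None = None
    explained_variance_ratio: np.ndarray | None = None  # linear_pca only


def _require_processed(matrix: QuantMatrix, step: str) -> None:
    if matrix.stage != "log2":
        raise PipelineOrderError(
            f"{step} requires a filtered, imputed and log2-normalized matrix "
            f"(stage={matrix.stage!r}); run filter_missing -> impute_min -> log2_normalize"
        )


def embed(
    matrix: QuantMatrix,
    method: str = "linear_pca",
    n_components: int = 2,
    seed: int = 0,
) -> EmbeddingResult:
    """Embed samples with PCA or a UMAP-style nonlinear projection.

    Operates on the processed matrix (samples as observations, proteins as
    features). UMAP defaults: 15 neighbors, min_dist 0.1, seeded.
    """
    _require_processed(matrix, "embed")
    X = matrix.values.to_numpy().T
    n_samples, n_features = X.shape
    if n_samples < 3:
        raise ValueError("need >= 3 samples to embed")
    if n_components > min(n_samples, n_features):
        raise ValueError("n_components exceeds matrix rank bound")
    cols = [f"dim{i + 1}" for i in range(n_components)]
    if method == "linear_pca":
        pca = PCA(n_components=n_components, random_state=seed)
        coords = pca.fit_transform(X)
        return EmbeddingResult(
            coordinates=pd.DataFrame(coords, index=matrix.values.columns, columns=cols),
            method=method,
            seed=seed,
            explained_variance_ratio=pca.explained_variance_ratio_,
        )
    if method == "umap_like":
        import umap  # deferred: numba compilation is slow at import

        reducer = umap.UMAP(
            n_components=n_components,
            n_neighbors=min(15, n_samples - 1),
            min_dist=0.1,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = reducer.fit_transform(X)
        return EmbeddingResult(
            coordinates=pd.DataFrame(coords, index=matrix.values.columns, columns=cols),
            method=method,
            seed=seed,
        )
    raise ValueError(f"unknown embedding method {method!r}")


def differential_expression(
    matrix: QuantMatrix,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression (orientation B over A).

    The two-sided Student's t-test (pooled variance) runs on the log2
    processed values; the fold change is the ratio of linear group means from
    the post-imputation values. BH correction is applied over all tested
    proteins; ``upregulated`` requires q < alpha and linear fold change > 1.
    Proteins with zero within-group variance in both groups get p = 1 and a
    ``degenerate`` flag.
    """
    _require_processed(matrix, "differential_expression")
    if matrix.linear is None:
        raise PipelineOrderError("matrix lost its linear values; rerun impute_min")
    if len(group_a_ids) < 2 or len(group_b_ids) < 2:
        raise ValueError("need >= 2 samples per group")
    if "is_blank" in matrix.sample_meta.columns:
        blanks = set(matrix.sample_meta.index[matrix.sample_meta["is_blank"].astype(bool)])
        used = set(group_a_ids) | set(group_b_ids)
        if used & blanks:
            raise ValueError(f"blank samples in DE groups: {sorted(used & blanks)}")

    log_a = matrix.values[list(group_a_ids)].to_numpy()
    log_b = matrix.values[list(group_b_ids)].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=True)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")

    lin_a = matrix.linear[list(group_a_ids)].mean(axis=1).to_numpy()
    lin_b = matrix.linear[list(group_b_ids)].mean(axis=1).to_numpy()
    fc = lin_b / lin_a
    out = pd.DataFrame(
        {
            "fc_linear": fc,
            "t_stat": t_stat,
            "p": p,
            "q": q,
            "upregulated": (q < alpha) & (fc > 1.0),
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    out.attrs["alpha"] = alpha
    out.attrs["orientation"] = "fc_linear = mean(group B) / mean(group A)"
    return out


def group_cv_summary(
    matrix: QuantMatrix, grouping: Mapping[str, Sequence[str]] | str
) -> pd.Series:
    """Median per-protein CV (%) within each sample group, on raw quantities.

    ``grouping`` maps group label -> sample ids, or names a ``sample_meta``
    column to group by. Groups need >= 2 members.
    """
    if isinstance(grouping, str):
        col = matrix.sample_meta[grouping]
        grouping = {str(g): list(col.index[col == g]) for g in col.dropna().unique()}
    medians: dict[str, float] = {}
    for label, samples in grouping.items():
        if len(samples) < 2:
            raise ValueError(f"group {label!r} has < 2 samples")
        sub = matrix.values[list(samples)]
        n_obs = sub.notna().sum(axis=1)
        sub = sub[n_obs >= 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = 100.0 * sub.std(axis=1, ddof=1, skipna=True) / sub.mean(axis=1, skipna=True)
        medians[label] = float(cv.dropna().median())
    return pd.Series(medians, name="median_cv_percent")


def cluster_order(
    matrix: QuantMatrix, axis: str = "samples", metric: str = "euclidean",
    method: str = "average"
) -> list[str]:
    """Hierarchical-clustering leaf order for heat-map display."""
    _require_processed(matrix, "cluster_order")
    data = matrix.values.to_numpy().T if axis == "samples" else matrix.values.to_numpy()
    labels = matrix.values.columns if axis == "samples" else matrix.values.index
    link = hierarchy.linkage(pdist(data, metric=metric), method=method)
    order = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(link, pdist(data, metric=metric)))
    return [labels[i] for i in order]
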