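"""Zero-transformation, fold-change filtering, clustering, paired comparison.

The zero-transformation converts absolute log2 expression into log2 ratios
relative to the mean of the matched control samples — per probe and, when
``match_time`` is set, per time point — so a ratio of 1.0 is a two-fold
change over control.  Fold-change filtering then keeps probes showing at
least a given fold change in at least a given number of samples, the
selection rule used throughout for display and screening.  Hierarchical
clustering (uncentered-correlation distance, average linkage by default,
mirroring the Cluster 3.0 conventions) provides the display ordering, and
``compare_response_magnitude`` is the paired probe-level t-test used to ask
whether one cell line's overall response is attenuated relative to another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

__all__ = [
    "zero_transform",
    "filter_fold_change",
    "hierarchical_cluster",
    "compare_response_magnitude",
    "pairwise_distance",
    "ClusterResult",
]

logger = logging.getLogger(__name__)

#: distance assigned to rows for which a correlation is undefined
MAX_CORRELATION_DISTANCE = 2.0


def _check_annotation(expr: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    if "arm" not in annot.columns:
        raise ValidationError("annotation must have an 'arm' column")
    missing = expr.columns.difference(annot.index)
    if len(missing) > 0:
        raise ValidationError(
            f"samples missing from annotation: {', '.join(map(str, missing[:5]))}"
        )
    if annot.index.has_duplicates:
        dupes = annot.index[annot.index.duplicated()].unique()
        raise ValidationError(
            f"duplicate sample annotation for: {', '.join(map(str, dupes[:5]))}"
        )
    return annot.loc[expr.columns]


def zero_transform(
    expr: pd.DataFrame, annot: pd.DataFrame, match_time: bool = True
) -> pd.DataFrame:
    """Subtract the (time-matched) control mean from every non-control sample.

    Parameters
    ----------
    expr:
        Log2 expression, probes x samples.
    annot:
        Sample annotation indexed by sample id with columns ``arm`` and,
        if ``match_time``, ``time_point``.
    match_time:
        When True each treatment sample is referenced to the mean of the
        control samples sharing its time point; otherwise to the mean of
        all control samples.

    Returns
    -------
    A probes x treatment-samples DataFrame of log2 ratios; control columns
    are dropped.
    """
    annot = _check_annotation(expr, annot)
    is_control = annot["arm"] == "control"
    if not is_control.any():
        raise ValidationError("no control samples in annotation")
    treat_cols = [s for s in expr.columns if not is_control.loc[s]]
    if not treat_cols:
        raise ValidationError("no non-control samples to transform")

    out = {}
    if match_time:
        if "time_point" not in annot.columns:
            raise ValidationError("match_time requires a 'time_point' column")
        for s in treat_cols:
            tp = annot.loc[s, "time_point"]
            ctrl = annot.index[(annot["time_point"] == tp) & is_control]
            if len(ctrl) == 0:
                raise ValidationError(
                    f"no control samples for time point {tp!r}"
                )
            out[s] = expr[s] - expr[list(ctrl)].mean(axis=1)
    else:
        ref = expr[list(annot.index[is_control])].mean(axis=1)
        for s in treat_cols:
            out[s] = expr[s] - ref
    return pd.DataFrame(out, index=expr.index)[treat_cols]


def filter_fold_change(
    ztm: pd.DataFrame, fold: float, min_obs: int
) -> pd.Index:
    """Probes with ``|log2 ratio| >= log2(fold)`` in at least ``min_obs`` samples.

    The threshold is inclusive (a ratio of exactly ``log2(fold)`` counts),
    matching the usual microarray convention.  Input probe order is
    preserved.
    """
    if fold <= 1:
        raise ValidationError(f"fold must be > 1, got {fold}")
    if not 1 <= min_obs <= ztm.shape[1]:
        raise ValidationError(
            f"min_obs must be in [1, {ztm.shape[1]}], got {min_obs}"
        )
    cutoff = np.log2(fold)
    counts = (ztm.abs() >= cutoff).sum(axis=1)
    return ztm.index[counts >= min_obs]


@dataclass
class ClusterResult:
    """Row dendrogram: scipy linkage matrix plus the resulting leaf order."""

    probe_ids: pd.Index
    leaf_order: np.ndarray       # permutation of row indices
    linkage_matrix: np.ndarray   # scipy (n-1) x 4 merge table
    distance: str
    linkage: str

    @property
    def ordered_probes(self) -> pd.Index:
        return self.probe_ids[self.leaf_order]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def pairwise_distance(matrix: pd.DataFrame, metric: str) -> np.ndarray:
    """Square distance matrix between rows.

    ``uncentered``: 1 minus the uncentered Pearson correlation
    (cosine similarity of the raw rows); ``pearson``: 1 - r; ``euclidean``:
    the usual metric.  Rows for which a correlation is undefined (zero norm
    or zero variance) get the maximal correlation distance 2.0.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if metric == "euclidean":
        return squareform(pdist(x, metric="euclidean"))
    if metric == "uncentered":
        norms = np.sqrt((x**2).sum(axis=1))
        bad = norms == 0
        safe = np.where(bad, 1.0, norms)
        sim = (x @ x.T) / np.outer(safe, safe)
        dist = 1.0 - sim
    elif metric == "pearson":
        sd = x.std(axis=1)
        bad = sd == 0
        centered = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        safe = np.where(bad, 1.0, norms)
        sim = (centered @ centered.T) / np.outer(safe, safe)
        dist = 1.0 - sim
    else:
        raise ValidationError(
            f"unknown distance {metric!r}; expected uncentered, pearson or "
            "euclidean"
        )
    dist[bad, :] = MAX_CORRELATION_DISTANCE
    dist[:, bad] = MAX_CORRELATION_DISTANCE
    np.fill_diagonal(dist, 0.0)
    np.clip(dist, 0.0, None, out=dist)
    return (dist + dist.T) / 2.0


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "uncentered",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows for display ordering.

    Defaults follow the Cluster 3.0 conventions: uncentered correlation
    distance with average linkage.  The agglomeration itself is scipy's;
    given a fixed input it is deterministic.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 rows")
    if linkage not in ("average", "complete", "single"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    dist = pairwise_distance(matrix, distance)
    condensed = squareform(dist, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        probe_ids=matrix.index,
        leaf_order=order,
        linkage_matrix=z,
        distance=distance,
        linkage=linkage,
    )


def compare_response_magnitude(
    ztm_a: pd.DataFrame,
    ztm_b: pd.DataFrame,
    probes=None,
) -> tuple[float, float]:
    """Paired t-test of per-probe mean responses between two experiments.

    Each probe contributes one pair: its mean log2 ratio over the samples of
    experiment A vs. the same mean in experiment B.  A positive t means the
    A responses are larger.  Degenerate case: if every pairwise difference
    is identical the statistic is undefined; the test reports (0, 1) when
    the common difference is zero and a signed infinite statistic with p=0
    otherwise.
    """
    if probes is None:
        probes = ztm_a.index.intersection(ztm_b.index)
    else:
        probes = pd.Index(probes)
        for name, ztm in (("A", ztm_a), ("B", ztm_b)):
            missing = probes.difference(ztm.index)
            if len(missing) > 0:
                raise ValidationError(
                    f"probes missing from matrix {name}: "
                    f"{', '.join(map(str, missing[:5]))}"
                )
    if len(probes) < 2:
        raise ValidationError("need at least 2 shared probes")
    mean_a = ztm_a.loc[probes].mean(axis=1).to_numpy()
    mean_b = ztm_b.loc[probes].mean(axis=1).to_numpy()
    diff = mean_a - mean_b
    if np.std(diff, ddof=1) == 0:
        d = diff[0]
        if d == 0:
            return 0.0, 1.0
        logger.warning("degenerate paired t-test: constant nonzero difference")
        return float(np.sign(d)) * float("inf"), 0.0
    t, p = stats.ttest_rel(mean_a, mean_b)
    return float(t), float(p)
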