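"""Gaussian-mixture clustering of z-scored expression trajectories.

Each gene's replicate-averaged log2 normalized trajectory is standardized
across timepoints; for each candidate k a full-covariance GMM is fitted with
``gmm_n_init`` random initializations, k is selected by minimum mean BIC,
and the final labels come from consensus over the per-seed partitions
(co-association matrix cut by average-linkage).  Clusters are then mapped to
the three qualitative patterns: steep upregulation after day 3, gradual
downregulation, or transient (up until day 3, then repressed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture

from .config import Thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "z_transform",
    "select_k_and_cluster",
    "consensus_labels",
    "assign_patterns",
    "cluster_trajectories",
    "ClusterResult",
]


@dataclass
class ClusterResult:
    k_selected: int
    labels: pd.Series  # gene -> consensus cluster
    patterns: dict[int, str]  # cluster -> pattern
    bic_by_k: pd.DataFrame  # k x seed BIC values
    flat_genes: list[str]  # zero-variance genes excluded from clustering


def z_transform(traj: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row across timepoints; flag zero-variance rows.

    Zero-variance genes get an all-zero vector and are reported separately
    rather than clustered.
    """
    if traj.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    mu = traj.mean(axis=1)
    sd = traj.std(axis=1, ddof=0)
    flat = sd == 0
    z = traj.sub(mu, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return z, list(traj.index[flat])


def select_k_and_cluster(
    z: pd.DataFrame,
    k_range: range = range(2, 11),
    n_init: int = 20,
    seed: int = 0,
) -> tuple[int, list[np.ndarray], pd.DataFrame]:
    """Fit n_init seeded GMMs per k; pick k by minimum mean BIC.

    Returns the selected k, the per-seed label vectors at that k, and the
    full k x seed BIC table.  Singular fits are retried with a stronger
    covariance ridge.
    """
    ks = list(k_range)
    if len(ks) < 2:
        raise ValueError("k_range must contain >= 2 values")
    if len(z) <= max(ks):
        raise ValueError("need more genes than the largest k")
    x = z.to_numpy(float)
    seeds = np.random.SeedSequence(seed).generate_state(n_init) % (2**31)
    bic = np.zeros((len(ks), n_init))
    labels_by_k: dict[int, list[np.ndarray]] = {k: [] for k in ks}
    for i, k in enumerate(ks):
        for j, s in enumerate(seeds):
            gm = _fit_gmm(x, k, int(s))
            bic[i, j] = gm.bic(x)
            labels_by_k[k].append(gm.predict(x))
    mean_bic = bic.mean(axis=1)
    k_sel = ks[int(np.argmin(mean_bic))]
    table = pd.DataFrame(bic, index=pd.Index(ks, name="k"))
    return k_sel, labels_by_k[k_sel], table


def _fit_gmm(x: np.ndarray, k: int, seed: int) -> GaussianMixture:
    for reg in (1e-6, 1e-3, 1e-1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=1,
            reg_covar=reg,
            random_state=seed,
        )
        try:
            gm.fit(x)
            return gm
        except ValueError:
            logger.warning("singular GMM fit at k=%d, retrying with reg_covar=%g", k, reg * 100)
    raise RuntimeError(f"GMM fit failed for k={k} at all ridge levels")


def consensus_labels(label_vectors: list[np.ndarray], k: int) -> np.ndarray:
    """Consensus partition from per-seed labels via co-association.

    The co-association matrix holds the fraction of seeds in which two
    items share a cluster; average-linkage hierarchical clustering on
    1 - co-association is cut at k groups.  Invariant to any per-seed
    relabeling of clusters.
    """
    if len(label_vectors) < 2:
        raise ValueError("need >= 2 label vectors")
    n = len(label_vectors[0])
    co = np.zeros((n, n))
    for lab in label_vectors:
        lab = np.asarray(lab)
        co += (lab[:, None] == lab[None, :]).astype(float)
    co /= len(label_vectors)
    dist = 1.0 - co
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust") - 1


def assign_patterns(
    mean_trajectories: pd.DataFrame,
    days: list[int],
    delta: float = 0.5,
) -> dict[int, str]:
    """Map each cluster's mean z-trajectory to a qualitative pattern.

    up_after_d3: mean(after day 3) - mean(<= day 3) > +delta and the
    trajectory peaks at the final timepoint.  transient: rises to a peak
    after day 0 but at or before day 3, then ends below its own mean
    (a monotone decline peaks at day 0 and is gradual, not transient).
    Otherwise gradual_down.
    """
    days_arr = np.asarray(days)
    early = days_arr <= 3
    late = ~early
    if not late.any():
        raise ValueError("need at least one timepoint after day 3")
    out = {}
    for cl, row in mean_trajectories.iterrows():
        v = row.to_numpy(float)
        lift = v[late].mean() - v[early].mean()
        argmax_day = days_arr[int(np.argmax(v))]
        if lift > delta and np.argmax(v) == len(v) - 1:
            out[cl] = "up_after_d3"
        elif 0 < argmax_day <= 3 and v[-1] < v.mean():
            out[cl] = "transient"
        else:
            out[cl] = "gradual_down"
    return out


def cluster_trajectories(
    traj: pd.DataFrame,
    days: list[int],
    k_range: range = range(2, 11),
    thresholds: Thresholds | None = None,
    seed: int = 0,
    pattern_delta: float = 0.5,
) -> ClusterResult:
    """Full clustering pass: z-transform, k selection, consensus, patterns."""
    th = thresholds or Thresholds()
    z, flat = z_transform(traj)
    z_used = z.drop(index=flat)
    k_sel, per_seed, bic = select_k_and_cluster(
        z_used, k_range=k_range, n_init=th.gmm_n_init, seed=seed
    )
    cons = consensus_labels(per_seed, k_sel)
    labels = pd.Series(cons, index=z_used.index, name="cluster")
    means = z_used.groupby(labels).mean()
    patterns = assign_patterns(means, days, delta=pattern_delta)
    return ClusterResult(
        k_selected=k_sel, labels=labels, patterns=patterns, bic_by_k=bic, flat_genes=flat
    )
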