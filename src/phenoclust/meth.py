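"""Methylation grouping: probe filtering, Spearman-distance consensus
k-means, and CDF/silhouette selection of the number of groups.

Beta values (methylation fractions, bimodal in [0, 1]) are clustered
directly; Spearman correlation is used as the distance because beta values
are far from normally distributed.  Cluster stability is assessed by Monti
consensus clustering: repeated k-means on random sample subsets, aggregated
into a consensus matrix per k, with the number of groups chosen from the
consensus CDF area gains together with silhouette widths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_samples, silhouette_score

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# probe-level preprocessing


def validate_beta(beta: pd.DataFrame) -> None:
    values = beta.to_numpy()
    if np.isnan(values).any():
        probe = beta.index[np.isnan(values).any(axis=1)][0]
        raise ValueError(f"beta matrix contains missing values (e.g. probe {probe})")
    if (values < 0).any() or (values > 1).any():
        bad = np.argwhere((values < 0) | (values > 1))[0]
        raise ValueError(
            f"beta values outside [0, 1]: probe {beta.index[bad[0]]}, "
            f"sample {beta.columns[bad[1]]} = {values[bad[0], bad[1]]!r}"
        )


def filter_probes(beta: pd.DataFrame, annotation: pd.DataFrame,
                  detection_p: pd.DataFrame, p_thresh: float = 0.05):
    """Apply the standard methylation-array probe filters.

    A probe is retained when it (i) does not map to chrX/chrY, (ii) has no
    common SNP at or adjacent to the targeted CpG, (iii) maps uniquely, and
    additionally has detection p < ``p_thresh`` in *every* sample.

    Returns ``(filtered_beta, tally)`` where ``tally`` counts removals per
    rule, attributing each removed probe to the first rule it violates (in
    the order above) while all rules are applied.
    """
    missing_ann = beta.index.difference(annotation.index)
    if len(missing_ann):
        raise ValueError(
            f"probes missing from annotation, e.g. {missing_ann.tolist()[:5]}"
        )
    if not beta.index.equals(detection_p.index) or not beta.columns.equals(
        detection_p.columns
    ):
        diff = beta.index.symmetric_difference(detection_p.index)
        raise ValueError(
            f"detection-p matrix keys do not match beta matrix "
            f"(e.g. {diff.tolist()[:5]})"
        )
    ann = annotation.loc[beta.index]
    sex = ann["chrom"].isin(["chrX", "chrY"]).to_numpy()
    snp = ann["snp_overlap"].astype(bool).to_numpy()
    multi = ann["multimap"].astype(bool).to_numpy()
    det_fail = (detection_p.to_numpy() >= p_thresh).any(axis=1)

    removed = sex | snp | multi | det_fail
    tally = {
        "sex_chrom": int(sex.sum()),
        "snp_overlap": int((snp & ~sex).sum()),
        "multimap": int((multi & ~sex & ~snp).sum()),
        "detection_fail": int((det_fail & ~sex & ~snp & ~multi).sum()),
        "retained": int((~removed).sum()),
    }
    logger.info("probe filtering: %s", tally)
    return beta[~removed], tally


def select_variable_probes(beta: pd.DataFrame, n: int) -> pd.DataFrame:
    """Keep the ``n`` most variable probes (SD of beta across samples).

    Ties are broken by lexicographic probe id; if ``n`` exceeds the number
    of available probes everything is kept with a warning.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n >= len(beta):
        if n > len(beta):
            warnings.warn(
                f"requested {n} probes but only {len(beta)} available; keeping all",
                stacklevel=2,
            )
        return beta
    sd = beta.std(axis=1, ddof=1).to_numpy()
    # primary key: SD descending; ties resolved by probe id ascending
    order = np.lexsort((beta.index.to_numpy(), -sd))
    return beta.iloc[order[:n]]


def spearman_distance_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample distance ``1 - rho_Spearman`` over probes."""
    if beta.shape[0] < 2 or beta.shape[1] < 2:
        raise ValueError("need at least 2 probes and 2 samples")
    ranks = rankdata(beta.to_numpy(), axis=0)
    sds = ranks.std(axis=0)
    if (sds == 0).any():
        bad = beta.columns[np.where(sds == 0)[0]].tolist()
        raise ValueError(f"constant samples have undefined rank correlation: {bad}")
    rho = np.corrcoef(ranks, rowvar=False)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=beta.columns, columns=beta.columns)


# ---------------------------------------------------------------------------
# consensus clustering


@dataclass
class ConsensusResult:
    """Consensus matrices plus k-selection diagnostics.

    ``consensus[k]`` is the sample x sample co-clustering frequency matrix
    (symmetric, unit diagonal), ``labels[k]`` the per-k partition obtained
    by average-linkage clustering of ``1 - consensus[k]``.  The diagnostic
    fields (``cdf``, ``auc``, ``delta_auc``, silhouettes, ``selected_k``)
    are filled by :func:`evaluate_k`.
    """

    sample_ids: list
    k_values: list
    consensus: dict
    labels: dict
    resample_indices: dict
    resample_labels: dict
    data_distance: pd.DataFrame | None = None
    cdf: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)
    delta_auc: dict = field(default_factory=dict)
    silhouette: dict = field(default_factory=dict)
    silhouette_consensus: dict = field(default_factory=dict)
    selected_k: int | None = None
    params: dict = field(default_factory=dict)


def _rank_embedding(X: np.ndarray) -> np.ndarray:
    """Rank-transform each sample across features, then rotate to a compact
    orthonormal basis.

    Euclidean k-means on per-sample rank vectors is the coordinate analogue
    of clustering under Spearman correlation.  The SVD rotation preserves
    all pairwise Euclidean distances exactly while reducing the feature
    dimension to at most n_samples, which makes the resampled k-means loop
    cheap.
    """
    ranks = rankdata(X, axis=1)
    centered = ranks - ranks.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u * s


def _consensus_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut average-linkage clustering of 1 - consensus into k groups."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    lk = linkage(squareform(dist, checks=False), method="average")
    return fcluster(lk, t=k, criterion="maxclust")


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by decreasing cluster size (ties: smallest
    member index first)."""
    order = sorted(
        np.unique(labels),
        key=lambda lab: (-(labels == lab).sum(), int(np.argmax(labels == lab))),
    )
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([mapping[lab] for lab in labels])


def _run_consensus(X: np.ndarray, k_values, n_resamples: int, item_fraction: float,
                   n_init: int, seed, sample_names=None):
    """Shared resampling loop: consensus matrices and per-k labels.

    ``X`` is samples x features.  Returns ``(consensus, labels,
    resample_indices, resample_labels)`` keyed by k.
    """
    n = X.shape[0]
    if min(k_values) < 2:
        raise ValueError("k_min must be >= 2")
    if n < max(k_values) + 1:
        raise ValueError(
            f"need at least k_max+1 = {max(k_values) + 1} samples, got {n}"
        )
    if not (0 < item_fraction <= 1):
        raise ValueError("item_fraction must lie in (0, 1]")

    coords = _rank_embedding(X)
    n_sub = int(np.ceil(item_fraction * n))
    root = np.random.SeedSequence(seed)
    consensus, labels, r_idx, r_lab = {}, {}, {}, {}
    for k, ss in zip(k_values, root.spawn(len(k_values))):
        rng = np.random.default_rng(ss)
        hit = np.zeros((n, n))
        both = np.zeros((n, n))
        idx_list, lab_list = [], []
        for _ in range(n_resamples):
            idx = rng.choice(n, size=n_sub, replace=False)
            km_seed = int(rng.integers(0, 2**31 - 1))
            lab = KMeans(n_clusters=k, n_init=n_init,
                         random_state=km_seed).fit_predict(coords[idx])
            same = (lab[:, None] == lab[None, :]).astype(float)
            hit[np.ix_(idx, idx)] += same
            both[np.ix_(idx, idx)] += 1.0
            idx_list.append(idx)
            lab_list.append(lab)
        if (both == 0).any():
            i, j = np.argwhere(both == 0)[0]
            ni = sample_names[i] if sample_names is not None else i
            nj = sample_names[j] if sample_names is not None else j
            raise ValueError(
                f"sample pair ({ni}, {nj}) was never co-sampled; increase "
                "n_resamples"
            )
        m = hit / both
        np.fill_diagonal(m, 1.0)
        m = np.clip((m + m.T) / 2.0, 0.0, 1.0)
        consensus[k] = m
        labels[k] = _canonical_labels(_consensus_labels(m, k))
        r_idx[k] = idx_list
        r_lab[k] = lab_list
        logger.debug("consensus for k=%d done", k)
    return consensus, labels, r_idx, r_lab


def _spearman_distance_array(X: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between rows of ``X`` (samples x features)."""
    ranks = rankdata(X, axis=1)
    rho = np.corrcoef(ranks)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return np.clip((dist + dist.T) / 2.0, 0.0, None)


class ConsensusKMeans(ClusterMixin, BaseEstimator):
    """Consensus k-means over Spearman geometry with automatic k selection.

    Parameters
    ----------
    k_min, k_max
        Inclusive range of cluster numbers to evaluate.
    n_resamples
        Number of random sample subsets per k.
    item_fraction
        Fraction of samples drawn (without replacement) per resample.
    n_init
        k-means++ restarts per k-means run.
    auc_gain_threshold
        Relative consensus-CDF area gain below which adding a cluster is
        considered uninformative.
    random_state
        Seed for subsampling and k-means.

    Attributes (after ``fit``)
    --------------------------
    consensus_matrices_ : dict of k -> (n, n) ndarray
    labels_per_k_ : dict of k -> ndarray of labels
    auc_, delta_auc_, silhouette_ : dict of per-k diagnostics
    selected_k_ : chosen number of clusters
    labels_ : labels at ``selected_k_``
    """

    def __init__(self, k_min=2, k_max=8, n_resamples=1000, item_fraction=0.8,
                 n_init=10, auc_gain_threshold=0.10, random_state=None):
        self.k_min = k_min
        self.k_max = k_max
        self.n_resamples = n_resamples
        self.item_fraction = item_fraction
        self.n_init = n_init
        self.auc_gain_threshold = auc_gain_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        """Cluster ``X`` (samples x features, e.g. beta values)."""
        X = np.asarray(X, dtype=float)
        k_values = list(range(self.k_min, self.k_max + 1))
        consensus, labels, r_idx, r_lab = _run_consensus(
            X, k_values, self.n_resamples, self.item_fraction, self.n_init,
            self.random_state,
        )
        self.n_samples_ = X.shape[0]
        self.k_values_ = k_values
        self.consensus_matrices_ = consensus
        self.labels_per_k_ = labels
        self.resample_indices_ = r_idx
        self.resample_labels_ = r_lab
        self.data_distance_ = _spearman_distance_array(X)
        self._evaluate()
        self.labels_ = self.labels_per_k_[self.selected_k_]
        return self

    def _evaluate(self):
        result = self.to_result()
        evaluate_k(result, auc_gain_threshold=self.auc_gain_threshold)
        self.cdf_ = result.cdf
        self.auc_ = result.auc
        self.delta_auc_ = result.delta_auc
        self.silhouette_ = result.silhouette
        self.silhouette_consensus_ = result.silhouette_consensus
        self.selected_k_ = result.selected_k

    def to_result(self, sample_ids=None) -> ConsensusResult:
        ids = list(sample_ids) if sample_ids is not None else list(range(self.n_samples_))
        dist = pd.DataFrame(self.data_distance_, index=ids, columns=ids)
        res = ConsensusResult(
            sample_ids=ids,
            k_values=list(self.k_values_),
            consensus={k: m.copy() for k, m in self.consensus_matrices_.items()},
            labels={k: l.copy() for k, l in self.labels_per_k_.items()},
            resample_indices=self.resample_indices_,
            resample_labels=self.resample_labels_,
            data_distance=dist,
            params=self.get_params(),
        )
        if getattr(self, "selected_k_", None) is not None:
            res.cdf = self.cdf_
            res.auc = self.auc_
            res.delta_auc = self.delta_auc_
            res.silhouette = self.silhouette_
            res.silhouette_consensus = self.silhouette_consensus_
            res.selected_k = self.selected_k_
        return res


def consensus_cluster(beta: pd.DataFrame, k_range=range(2, 9), n_resamples: int = 1000,
                      item_fraction: float = 0.8, seed: int | None = None,
                      n_init: int = 10) -> ConsensusResult:
    """Consensus k-means of the samples of a beta matrix (probes x samples).

    Thin wrapper over :class:`ConsensusKMeans` that returns a
    :class:`ConsensusResult` with consensus matrices and per-k labels filled
    and diagnostics left for :func:`evaluate_k`.
    """
    validate_beta(beta)
    k_values = sorted(k_range)
    X = beta.to_numpy().T  # samples x probes
    consensus, labels, r_idx, r_lab = _run_consensus(
        X, k_values, n_resamples, item_fraction, n_init, seed,
        sample_names=list(beta.columns),
    )
    return ConsensusResult(
        sample_ids=list(beta.columns),
        k_values=k_values,
        consensus=consensus,
        labels=labels,
        resample_indices=r_idx,
        resample_labels=r_lab,
        data_distance=spearman_distance_matrix(beta),
        params={
            "k_range": k_values, "n_resamples": n_resamples,
            "item_fraction": item_fraction, "seed": seed, "n_init": n_init,
        },
    )


def _consensus_cdf(m: np.ndarray, grid_size: int = 101):
    iu = np.triu_indices(m.shape[0], k=1)
    entries = m[iu]
    grid = np.linspace(0.0, 1.0, grid_size)
    cdf = np.searchsorted(np.sort(entries), grid, side="right") / entries.size
    return grid, cdf


def evaluate_k(result: ConsensusResult, auc_gain_threshold: float = 0.10) -> ConsensusResult:
    """Fill CDF/area/silhouette diagnostics and select the number of groups.

    For each k the CDF of the upper-triangle consensus entries is computed,
    its area A(k) by the trapezoid rule, and the relative area increment
    Delta(k) = (A(k) - A(k-1)) / A(k-1) (Delta at the smallest k is A itself).
    The CDF elbow -- the smallest k after which the area gain stays below
    ``auc_gain_threshold`` -- is reported as a diagnostic
    (``result.params['cdf_elbow_k']``).

    ``selected_k`` is the k maximizing the mean silhouette width, computed
    on the Spearman distance of the clustered data when available (otherwise
    on ``1 - M(k)``); ties go to the smallest k.  Consensus-stability
    measures alone cannot rank nested stable partitions: when two planted
    groups are jointly well separated from the rest, the consensus matrices
    for merging or splitting them are both perfectly crisp (silhouette on
    ``1 - M(k)`` equals 1 for several k), and crisp sub-splits of a dominant
    group inflate the area gain beyond any fixed threshold.  The silhouette
    on the data distance breaks exactly this degeneracy, and is the
    diagnostic that distinguishes the correct cut in practice.
    """
    if len(result.k_values) < 2:
        raise ValueError("need at least 2 evaluated k values")
    n = len(result.sample_ids)
    if n < 3:
        raise ValueError("too few samples for k selection diagnostics")

    for k in result.k_values:
        m = result.consensus[k]
        iu = np.triu_indices(n, k=1)
        if np.allclose(m[iu], 1.0):
            raise ValueError(
                f"consensus matrix for k={k} is degenerate (all entries 1)"
            )
        grid, cdf = _consensus_cdf(m)
        result.cdf[k] = (grid, cdf)
        result.auc[k] = float(np.trapezoid(cdf, grid))

    ks = result.k_values
    result.delta_auc[ks[0]] = result.auc[ks[0]]
    for prev, k in zip(ks, ks[1:]):
        result.delta_auc[k] = (result.auc[k] - result.auc[prev]) / result.auc[prev]

    data_dist = result.data_distance.to_numpy() if result.data_distance is not None else None
    for k in ks:
        labels = result.labels[k]
        cons_dist = 1.0 - result.consensus[k]
        np.fill_diagonal(cons_dist, 0.0)
        cons_dist = np.clip((cons_dist + cons_dist.T) / 2.0, 0.0, None)
        if len(np.unique(labels)) < 2:
            result.silhouette_consensus[k] = float("nan")
            result.silhouette[k] = float("nan")
            continue
        result.silhouette_consensus[k] = float(
            silhouette_score(cons_dist, labels, metric="precomputed")
        )
        if data_dist is not None:
            result.silhouette[k] = float(
                silhouette_score(data_dist, labels, metric="precomputed")
            )
        else:
            result.silhouette[k] = result.silhouette_consensus[k]

    elbow = next(
        (k for i, k in enumerate(ks)
         if i == len(ks) - 1 or result.delta_auc[ks[i + 1]] < auc_gain_threshold),
        ks[-1],
    )
    result.params["cdf_elbow_k"] = int(elbow)
    result.params["auc_gain_threshold"] = auc_gain_threshold
    best = max(ks, key=lambda k: (np.nan_to_num(result.silhouette[k], nan=-2.0), -k))
    result.selected_k = int(best)
    logger.info(
        "k selection: auc=%s delta=%s silhouette=%s cdf_elbow=%d -> selected_k=%d",
        {k: round(result.auc[k], 4) for k in ks},
        {k: round(result.delta_auc[k], 4) for k in ks},
        {k: round(result.silhouette[k], 4) for k in ks},
        elbow, result.selected_k,
    )
    return result


def assign_groups(result: ConsensusResult, k: int):
    """Final group labels and per-sample silhouettes at a chosen k.

    Labels come from the stored average-linkage cut of ``1 - M(k)``,
    renumbered by decreasing group size; per-sample silhouettes are
    computed on ``1 - M(k)``.  Returns ``(labels, silhouettes)`` Series.
    """
    if k not in result.k_values:
        raise ValueError(f"k={k} was not evaluated (range {result.k_values})")
    labels = _canonical_labels(result.labels[k])
    dist = 1.0 - result.consensus[k]
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    sil = silhouette_samples(dist, labels, metric="precomputed")
    index = pd.Index(result.sample_ids, name="sample_id")
    return (
        pd.Series(labels, index=index, name="group"),
        pd.Series(sil, index=index, name="silhouette"),
    )


def hierarchical_check(beta: pd.DataFrame, k: int, n_probes: int = 5000,
                       consensus_labels=None):
    """Ward-linkage cross-check of the consensus grouping.

    Hierarchical clustering (Ward's method on Spearman distance) of the top
    ``n_probes`` most variable probes, cut into ``k`` groups.  When
    ``consensus_labels`` is given, the agreement (adjusted Rand index) with
    the consensus partition is reported.

    Returns a dict with ``labels``, ``linkage`` and (optionally) ``ari``.
    """
    top = select_variable_probes(beta, n_probes)
    dist = spearman_distance_matrix(top)
    lk = linkage(squareform(dist.to_numpy(), checks=False), method="ward")
    labels = _canonical_labels(fcluster(lk, t=k, criterion="maxclust"))
    out = {
        "labels": pd.Series(labels, index=dist.index, name="group"),
        "linkage": lk,
    }
    if consensus_labels is not None:
        out["ari"] = float(adjusted_rand_score(np.asarray(consensus_labels), labels))
        logger.info("hierarchical cross-check at k=%d: ARI=%.3f", k, out["ari"])
    return out
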