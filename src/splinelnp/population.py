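"""Population-level statistics.

Three tools used on top of per-cell model results: the binomial
direction-preference test (continuity-corrected normal z statistic
paired with an exact two-sided binomial p), binned entropy and mutual
information with shuffle nulls, and the PCA "tuning-curve profile
space" clustering test (mean k-nearest same-label neighbor distance
against a label-permutation null, Bonferroni-corrected over k = 1..10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom
from sklearn.decomposition import PCA

__all__ = [
    "BinomialTestResult",
    "binomial_preference_test",
    "entropy",
    "uniform_entropy",
    "mutual_information",
    "ClusteringTestResult",
    "tuning_space_clustering_test",
]


@dataclass
class BinomialTestResult:
    k: int
    n: int
    z: float  # continuity-corrected normal statistic, signed
    p: float  # exact two-sided probability (doubled smaller tail, capped)


def binomial_preference_test(k: int, n: int) -> BinomialTestResult:
    """Test whether a preference split k / n departs from one half.

    z uses the half-count continuity correction,
    ``z = sign(k - n/2) * max(|k - n/2| - 0.5, 0) / (sqrt(n)/2)``
    (zero whenever the correction crosses the mean), and p is the exact
    two-sided binomial probability under Binomial(n, 1/2): twice the
    smaller tail, capped at 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    dev = k - n / 2.0
    corrected = max(abs(dev) - 0.5, 0.0)
    # exact zero (not signed) when the correction crosses the mean
    z = 0.0 if corrected == 0.0 else float(
        np.sign(dev) * corrected / (np.sqrt(n) / 2.0))
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    p = float(min(1.0, 2.0 * min(lower, upper)))
    return BinomialTestResult(k=k, n=n, z=z, p=p)


def entropy(samples: np.ndarray, n_bins: int,
            value_range: tuple[float, float] | None = None) -> float:
    """Entropy (nats) of the binned empirical distribution,
    ``H = -sum_i P(X_i) log P(X_i)`` over occupied bins."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("entropy of an empty sample is undefined")
    hist, _ = np.histogram(samples, bins=n_bins, range=value_range)
    p = hist[hist > 0] / samples.size
    return float(-(p * np.log(p)).sum())


def uniform_entropy(n_samples: int, n_bins: int) -> float:
    """Entropy of the equal-count uniform distribution of the same size
    and binning (the companion reference value)."""
    if n_samples <= 0 or n_bins <= 0:
        raise ValueError("need positive sample and bin counts")
    base, extra = divmod(n_samples, n_bins)
    counts = np.full(n_bins, base, dtype=float)
    counts[:extra] += 1
    p = counts[counts > 0] / n_samples
    return float(-(p * np.log(p)).sum())


def _joint_hist(a, b, bins, a_range=None, b_range=None):
    hist, _, _ = np.histogram2d(a, b, bins=bins,
                                range=None if a_range is None
                                else [a_range, b_range])
    return hist / hist.sum()


def mutual_information(
    a: np.ndarray,
    b: np.ndarray,
    bins: int = 20,
    n_shuffles: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Mutual information (nats) between two binned continuous variables,
    ``I = sum_ij P(a_i, b_j) log[ P(a_i, b_j) / (P(a_i) P(b_j)) ]``,
    with probabilities estimated empirically.

    With ``n_shuffles > 0`` a null distribution is returned, obtained by
    permuting one variable and recomputing I (the bin edges are held
    fixed so the marginals are identical under the null).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("variables must have equal length")
    a_range = (a.min(), a.max())
    b_range = (b.min(), b.max())

    def mi(x, y):
        pj = _joint_hist(x, y, bins, a_range, b_range)
        pa = pj.sum(axis=1, keepdims=True)
        pb = pj.sum(axis=0, keepdims=True)
        mask = pj > 0
        return float((pj[mask] * np.log(pj[mask]
                                        / (pa @ pb)[mask])).sum())

    observed = mi(a, b)
    null = np.empty(n_shuffles)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    for i in range(n_shuffles):
        null[i] = mi(a, rng.permutation(b))
    return observed, null


@dataclass
class ClusteringTestResult:
    label_name: str
    k_values: np.ndarray
    observed_d: np.ndarray  # mean same-label k-NN distance per k
    p_values: np.ndarray  # permutation p per k
    n_perm: int
    alpha_corrected: float = 0.005  # 0.05 / 10
    applicable: bool = True

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha_corrected


def _mean_knn_distance(dist: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Mean over labeled points of the mean distance to their k nearest
    same-labeled neighbors (self excluded)."""
    idx = np.flatnonzero(labels)
    sub = dist[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    kk = min(k, idx.size - 1)
    part = np.partition(sub, kk - 1, axis=1)[:, :kk]
    return float(part.mean())


def tuning_space_clustering_test(
    curves: np.ndarray,
    labels: np.ndarray,
    k_max: int = 10,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    label_name: str = "",
) -> ClusteringTestResult:
    """Do cells with similar tuning curves share a second encoded variable?

    Rows of the (n_cells x n_bins) curve matrix are mean-subtracted and
    re-scaled to unit range, projected onto the first two principal
    components, and for each k the mean distance from each labeled cell
    to its k nearest labeled neighbors is compared with a null built by
    scrambling the labels.  p is the fraction of permuted distances
    smaller than observed; significance requires p < 0.05 / 10.

    When every point carries the label the permutation null is
    degenerate and the test is reported inapplicable.
    """
    curves = np.asarray(curves, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if curves.ndim != 2 or curves.shape[0] < 5:
        raise ValueError("need >= 5 cells with equal-length curves")
    if labels.shape != (curves.shape[0],):
        raise ValueError("labels must be one boolean per cell")
    n_labeled = int(labels.sum())
    if n_labeled < 2:
        raise ValueError("need >= 2 labeled cells")

    X = curves - curves.mean(axis=1, keepdims=True)
    spans = np.ptp(X, axis=1)
    spans[spans == 0] = 1.0
    X = X / spans[:, None]
    proj = PCA(n_components=2).fit_transform(X)
    diff = proj[:, None, :] - proj[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    ks = np.arange(1, min(k_max, n_labeled - 1 if n_labeled > 1 else 1) + 1)
    observed = np.array([_mean_knn_distance(dist, labels, k) for k in ks])
    if n_labeled == labels.size:
        return ClusteringTestResult(
            label_name, ks, observed, np.full(ks.size, np.nan), n_perm,
            applicable=False,
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    smaller = np.zeros(ks.size)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        for j, k in enumerate(ks):
            if _mean_knn_distance(dist, perm, k) < observed[j]:
                smaller[j] += 1
    return ClusteringTestResult(
        label_name, ks, observed, smaller / n_perm, n_perm,
    )
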