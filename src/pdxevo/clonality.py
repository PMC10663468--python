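"""Per-mutation cancer-cell-fraction estimation and consensus clonality.

Three classifiers vote on each mutation:

* ``ccf_ci`` — the CCF confidence-interval method: a mutation is clonal when
  the 95% CI of its CCF (a linear map of the Wilson binomial CI on the VAF)
  overlaps 1;
* ``binomial_mixture`` — 1-D EM over CCF space with binomial read-count
  emissions, model order chosen by BIC (k = 1..5);
* ``kmeans_bic`` — k-means on CCF point estimates with BIC model selection
  (a Gaussian-mixture voter, ``gaussian_mixture``, is also available).

Cluster-based calls follow the consensus rules: a single cluster is wholly
clonal; otherwise the cluster with the highest mean CCF is clonal, any other
cluster with mean CCF above 0.9 is also clonal, and the rest are subclonal.
The consensus label requires agreement of at least two methods; mutations
lacking the copy-number or purity inputs are left unclassified.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ConfigurationError, DegenerateDataError
from .variants import VariantRecord

DEFAULT_METHODS = ("ccf_ci", "binomial_mixture", "kmeans_bic")
CLUSTER_METHODS = ("binomial_mixture", "gaussian_mixture", "kmeans_bic")

_Z95 = 1.959963984540054  # two-sided 95% normal quantile
CCF_CEILING = 2.0  # pre-report clamp; reported CCFs are additionally capped at 1


@dataclass(frozen=True)
class CCFEstimate:
    """CCF point estimate with 95% CI, clamped to [0, 2] internally."""

    ccf: float
    ci_low: float
    ci_high: float
    multiplicity: int
    cn_tumor: int
    purity_used: float
    alt_reads: int
    depth: int

    @property
    def ccf_reported(self) -> float:
        return min(self.ccf, 1.0)

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth

    @property
    def ccf_per_vaf(self) -> float:
        """d(CCF)/d(VAF): the linear factor mapping VAF space to CCF space."""
        denom = self.purity_used * self.cn_tumor + (1 - self.purity_used) * 2
        return denom / (self.purity_used * self.multiplicity)


@dataclass(frozen=True)
class ClonalityCall:
    per_method: dict[str, str]  # method -> clonal | subclonal
    consensus: str  # clonal | subclonal | ambiguous | unclassified


def wilson_interval(alt: int, depth: int, z: float = _Z95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if depth <= 0:
        raise DegenerateDataError("depth must be positive")
    phat = alt / depth
    denom = 1 + z**2 / depth
    center = (phat + z**2 / (2 * depth)) / denom
    half = z * math.sqrt(phat * (1 - phat) / depth + z**2 / (4 * depth**2)) / denom
    lo = 0.0 if alt == 0 else max(center - half, 0.0)
    hi = 1.0 if alt == depth else min(center + half, 1.0)
    return lo, hi


def estimate_multiplicity(
    vaf: float, purity: float, cn_tumor: int, cn_normal: int = 2
) -> int:
    """Most likely number of mutated copies per tumor cell:
    round(vaf/purity * (purity*cn_tumor + (1-purity)*cn_normal)),
    clamped to [1, max(1, cn_tumor)]."""
    if not 0 < purity <= 1:
        raise ConfigurationError(f"purity {purity} outside (0, 1]")
    denom = purity * cn_tumor + (1 - purity) * cn_normal
    m = round(vaf / purity * denom)
    return int(min(max(m, 1), max(1, cn_tumor)))


def estimate_ccf(
    record: VariantRecord,
    purity: float | None,
    cn_tumor: int | None,
    cn_normal: int = 2,
) -> CCFEstimate | None:
    """CCF of one mutation with a 95% CI.

    ``ccf = vaf * (purity*cn_tumor + (1-purity)*cn_normal) / (purity * m)``
    with the multiplicity ``m`` estimated from the same VAF; the CI applies
    the identical linear map to the Wilson interval on (alt_reads, depth).
    Returns ``None`` (the unclassified marker) when purity or copy number is
    missing or zero — never raises for those.
    """
    if purity is None or purity <= 0 or cn_tumor is None:
        return None
    if record.tumor_depth is None or record.tumor_depth <= 0:
        return None
    vaf = record.tumor_alt_reads / record.tumor_depth
    m = estimate_multiplicity(vaf, purity, cn_tumor, cn_normal)
    denom = purity * cn_tumor + (1 - purity) * cn_normal
    if denom == 0:
        return None
    factor = denom / (purity * m)
    lo, hi = wilson_interval(record.tumor_alt_reads, record.tumor_depth)
    clamp = lambda x: float(min(max(x, 0.0), CCF_CEILING))
    return CCFEstimate(
        ccf=clamp(vaf * factor),
        ci_low=clamp(lo * factor),
        ci_high=clamp(hi * factor),
        multiplicity=m,
        cn_tumor=cn_tumor,
        purity_used=purity,
        alt_reads=record.tumor_alt_reads,
        depth=record.tumor_depth,
    )


def ci_classify(est: CCFEstimate) -> str:
    """Clonal iff the CCF confidence interval overlaps 1 (or lies above it)."""
    return "clonal" if est.ci_high >= 1.0 else "subclonal"


# ---------------------------------------------------------------------------
# cluster-based classifiers


def _apply_cluster_rules(
    labels: np.ndarray, values: np.ndarray, high_ccf: float = 0.9
) -> np.ndarray:
    """Map cluster labels to clonal/subclonal via the consensus rules."""
    uniq = np.unique(labels)
    means = {c: values[labels == c].mean() for c in uniq}
    if len(uniq) == 1:
        return np.array(["clonal"] * len(values))
    top = max(means.values())
    out = np.empty(len(values), dtype=object)
    for c in uniq:
        # ties at the top mean break toward clonal; mean > 0.9 is also clonal
        clonal = means[c] >= top or means[c] > high_ccf
        out[labels == c] = "clonal" if clonal else "subclonal"
    return out


def _binom_loglik_matrix(alt, depth, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    const = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    return const + alt * np.log(p) + (depth - alt) * np.log1p(-p)


def _binomial_mixture_em(
    alt: np.ndarray,
    depth: np.ndarray,
    cfac: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_restarts: int = 10,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """EM for a k-component binomial mixture over CCF space.

    ``cfac`` maps a component CCF to the per-mutation success probability
    (expected VAF = cfac * theta). The M-step for theta uses the weighted
    moment solution sum(r*alt)/sum(r*depth*cfac), exact when cfac is constant
    across mutations (the diploid common case) and a close quasi-Newton step
    otherwise.
    """
    n = len(alt)
    ccf_obs = np.clip(alt / depth / cfac, 0.0, CCF_CEILING)
    const = (gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1))
    best_ll, best = -np.inf, None
    for _ in range(n_restarts):
        theta = np.clip(
            rng.choice(ccf_obs, size=k, replace=True) + rng.normal(0, 0.05, k),
            1e-3,
            CCF_CEILING,
        )
        w = np.full(k, 1.0 / k)
        ll_old = -np.inf
        for _ in range(max_iter):
            p = np.clip(cfac[:, None] * theta[None, :], 1e-12, 1 - 1e-12)
            logp = (
                const[:, None]
                + alt[:, None] * np.log(p)
                + (depth - alt)[:, None] * np.log1p(-p)
                + np.log(w)[None, :]
            )
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            resp = np.exp(logp - norm[:, None])
            w = np.clip(resp.mean(axis=0), 1e-12, None)
            w /= w.sum()
            num = resp.T @ alt
            den = resp.T @ (depth * cfac)
            theta = np.clip(num / np.maximum(den, 1e-12), 1e-4, CCF_CEILING)
            if ll - ll_old < tol:
                break
            ll_old = ll
        if ll > best_ll:
            best_ll, best = ll, (theta.copy(), w.copy(), resp.argmax(axis=1))
    n_params = 2 * k - 1
    bic = -2 * best_ll + n_params * math.log(n)
    theta, w, labels = best
    return labels, bic


def cluster_classify(
    ccfs: Sequence[CCFEstimate],
    method: str = "kmeans_bic",
    max_clusters: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Cluster CCFs in 1-D, pick the cluster count by BIC, and apply the
    clonal/subclonal cluster rules. Returns one label per input estimate."""
    if method not in CLUSTER_METHODS:
        raise ConfigurationError(f"unknown clustering method {method!r}")
    if len(ccfs) == 0:
        return np.array([], dtype=object)
    values = np.array([e.ccf for e in ccfs])
    # no more clusters than distinct CCF values (avoids degenerate fits)
    kmax = min(max_clusters, len(ccfs), len(np.unique(values)))
    rng = np.random.default_rng(seed)

    if method == "binomial_mixture":
        alt = np.array([e.alt_reads for e in ccfs], float)
        depth = np.array([e.depth for e in ccfs], float)
        cfac = np.array([1.0 / e.ccf_per_vaf for e in ccfs])
        best_bic, best_labels = np.inf, None
        for k in range(1, kmax + 1):
            labels, bic = _binomial_mixture_em(alt, depth, cfac, k, rng)
            if bic < best_bic:
                best_bic, best_labels = bic, labels
        return _apply_cluster_rules(best_labels, values)

    x = values.reshape(-1, 1)
    if method == "gaussian_mixture":
        from sklearn.mixture import GaussianMixture

        best_bic, best_labels = np.inf, None
        for k in range(1, kmax + 1):
            gm = GaussianMixture(
                n_components=k, n_init=3, random_state=seed, reg_covar=1e-6
            ).fit(x)
            bic = gm.bic(x)
            if bic < best_bic:
                best_bic, best_labels = bic, gm.predict(x)
        return _apply_cluster_rules(best_labels, values)

    # kmeans_bic: k-means assignments scored under the equal-variance
    # Gaussian-mixture likelihood (the hard-assignment likelihood of X-means
    # over-splits single Gaussian clusters; the mixture BIC is consistent)
    from sklearn.cluster import KMeans

    n = len(values)
    best_bic, best_labels = np.inf, None
    for k in range(1, kmax + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        centers = km.cluster_centers_.ravel()
        weights = np.bincount(km.labels_, minlength=k) / n
        sigma2 = max(float(km.inertia_) / n, 1e-9)
        logp = (
            -0.5 * math.log(2 * math.pi * sigma2)
            - 0.5 * (values[:, None] - centers[None, :]) ** 2 / sigma2
            + np.log(np.clip(weights, 1e-12, None))[None, :]
        )
        loglik = float(logsumexp(logp, axis=1).sum())
        bic = -2 * loglik + 2 * k * math.log(n)
        if bic < best_bic:
            best_bic, best_labels = bic, km.labels_
    return _apply_cluster_rules(best_labels, values)


def consensus_vote(per_method: Mapping[str, str]) -> str:
    """Clonal/subclonal when at least two methods agree, else ambiguous."""
    if len(per_method) < 2:
        raise ConfigurationError("consensus vote needs >= 2 method calls")
    counts = Counter(per_method.values())
    clonal_win = counts.get("clonal", 0) >= 2
    subclonal_win = counts.get("subclonal", 0) >= 2
    if clonal_win and not subclonal_win:
        return "clonal"
    if subclonal_win and not clonal_win:
        return "subclonal"
    # includes the split 2-2 vote with four methods
    return "ambiguous"


def classify_sample(
    estimates: Mapping[tuple, CCFEstimate | None],
    methods: Sequence[str] = DEFAULT_METHODS,
    seed: int = 0,
) -> dict[tuple, ClonalityCall]:
    """Run every classifier over one sample and take the consensus.

    ``estimates`` maps mutation keys to CCF estimates; ``None`` marks a
    mutation without the copy-number/purity inputs, which stays
    ``unclassified``.
    """
    keys = [k for k, e in estimates.items() if e is not None]
    ests = [estimates[k] for k in keys]
    per_method: dict[str, np.ndarray] = {}
    for method in methods:
        if method == "ccf_ci":
            per_method[method] = np.array([ci_classify(e) for e in ests], dtype=object)
        else:
            per_method[method] = cluster_classify(ests, method=method, seed=seed)
    calls: dict[tuple, ClonalityCall] = {}
    for i, key in enumerate(keys):
        votes = {m: str(per_method[m][i]) for m in methods}
        calls[key] = ClonalityCall(per_method=votes, consensus=consensus_vote(votes))
    for key, est in estimates.items():
        if est is None:
            calls[key] = ClonalityCall(per_method={}, consensus="unclassified")
    return calls


def genetic_heterogeneity(calls: Iterable[ClonalityCall]) -> float:
    """Fraction of subclonal mutations among the clonal+subclonal consensus
    calls; ambiguous and unclassified mutations are excluded."""
    counts = Counter(c.consensus for c in calls)
    denom = counts.get("clonal", 0) + counts.get("subclonal", 0)
    if denom == 0:
        raise DegenerateDataError(
            "no clonal or subclonal consensus calls; heterogeneity undefined"
        )
    return counts.get("subclonal", 0) / denom
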