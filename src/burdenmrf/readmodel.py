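"""VAF statistics, per-site t statistics and pairwise interaction weights.

Tumor/normal read counts at a site give per-sample variant allelic
frequency (VAF) estimates; a paired t statistic summarises the tumor-normal
VAF contrast per site, and two sites are weighted by the cosine-like kernel
``omega = 2 t t' / (t^2 + t'^2)`` which is 1 for identical statistics and
-1 for opposite ones.  Somatic sites are assigned to sub-clones by 1-D
Gaussian-mixture clustering of their mean carrier VAF, and interaction
weights are only retained for pairs inside one four-gamete-compatible
interval (and, for somatic pairs, one sub-clone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .simdata import ReadCountTable

__all__ = [
    "T_CAP",
    "SiteStats",
    "InteractionWeights",
    "SubcloneAssignment",
    "vaf_estimates",
    "site_t_statistic",
    "genotype_t_statistics",
    "interaction_weight",
    "cluster_subclones",
    "build_interaction_weights",
]

# |t| for a zero-variance nonzero paired difference: roughly the t value at
# machine-precision p, so degenerate sites dominate nothing downstream.
T_CAP = 37.62


@dataclass
class SiteStats:
    """Per-site VAF summary: paired t, mean VAFs, informative sample count."""

    t_stat: np.ndarray
    tumor_vaf_mean: np.ndarray
    normal_vaf_mean: np.ndarray
    n_informative: np.ndarray


@dataclass
class SubcloneAssignment:
    cluster_id: np.ndarray      # per somatic site
    cluster_mean_vaf: np.ndarray  # per cluster


@dataclass
class InteractionWeights:
    """Sparse symmetric map of pairwise weights plus neighborhoods."""

    n_sites: int
    pairs: dict[tuple[int, int], float] = field(default_factory=dict)

    def set(self, a: int, b: int, w: float) -> None:
        if a == b:
            raise ValueError("no self-interactions")
        if not -1.0 <= w <= 1.0 + 1e-12:
            raise ValueError("|omega| must be <= 1")
        self.pairs[(min(a, b), max(a, b))] = float(w)

    def get(self, a: int, b: int) -> float:
        return self.pairs.get((min(a, b), max(a, b)), 0.0)

    def neighbors(self, s: int) -> list[int]:
        out = [b if a == s else a for (a, b) in self.pairs if s in (a, b)]
        return sorted(out)

    def to_matrix(self) -> np.ndarray:
        w = np.zeros((self.n_sites, self.n_sites))
        for (a, b), v in self.pairs.items():
            w[a, b] = w[b, a] = v
        return w


def vaf_estimates(rc: ReadCountTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample per-site tumor and normal VAFs (NaN where depth is 0)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        tumor = np.where(rc.tumor_depth > 0,
                         rc.tumor_support / np.maximum(rc.tumor_depth, 1),
                         np.nan)
        normal = np.where(rc.normal_depth > 0,
                          rc.normal_support / np.maximum(rc.normal_depth, 1),
                          np.nan)
    return tumor, normal


def site_t_statistic(tumor_vafs: np.ndarray,
                     normal_vafs: np.ndarray) -> float:
    """Paired t statistic of the tumor-normal VAF difference across samples.

    NaN pairs are dropped.  Fewer than two informative pairs is an error;
    a zero-variance nonzero difference returns +-``T_CAP``; identical
    vectors return 0.
    """
    tumor = np.asarray(tumor_vafs, dtype=float)
    normal = np.asarray(normal_vafs, dtype=float)
    ok = ~(np.isnan(tumor) | np.isnan(normal))
    diff = tumor[ok] - normal[ok]
    n = diff.size
    if n < 2:
        raise ValueError("need >= 2 informative paired samples")
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return 0.0 if mean == 0.0 else float(np.sign(mean) * T_CAP)
    t = mean / (sd / np.sqrt(n))
    return float(np.clip(t, -T_CAP, T_CAP))


def genotype_t_statistics(carriers: np.ndarray,
                          labels: np.ndarray) -> np.ndarray:
    """Signed case/control carrier-contrast z per site.

    Stand-in for the paired VAF t when read counts are absent: the signed
    square root of the per-site Pearson chi-square on the carrier 2x2 table,
    positive for case enrichment.  Scale-compatible with a t statistic, so
    the omega kernel applies unchanged.
    """
    carriers = np.asarray(carriers, dtype=bool)
    labels = np.asarray(labels).astype(bool)
    nc, nn = labels.sum(), (~labels).sum()
    a = carriers[labels].sum(axis=0).astype(float)
    b = carriers[~labels].sum(axis=0).astype(float)
    n = nc + nn
    k = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (n * (a * (nn - b) - b * (nc - a)) ** 2
                / (k * (n - k) * nc * nn))
    z = np.sign(a / nc - b / nn) * np.sqrt(np.where(np.isfinite(chi2),
                                                    chi2, 0.0))
    return np.clip(np.nan_to_num(z), -T_CAP, T_CAP)


def interaction_weight(t_a: float, t_b: float) -> float:
    """Cosine-similarity-like kernel ``2 t t' / (t^2 + t'^2)`` in [-1, 1].

    Scale-invariant by construction; inputs are normalized by the larger
    magnitude first so the identity survives extreme values.
    """
    scale = max(abs(t_a), abs(t_b))
    if scale == 0.0:
        return 0.0
    a, b = t_a / scale, t_b / scale
    return float(2.0 * a * b / (a * a + b * b))


def cluster_subclones(tumor_vafs: np.ndarray, k_max: int = 5,
                      random_state: int = 0) -> SubcloneAssignment:
    """Assign somatic sites to sub-clones by 1-D GMM with BIC model choice."""
    v = np.asarray(tumor_vafs, dtype=float).reshape(-1, 1)
    if v.size == 0:
        raise ValueError("need at least one somatic site")
    if v.size == 1 or np.ptp(v) < 1e-12:
        return SubcloneAssignment(np.zeros(v.size, dtype=int),
                                  np.array([float(v.mean())]))
    best = None
    for k in range(1, min(k_max, v.size) + 1):
        gm = GaussianMixture(n_components=k, random_state=random_state,
                             n_init=3, reg_covar=1e-6).fit(v)
        bic = gm.bic(v)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]
    ids = gm.predict(v)
    # renumber clusters consecutively in order of appearance
    _, ids = np.unique(ids, return_inverse=True)
    means = np.array([v[ids == c].mean() for c in range(ids.max() + 1)])
    return SubcloneAssignment(ids, means)


def build_interaction_weights(
        t_stats: np.ndarray,
        intervals: list[tuple[int, int]],
        somatic_mask: np.ndarray | None = None,
        subclones: SubcloneAssignment | None = None,
        min_abs_t: float = 1e-9) -> InteractionWeights:
    """Pairwise omega weights for all pairs inside one compatible interval.

    Somatic-somatic pairs must additionally share a sub-clone (germline and
    mixed pairs are constrained by the interval only).  Pairs where either
    statistic is ~0 are omitted (omega would be 0).
    """
    t = np.asarray(t_stats, dtype=float)
    iw = InteractionWeights(n_sites=t.size)
    if somatic_mask is None:
        somatic_mask = np.zeros(t.size, dtype=bool)
    somatic_idx = np.nonzero(somatic_mask)[0]
    sub_of = {}
    if subclones is not None:
        sub_of = {int(s): int(c)
                  for s, c in zip(somatic_idx, subclones.cluster_id)}
    for start, end in intervals:
        for a in range(start, end):
            if abs(t[a]) < min_abs_t:
                continue
            for b in range(a + 1, end):
                if abs(t[b]) < min_abs_t:
                    continue
                if (somatic_mask[a] and somatic_mask[b]
                        and sub_of.get(a) != sub_of.get(b)):
                    continue
                iw.set(a, b, interaction_weight(t[a], t[b]))
    return iw
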