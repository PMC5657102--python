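"""Simulation of case/control rare-variant datasets.

Implements the fixed-number simulation scheme used throughout the package's
evaluation harness: per-site minor allele frequencies are drawn from Wright's
stationary distribution under purifying selection, a preset number ``C`` of
causal sites receives a case-frequency increment derived from the marginal
population attributable risk (PAR), and genotypes are sampled independently
per site (no linkage disequilibrium between rare variants).  A separate
generator produces null datasets (i.i.d. Bernoulli genotypes, random labels)
for calibration experiments, and a read-count overlay equips simulated
genotypes with synthetic tumor/normal read counts so the VAF-based weighting
machinery can be exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "ReadCountTable",
    "ReadOverlayConfig",
    "Dataset",
    "WrightDistribution",
    "sample_wright_maf",
    "relative_risk",
    "case_maf",
    "generate_dataset",
    "generate_null_dataset",
    "overlay_read_counts",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the fixed-number case/control simulation.

    Parameters
    ----------
    n_cases, n_controls : int
        Cohort arm sizes.
    n_sites : int
        Total number of variant sites ``M`` per dataset.
    n_causal : int
        Number of causal sites ``C`` (fixed-number strategy).
    group_par : float
        Group population attributable risk; the marginal per-variant PAR is
        ``delta = group_par / n_causal``.
    sigma : float
        Selection coefficient of Wright's distribution.
    beta_site : float
        Probability of mutating a neutral variant to a causal one
        (shape parameter ``beta_i`` of Wright's distribution).
    beta_repair : float
        Probability of repairing a causal variant to a neutral one
        (shape parameter ``beta_L``).
    maf_upper : float or None
        Optional truncation of the MAF distribution to ``(0, maf_upper]``.
    require_polymorphic : bool
        When True (default) each site is conditioned on carrying at least one
        minor allele in the sampled cohort, i.e. sites represent *observed*
        variants.  Without this, Wright's distribution at the default shape
        parameters leaves the vast majority of sites monomorphic in a cohort
        of thousands.
    coding : {"carrier", "diploid"}
        ``"carrier"`` stores 0/1 carrier indicators (a diploid individual is
        a carrier with probability ``1-(1-maf)^2``); ``"diploid"`` stores
        0/1/2 minor-allele counts.  The model always collapses to carriers.
    seed : int
        Base seed used when no external generator is supplied.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    n_sites: int = 100
    n_causal: int = 50
    group_par: float = 0.02
    sigma: float = 12.0
    beta_site: float = 0.001
    beta_repair: float = 0.00033
    maf_upper: float | None = None
    require_polymorphic: bool = True
    coding: Literal["carrier", "diploid"] = "carrier"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_sites:
            raise ValueError("n_causal must not exceed n_sites")
        if not 0.0 <= self.group_par < 1.0:
            raise ValueError("group_par must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in ("beta_site", "beta_repair"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.maf_upper is not None and not 0.0 < self.maf_upper <= 1.0:
            raise ValueError("maf_upper must lie in (0, 1]")
        if min(self.n_cases, self.n_controls, self.n_sites) < 1:
            raise ValueError("cohort and site counts must be positive")

    @property
    def delta(self) -> float:
        """Marginal per-variant PAR (group PAR split across causal sites)."""
        return self.group_par / self.n_causal


@dataclass
class GenotypeMatrix:
    """``N x M`` genotype matrix; 0 = reference, >=1 = carrier."""

    values: np.ndarray
    site_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x sites)")
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > 2:
            raise ValueError("genotype values must be in {0, 1, 2}")
        if self.site_positions is None:
            self.site_positions = np.arange(self.values.shape[1])
        else:
            self.site_positions = np.asarray(self.site_positions)
            if np.any(np.diff(self.site_positions) < 0):
                raise ValueError("site_positions must be monotone")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def carriers(self) -> np.ndarray:
        """Collapse to a boolean carrier matrix (any minor allele)."""
        return self.values > 0


@dataclass
class ReadCountTable:
    """Per-sample, per-site tumor/normal supporting reads and depths."""

    tumor_support: np.ndarray
    tumor_depth: np.ndarray
    normal_support: np.ndarray
    normal_depth: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(a) for a in (
            self.tumor_support, self.tumor_depth,
            self.normal_support, self.normal_depth)]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError("all read-count arrays must share one shape")
        (self.tumor_support, self.tumor_depth,
         self.normal_support, self.normal_depth) = arrs
        for sup, dep, tag in (
                (self.tumor_support, self.tumor_depth, "tumor"),
                (self.normal_support, self.normal_depth, "normal")):
            if np.any(sup < 0) or np.any(dep < 0):
                raise ValueError(f"negative {tag} read counts")
            if np.any(sup > dep):
                raise ValueError(f"{tag} support exceeds depth")


@dataclass(frozen=True)
class ReadOverlayConfig:
    """Synthetic read-count overlay settings.

    Germline heterozygous carriers get VAF 0.5 in both tissues; somatic
    carriers get a sub-clonal VAF in the tumor and 0 in the normal sample.
    Non-carriers see supporting reads only at ``error_rate``.
    """

    depth_mean: float = 60.0
    error_rate: float = 1e-3
    germline_vaf: float = 0.5
    somatic_sites: tuple[int, ...] = ()
    somatic_vaf: float | Mapping[int, float] = 0.3

    def vaf_at(self, site: int) -> float:
        if site in self.somatic_sites:
            if isinstance(self.somatic_vaf, Mapping):
                return float(self.somatic_vaf[site])
            return float(self.somatic_vaf)
        return self.germline_vaf


@dataclass
class Dataset:
    """A simulated (or ingested) case/control dataset."""

    genotypes: GenotypeMatrix
    labels: np.ndarray  # 1 = case, 0 = control
    causal_truth: np.ndarray
    control_mafs: np.ndarray
    case_mafs: np.ndarray
    read_counts: ReadCountTable | None = None
    somatic_mask: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int8)
        if self.labels.shape[0] != self.genotypes.n_samples:
            raise ValueError("labels do not match sample count")
        for name in ("causal_truth", "control_mafs", "case_mafs"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != self.genotypes.n_sites:
                raise ValueError(f"{name} does not match site count")
            setattr(self, name, arr)
        if not self.sample_ids:
            self.sample_ids = [
                f"{'case' if l else 'ctrl'}_{i:05d}"
                for i, l in enumerate(self.labels)
            ]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.labels).sum())


# --------------------------------------------------------------------------
# Wright's distribution
# --------------------------------------------------------------------------


class WrightDistribution:
    """Wright's stationary MAF distribution under purifying selection.

    Density (up to normalization) on (0, 1):

        f(rho) ∝ rho^(beta_i - 1) (1 - rho)^(beta_L - 1) exp(sigma - rho sigma)

    For very small shape parameters the density has integrable power-law
    spikes at both endpoints; the bulk of the mass can sit at frequencies far
    below floating-point grid resolution.  The distribution is therefore
    represented piecewise: exact power-law branches on (0, eps) and
    (1 - eps, 1) — where the remaining factors are constant to O(eps) — and a
    tabulated inverse CDF on two log-spaced grids covering [eps, 0.5] and
    [0.5, 1 - eps].
    """

    _EPS = 1e-6
    _GRID = 50_000  # points per numeric branch

    def __init__(self, sigma: float, beta_i: float, beta_l: float):
        if sigma <= 0 or beta_i <= 0 or beta_l <= 0:
            raise ValueError("sigma, beta_i and beta_L must be positive")
        self.sigma = float(sigma)
        self.beta_i = float(beta_i)
        self.beta_l = float(beta_l)

        eps = self._EPS
        # analytic endpoint masses (unnormalized, e^sigma dropped)
        self._w_left = eps**beta_i / beta_i
        self._w_right = np.exp(-sigma) * eps**beta_l / beta_l

        # numeric branch on [eps, 0.5] (log grid in rho)
        x_lo = np.exp(np.linspace(np.log(eps), np.log(0.5), self._GRID))
        dens_lo = self._unnorm_pdf(x_lo) * x_lo  # measure d(ln rho)
        cum_lo = self._cumtrapz(dens_lo, np.log(x_lo))
        self._x_lo, self._cum_lo = x_lo, cum_lo
        self._w_lo = cum_lo[-1]

        # numeric branch on [0.5, 1-eps] (log grid in 1-rho, descending rho)
        t = np.exp(np.linspace(np.log(eps), np.log(0.5), self._GRID))
        x_hi = 1.0 - t  # descending in t <=> ascending ... careful below
        dens_hi = self._unnorm_pdf(x_hi) * t
        cum_hi = self._cumtrapz(dens_hi, np.log(t))
        self._t_hi, self._cum_hi = t, cum_hi
        self._w_hi = cum_hi[-1]

        self._z = self._w_left + self._w_lo + self._w_hi + self._w_right
        if not np.isfinite(self._z) or self._z <= 0:
            raise ValueError("non-finite normalizing constant; "
                             "check beta parameters")

    @staticmethod
    def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
        out = np.concatenate(
            [[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))])
        return out

    def _unnorm_pdf(self, rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        return (rho**(self.beta_i - 1.0)
                * (1.0 - rho)**(self.beta_l - 1.0)
                * np.exp(-self.sigma * rho))

    # -- CDF ---------------------------------------------------------------
    def cdf(self, x):
        """Exact (to grid tolerance) CDF, vectorized."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty_like(x)
        eps = self._EPS
        z = self._z

        left = x < eps
        out[left] = np.clip(x[left], 0, None)**self.beta_i / self.beta_i / z

        lo = (x >= eps) & (x <= 0.5)
        out[lo] = (self._w_left + np.interp(
            np.log(x[lo]), np.log(self._x_lo), self._cum_lo)) / z

        hi = (x > 0.5) & (x <= 1.0 - eps)
        # mass above x equals integral over t=1-rho from eps to 1-x
        t = 1.0 - x[hi]
        above = self._w_right + np.interp(
            np.log(t), np.log(self._t_hi), self._cum_hi)
        out[hi] = 1.0 - above / z

        right = x > 1.0 - eps
        t = np.clip(1.0 - x[right], 0.0, None)
        out[right] = 1.0 - (np.exp(-self.sigma) * t**self.beta_l
                            / self.beta_l) / z
        return out if out.shape else float(out)

    # -- inverse CDF --------------------------------------------------------
    def ppf(self, u):
        """Quantile function, vectorized; exact power-law endpoint branches."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if np.any((u < 0) | (u > 1)):
            raise ValueError("u must lie in [0, 1]")
        z = self._z
        m = u * z  # unnormalized target mass
        out = np.empty_like(u)

        b0 = self._w_left
        b1 = b0 + self._w_lo
        b2 = b1 + self._w_hi

        sel = m <= b0
        # rho = eps * (m/w_left)^(1/beta_i); compute in log space to dodge
        # underflow, clamping to the smallest positive normal float
        with np.errstate(divide="ignore"):
            lr = np.log(self._EPS) + np.log(m[sel] / b0) / self.beta_i
        out[sel] = np.exp(np.maximum(lr, np.log(1e-300)))

        sel = (m > b0) & (m <= b1)
        out[sel] = np.exp(np.interp(
            m[sel] - b0, self._cum_lo, np.log(self._x_lo)))

        sel = (m > b1) & (m <= b2)
        # mass above rho: z - m = w_right + cum_hi(t)
        out[sel] = 1.0 - np.exp(np.interp(
            z - m[sel] - self._w_right, self._cum_hi, np.log(self._t_hi)))

        sel = m > b2
        with np.errstate(divide="ignore"):
            lt = (np.log(self._EPS)
                  + np.log(np.clip(z - m[sel], 1e-300, None)
                           / self._w_right) / self.beta_l)
        out[sel] = 1.0 - np.exp(np.minimum(lt, np.log(0.5)))
        return np.clip(out, 1e-300, 1.0 - 1e-16)


_WRIGHT_CACHE: dict[tuple[float, float, float], WrightDistribution] = {}


def _wright(cfg: SimConfig) -> WrightDistribution:
    key = (cfg.sigma, cfg.beta_site, cfg.beta_repair)
    if key not in _WRIGHT_CACHE:
        _WRIGHT_CACHE[key] = WrightDistribution(*key)
    return _WRIGHT_CACHE[key]


def sample_wright_maf(cfg: SimConfig, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. MAFs from Wright's distribution.

    Honours ``cfg.maf_upper`` by sampling from the truncated distribution
    (conditioning on ``rho <= maf_upper``).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty(0)
    dist = _wright(cfg)
    u = rng.random(n)
    if cfg.maf_upper is not None:
        u = u * dist.cdf(cfg.maf_upper)
    return dist.ppf(u)


# --------------------------------------------------------------------------
# risk model
# --------------------------------------------------------------------------


def relative_risk(delta: float, rho: float | np.ndarray):
    """Relative risk ``RR = delta / ((1 - delta) rho) + 1``.

    ``delta`` is the marginal (per-variant) population attributable risk and
    ``rho`` the control MAF.  RR = 1 iff delta = 0 and decreases in rho.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0) or np.any(rho >= 1):
        raise ValueError("rho must lie in (0, 1)")
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must lie in [0, 1)")
    out = delta / ((1.0 - delta) * rho) + 1.0
    return out if out.shape else float(out)


def case_maf(rr: float | np.ndarray, rho: float | np.ndarray):
    """Case MAF ``theta = RR rho / ((RR - 1) rho + 1)``."""
    rr = np.asarray(rr, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(rr < 1):
        raise ValueError("relative risk must be >= 1")
    out = rr * rho / ((rr - 1.0) * rho + 1.0)
    return out if out.shape else float(out)


# --------------------------------------------------------------------------
# dataset generators
# --------------------------------------------------------------------------


def _carrier_prob(maf: np.ndarray, coding: str) -> np.ndarray:
    """Per-sample probability of carrying >= 1 minor allele."""
    if coding == "diploid" or coding == "carrier":
        return 1.0 - (1.0 - maf) ** 2
    raise ValueError(f"unknown coding {coding!r}")


def _truncated_binomial(n: int, p: float, rng: np.random.Generator) -> int:
    """Sample Binomial(n, p) conditioned on >= 1 via the inverse CDF."""
    p0 = (1.0 - p) ** n
    u = p0 + rng.random() * (1.0 - p0)
    return int(stats.binom.ppf(np.clip(u, 0.0, 1.0 - 1e-16), n, p))

def _conditional_counts(nc: int, pc: float, nn: int, pn: float,
                        rng: np.random.Generator) -> tuple[int, int]:
    """(case, control) carrier counts given at least one carrier overall."""
    a0 = (1.0 - pc) ** nc
    b0 = (1.0 - pn) ** nn
    q = 1.0 - a0 * b0
    if rng.random() < (1.0 - a0) / q:
        kc = _truncated_binomial(nc, pc, rng)
        kn = int(rng.binomial(nn, pn))
    else:
        kc = 0
        kn = _truncated_binomial(nn, pn, rng)
    return kc, kn


def _fill_column(col: np.ndarray, idx: np.ndarray, maf: float,
                 coding: str, rng: np.random.Generator) -> None:
    if coding == "carrier":
        col[idx] = 1
    else:  # diploid: carrier is het or hom-alt
        p_hom = maf / (2.0 - maf)  # P(G=2 | carrier)
        col[idx] = np.where(rng.random(idx.size) < p_hom, 2, 1)


def generate_dataset(cfg: SimConfig,
                     rng: np.random.Generator | None = None) -> Dataset:
    """Generate one fixed-number case/control dataset.

    Control genotypes are drawn from the Wright MAF at every site; case
    genotypes use the RR-inflated case MAF at the ``C`` randomly chosen
    causal sites and the control MAF elsewhere.  Sites are independent.
    With ``cfg.require_polymorphic`` each site is conditioned on having at
    least one carrier in the cohort (rejection on the MAF with analytic
    acceptance probability, then carrier counts from the truncated joint
    law), so the output matrix contains only observed variants.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m, nc, nn = cfg.n_sites, cfg.n_cases, cfg.n_controls
    causal = np.zeros(m, dtype=np.int8)
    causal_idx = rng.choice(m, size=cfg.n_causal, replace=False)
    causal[causal_idx] = 1

    rho = np.empty(m)
    theta = np.empty(m)
    geno = np.zeros((nc + nn, m), dtype=np.int8)
    labels = np.concatenate([np.ones(nc, np.int8), np.zeros(nn, np.int8)])
    case_rows = np.arange(nc)
    ctrl_rows = nc + np.arange(nn)

    def site_mafs(r: float, is_causal: bool) -> tuple[float, float]:
        if is_causal and cfg.group_par > 0:
            th = case_maf(relative_risk(cfg.delta, r), r)
        else:
            th = r
        return r, th

    if not cfg.require_polymorphic:
        rho[:] = sample_wright_maf(cfg, m, rng)
        for s in range(m):
            _, theta[s] = site_mafs(rho[s], bool(causal[s]))
            pc = _carrier_prob(np.array(theta[s]), cfg.coding)
            pn = _carrier_prob(np.array(rho[s]), cfg.coding)
            kc = int(rng.binomial(nc, pc))
            kn = int(rng.binomial(nn, pn))
            if kc:
                _fill_column(geno[:, s], rng.choice(case_rows, kc, False),
                             theta[s], cfg.coding, rng)
            if kn:
                _fill_column(geno[:, s], rng.choice(ctrl_rows, kn, False),
                             rho[s], cfg.coding, rng)
    else:
        batch = 64  # candidate MAFs drawn per pending site per round
        pending = np.arange(m)
        while pending.size:
            draws = sample_wright_maf(cfg, pending.size * batch,
                                      rng).reshape(pending.size, batch)
            is_causal = causal[pending].astype(bool)[:, None]
            if cfg.group_par > 0:
                th_all = np.where(
                    is_causal,
                    case_maf(relative_risk(cfg.delta, draws), draws),
                    draws)
            else:
                th_all = draws
            pc_all = _carrier_prob(th_all, cfg.coding)
            pn_all = _carrier_prob(draws, cfg.coding)
            q = 1.0 - (1.0 - pc_all) ** nc * (1.0 - pn_all) ** nn
            hit = rng.random(q.shape) < q
            got = hit.any(axis=1)
            first = hit.argmax(axis=1)
            for row in np.nonzero(got)[0]:
                s, j = pending[row], first[row]
                r, th = float(draws[row, j]), float(th_all[row, j])
                rho[s], theta[s] = r, th
                kc, kn = _conditional_counts(
                    nc, float(pc_all[row, j]), nn, float(pn_all[row, j]), rng)
                if kc:
                    _fill_column(geno[:, s], rng.choice(case_rows, kc, False),
                                 th, cfg.coding, rng)
                if kn:
                    _fill_column(geno[:, s], rng.choice(ctrl_rows, kn, False),
                                 r, cfg.coding, rng)
            pending = pending[~got]

    return Dataset(
        genotypes=GenotypeMatrix(geno),
        labels=labels,
        causal_truth=causal,
        control_mafs=rho,
        case_mafs=theta,
    )


def generate_null_dataset(n_samples: int, n_sites: int, mut_prob: float,
                          rng: np.random.Generator | None = None) -> Dataset:
    """Null-model dataset: i.i.d. Bernoulli genotypes, fair random labels."""
    if not 0.0 <= mut_prob < 1.0:
        raise ValueError("mut_prob must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(0)
    geno = (rng.random((n_samples, n_sites)) < mut_prob).astype(np.int8)
    labels = (rng.random(n_samples) < 0.5).astype(np.int8)
    mafs = np.full(n_sites, max(mut_prob, 1e-12))
    return Dataset(
        genotypes=GenotypeMatrix(geno),
        labels=labels,
        causal_truth=np.zeros(n_sites, dtype=np.int8),
        control_mafs=mafs,
        case_mafs=mafs.copy(),
    )


def overlay_read_counts(ds: Dataset,
                        overlay: ReadOverlayConfig | None = None,
                        rng: np.random.Generator | None = None) -> Dataset:
    """Attach synthetic tumor/normal read counts to a dataset.

    Depths are Poisson with the configured mean (floored at 1); supporting
    reads are binomial given depth, with per-genotype VAF: germline carriers
    0.5 in both tissues, somatic carriers the configured sub-clonal fraction
    in the tumor and the error rate in the normal, non-carriers the error
    rate everywhere.
    """
    if overlay is None:
        overlay = ReadOverlayConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    carriers = ds.genotypes.carriers()
    n, m = carriers.shape

    t_depth = np.maximum(rng.poisson(overlay.depth_mean, (n, m)), 1)
    n_depth = np.maximum(rng.poisson(overlay.depth_mean, (n, m)), 1)

    tumor_vaf = np.full((n, m), overlay.error_rate)
    normal_vaf = np.full((n, m), overlay.error_rate)
    somatic = np.zeros(m, dtype=bool)
    somatic[list(overlay.somatic_sites)] = True
    for s in range(m):
        idx = carriers[:, s]
        tumor_vaf[idx, s] = overlay.vaf_at(s)
        if not somatic[s]:
            normal_vaf[idx, s] = overlay.germline_vaf

    t_sup = rng.binomial(t_depth, np.clip(tumor_vaf, 0.0, 1.0))
    n_sup = rng.binomial(n_depth, np.clip(normal_vaf, 0.0, 1.0))
    rc = ReadCountTable(t_sup, t_depth, n_sup, n_depth)
    return Dataset(
        genotypes=ds.genotypes,
        labels=ds.labels,
        causal_truth=ds.causal_truth,
        control_mafs=ds.control_mafs,
        case_mafs=ds.case_mafs,
        read_counts=rc,
        somatic_mask=somatic,
        sample_ids=list(ds.sample_ids),
    )
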