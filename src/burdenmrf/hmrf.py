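"""Hidden Markov random field over variant causal status.

The model couples three latent layers along the site axis: per-site hidden
genotype states ``H`` (observed genotypes are noisy copies at mutation rate
``mu``), a region indicator ``R`` (elevated vs background, a two-level
silent-state chain whose transitions depend on the deleterious-region
parameter ``theta`` and inter-site distances), and the causal-status vector
``X`` updated by iterated conditional modes (ICM).  Interactions between
sites enter through the ``omega`` kernel restricted to four-gamete
compatible intervals.  Parameters ``(mu, theta, P^e)`` are estimated by an
EM-style pseudo-likelihood iteration built on scaled forward/backward
recursions; ``X`` is maximized site-wise between EM steps.

Reconstruction notes (the source model is under-specified in places) are in
``docs/methods.md``: the solo-evidence classifier ``m``, its cap, the
log-odds form of ``B``, the saturation of the interaction sum and the
global elevation field are this package's design decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .readmodel import genotype_t_statistics
from .simdata import Dataset

__all__ = [
    "HMRFConfig",
    "HMRFParams",
    "HiddenState",
    "TrellisTables",
    "FittedModel",
    "f_func",
    "trans_H",
    "trans_J",
    "region_potential",
    "parity_emissions",
    "forward_backward_R",
    "xi_pairwise",
    "em_update_mu",
    "em_update_theta",
    "em_update_pb",
    "site_evidence",
    "carrier_error_posterior",
    "icm_update_X",
    "fit",
]


# --------------------------------------------------------------------------
# configuration and state containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HMRFConfig:
    """Hyper-parameters of the field and its fit.

    ``tau`` and ``nu`` balance solo versus interaction effects (tau+nu=1).
    ``evidence_cap`` bounds the per-site classifier so that elevated regions
    are a multi-site phenomenon; ``elevation_margin`` is the per-site cost
    of calling a site elevated; ``gamma`` couples the region posterior into
    the ICM score and ``prior_logodds`` is the sparsity prior on X=1.
    Defaults were calibrated once against the null-model experiment
    (selection must be essentially always empty on null data) and for
    non-degenerate power — see docs/methods.md.
    """

    tau: float = 0.5
    nu: float = 0.5
    mu0: float = 0.01
    mu_max: float = 0.05
    theta0: float = 1.0
    theta_bounds: tuple[float, float] = (1e-3, 50.0)
    evidence_cap: float = 2.0
    elevation_margin: float = 0.75
    gamma: float = 1.5
    prior_logodds: float = -2.0
    x_init_z: float = 1.35
    interaction_cap: float = 3.0
    global_field: float = 3.0
    global_field_floor: float = -3.0
    evidence_mass_ref: float = 24.0
    region_prior: float = 0.25
    pb_eps: float = 1e-3
    pe_damping: float = 0.5
    tol: float = 1e-4
    max_iter: int = 100
    icm_max_sweeps: int = 20
    b_form: str = "logodds"  # or "difference"

    def __post_init__(self) -> None:
        if abs(self.tau + self.nu - 1.0) > 1e-9:
            raise ValueError("tau + nu must equal 1")
        if self.b_form not in ("logodds", "difference"):
            raise ValueError("b_form must be 'logodds' or 'difference'")


@dataclass
class HMRFParams:
    """Fitted field parameters."""

    mu: float
    theta_region: float
    p_elev: np.ndarray  # per-site P^e
    tau: float
    nu: float
    distances: np.ndarray  # per adjacent pair, length M-1

    @property
    def p_back(self) -> np.ndarray:
        return 1.0 - self.p_elev


@dataclass
class HiddenState:
    H: np.ndarray  # per-site collapsed hidden-genotype representative
    R: np.ndarray  # per-site region indicator (1 = elevated)
    X: np.ndarray  # per-site causal indicator


@dataclass
class TrellisTables:
    alpha: np.ndarray        # (M, S) scaled forward
    beta: np.ndarray         # (M, S) scaled backward
    gamma: np.ndarray        # (M, S) per-site posterior
    xi: np.ndarray           # (M-1, S, S) pairwise posterior
    scales: np.ndarray       # (M,)
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class FittedModel:
    params: HMRFParams
    state: HiddenState
    region_posterior: np.ndarray       # q_s = P(R_s = elevated)
    evidence: np.ndarray               # capped classifier m_s
    t_stats: np.ndarray
    omega: np.ndarray                  # (M, M) interval-masked kernel
    intervals: list[tuple[int, int]]
    tables: TrellisTables
    error_posterior: np.ndarray        # (N, M) P(observed genotype wrong)
    trace: list[dict]
    converged: bool
    config: HMRFConfig
    labels: np.ndarray
    carriers: np.ndarray

    @property
    def selected(self) -> np.ndarray:
        return np.nonzero(self.state.X == 1)[0]


# --------------------------------------------------------------------------
# elementary potentials
# --------------------------------------------------------------------------


def f_func(x: float, n: int) -> float:
    """``f(x) = (1 - e^{-x}) / n``; 0 at x=0, increasing, -> 1/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float((1.0 - np.exp(-x)) / n)


def trans_H(mu: float, theta_region: float, d: float,
            same_state: bool, n: int) -> float:
    """Unnormalized H-transition potential.

    ``exp(N mu + (1 - mu)(1 - e^{-arg}))`` with
    ``arg = -theta d + I e^{-theta d}`` and agreement indicator I.
    The exponent is the sum over the N samples of
    ``mu + (1 - mu) f(arg)``.
    """
    arg = -theta_region * d + (1.0 if same_state else 0.0) * np.exp(
        -theta_region * d)
    return float(np.exp(n * mu + (1.0 - mu) * n * f_func(arg, n)))


def trans_J(theta_region: float, d: float, n: int) -> tuple[float, float]:
    """Silent-state transition probabilities (duplicate, permute channels).

    Duplicate channel ``f(-theta d) + e^{-theta d}``, permutation channel
    ``f(-theta d) / (n - 1)``; both clipped to [0, 1] after evaluation.
    """
    dup = f_func(-theta_region * d, n) + np.exp(-theta_region * d)
    perm = f_func(-theta_region * d, n) / max(n - 1, 1)
    return (float(np.clip(dup, 0.0, 1.0)), float(np.clip(perm, 0.0, 1.0)))


def region_potential(b_val: float, neighbor_r: np.ndarray,
                     omegas: np.ndarray, tau: float, nu: float) -> float:
    """Unnormalized potential for R_s = elevated:
    ``exp(tau B + nu sum omega_{s,s'} R_{s'})``."""
    neighbor_r = np.asarray(neighbor_r, dtype=float)
    omegas = np.asarray(omegas, dtype=float)
    return float(np.exp(tau * b_val + nu * float(omegas @ neighbor_r)))


def b_value(p_elev: np.ndarray, p_back: np.ndarray,
            form: str = "logodds") -> np.ndarray:
    """``B(P^e, P^b)``: Bernoulli log-odds (default) or difference."""
    if form == "logodds":
        return np.log(p_elev) - np.log(p_back)
    return np.asarray(p_elev) - np.asarray(p_back)


# --------------------------------------------------------------------------
# forward/backward machinery
# --------------------------------------------------------------------------


def parity_emissions(p_back: np.ndarray, p_elev: np.ndarray,
                     r_given_x: np.ndarray) -> np.ndarray:
    """Emission table over a 2J state space with the parity rule.

    Even state indices carry ``P^b``, odd indices ``P^e``; both are
    modulated by the per-site ``P(R_s | X)`` factor for that state.
    ``r_given_x`` has shape (M, 2J).
    """
    r_given_x = np.asarray(r_given_x, dtype=float)
    m, s = r_given_x.shape
    if s % 2:
        raise ValueError("state count must be even (parity rule)")
    base = np.empty((m, s))
    base[:, 0::2] = np.asarray(p_back)[:, None]
    base[:, 1::2] = np.asarray(p_elev)[:, None]
    return base * r_given_x


def forward_backward_R(emissions: np.ndarray, trans: np.ndarray,
                       prior: np.ndarray) -> TrellisTables:
    """Scaled forward/backward over an S-state chain.

    ``emissions``: (M, S) nonnegative; ``trans``: (S, S) or (M-1, S, S)
    row-stochastic; ``prior``: (S,).  Posteriors ``gamma`` and pairwise
    ``xi`` are exactly normalized; ``loglik`` is the log of the summed
    path weights.
    """
    e = np.asarray(emissions, dtype=float)
    m, s = e.shape
    tr = np.asarray(trans, dtype=float)
    if tr.ndim == 2:
        tr = np.broadcast_to(tr, (max(m - 1, 0), s, s))
    prior = np.asarray(prior, dtype=float)

    alpha = np.empty((m, s))
    scales = np.empty(m)
    a = prior * e[0]
    scales[0] = a.sum()
    if scales[0] <= 0:
        raise FloatingPointError("degenerate emissions: zero forward mass")
    alpha[0] = a / scales[0]
    for t in range(1, m):
        a = (alpha[t - 1] @ tr[t - 1]) * e[t]
        scales[t] = a.sum()
        if scales[t] <= 0:
            raise FloatingPointError("degenerate emissions: underflow")
        alpha[t] = a / scales[t]

    beta = np.empty((m, s))
    beta[m - 1] = 1.0
    for t in range(m - 2, -1, -1):
        beta[t] = (tr[t] @ (e[t + 1] * beta[t + 1])) / scales[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(scales).sum())

    tables = TrellisTables(alpha=alpha, beta=beta, gamma=gamma,
                           xi=np.empty((max(m - 1, 0), s, s)),
                           scales=scales, loglik=loglik)
    tables.xi = xi_pairwise(tables, tr, e)
    return tables


def xi_pairwise(tables: TrellisTables, trans: np.ndarray,
                emissions: np.ndarray) -> np.ndarray:
    """Normalized adjacent-pair posteriors xi(s, i, j)."""
    e = np.asarray(emissions, dtype=float)
    m, s = e.shape
    tr = np.asarray(trans, dtype=float)
    if tr.ndim == 2:
        tr = np.broadcast_to(tr, (max(m - 1, 0), s, s))
    xi = np.empty((max(m - 1, 0), s, s))
    for t in range(m - 1):
        num = (tables.alpha[t][:, None] * tr[t]
               * (e[t + 1] * tables.beta[t + 1])[None, :])
        xi[t] = num / num.sum()
    return xi


# --------------------------------------------------------------------------
# EM updates
# --------------------------------------------------------------------------


def em_update_mu(h_hat: np.ndarray, g: np.ndarray,
                 posteriors: np.ndarray) -> float:
    """Posterior-weighted disagreement over carrier mass.

    ``mu = sum I(H != G) w / sum I(G > 0) w`` with all arrays broadcastable
    to a common shape (candidate H configurations may be stacked along a
    leading axis).  Scale-invariant in ``w``; clipped to [0, 1].
    """
    h_hat = np.asarray(h_hat)
    g = np.asarray(g)
    w = np.asarray(posteriors, dtype=float)
    h_hat, g, w = np.broadcast_arrays(h_hat, g, w)
    denom = float(((g > 0) * w).sum())
    if denom <= 0:
        raise ZeroDivisionError("all-reference matrix: no carrier mass")
    num = float(((h_hat != g) * w).sum())
    return float(np.clip(num / denom, 0.0, 1.0))


def _theta_objective(theta: float, xi: np.ndarray, distances: np.ndarray,
                     mu: float, n: int) -> float:
    """Expected transition log-likelihood of the region chain.

    Transitions sharing a distance are aggregated, so the common case of a
    uniform site grid costs a single matrix evaluation.
    """
    dists = np.asarray(distances, dtype=float)[:xi.shape[0]]
    if dists.size < xi.shape[0]:  # distances may be shorter; pad with last
        dists = np.resize(dists, xi.shape[0])
    total = 0.0
    for dv in np.unique(dists):
        agg = xi[dists == dv].sum(axis=0)
        tr = _region_transition(mu, theta, float(dv), n, xi.shape[1])
        total += float((agg * np.log(np.clip(tr, 1e-300, None))).sum())
    return total


def em_update_theta(xi: np.ndarray, distances: np.ndarray, mu: float,
                    n: int, bounds: tuple[float, float] = (1e-3, 50.0),
                    grid_size: int = 25) -> float:
    """1-D maximization of the expected transition log-likelihood.

    A coarse log-grid scan seeds a bounded Brent search; if the grid shows
    multiple local maxima a warning is emitted and the global grid/Brent
    best is returned.  Degenerate chains (no transitions) return the lower
    bound with a warning.
    """
    if xi.shape[0] == 0:
        warnings.warn("no transitions: returning theta lower bound")
        return bounds[0]
    grid = np.exp(np.linspace(np.log(bounds[0]), np.log(bounds[1]),
                              grid_size))
    vals = np.array([_theta_objective(t, xi, distances, mu, n)
                     for t in grid])
    interior = vals[1:-1]
    peaks = np.sum((interior > vals[:-2]) & (interior >= vals[2:]))
    if peaks > 1:
        warnings.warn("theta objective is not unimodal; using grid fallback")
    k = int(vals.argmax())
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_size - 1)]
    res = minimize_scalar(
        lambda t: -_theta_objective(t, xi, distances, mu, n),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-5})
    best = float(res.x) if -res.fun >= vals[k] else float(grid[k])
    return best


def em_update_pb(xi: np.ndarray, theta_region: float,
                 distances: np.ndarray, n: int,
                 eps: float = 1e-3,
                 normalize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-site background probability from the pairwise posterior.

    ``P^b_s = xi(s, 0, 0) / ((1/N)(1 + (N-1) e^{-theta d}))``, clipped to
    (eps, 1-eps); ``P^e`` is the complement.  The first site reuses the
    first transition's statistics.

    With ``normalize=True`` the background and elevated diagonal masses are
    scored through the same denominator and renormalized as a pair,
    ``P^b = xi(0,0) / (xi(0,0) + xi(1,1))``: the literal ratio exceeds 1
    for persistent chains and would always clip to the boundary, destroying
    the per-site anchor (see docs/methods.md); the fit loop therefore uses
    the normalized form.
    """
    m = xi.shape[0] + 1
    pb = np.empty(m)
    for s in range(m):
        t = max(s - 1, 0)
        if normalize:
            diag = xi[t, 0, 0] + xi[t, 1, 1]
            pb[s] = xi[t, 0, 0] / diag if diag > 0 else 0.5
        else:
            denom = (1.0 / n) * (
                1.0 + (n - 1)
                * np.exp(-theta_region * float(distances[t])))
            pb[s] = xi[t, 0, 0] / denom
    pb = np.clip(pb, eps, 1.0 - eps)
    return pb, 1.0 - pb


# --------------------------------------------------------------------------
# evidence, error model, ICM
# --------------------------------------------------------------------------


def site_evidence(carriers: np.ndarray, labels: np.ndarray,
                  read_counts=None, pseudo: float = 0.5) -> np.ndarray:
    """Per-site solo-effect classifier ``m(G_.,s)``.

    Carrier-frequency log-odds of cases versus controls with a Jeffreys
    pseudo-count; positive means case enrichment.  When read counts are
    present the carrier calls are first re-weighted by the per-entry
    binomial read support (confident carriers only), which guards against
    miscalled genotypes in real data.
    """
    carriers = np.asarray(carriers, dtype=float)
    if read_counts is not None:
        from .readmodel import vaf_estimates
        tumor, _ = vaf_estimates(read_counts)
        # a carrier entry with essentially no supporting reads is discounted
        support = np.where(np.isnan(tumor), 0.0,
                           np.clip(tumor / 0.25, 0.0, 1.0))
        carriers = carriers * np.where(carriers > 0, support, 0.0)
    labels = np.asarray(labels).astype(bool)
    nc, nn = labels.sum(), (~labels).sum()
    a = carriers[labels].sum(axis=0)
    b = carriers[~labels].sum(axis=0)
    return (np.log((a + pseudo) / (nc - a + pseudo))
            - np.log((b + pseudo) / (nn - b + pseudo)))


def carrier_error_posterior(carriers: np.ndarray, labels: np.ndarray,
                            mu: float, pseudo: float = 0.5) -> np.ndarray:
    """P(observed genotype is wrong) per entry.

    Carrier entries: posterior that a carrier call at a site whose arm
    carrier frequency is ``p_hat`` arose from the mutation/error channel at
    rate ``mu`` rather than a true carrier.  Non-carrier entries get the
    symmetric false-negative posterior (numerically ~0 for rare sites).
    """
    carriers = np.asarray(carriers, dtype=bool)
    labels = np.asarray(labels).astype(bool)
    n, m = carriers.shape
    p_hat = np.empty((n, m))
    for arm in (labels, ~labels):
        cnt = arm.sum()
        freq = (carriers[arm].sum(axis=0) + pseudo) / (cnt + 2 * pseudo)
        p_hat[arm] = freq[None, :]
    mu = float(np.clip(mu, 1e-12, 1.0 - 1e-12))
    err_carrier = mu * (1 - p_hat) / (mu * (1 - p_hat) + (1 - mu) * p_hat)
    err_ref = mu * p_hat / (mu * p_hat + (1 - mu) * (1 - p_hat))
    return np.where(carriers, err_carrier, err_ref)


def icm_update_X(x: np.ndarray, m_evidence: np.ndarray, omega: np.ndarray,
                 region_posterior: np.ndarray, cfg: HMRFConfig,
                 max_sweeps: int | None = None) -> np.ndarray:
    """Site-wise conditional maximization of the causal vector.

    X_s = 1 iff ``tau m_s + nu S_s + gamma (2 q_s - 1) + prior > 0`` where
    ``S_s = min(sum omega_{s,s'} q_{s'} X_{s'}, interaction_cap)`` sums
    over currently selected interval neighbors: the support a site receives
    grows with the *number* of interacting selected neighbors (the
    signature of a genuine multi-site hotspot) but saturates so that runaway
    mutual reinforcement is impossible.  Sweeps run until no flip; on
    oscillation the best-scoring configuration seen is kept.
    """
    x = np.asarray(x, dtype=np.int8).copy()
    m_ev = np.asarray(m_evidence, dtype=float)
    q = np.asarray(region_posterior, dtype=float)
    wq = omega * q[None, :]  # omega_{s,s'} * q_{s'}
    sweeps = max_sweeps if max_sweeps is not None else cfg.icm_max_sweeps
    base = cfg.tau * m_ev + cfg.gamma * (2.0 * q - 1.0) + cfg.prior_logodds

    def scores(xv: np.ndarray) -> np.ndarray:
        s_term = np.clip(wq @ xv.astype(float),
                         -cfg.interaction_cap, cfg.interaction_cap)
        return base + cfg.nu * s_term

    best_x, best_val = x.copy(), -np.inf
    for _ in range(sweeps):
        sc = scores(x)
        new = (sc > 0).astype(np.int8)
        val = float((sc * new).sum())
        if val > best_val:
            best_val, best_x = val, new.copy()
        if np.array_equal(new, x):
            break
        x = new
    if not np.array_equal(x, best_x) and best_val > float(
            (scores(x) * x).sum()):
        x = best_x
    return x


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _region_transition(mu: float, theta: float, d: float, n: int,
                       s: int = 2) -> np.ndarray:
    """Row-stochastic S-state transition from the H-potential (same/diff).

    Works on log-potentials (the common ``N mu`` term cancels) so large
    cohorts cannot overflow the literal exponential.
    """
    log_pot = []
    for same in (True, False):
        arg = -theta * d + (1.0 if same else 0.0) * np.exp(-theta * d)
        log_pot.append((1.0 - mu) * (1.0 - np.exp(-arg)))
    lsame, ldiff = log_pot
    mx = max(lsame, ldiff)
    same_w, diff_w = np.exp(lsame - mx), np.exp(ldiff - mx)
    tr = np.full((s, s), diff_w)
    np.fill_diagonal(tr, same_w)
    return tr / tr.sum(axis=1, keepdims=True)


def _neighbor_counts(omega: np.ndarray) -> np.ndarray:
    return np.maximum((omega != 0).sum(axis=1), 1)


def fit(ds: Dataset,
        weights: np.ndarray | None = None,
        intervals: list[tuple[int, int]] | None = None,
        cfg: HMRFConfig | None = None,
        t_stats: np.ndarray | None = None) -> FittedModel:
    """Fit the field to a dataset and return parameters, X and posteriors.

    Alternates the E-step (scaled forward/backward over the region chain,
    pairwise posteriors), the M-step (``mu`` from the error model, ``theta``
    by 1-D maximization, ``P^b`` from xi) and ICM on ``X`` until parameter
    changes fall below ``cfg.tol`` with a stable ``X``, or ``max_iter``.
    """
    if cfg is None:
        cfg = HMRFConfig()
    carriers = ds.genotypes.carriers()
    labels = np.asarray(ds.labels).astype(bool)
    n, m = carriers.shape

    if intervals is None:
        from .regions import partition_sites
        intervals = list(partition_sites(carriers, labels).intervals)

    if t_stats is None:
        if ds.read_counts is not None:
            from .readmodel import site_t_statistic, vaf_estimates
            tumor, normal = vaf_estimates(ds.read_counts)
            t_stats = np.zeros(m)
            for s in range(m):
                idx = carriers[:, s]
                if idx.sum() >= 2:
                    t_stats[s] = site_t_statistic(tumor[idx, s],
                                                  normal[idx, s])
        else:
            t_stats = genotype_t_statistics(carriers, ds.labels)

    if weights is None:
        omega = np.zeros((m, m))
        t = np.asarray(t_stats, dtype=float)
        for a, b in intervals:
            sub = t[a:b]
            denom = sub[:, None] ** 2 + sub[None, :] ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(denom > 0, 2.0 * sub[:, None] * sub[None, :]
                             / np.where(denom > 0, denom, 1.0), 0.0)
            np.fill_diagonal(w, 0.0)
            omega[a:b, a:b] = w
    else:
        omega = np.asarray(weights, dtype=float)

    m_raw = site_evidence(carriers, ds.labels, ds.read_counts)
    m_ev = np.clip(m_raw, -cfg.evidence_cap, cfg.evidence_cap)

    positions = np.asarray(ds.genotypes.site_positions, dtype=float)
    d = np.diff(positions)
    d = np.where(d > 0, d, 1.0)
    if positions.max(initial=0) > m * 10:  # physical coordinates: bp / 1e4
        d = d / 1e4
    if d.size == 0:
        d = np.ones(1)

    mu = cfg.mu0
    theta = cfg.theta0
    pe = np.clip(expit(m_ev), cfg.pb_eps, 1 - cfg.pb_eps)
    pb = 1.0 - pe
    q = pe.copy()
    x = (np.asarray(t_stats) >= cfg.x_init_z).astype(np.int8)

    prior = np.array([1.0 - cfg.region_prior, cfg.region_prior])
    ncnt = _neighbor_counts(omega)
    # global elevation field: the elevated phase of the random field is only
    # as accessible as the dataset's total standardized evidence makes it.
    # Elevation is suppressed (never boosted) when the aggregate mass of
    # above-margin evidence falls short of the reference; this is what keeps
    # selection empty on evidence-free (null) data while costing signal-rich
    # data nothing.  Static in the data, so the EM dynamics stay stable.
    e_mass = float(np.clip(m_ev - cfg.elevation_margin, 0.0, None).sum())
    field = max(cfg.global_field
                * min(0.0, np.log(max(e_mass, 1e-3)
                                  / cfg.evidence_mass_ref)),
                cfg.global_field_floor)
    trace: list[dict] = []
    converged = False
    tables = None

    for it in range(cfg.max_iter):
        # E-step emissions: background potential 1, elevated potential
        # exp(tau (B - margin) + nu S) with S the neighbor-mean interaction
        bvals = b_value(pe, pb, cfg.b_form)
        s_term = np.clip((omega * q[None, :]) @ x.astype(float),
                         -cfg.interaction_cap, cfg.interaction_cap)
        eta = (cfg.tau * (bvals - cfg.elevation_margin)
               + cfg.nu * s_term + field)
        emis = np.column_stack([np.ones(m), np.exp(np.clip(eta, -30, 30))])
        emis /= emis.sum(axis=1, keepdims=True)

        if m > 1:
            tr = np.stack([
                _region_transition(mu, theta,
                                   float(d[min(t, d.size - 1)]), n)
                for t in range(m - 1)])
        else:
            tr = np.empty((0, 2, 2))
        tables = forward_backward_R(emis, tr, prior)
        q_new = tables.gamma[:, 1]

        # M-step
        err = carrier_error_posterior(carriers, ds.labels, mu)
        h_stack = np.stack([carriers.astype(np.int8),
                            (~carriers).astype(np.int8)])
        w_stack = np.stack([1.0 - err, err])
        mu_raw = em_update_mu(h_stack, carriers.astype(np.int8)[None],
                              w_stack)
        # damped and bounded: for rare variants a true singleton carrier and
        # a mutation-channel event are marginally indistinguishable, so the
        # raw update drifts upward; mu is a noise rate and stays small
        mu_new = float(np.clip(cfg.pe_damping * mu_raw
                               + (1 - cfg.pe_damping) * mu,
                               1e-6, cfg.mu_max))
        theta_new = (em_update_theta(tables.xi, d, mu_new, n,
                                     bounds=cfg.theta_bounds)
                     if m > 1 else cfg.theta_bounds[0])
        pb_new, pe_new = em_update_pb(tables.xi, theta_new, d, n,
                                      cfg.pb_eps, normalize=True) \
            if m > 1 else (pb, pe)
        # damped update keeps the classifier anchor from label-switching
        pe_new = np.clip(cfg.pe_damping * pe_new
                         + (1 - cfg.pe_damping) * expit(m_ev),
                         cfg.pb_eps, 1 - cfg.pb_eps)
        pb_new = 1.0 - pe_new

        x_new = icm_update_X(x, m_ev, omega, q_new, cfg)

        d_par = max(abs(mu_new - mu), abs(theta_new - theta),
                    float(np.abs(pe_new - pe).max()),
                    float(np.abs(q_new - q).max()))
        trace.append({"iter": it, "loglik": tables.loglik, "mu": mu_new,
                      "theta": theta_new, "dpar": d_par,
                      "n_selected": int(x_new.sum())})
        mu, theta, pe, pb, q = mu_new, theta_new, pe_new, pb_new, q_new
        stable_x = np.array_equal(x_new, x)
        x = x_new
        if d_par < cfg.tol and stable_x:
            converged = True
            break

    params = HMRFParams(mu=mu, theta_region=theta, p_elev=pe,
                        tau=cfg.tau, nu=cfg.nu, distances=d)
    err = carrier_error_posterior(carriers, ds.labels, mu)
    # collapsed hidden representative: flip entries more likely wrong
    h_rep = np.where(err > 0.5, ~carriers, carriers).astype(np.int8)
    state = HiddenState(H=h_rep, R=(q > 0.5).astype(np.int8), X=x)
    return FittedModel(
        params=params, state=state, region_posterior=q, evidence=m_ev,
        t_stats=np.asarray(t_stats, float), omega=omega,
        intervals=list(intervals), tables=tables, error_posterior=err,
        trace=trace, converged=converged, config=cfg, labels=labels,
        carriers=carriers)
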