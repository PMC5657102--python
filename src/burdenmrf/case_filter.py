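"""Removal of singular cases by per-genotype posterior probability.

A genotype's posterior ``zeta(G_{i,s})`` is the probability, under the
fitted mutation-rate model, that the observed genotype is the true one;
``zeta`` of a genotype and of its complement sum to 1.  A variant whose
observed genotype is less probable than its complement marks a divergent
feature pattern; cases accumulating more than a user-set number of such
variants are singular and removed before the association test.

To keep refitting cheap the filter shortlists the ``L`` most typical cases
(largest total log posterior of their observed genotypes), re-estimates the
structural error model on bootstrap resamples of the shortlist, and flags
against the bootstrap-averaged model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmrf import FittedModel, carrier_error_posterior
from .simdata import Dataset, GenotypeMatrix

__all__ = [
    "CaseFilterConfig",
    "posterior_zeta",
    "zeta_matrix",
    "flag_singular_variants",
    "filter_cases",
    "CaseFilterReport",
]


@dataclass(frozen=True)
class CaseFilterConfig:
    """Singular-case filter settings (all counts >= 1)."""

    singular_variant_threshold: int = 5
    bootstrap_reps: int = 50
    shortlist_size: int | None = None  # default: half the cases

    def __post_init__(self) -> None:
        if self.singular_variant_threshold < 1 or self.bootstrap_reps < 1:
            raise ValueError("thresholds and rep counts must be >= 1")
        if self.shortlist_size is not None and self.shortlist_size < 1:
            raise ValueError("shortlist_size must be >= 1")


@dataclass
class CaseFilterReport:
    removed: np.ndarray           # sample indices removed
    flagged_counts: np.ndarray    # per-sample flagged-variant counts
    threshold: int


def zeta_matrix(fitted: FittedModel,
                error_posterior: np.ndarray | None = None) -> np.ndarray:
    """(N, M) posterior probability of each *observed* genotype."""
    err = (fitted.error_posterior if error_posterior is None
           else error_posterior)
    return 1.0 - err


def posterior_zeta(fitted: FittedModel, site: int, sample: int,
                   geno: int | None = None) -> float:
    """zeta of a genotype at (sample, site), normalized over alternatives.

    With ``geno=None`` the observed genotype is scored; passing the
    complement genotype returns ``1 - zeta(observed)``.
    """
    z_obs = float(zeta_matrix(fitted)[sample, site])
    if geno is None:
        return z_obs
    observed = int(fitted.carriers[sample, site])
    return z_obs if int(bool(geno)) == observed else 1.0 - z_obs


def flag_singular_variants(fitted: FittedModel, sample: int,
                           zeta: np.ndarray | None = None) -> int:
    """Number of sites where zeta(observed) < zeta(complement)."""
    z = zeta_matrix(fitted) if zeta is None else zeta
    return int((z[sample] < 0.5).sum())


def filter_cases(ds: Dataset, fitted: FittedModel,
                 cfg: CaseFilterConfig | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Dataset, CaseFilterReport]:
    """Remove singular cases; controls are never removed.

    Shortlists the most typical ``L`` cases, refits the error-model
    structural parameter on ``bootstrap_reps`` resamples of the shortlist,
    recomputes flags for every sample against the averaged model, and
    removes cases whose flagged count exceeds the threshold.
    """
    if cfg is None:
        cfg = CaseFilterConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    labels = np.asarray(ds.labels).astype(bool)
    carriers = ds.genotypes.carriers()
    case_idx = np.nonzero(labels)[0]
    if case_idx.size == 0:
        raise ValueError("no cases to filter")

    z = zeta_matrix(fitted)
    typicality = np.log(np.clip(z, 1e-12, 1.0)).sum(axis=1)
    ell = cfg.shortlist_size or max(case_idx.size // 2, 1)
    ell = min(ell, case_idx.size)
    shortlist = case_idx[np.argsort(typicality[case_idx])[::-1][:ell]]

    # bootstrap re-estimate of mu on the shortlist (plus all controls,
    # which anchor the per-site carrier frequencies)
    ctrl_idx = np.nonzero(~labels)[0]
    mus = []
    for _ in range(cfg.bootstrap_reps):
        boot = rng.choice(shortlist, size=shortlist.size, replace=True)
        rows = np.concatenate([boot, ctrl_idx])
        sub_c = carriers[rows]
        sub_l = np.concatenate([np.ones(boot.size, bool),
                                np.zeros(ctrl_idx.size, bool)])
        err = carrier_error_posterior(sub_c, sub_l, fitted.params.mu)
        carr = sub_c.sum()
        mus.append(float((err * sub_c).sum() / max(carr, 1)))
    mu_star = float(np.clip(np.mean(mus), 1e-6, 0.5))

    err_all = carrier_error_posterior(carriers, ds.labels, mu_star)
    z_all = 1.0 - err_all
    flagged = (z_all < 0.5).sum(axis=1)

    remove_mask = labels & (flagged > cfg.singular_variant_threshold)
    if remove_mask[labels].all():
        raise ValueError("filter would remove every case; "
                         "check singular_variant_threshold")
    keep = ~remove_mask
    sub = Dataset(
        genotypes=GenotypeMatrix(ds.genotypes.values[keep],
                                 ds.genotypes.site_positions),
        labels=ds.labels[keep],
        causal_truth=ds.causal_truth,
        control_mafs=ds.control_mafs,
        case_mafs=ds.case_mafs,
        read_counts=None if ds.read_counts is None else type(ds.read_counts)(
            ds.read_counts.tumor_support[keep],
            ds.read_counts.tumor_depth[keep],
            ds.read_counts.normal_support[keep],
            ds.read_counts.normal_depth[keep]),
        somatic_mask=ds.somatic_mask,
        sample_ids=[sid for sid, k in zip(ds.sample_ids, keep) if k],
    )
    report = CaseFilterReport(
        removed=np.nonzero(remove_mask)[0],
        flagged_counts=flagged,
        threshold=cfg.singular_variant_threshold)
    return sub, report
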