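"""Collapsing association test and study-level evaluation.

Selected candidate variants are collapsed to a virtual locus: a sample is a
virtual-locus carrier iff it carries at least one selected variant.  The
2x2 carrier table (case/control x carrier/non-carrier) is tested with a
Pearson 1-df chi-square (Fisher's exact test when any expected cell is
below 5).  Dataset-level significance uses P < 0.05 in simulation mode and
the exome-wide Bonferroni threshold 2.5e-6 (20000 genes) in exome mode.

Error-rate conventions for the evaluation report follow the selection
literature this pipeline belongs to (note they are *selection* rates, not
test sizes): the type-I rate is the fraction of preset causal variants NOT
selected, the type-II rate the fraction of preset neutral variants
selected, and power the fraction of replicate datasets whose collapsed
test is significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simdata import Dataset

__all__ = [
    "SIMULATION_ALPHA",
    "EXOME_ALPHA",
    "AssocResult",
    "EvalReport",
    "collapse",
    "burden_test",
    "declare_significance",
    "evaluate",
]

SIMULATION_ALPHA = 0.05
EXOME_ALPHA = 2.5e-6


@dataclass
class AssocResult:
    selected_sites: np.ndarray
    table: np.ndarray          # [[case carriers, case non], [ctrl ...]]
    statistic: float
    p_value: float
    significant: bool
    threshold_used: float
    test_used: str = "chi2"


@dataclass
class EvalReport:
    power: float
    type_i: float
    type_ii: float
    n_datasets: int
    mean_selected: float


def collapse(ds: Dataset, selected: np.ndarray) -> np.ndarray:
    """2x2 carrier table for the virtual locus over ``selected`` sites."""
    selected = np.asarray(selected, dtype=int)
    labels = np.asarray(ds.labels).astype(bool)
    if selected.size == 0:
        nc, nn = labels.sum(), (~labels).sum()
        return np.array([[0, nc], [0, nn]], dtype=int)
    hit = ds.genotypes.carriers()[:, selected].any(axis=1)
    a = int((hit & labels).sum())
    b = int((hit & ~labels).sum())
    return np.array([[a, int(labels.sum()) - a],
                     [b, int((~labels).sum()) - b]], dtype=int)


def burden_test(table: np.ndarray) -> tuple[float, float, str]:
    """Pearson chi-square (two-sided) with Fisher exact fallback.

    Returns (statistic, p, test name).  Degenerate margins give p = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or np.any(table.sum(axis=1) == 0) \
            or np.any(table.sum(axis=0) == 0):
        return 0.0, 1.0, "degenerate"
    expected = (table.sum(axis=1, keepdims=True)
                * table.sum(axis=0, keepdims=True) / table.sum())
    if np.any(expected < 5):
        odds, p = stats.fisher_exact(table.astype(int))
        return float(odds), float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi2"


def declare_significance(p: float, mode: str = "simulation") -> bool:
    """Strict-inequality significance call at the mode's threshold."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if mode == "simulation":
        return p < SIMULATION_ALPHA
    if mode == "exome":
        return p < EXOME_ALPHA
    raise ValueError("mode must be 'simulation' or 'exome'")


def test_selection(ds: Dataset, selected: np.ndarray,
                   mode: str = "simulation") -> AssocResult:
    """Collapse + burden test + significance call in one step."""
    selected = np.asarray(selected, dtype=int)
    threshold = SIMULATION_ALPHA if mode == "simulation" else EXOME_ALPHA
    if selected.size == 0:
        table = collapse(ds, selected)
        return AssocResult(selected, table, 0.0, 1.0, False, threshold,
                           "empty")
    table = collapse(ds, selected)
    stat, p, used = burden_test(table)
    return AssocResult(selected, table, stat, p,
                       declare_significance(p, mode), threshold, used)


def evaluate(selections: list[np.ndarray], significants: list[bool],
             truths: list[np.ndarray]) -> EvalReport:
    """Aggregate selection error rates and power over replicate datasets.

    type-I = mean over datasets of (#causal not selected) / C;
    type-II = mean of (#neutral selected) / (M - C);
    power = fraction of significant datasets.
    """
    if not (len(selections) == len(significants) == len(truths)):
        raise ValueError("per-dataset inputs must align")
    t1, t2 = [], []
    for sel, truth in zip(selections, truths):
        truth = np.asarray(truth).astype(bool)
        chosen = np.zeros(truth.size, dtype=bool)
        chosen[np.asarray(sel, dtype=int)] = True
        c = truth.sum()
        if c > 0:
            t1.append((truth & ~chosen).sum() / c)
        if c < truth.size:
            t2.append((chosen & ~truth).sum() / (truth.size - c))
    return EvalReport(
        power=float(np.mean([bool(s) for s in significants])),
        type_i=float(np.mean(t1)) if t1 else float("nan"),
        type_ii=float(np.mean(t2)) if t2 else float("nan"),
        n_datasets=len(selections),
        mean_selected=float(np.mean([len(s) for s in selections])),
    )
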