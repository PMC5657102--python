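"""End-to-end orchestration: weights -> regions -> fit -> filter -> test.

`analyze_dataset` runs the full selection-and-test pipeline on one dataset
in memory; `run_study` repeats it over replicate simulated datasets and
aggregates power and error rates; `run_null_battery` measures the
dataset-level false-positive rate on null-model data.  Each stage draws
randomness from a named child of one seed sequence, so stage order cannot
silently reshuffle streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import assoc
from .case_filter import CaseFilterConfig, CaseFilterReport, filter_cases
from .hmrf import FittedModel, HMRFConfig, fit
from .regions import partition_sites
from .simdata import Dataset, SimConfig, generate_dataset, \
    generate_null_dataset

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "stage_rng",
    "analyze_dataset",
    "run_study",
    "run_null_battery",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    hmrf: HMRFConfig = field(default_factory=HMRFConfig)
    case_filter: CaseFilterConfig = field(default_factory=CaseFilterConfig)
    apply_case_filter: bool = True
    refit_after_filter: bool = True
    mode: str = "simulation"


@dataclass
class PipelineResult:
    selected: np.ndarray
    assoc: assoc.AssocResult
    fitted: FittedModel
    filter_report: CaseFilterReport | None
    intervals: list[tuple[int, int]]


def stage_rng(seed: int, *stage: str | int) -> np.random.Generator:
    """Named-substream generator: one base seed, one child per stage.

    Stage names are hashed with crc32 (stable across processes, unlike
    Python's builtin string hash).
    """
    import zlib
    key = tuple(s % (2**31) if isinstance(s, int)
                else zlib.crc32(s.encode()) % (2**31) for s in stage)
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=key))


def analyze_dataset(ds: Dataset, cfg: PipelineConfig | None = None,
                    rng: np.random.Generator | None = None
                    ) -> PipelineResult:
    """Select candidate variants on one dataset and run the burden test."""
    if cfg is None:
        cfg = PipelineConfig()
    if rng is None:
        rng = np.random.default_rng(0)

    carriers = ds.genotypes.carriers()
    intervals = list(partition_sites(carriers, ds.labels).intervals)
    fitted = fit(ds, intervals=intervals, cfg=cfg.hmrf)

    report = None
    working = ds
    if cfg.apply_case_filter:
        working, report = filter_cases(ds, fitted, cfg.case_filter, rng)
        if report.removed.size and cfg.refit_after_filter:
            fitted = fit(working, intervals=intervals, cfg=cfg.hmrf)

    selected = fitted.selected
    result = assoc.test_selection(working, selected, mode=cfg.mode)
    return PipelineResult(selected=selected, assoc=result, fitted=fitted,
                          filter_report=report, intervals=intervals)


def run_study(sim: SimConfig, n_datasets: int, seed: int,
              cfg: PipelineConfig | None = None
              ) -> tuple[assoc.EvalReport, list[PipelineResult]]:
    """Replicate the simulation study at one configuration."""
    if cfg is None:
        cfg = PipelineConfig()
    selections, sigs, truths, results = [], [], [], []
    for k in range(n_datasets):
        ds = generate_dataset(sim, stage_rng(seed, "simulate", k))
        res = analyze_dataset(ds, cfg, stage_rng(seed, "analyze", k))
        selections.append(res.selected)
        sigs.append(res.assoc.significant)
        truths.append(ds.causal_truth)
        results.append(res)
    return assoc.evaluate(selections, sigs, truths), results


def run_pipeline(run_cfg, output_dir: str | None = None) -> dict:
    """End-to-end on-disk run: simulate -> analyze -> write artifacts.

    Accepts a :class:`burdenmrf.io.RunConfig`; every artifact is stamped
    with the seed and a hash of the full configuration.  Returns a summary
    dict (paths, p-value, selection size).
    """
    import json
    from pathlib import Path

    from . import io as bio

    out = Path(output_dir or run_cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = bio.config_hash(run_cfg)
    seed = run_cfg.seed

    ds = generate_dataset(run_cfg.sim, stage_rng(seed, "simulate", 0))
    bio.write_genotype_tsv(out / "genotypes.tsv", ds, seed=seed)
    bio.write_causal_truth_tsv(out / "causal_truth.tsv", ds, seed=seed)

    cfg = PipelineConfig(hmrf=run_cfg.hmrf, case_filter=run_cfg.case_filter,
                         mode=run_cfg.mode)
    res = analyze_dataset(ds, cfg, stage_rng(seed, "analyze", 0))

    bio.write_intervals_bed(out / "intervals.bed", res.intervals)
    bio.write_fitted_json(out / "fitted.json", res.fitted, seed=seed,
                          cfg_hash=h)
    bio.write_trace_tsv(out / "trace.tsv", res.fitted)
    summary = {
        "seed": seed,
        "config_hash": h,
        "n_selected": int(res.selected.size),
        "selected": res.selected.tolist(),
        "statistic": res.assoc.statistic,
        "p_value": res.assoc.p_value,
        "significant": bool(res.assoc.significant),
        "test_used": res.assoc.test_used,
        "n_cases_removed": (0 if res.filter_report is None
                            else int(res.filter_report.removed.size)),
    }
    (out / "result.json").write_text(json.dumps(summary, indent=1,
                                                sort_keys=True))
    return summary


def run_null_battery(n_datasets: int, seed: int,
                     n_samples: int = 1000, n_sites: int = 100,
                     mut_prob: float = 0.005,
                     cfg: PipelineConfig | None = None) -> dict:
    """Dataset-level false-positive rate on null-model data."""
    if cfg is None:
        cfg = PipelineConfig()
    n_sig = 0
    n_selected = []
    for k in range(n_datasets):
        ds = generate_null_dataset(n_samples, n_sites, mut_prob,
                                   stage_rng(seed, "null-sim", k))
        res = analyze_dataset(ds, cfg, stage_rng(seed, "null-analyze", k))
        n_sig += int(res.assoc.significant)
        n_selected.append(res.selected.size)
    return {
        "n_datasets": n_datasets,
        "n_significant": n_sig,
        "significant_fraction": n_sig / n_datasets,
        "mean_selected": float(np.mean(n_selected)),
    }
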