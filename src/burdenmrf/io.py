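"""File formats: genotype/read-count/site-stat TSV, BED intervals, VCF.

TSV dialect: tab-separated, UTF-8, a single '#'-prefixed header line,
``.`` for missing values.  Genotype tables are samples x sites with the
sample ID in the first column and the ``case|control`` label in the
second.  Intervals are written as BED (0-based, half-open) on a synthetic
chromosome.  A minimal VCF round trip (GT only, 1-based positions) is
provided for interoperability; reading goes through cyvcf2.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .case_filter import CaseFilterConfig
from .hmrf import FittedModel, HMRFConfig
from .readmodel import InteractionWeights, SiteStats
from .simdata import Dataset, GenotypeMatrix, ReadCountTable, SimConfig

__all__ = [
    "RunConfig",
    "write_genotype_tsv", "read_genotype_tsv",
    "write_causal_truth_tsv", "read_causal_truth_tsv",
    "write_read_counts_tsv", "read_read_counts_tsv",
    "write_site_stats_tsv", "write_weights_tsv", "read_weights_tsv",
    "write_intervals_bed", "read_intervals_bed",
    "write_fitted_json", "write_vcf_minimal", "read_vcf_minimal",
    "config_hash",
]

BED_CHROM = "sim1"


@dataclass
class RunConfig:
    """Umbrella configuration for an end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    hmrf: HMRFConfig = field(default_factory=HMRFConfig)
    case_filter: CaseFilterConfig = field(default_factory=CaseFilterConfig)
    seed: int = 0
    mode: str = "simulation"
    log_level: str = "INFO"
    output_dir: str = "burdenmrf_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "sim" in raw:
            kw["sim"] = SimConfig(**raw["sim"])
        if "hmrf" in raw:
            hv = dict(raw["hmrf"])
            if "theta_bounds" in hv:
                hv["theta_bounds"] = tuple(hv["theta_bounds"])
            kw["hmrf"] = HMRFConfig(**hv)
        if "case_filter" in raw:
            kw["case_filter"] = CaseFilterConfig(**raw["case_filter"])
        for key in ("seed", "mode", "log_level", "output_dir"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header_comment(seed: int | None = None, extra: str = "") -> str:
    parts = ["burdenmrf"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if extra:
        parts.append(extra)
    return " ".join(parts)


# -- genotypes --------------------------------------------------------------


def write_genotype_tsv(path: str | Path, ds: Dataset,
                       seed: int | None = None) -> None:
    m = ds.genotypes.n_sites
    cols = [f"site_{i:04d}" for i in range(m)]
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment(seed)}\n")
        fh.write("#sample\tlabel\t" + "\t".join(cols) + "\n")
        for i, sid in enumerate(ds.sample_ids):
            lab = "case" if ds.labels[i] else "control"
            row = "\t".join(str(int(v)) for v in ds.genotypes.values[i])
            fh.write(f"{sid}\t{lab}\t{row}\n")


def read_genotype_tsv(path: str | Path) -> Dataset:
    """Parse a genotype TSV; round-trips with :func:`write_genotype_tsv`."""
    header = None
    rows, ids, labels = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#sample"):
                header = line.lstrip("#").split("\t")[2:]
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is not None and len(parts) != len(header) + 2:
                raise ValueError(
                    f"ragged row for sample {parts[0]!r}: "
                    f"{len(parts) - 2} genotypes, expected {len(header)}")
            sid, lab, *geno = parts
            if lab not in ("case", "control"):
                raise ValueError(f"unknown label {lab!r}")
            if sid in ids:
                raise ValueError(f"duplicate sample ID {sid!r}")
            try:
                vals = [int(g) for g in geno]
            except ValueError as exc:
                raise ValueError(f"non-integer genotype cell: {exc}") from exc
            if any(v not in (0, 1, 2) for v in vals):
                raise ValueError("genotype cells must be 0, 1 or 2")
            ids.append(sid)
            labels.append(1 if lab == "case" else 0)
            rows.append(vals)
    if not rows:
        raise ValueError("empty genotype file")
    geno = np.asarray(rows, dtype=np.int8)
    m = geno.shape[1]
    placeholder = np.full(m, np.nan)
    return Dataset(genotypes=GenotypeMatrix(geno),
                   labels=np.asarray(labels, np.int8),
                   causal_truth=np.zeros(m, np.int8),
                   control_mafs=placeholder, case_mafs=placeholder.copy(),
                   sample_ids=ids)


# -- causal truth ------------------------------------------------------------


def write_causal_truth_tsv(path: str | Path, ds: Dataset,
                           seed: int | None = None) -> None:
    df = pd.DataFrame({
        "site": [f"site_{i:04d}" for i in range(ds.genotypes.n_sites)],
        "causal": ds.causal_truth.astype(int),
        "control_maf": ds.control_mafs,
        "case_maf": ds.case_mafs,
    })
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment(seed)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_causal_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       names=["site", "causal", "control_maf", "case_maf"],
                       header=0, skiprows=1)


# -- read counts (long format) ----------------------------------------------


def write_read_counts_tsv(path: str | Path, ds: Dataset,
                          seed: int | None = None) -> None:
    if ds.read_counts is None:
        raise ValueError("dataset has no read counts")
    rc = ds.read_counts
    n, m = rc.tumor_depth.shape
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment(seed)}\n")
        fh.write("#sample\tsite\tc_plus\td_plus\tc_minus\td_minus\n")
        for i in range(n):
            sid = ds.sample_ids[i]
            for s in range(m):
                fh.write(f"{sid}\tsite_{s:04d}\t"
                         f"{rc.tumor_support[i, s]}\t{rc.tumor_depth[i, s]}"
                         f"\t{rc.normal_support[i, s]}\t"
                         f"{rc.normal_depth[i, s]}\n")


def read_read_counts_tsv(path: str | Path,
                         sample_ids: list[str]) -> ReadCountTable:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["sample", "site", "c_plus", "d_plus",
                            "c_minus", "d_minus"])
    sites = sorted(df["site"].unique())
    s_idx = {s: i for i, s in enumerate(sites)}
    i_idx = {s: i for i, s in enumerate(sample_ids)}
    shape = (len(sample_ids), len(sites))
    arrs = [np.zeros(shape, dtype=int) for _ in range(4)]
    rows = df["sample"].map(i_idx).to_numpy()
    cols = df["site"].map(s_idx).to_numpy()
    for arr, col in zip(arrs, ["c_plus", "d_plus", "c_minus", "d_minus"]):
        arr[rows, cols] = df[col].to_numpy()
    return ReadCountTable(*arrs)


# -- site stats and weights --------------------------------------------------


def write_site_stats_tsv(path: str | Path, stats: SiteStats) -> None:
    df = pd.DataFrame({
        "site": [f"site_{i:04d}" for i in range(stats.t_stat.size)],
        "t": stats.t_stat,
        "tumor_vaf_mean": stats.tumor_vaf_mean,
        "normal_vaf_mean": stats.normal_vaf_mean,
        "n_informative": stats.n_informative,
    })
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment()}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def write_weights_tsv(path: str | Path, iw: InteractionWeights) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment()}\n")
        fh.write("#s\ts_prime\tomega\n")
        for (a, b), w in sorted(iw.pairs.items()):
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def read_weights_tsv(path: str | Path, n_sites: int) -> InteractionWeights:
    iw = InteractionWeights(n_sites=n_sites)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["s", "s_prime", "omega"])
    for _, row in df.iterrows():
        iw.set(int(row["s"]), int(row["s_prime"]), float(row["omega"]))
    return iw


# -- intervals ---------------------------------------------------------------


def write_intervals_bed(path: str | Path,
                        intervals: list[tuple[int, int]]) -> None:
    with open(path, "w") as fh:
        for a, b in intervals:
            fh.write(f"{BED_CHROM}\t{a}\t{b}\n")


def read_intervals_bed(path: str | Path) -> list[tuple[int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            _, a, b = line.split("\t")[:3]
            out.append((int(a), int(b)))
    return out


# -- fitted model ------------------------------------------------------------


def write_fitted_json(path: str | Path, fitted: FittedModel,
                      seed: int | None = None,
                      cfg_hash: str | None = None) -> None:
    payload = {
        "seed": seed,
        "config_hash": cfg_hash,
        "mu": fitted.params.mu,
        "theta_region": fitted.params.theta_region,
        "tau": fitted.params.tau,
        "nu": fitted.params.nu,
        "p_elev": fitted.params.p_elev.tolist(),
        "X": fitted.state.X.tolist(),
        "region_posterior": fitted.region_posterior.tolist(),
        "evidence": fitted.evidence.tolist(),
        "selected": fitted.selected.tolist(),
        "converged": fitted.converged,
        "n_iter": len(fitted.trace),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_trace_tsv(path: str | Path, fitted: FittedModel) -> None:
    pd.DataFrame(fitted.trace).to_csv(path, sep="\t", index=False)


# -- VCF ---------------------------------------------------------------------


def write_vcf_minimal(path: str | Path, ds: Dataset) -> None:
    """GT-only VCF export; site index i becomes 1-based position i+1."""
    n, m = ds.genotypes.values.shape
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={BED_CHROM},length={m + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.sample_ids) + "\n")
        for s in range(m):
            gts = []
            for i in range(n):
                v = int(ds.genotypes.values[i, s])
                gts.append("0/0" if v == 0 else ("0/1" if v == 1 else "1/1"))
            fh.write(f"{BED_CHROM}\t{s + 1}\tsite_{s:04d}\tA\tT\t.\t.\t.\t"
                     "GT\t" + "\t".join(gts) + "\n")


def read_vcf_minimal(path: str | Path) -> tuple[GenotypeMatrix, list[str],
                                                np.ndarray]:
    """Carrier-coded genotypes from a VCF (any non-ref allele -> carrier).

    Returns (matrix, sample IDs, per-sample-per-site missing mask).
    Positions are mapped from 1-based VCF to 0-based site coordinates.
    """
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, positions, missing_cols = [], [], []
    for rec in vcf:
        gt = np.asarray(rec.genotype.array())[:, :2]
        missing = (gt < 0).any(axis=1)
        carrier = (gt > 0).any(axis=1) & ~missing
        hom = (gt > 0).all(axis=1) & ~missing
        cols.append(np.where(hom, 2, carrier.astype(int)))
        missing_cols.append(missing)
        positions.append(rec.POS - 1)
    if not cols:
        raise ValueError("VCF contains no records")
    values = np.stack(cols, axis=1).astype(np.int8)
    missing = np.stack(missing_cols, axis=1)
    return (GenotypeMatrix(values, np.asarray(positions)), samples, missing)
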