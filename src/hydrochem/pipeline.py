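"""End-to-end analysis pipeline: qc -> stats -> facies -> quality -> risk.

A run is fully described by a :class:`RunConfig` (YAML-serializable);
every stage writes its table under the output directory and the
consolidated summary mirrors a field-survey report: descriptive
statistics, water-type counts, WQI class proportions, irrigation band
counts and the per-group hazard-quotient summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .chemistry import (
    classify_hardness,
    classify_tds,
    descriptive_stats,
    samples_to_frame,
    summary_frame,
)
from .facies import facies_report, nitrate_exceedance, pearson_matrix
from .io import read_samples, write_samples
from .quality import DEFAULT_WEIGHT_TABLE, WeightTable, quality_report
from .risk import (
    DEFAULT_EXPOSURE,
    Distribution,
    ExposureParams,
    MCConfig,
    cohort_risk,
    monte_carlo_hq,
    risk_report,
)
from .synthetic import default_config, generate, validate

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("qc", "stats", "facies", "wqi", "irrigation", "risk")

STAT_ANALYTES = ("tds", "ph", "th", "ca", "mg", "k", "na", "cl", "so4", "hco3", "no3")
CORR_VARS = ("ph", "tds", "ca", "mg", "k", "na", "cl", "so4", "hco3", "no3")


@dataclass
class RunConfig:
    """One pipeline run: input (file or simulation), stages, outputs."""

    input_path: str | None = None  # CSV; None -> simulate
    simulate_n: int = 63
    seed: int = 20230726
    stages: tuple[str, ...] = ALL_STAGES
    output_dir: str = "hydrochem_out"
    weight_table: WeightTable = field(default_factory=lambda: DEFAULT_WEIGHT_TABLE)
    exposure: Mapping[str, ExposureParams] = field(default_factory=lambda: dict(DEFAULT_EXPOSURE))
    mc_iterations: int = 10_000
    nitrate_basis: str = "as_no3"
    nitrate_threshold: float = 20.0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage list must be nonempty")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "input": self.input_path,
                "n": self.simulate_n,
                "seed": self.seed,
                "stages": list(self.stages),
                "weights": dict(self.weight_table.weights),
                "standards": dict(self.weight_table.standards),
                "mc": self.mc_iterations,
                "basis": self.nitrate_basis,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict[str, Any]:
    return {"config_hash": config.fingerprint(), "seed": config.seed, "version": __version__}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write every report to disk.

    Returns the report bundle as a dict (tables as DataFrames plus the
    human-readable summary text).  Reruns with an identical config are
    byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"provenance": _provenance(config)}
    summary: list[str] = [
        "groundwater survey report",
        f"  config {config.fingerprint()}  seed {config.seed}  hydrochem {__version__}",
    ]

    if config.input_path is not None:
        samples = read_samples(config.input_path)
        summary.append(f"  input: {config.input_path} ({len(samples)} samples)")
    else:
        syn = default_config(n=config.simulate_n, seed=config.seed)
        samples = generate(syn)
        write_samples(samples, out / "samples.csv")
        report = validate(samples, syn)
        report.marginals.to_csv(out / "synthetic_validation_marginals.csv", index=False)
        report.correlations.to_csv(out / "synthetic_validation_correlations.csv", index=False)
        summary.append(f"  input: simulated cohort (n={config.simulate_n}, seed={config.seed})")
    if not samples:
        raise ValueError("no samples to analyse")
    frame = samples_to_frame(samples)

    if "qc" in config.stages:
        qc = frame[["sample_id", "cbe"]].copy()
        qc["cbe_pass"] = qc["cbe"].abs() <= 5.0
        qc["tds_class"] = frame["tds"].map(classify_tds)
        qc["th"] = frame["th"]
        qc["th_class"] = frame["th"].map(classify_hardness)
        qc["depth_class"] = frame["depth_class"]
        qc.to_csv(out / "qc.csv", index=False)
        bundle["qc"] = qc
        summary += [
            "qc:",
            f"  |CBE| <= 5%: {100 * qc['cbe_pass'].mean():.2f}% of samples"
            f" (mean CBE {qc['cbe'].mean():+.2f}%)",
            f"  fresh {100 * (qc['tds_class'] == 'fresh').mean():.2f}%"
            f" / soft {100 * (qc['th_class'] == 'soft').mean():.2f}%",
        ]

    if "stats" in config.stages:
        rows = descriptive_stats(frame, [a for a in STAT_ANALYTES if a in frame.columns])
        stats_df = summary_frame(rows)
        stats_df.to_csv(out / "descriptive_stats.csv", index=False)
        r, p, stars = pearson_matrix(frame, [v for v in CORR_VARS if v in frame.columns])
        r.to_csv(out / "correlation_matrix.csv")
        stars.to_csv(out / "correlation_stars.csv")
        bundle["stats"], bundle["correlation"] = stats_df, r
        count, pct = nitrate_exceedance(samples, config.nitrate_threshold)
        summary += [
            "descriptive statistics: see descriptive_stats.csv",
            f"  NO3 > {config.nitrate_threshold:g} mg/L: {count} samples ({pct:.2f}%)",
        ]

    if "facies" in config.stages:
        fac = facies_report(samples)
        fac.to_csv(out / "facies.csv", index=False)
        bundle["facies"] = fac
        top = fac["facies"].value_counts()
        neg_cai = (
            100 * float(np.mean((fac["cai_1"] < 0).to_numpy() | (fac["cai_2"] < 0).to_numpy()))
        )
        summary += [
            "facies:",
            "  water types: " + "; ".join(f"{t} ({c})" for t, c in top.head(4).items()),
            "  Gibbs regions: "
            + "; ".join(f"{g} ({c})" for g, c in fac["gibbs_region"].value_counts().items()),
            f"  negative CAI (forward exchange): {neg_cai:.2f}%",
        ]

    if "wqi" in config.stages or "irrigation" in config.stages:
        qual = quality_report(samples, config.weight_table)
        qual.to_csv(out / "quality.csv", index=False)
        bundle["quality"] = qual
        if "wqi" in config.stages:
            shares = qual["wqi_class"].value_counts(normalize=True) * 100
            summary += [
                "drinking water (WQI):",
                f"  WQI {qual['wqi'].min():.2f}–{qual['wqi'].max():.2f},"
                f" mean {qual['wqi'].mean():.2f}",
                "  classes: " + "; ".join(f"{k} {v:.2f}%" for k, v in shares.items()),
            ]
        if "irrigation" in config.stages:
            summary += [
                "irrigation:",
                f"  SAR {qual['sar'].min():.2f}–{qual['sar'].max():.2f};"
                f" %Na {qual['percent_na'].min():.2f}–{qual['percent_na'].max():.2f};"
                f" RSC {qual['rsc'].min():.2f}–{qual['rsc'].max():.2f} meq/L",
                "  %Na bands: "
                + "; ".join(f"{k} {v}" for k, v in qual["na_band"].value_counts().items()),
                "  USSL: "
                + "; ".join(f"{k} {v}" for k, v in qual["ussl_class"].value_counts().items()),
                "  Wilcox: "
                + "; ".join(f"{k} {v}" for k, v in qual["wilcox_class"].value_counts().items()),
            ]

    if "risk" in config.stages:
        det = cohort_risk(samples, config.exposure, config.nitrate_basis)
        det.to_csv(out / "risk_cohort.csv", index=False)
        risk_report(samples, config.exposure, config.nitrate_basis).to_csv(
            out / "risk_per_sample.csv", index=False
        )
        no3 = frame["no3"].to_numpy(dtype=float)
        mc_rows = []
        for idx, (group, p) in enumerate(config.exposure.items()):
            mc = monte_carlo_hq(
                MCConfig(
                    dist_c=Distribution.lognormal(
                        float(np.mean(no3)), float(np.std(no3, ddof=1))
                    )
                    if np.std(no3) > 0
                    else Distribution.point(float(np.mean(no3))),
                    dist_bw=Distribution.normal_truncated(p.bw, 0.15 * p.bw, lower=0.0),
                    dist_ir=Distribution.normal_truncated(p.ir, 0.2 * p.ir, lower=0.0),
                    iterations=config.mc_iterations,
                    seed=config.seed + idx,
                ),
                p,
            )
            mc_rows.append(
                {
                    "group": group,
                    "mean_hq": mc.mean_hq,
                    "sd_hq": mc.sd_hq,
                    **{f"p{q}": v for q, v in mc.percentiles.items()},
                    "p_exceed": mc.p_exceed,
                }
            )
        mc_df = pd.DataFrame(mc_rows)
        mc_df.to_csv(out / "risk_montecarlo.csv", index=False)
        bundle["risk"], bundle["risk_mc"] = det, mc_df
        summary.append("nitrate health risk (HQ = E/RfD, limit 1):")
        for _, row in det.iterrows():
            mc_row = mc_df[mc_df["group"] == row["group"]].iloc[0]
            summary.append(
                f"  {row['group']}: mean HQ {row['hq_mean']:.2f}"
                f" (range {row['hq_min']:.2f}–{row['hq_max']:.2f}),"
                f" {row['pct_exceed']:.2f}% above 1;"
                f" MC mean {mc_row['mean_hq']:.2f}, P(HQ>1) {100 * mc_row['p_exceed']:.2f}%"
            )

    text = "\n".join(summary) + "\n"
    (out / "summary.txt").write_text(text)
    bundle["summary"] = text
    logger.info("pipeline finished: %s", out)
    return bundle
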