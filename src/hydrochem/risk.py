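"""Non-carcinogenic nitrate health risk via the USEPA oral-ingestion model.

Exposure dose and hazard quotient::

    E  = (C * IR * EF * ED) / (BW * AT)     [mg/(kg d)]
    HQ = E / RfD                            [-]

with C the nitrate concentration (mg/L), IR daily water intake (L/d),
EF exposure frequency (d/a), ED exposure duration (a), BW body weight
(kg), AT averaging time (d) and RfD the nitrate reference dose.
HQ > 1 marks unacceptable non-carcinogenic risk.  Uncertainty in C, BW
and IR is propagated by seeded Monte Carlo simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import WaterSample

__all__ = [
    "ExposureParams",
    "Distribution",
    "MCConfig",
    "MCResult",
    "DEFAULT_EXPOSURE",
    "NITRATE_RFD",
    "exposure_dose",
    "hazard_quotient",
    "cohort_risk",
    "monte_carlo_hq",
    "risk_report",
]

#: USEPA oral reference dose for nitrate, mg/(kg day)
NITRATE_RFD = 1.6

#: mass ratio NO3 / N for converting nitrate-as-nitrogen input
NO3_PER_N = 4.427


@dataclass(frozen=True)
class ExposureParams:
    """One age group's ingestion-exposure parameters."""

    group: str
    ir: float  # L/day
    ef: float  # days/year
    ed: float  # years
    bw: float  # kg
    at: float  # days
    rfd: float = NITRATE_RFD  # mg/(kg day)

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "at", "rfd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.group}: {name} must be positive")


def _grp(group: str, ir: float, bw: float, ed: float) -> ExposureParams:
    return ExposureParams(group=group, ir=ir, ef=365.0, ed=ed, bw=bw, at=ed * 365.0)


# Chinese exposure-factor handbook values; AT = ED*365 for
# non-carcinogenic endpoints, so E reduces to C*IR/BW.
DEFAULT_EXPOSURE: dict[str, ExposureParams] = {
    "infant": _grp("infant", ir=0.6, bw=9.0, ed=1.0),
    "child": _grp("child", ir=1.0, bw=20.0, ed=10.0),
    "teenager": _grp("teenager", ir=1.4, bw=50.0, ed=8.0),
    "adult": _grp("adult", ir=1.5, bw=60.0, ed=30.0),
}


def exposure_dose(c: float | np.ndarray, p: ExposureParams,
                  ir=None, bw=None) -> float | np.ndarray:
    """Daily ingestion dose E = C*IR*EF*ED/(BW*AT) in mg/(kg day).

    ``ir``/``bw`` override the point values in ``p`` (used by the
    Monte Carlo path so both routes share one formula).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    ir = p.ir if ir is None else ir
    bw = p.bw if bw is None else bw
    if np.any(np.asarray(bw) <= 0):
        raise ValueError("body weight must be positive")
    out = c * ir * p.ef * p.ed / (bw * p.at)
    return float(out) if out.ndim == 0 and np.ndim(ir) == 0 and np.ndim(bw) == 0 else out


def hazard_quotient(e: float | np.ndarray, rfd: float = NITRATE_RFD):
    """HQ = E / RfD; values above 1 are unacceptable."""
    if rfd <= 0:
        raise ValueError("RfD must be positive")
    out = np.asarray(e, dtype=float) / rfd
    return float(out) if out.ndim == 0 else out


def cohort_risk(
    samples: Sequence[WaterSample],
    params: Mapping[str, ExposureParams] = DEFAULT_EXPOSURE,
    nitrate_basis: str = "as_no3",
) -> pd.DataFrame:
    """Deterministic per-group HQ summary over a sample cohort.

    Returns one row per age group with min/mean/max HQ and the percent
    of samples strictly above HQ = 1.  ``nitrate_basis="as_n"``
    converts reported nitrate-N to NO3 before dosing.
    """
    if not samples:
        raise ValueError("empty cohort")
    c = np.array([s.no3 for s in samples], dtype=float)
    if nitrate_basis == "as_n":
        c = c * NO3_PER_N
    elif nitrate_basis != "as_no3":
        raise ValueError("nitrate_basis must be 'as_no3' or 'as_n'")
    rows = []
    for group, p in params.items():
        hq = hazard_quotient(exposure_dose(c, p), p.rfd)
        rows.append(
            {
                "group": group,
                "hq_min": float(np.min(hq)),
                "hq_mean": float(np.mean(hq)),
                "hq_max": float(np.max(hq)),
                "pct_exceed": round(100.0 * float(np.mean(hq > 1.0)), 2),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Distribution:
    """Named sampling distribution for one Monte Carlo input.

    families: ``point(value)``, ``normal_truncated(mean, sd, lower,
    upper)``, ``lognormal(mean, sd)`` (moment-parameterized on the
    natural scale), ``triangular(left, mode, right)``.
    """

    family: str
    params: Mapping[str, float]

    @staticmethod
    def point(value: float) -> "Distribution":
        return Distribution("point", {"value": value})

    @staticmethod
    def normal_truncated(mean: float, sd: float, lower: float = 0.0,
                         upper: float = np.inf) -> "Distribution":
        return Distribution(
            "normal_truncated", {"mean": mean, "sd": sd, "lower": lower, "upper": upper}
        )

    @staticmethod
    def lognormal(mean: float, sd: float) -> "Distribution":
        """Lognormal with target arithmetic mean and SD."""
        if mean <= 0 or sd < 0:
            raise ValueError("lognormal needs mean > 0 and sd >= 0")
        return Distribution("lognormal", {"mean": mean, "sd": sd})

    @staticmethod
    def triangular(left: float, mode: float, right: float) -> "Distribution":
        return Distribution("triangular", {"left": left, "mode": mode, "right": right})

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(n, float(p["value"]))
        if self.family == "normal_truncated":
            from scipy.stats import truncnorm

            if p["sd"] == 0:
                return np.full(n, float(p["mean"]))
            a = (p["lower"] - p["mean"]) / p["sd"]
            b = (p["upper"] - p["mean"]) / p["sd"]
            return truncnorm.rvs(a, b, loc=p["mean"], scale=p["sd"], size=n, random_state=rng)
        if self.family == "lognormal":
            m, s = p["mean"], p["sd"]
            if s == 0:
                return np.full(n, float(m))
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
        if self.family == "triangular":
            return rng.triangular(p["left"], p["mode"], p["right"], size=n)
        raise ValueError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings: C, BW and IR vary; everything else is fixed."""

    dist_c: Distribution
    dist_bw: Distribution
    dist_ir: Distribution
    iterations: int = 10_000
    seed: int = 20230726

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class MCResult:
    mean_hq: float
    sd_hq: float
    percentiles: Mapping[int, float]  # keys 5, 25, 50, 75, 95
    p_exceed: float  # P(HQ > 1)
    iterations: int
    seed: int


_MAX_RESAMPLE_ROUNDS = 100


def _draw_nonnegative(dist: Distribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n values, resampling any negatives (bounded retries)."""
    x = dist.sample(n, rng)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = x < 0
        if not bad.any():
            return x
        x[bad] = dist.sample(int(bad.sum()), rng)
    raise RuntimeError(f"distribution {dist.family} keeps producing negative draws")


def monte_carlo_hq(config: MCConfig, p: ExposureParams) -> MCResult:
    """Propagate C/BW/IR uncertainty through the HQ model.

    Draws are independent across the three inputs (no copula), seeded
    and reproducible; negative draws are rejected and resampled.  With
    all three inputs point masses the result equals the deterministic
    path bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.iterations
    c = _draw_nonnegative(config.dist_c, n, rng)
    bw = _draw_nonnegative(config.dist_bw, n, rng)
    ir = _draw_nonnegative(config.dist_ir, n, rng)
    hq = hazard_quotient(exposure_dose(c, p, ir=ir, bw=bw), p.rfd)
    hq = np.atleast_1d(hq)
    pct = {q: float(np.percentile(hq, q)) for q in (5, 25, 50, 75, 95)}
    degenerate = np.ptp(hq) == 0.0  # all draws identical: mean is exact
    return MCResult(
        mean_hq=float(hq[0]) if degenerate else float(np.mean(hq)),
        sd_hq=0.0 if degenerate else (float(np.std(hq, ddof=1)) if n > 1 else 0.0),
        percentiles=pct,
        p_exceed=float(np.mean(hq > 1.0)),
        iterations=n,
        seed=config.seed,
    )


def risk_report(
    samples: Sequence[WaterSample],
    params: Mapping[str, ExposureParams] = DEFAULT_EXPOSURE,
    nitrate_basis: str = "as_no3",
) -> pd.DataFrame:
    """Per sample x group table of dose, HQ and the acceptability flag."""
    rows = []
    factor = NO3_PER_N if nitrate_basis == "as_n" else 1.0
    for s in samples:
        for group, p in params.items():
            e = exposure_dose(s.no3 * factor, p)
            hq = hazard_quotient(e, p.rfd)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": group,
                    "dose": e,
                    "hq": hq,
                    "acceptable": hq <= 1.0,
                }
            )
    return pd.DataFrame(rows)
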