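"""Seeded generator of island-aquifer-like groundwater survey datasets.

The generator emulates a tropical-island groundwater campaign: a
HCO3-dominated, fresh, weakly alkaline system with right-skewed
major-ion concentrations, strong Na–Cl and Ca/Mg–HCO3 coupling, an
agricultural NO3–K association, and mixed well depths.

Construction: each analyte gets a moment-matched marginal (lognormal
for ions and TDS, truncated normal for pH) and dependence is imposed
through a Gaussian copula.  Because the targets are *sample*
statistics of a finite survey, the generator matches them as sample
statistics: the latent normals are empirically whitened and recolored
so their sample correlation is exact, marginal parameters are solved
against the realized draws, and a short fixed-point loop recalibrates
the pre-repair targets and latent correlations so that the dataset
*after* charge-balance repair still reproduces every requested mean,
SD and Pearson correlation.  Charge-balance repair brings |CBE| inside
the analytical acceptance band either by rescaling one balancing ion
(Na or Cl, the classical single-ion convention) or — the generator's
default — by scaling all cations by s and all anions by 1/s, which
preserves intra-class ion ratios and the dependence structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chemistry import (
    ANIONS,
    CATIONS,
    WaterSample,
    charge_balance_error,
    from_meq,
    to_meq,
)

__all__ = [
    "MarginalSpec",
    "SyntheticConfig",
    "default_config",
    "generate",
    "generate_frame",
    "cbe_repair",
    "validate",
    "ValidationReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarginalSpec:
    """Moment targets for one analyte's marginal distribution."""

    analyte: str
    family: str  # lognormal | truncated_normal | point
    target_mean: float
    target_sd: float = 0.0
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.target_sd < 0:
            raise ValueError(f"{self.analyte}: target SD must be >= 0")
        if self.lower >= self.upper:
            raise ValueError(f"{self.analyte}: empty truncation interval")


@dataclass(frozen=True)
class SyntheticConfig:
    """Targets, dependence structure and bookkeeping for one dataset."""

    n: int = 63
    seed: int = 20230726
    marginals: tuple[MarginalSpec, ...] = ()
    correlation_targets: tuple[tuple[str, str, float], ...] = ()
    cbe_repair: bool = True
    cbe_tolerance: float = 5.0
    repair_mode: str = "proportional"  # or "single_ion"
    depth_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # shallow/middle/deep
    depth_ranges: tuple[tuple[float, float], ...] = ((3.5, 20.0), (20.0, 50.0), (50.0, 340.0))
    ec_from_tds: float = 0.646  # EC = TDS / factor
    calibration_rounds: int = 10

    def marginal(self, analyte: str) -> MarginalSpec:
        for m in self.marginals:
            if m.analyte == analyte:
                return m
        raise KeyError(analyte)


# Field-survey moment targets for the default island aquifer system
# (mg/L except pH): right-skewed ions, pH truncated to the observed
# range, TDS supplied as its own marginal.
_DEFAULT_MARGINALS: tuple[MarginalSpec, ...] = (
    MarginalSpec("tds", "lognormal", 287.41, 216.13),
    MarginalSpec("ph", "truncated_normal", 7.47, 1.03, lower=5.11, upper=9.37),
    MarginalSpec("ca", "lognormal", 30.25, 26.41),
    MarginalSpec("mg", "lognormal", 11.28, 13.30),
    MarginalSpec("k", "lognormal", 13.16, 21.13),
    MarginalSpec("na", "lognormal", 30.30, 29.60),
    MarginalSpec("cl", "lognormal", 43.88, 55.99),
    MarginalSpec("so4", "lognormal", 29.39, 42.12),
    MarginalSpec("hco3", "lognormal", 111.29, 98.49),
    MarginalSpec("no3", "lognormal", 38.92, 51.52),
)

_DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("na", "cl", 0.92),
    ("ca", "hco3", 0.78),
    ("mg", "hco3", 0.70),
    ("no3", "k", 0.71),
)


def default_config(n: int = 63, seed: int = 20230726, cbe_repair: bool = True) -> SyntheticConfig:
    """The calibrated island-survey configuration."""
    return SyntheticConfig(
        n=n,
        seed=seed,
        marginals=_DEFAULT_MARGINALS,
        correlation_targets=_DEFAULT_CORRELATIONS,
        cbe_repair=cbe_repair,
    )


# ---------------------------------------------------------------------------
# marginal transforms (population-matched)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) giving a lognormal with the target moments."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _truncnorm_parent(spec: MarginalSpec, mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lower, upper]-truncation hits the targets.

    The truncated SD is bounded above by the uniform SD on the
    interval; an unreachable target raises naming the analyte.
    """
    lo, hi = spec.lower, spec.upper
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError(f"{spec.analyte}: truncated_normal needs finite bounds")
    sd_max = (hi - lo) / math.sqrt(12.0)
    if sd >= sd_max:
        raise ValueError(
            f"{spec.analyte}: target SD {sd} infeasible under truncation "
            f"to [{lo}, {hi}] (uniform limit {sd_max:.3f})"
        )

    def resid(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    sol = optimize.root(resid, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise ValueError(f"{spec.analyte}: truncated-normal moment match failed")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _transform_population(spec: MarginalSpec, mean: float, sd: float) -> Callable[[np.ndarray], np.ndarray]:
    """Map standard-normal latent draws to the analyte's marginal
    (population moments equal the targets)."""
    if spec.family == "point" or sd == 0:
        return lambda z: np.full_like(z, mean, dtype=float)
    if spec.family == "lognormal":
        if (np.isfinite(spec.lower) and spec.lower > 0) or np.isfinite(spec.upper):
            raise ValueError(f"{spec.analyte}: truncation is not supported for lognormal")
        mu, sigma = _lognormal_params(mean, sd)
        return lambda z: np.exp(mu + sigma * z)
    if spec.family == "truncated_normal":
        mu, sigma = _truncnorm_parent(spec, mean, sd)
        a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma

        def transform(z: np.ndarray) -> np.ndarray:
            return stats.truncnorm.ppf(stats.norm.cdf(z), a, b, loc=mu, scale=sigma)

        return transform
    raise ValueError(f"{spec.analyte}: unknown family {spec.family!r}")


def _column_sample_matched(spec: MarginalSpec, z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Transform one latent column so the realized *sample* mean and SD
    equal the targets exactly (the targets are survey sample statistics)."""
    if spec.family == "point" or sd == 0:
        return np.full_like(z, mean, dtype=float)
    if spec.family == "lognormal":
        cv = sd / mean

        def f(s: float) -> float:
            x = np.exp(s * z)
            return float(np.std(x, ddof=1) / np.mean(x)) - cv

        s = optimize.brentq(f, 1e-8, 8.0)
        x = np.exp(s * z)
        return x * (mean / np.mean(x))
    if spec.family == "truncated_normal":
        u = stats.norm.cdf(z)
        mu0, sig0 = _truncnorm_parent(spec, mean, sd)

        def resid(x: np.ndarray) -> np.ndarray:
            mu, log_sigma = x
            sigma = math.exp(log_sigma)
            a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma
            v = stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
            return np.array([np.mean(v) - mean, np.std(v, ddof=1) - sd])

        sol = optimize.root(resid, x0=[mu0, math.log(sig0)], method="hybr")
        mu, sigma = (sol.x[0], math.exp(sol.x[1])) if sol.success else (mu0, sig0)
        a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma
        return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
    raise ValueError(f"{spec.analyte}: unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# latent correlation


def _latent_rho_lognormal(s1: float, s2: float, r_target: float) -> float:
    """Exact latent correlation for a lognormal pair.

    For X_i = exp(mu_i + s_i Z_i) with corr(Z1, Z2) = rho, Pearson r is
    (exp(rho s1 s2) - 1)/sqrt((exp(s1^2)-1)(exp(s2^2)-1)); inverting
    gives rho in closed form.
    """
    denom = math.sqrt(math.expm1(s1**2) * math.expm1(s2**2))
    arg = 1.0 + r_target * denom
    if arg <= 0:
        raise ValueError(f"Pearson target {r_target} infeasible for lognormal margins")
    rho = math.log(arg) / (s1 * s2)
    if abs(rho) > 1.0:
        raise ValueError(f"Pearson target {r_target} requires |latent rho| > 1")
    return rho


_GH_NODES = 48


def _pearson_given_rho(f1: Callable, f2: Callable, rho: float) -> float:
    """Population Pearson r under latent correlation rho, by
    Gauss-Hermite quadrature on the bivariate normal."""
    x, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    w = w / math.sqrt(2.0 * math.pi)
    z1, z2 = np.repeat(x, _GH_NODES), np.tile(x, _GH_NODES)
    ww = np.repeat(w, _GH_NODES) * np.tile(w, _GH_NODES)
    y1 = f1(z1)
    y2 = f2(rho * z1 + math.sqrt(max(1.0 - rho**2, 0.0)) * z2)
    m1, m2 = ww @ y1, ww @ y2
    v1, v2 = ww @ (y1 - m1) ** 2, ww @ (y2 - m2) ** 2
    cov = ww @ ((y1 - m1) * (y2 - m2))
    return float(cov / math.sqrt(v1 * v2))


def _initial_latent_rho(spec1: MarginalSpec, spec2: MarginalSpec, r_target: float,
                        max_iter: int = 8) -> float:
    """Population-level latent rho for a pair (closed form for
    lognormals, secant on the quadrature map otherwise)."""
    if spec1.family == "lognormal" and spec2.family == "lognormal":
        s1 = _lognormal_params(spec1.target_mean, spec1.target_sd)[1]
        s2 = _lognormal_params(spec2.target_mean, spec2.target_sd)[1]
        return _latent_rho_lognormal(s1, s2, r_target)
    f1 = _transform_population(spec1, spec1.target_mean, spec1.target_sd)
    f2 = _transform_population(spec2, spec2.target_mean, spec2.target_sd)
    rho = float(np.clip(r_target, -0.99, 0.99))
    prev: tuple[float, float] | None = None
    for _ in range(max_iter):
        r_now = _pearson_given_rho(f1, f2, rho)
        if abs(r_now - r_target) < 1e-6:
            break
        if prev is None or r_now == prev[1]:
            step = r_target - r_now
        else:
            step = (r_target - r_now) * (rho - prev[0]) / (r_now - prev[1])
        prev = (rho, r_now)
        rho = float(np.clip(rho + step, -0.999, 0.999))
    return rho


def _nearest_psd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped nearest correlation matrix (unit diagonal)."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr
    logger.info("correlation matrix repaired: min eigenvalue %.3g clipped", vals.min())
    vals = np.clip(vals, eps, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _constrained_psd(
    corr: np.ndarray,
    fixed: np.ndarray,
    eps: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Positive-definite completion holding the ``fixed`` entries.

    Requested pairs can be jointly infeasible when every unspecified
    correlation is pinned at zero (e.g. one analyte strongly tied to
    two mutually-uncorrelated partners), so the unspecified entries are
    free: alternate eigenvalue clipping with re-imposing the fixed
    entries until the matrix is PSD with the targets intact.
    """
    target = corr.copy()
    out = corr.copy()
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() >= eps:
            return out
        vals = np.clip(vals, eps, None)
        out = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out[fixed] = target[fixed]
        np.fill_diagonal(out, 1.0)
    # the alternation can hover just below the eigenvalue floor; finish
    # with a plain clip — the tiny drift in the fixed entries is absorbed
    # by the caller's calibration loop
    logger.debug("constrained PSD completion finished by final clipping")
    return _nearest_psd(out)


# ---------------------------------------------------------------------------
# charge-balance repair

_BALANCE_IONS = ("na", "cl")
#: repaired samples are placed just inside the band so they survive
#: a subsequent |CBE| <= tolerance check despite rounding
_EDGE_SHRINK = 0.999


def cbe_repair(
    sample: WaterSample,
    tolerance: float = 5.0,
    balance_ions: Sequence[str] = _BALANCE_IONS,
) -> WaterSample:
    """Minimally rescale one balancing ion so |CBE| <= ``tolerance`` %.

    The candidate (Na or Cl by default) needing the smaller relative
    change is moved just inside the tolerance edge; every other analyte
    is untouched.  If no nonnegative adjustment attains the band the
    sample is returned unchanged with a warning (flagged, not dropped).
    """
    cbe = charge_balance_error(sample)
    if abs(cbe) <= tolerance:
        return sample
    t = math.copysign(_EDGE_SHRINK * tolerance / 100.0, cbe)

    cat_meq = {i: sample.meq(i) for i in CATIONS}
    an_meq = {i: sample.meq(i) for i in ANIONS}
    candidates: list[tuple[float, str, float]] = []
    for ion in balance_ions:
        if ion in CATIONS:
            others = sum(v for key, v in cat_meq.items() if key != ion)
            # (others + x - anions) = t (others + x + anions)
            new_meq = sum(an_meq.values()) * (1 + t) / (1 - t) - others
        else:
            others = sum(v for key, v in an_meq.items() if key != ion)
            # (cations - others - y) = t (cations + others + y)
            new_meq = sum(cat_meq.values()) * (1 - t) / (1 + t) - others
        if new_meq < 0:
            continue
        old_meq = sample.meq(ion)
        change = abs(new_meq - old_meq) / old_meq if old_meq > 0 else abs(new_meq)
        candidates.append((change, ion, new_meq))

    if not candidates:
        logger.warning("%s: CBE %.2f%% not repairable within nonnegativity", sample.sample_id, cbe)
        return sample
    _, ion, new_meq = min(candidates)
    return replace(sample, **{ion: float(from_meq(new_meq, ion))})


def _repair_frame(df: pd.DataFrame, tolerance: float, mode: str) -> pd.DataFrame:
    """Vectorized repair of a generated table; returns a copy."""
    df = df.copy()
    ion_cols = [c for c in (*CATIONS, *ANIONS) if c in df.columns]
    cat = sum(to_meq(df[i].to_numpy(), i) for i in CATIONS if i in df.columns)
    an = sum(to_meq(df[i].to_numpy(), i) for i in ANIONS if i in df.columns)
    total = cat + an
    with np.errstate(invalid="ignore", divide="ignore"):
        cbe = np.where(total > 0, 100.0 * (cat - an) / total, 0.0)
    bad = np.abs(cbe) > tolerance
    if not bad.any():
        return df
    t = np.sign(cbe) * _EDGE_SHRINK * tolerance / 100.0

    if mode == "proportional":
        # cations *= s, anions /= s closes the gap while preserving
        # intra-class ratios: s^2 = anions(1+t) / (cations(1-t))
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.sqrt(an * (1 + t) / (cat * (1 - t)))
        s = np.where(bad & np.isfinite(s) & (s > 0), s, 1.0)
        for i in ion_cols:
            df[i] = df[i].to_numpy() * (s if i in CATIONS else 1.0 / s)
        return df
    if mode == "single_ion":
        na = to_meq(df["na"].to_numpy(), "na")
        cl = to_meq(df["cl"].to_numpy(), "cl")
        new_na = an * (1 + t) / (1 - t) - (cat - na)
        new_cl = cat * (1 - t) / (1 + t) - (an - cl)
        with np.errstate(invalid="ignore", divide="ignore"):
            ch_na = np.where(new_na >= 0, np.abs(new_na - na) / np.maximum(na, 1e-300), np.inf)
            ch_cl = np.where(new_cl >= 0, np.abs(new_cl - cl) / np.maximum(cl, 1e-300), np.inf)
        use_na = bad & (ch_na <= ch_cl) & np.isfinite(ch_na)
        use_cl = bad & ~use_na & np.isfinite(ch_cl)
        na_out, cl_out = df["na"].to_numpy().copy(), df["cl"].to_numpy().copy()
        na_out[use_na] = from_meq(new_na[use_na], "na")
        cl_out[use_cl] = from_meq(new_cl[use_cl], "cl")
        df["na"], df["cl"] = na_out, cl_out
        return df
    raise ValueError(f"unknown repair mode {mode!r}")


# ---------------------------------------------------------------------------
# generation

#: below this sample count the generator uses plain population
#: moment matching (sample statistics are too noisy to pin down)
_MIN_CALIBRATION_N = 30


def generate_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the dataset as a DataFrame with the standard schema.

    Deterministic for a given config (seed included); the returned
    table carries sample_id, depth_m, ph, tds, ec, the ions and co3.
    """
    if config.n < 0:
        raise ValueError("n must be >= 0")
    analytes = [m.analyte for m in config.marginals]
    if config.n == 0 or not analytes:
        return pd.DataFrame(
            columns=["sample_id", "depth_m", "ph", "tds", "ec", *CATIONS, *ANIONS]
        )
    for a1, a2, _ in config.correlation_targets:
        for a in (a1, a2):
            if config.marginal(a).target_sd == 0 or config.marginal(a).family == "point":
                raise ValueError(f"correlation target on degenerate analyte {a!r}")

    k = len(analytes)
    rng = np.random.default_rng(config.seed)
    z_raw = rng.standard_normal((config.n, k))

    calibrate = config.n >= max(_MIN_CALIBRATION_N, k + 2)
    if calibrate:
        # empirical whitening: latent columns get exactly zero mean, unit
        # variance and exactly the requested latent sample correlation
        z_std = (z_raw - z_raw.mean(axis=0)) / z_raw.std(axis=0)
        chol_emp = np.linalg.cholesky(np.atleast_2d(np.cov(z_std.T, bias=True)))
        z_base = np.linalg.solve(chol_emp, z_std.T).T
    else:
        z_base = z_raw

    latent = np.eye(k)
    fixed = np.zeros((k, k), dtype=bool)
    for a1, a2, r_target in config.correlation_targets:
        i, j = analytes.index(a1), analytes.index(a2)
        rho = _initial_latent_rho(config.marginal(a1), config.marginal(a2), r_target)
        latent[i, j] = latent[j, i] = rho
        fixed[i, j] = fixed[j, i] = True
    latent = _constrained_psd(latent, fixed)

    # fixed-point calibration: adjust pre-repair moment targets and the
    # latent correlations until the post-repair dataset matches.
    mean_adj = {a: 1.0 for a in analytes}
    sd_adj = {a: 1.0 for a in analytes}
    pair_state: dict[tuple[str, str], tuple[float, float] | None] = {
        (a1, a2): None for a1, a2, _ in config.correlation_targets
    }
    rounds = config.calibration_rounds if (calibrate and config.cbe_repair) else 1

    df = pd.DataFrame()
    for round_idx in range(max(rounds, 1)):
        z_lat = z_base @ np.linalg.cholesky(latent).T
        cols = {}
        for idx, m in enumerate(config.marginals):
            mean = m.target_mean * mean_adj[m.analyte]
            sd = m.target_sd * sd_adj[m.analyte]
            if calibrate:
                cols[m.analyte] = _column_sample_matched(m, z_lat[:, idx], mean, sd)
            else:
                cols[m.analyte] = _transform_population(m, mean, sd)(z_lat[:, idx])
        df = pd.DataFrame(cols)
        if "co3" not in df.columns:
            df["co3"] = 0.0
        if config.cbe_repair:
            df = _repair_frame(df, config.cbe_tolerance, config.repair_mode)
        if not (calibrate and config.cbe_repair) or round_idx == rounds - 1:
            break

        converged = True
        for m in config.marginals:
            if m.target_sd == 0:
                continue
            x = df[m.analyte].to_numpy()
            mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
            if abs(mean / m.target_mean - 1) > 0.005:
                mean_adj[m.analyte] *= m.target_mean / mean
                converged = False
            if abs(sd / m.target_sd - 1) > 0.01:
                sd_adj[m.analyte] *= m.target_sd / sd
                converged = False
        for a1, a2, r_target in config.correlation_targets:
            i, j = analytes.index(a1), analytes.index(a2)
            r_now = float(np.corrcoef(df[a1], df[a2])[0, 1])
            if abs(r_now - r_target) > 0.005:
                prev = pair_state[(a1, a2)]
                if prev is None or abs(r_now - prev[1]) < 1e-12:
                    step = 0.8 * (r_target - r_now)
                else:
                    step = (r_target - r_now) * (latent[i, j] - prev[0]) / (r_now - prev[1])
                pair_state[(a1, a2)] = (latent[i, j], r_now)
                rho = float(np.clip(latent[i, j] + step, -0.999, 0.999))
                latent[i, j] = latent[j, i] = rho
                converged = False
        if converged:
            break
        latent = _constrained_psd(latent, fixed)

    # depth classes, then a uniform depth within each class band
    mix = np.asarray(config.depth_mix, dtype=float)
    mix = mix / mix.sum()
    cls = rng.choice(3, size=config.n, p=mix)
    lo = np.array([r[0] for r in config.depth_ranges])
    hi = np.array([r[1] for r in config.depth_ranges])
    df["depth_m"] = rng.uniform(lo[cls], hi[cls])

    if "tds" not in df.columns:
        ion_cols = [c for c in df.columns if c in (*CATIONS, *ANIONS)]
        df["tds"] = 0.9 * df[ion_cols].sum(axis=1) * rng.lognormal(0.0, 0.02, size=config.n)
    df["ec"] = df["tds"] / config.ec_from_tds
    df.insert(0, "sample_id", [f"SYN-{i + 1:05d}" for i in range(config.n)])
    front = ["sample_id", "depth_m", "ph", "tds", "ec"]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest]


def generate(config: SyntheticConfig) -> list[WaterSample]:
    """Generate ``config.n`` synthetic samples (seeded, reproducible)."""
    df = generate_frame(config)
    if not len(df):
        return []
    from .chemistry import frame_to_samples

    return frame_to_samples(df)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationReport:
    marginals: pd.DataFrame  # analyte, target/achieved mean & sd, pass flags
    correlations: pd.DataFrame  # pair, target r, achieved r, pass flag
    cbe_pass_fraction: float
    passed: bool


def validate(
    dataset: Sequence[WaterSample] | pd.DataFrame,
    config: SyntheticConfig,
    mean_rtol: float = 0.03,
    sd_rtol: float = 0.05,
    corr_atol: float = 0.05,
    cbe_tolerance: float = 5.0,
) -> ValidationReport:
    """Recovery report: achieved vs target moments and correlations.

    Default tolerances are relative 3% on means, 5% on SDs and absolute
    0.05 on Pearson correlations — the generator's large-n contract.
    """
    from .chemistry import samples_to_frame

    if not isinstance(dataset, pd.DataFrame):
        dataset = samples_to_frame(dataset)
    if len(dataset) == 0:
        raise ValueError("empty dataset cannot be validated")

    rows = []
    for m in config.marginals:
        x = dataset[m.analyte].to_numpy(dtype=float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        mean_ok = abs(mean - m.target_mean) <= mean_rtol * abs(m.target_mean)
        sd_ok = abs(sd - m.target_sd) <= sd_rtol * abs(m.target_sd) if m.target_sd > 0 else sd == 0.0
        rows.append(
            {
                "analyte": m.analyte,
                "target_mean": m.target_mean,
                "achieved_mean": mean,
                "mean_ok": mean_ok,
                "target_sd": m.target_sd,
                "achieved_sd": sd,
                "sd_ok": sd_ok,
            }
        )
    marg = pd.DataFrame(rows)

    crows = []
    for a1, a2, r_target in config.correlation_targets:
        r = float(np.corrcoef(dataset[a1], dataset[a2])[0, 1]) if len(dataset) > 2 else np.nan
        crows.append(
            {
                "pair": f"{a1}-{a2}",
                "target_r": r_target,
                "achieved_r": r,
                "r_ok": bool(np.isfinite(r) and abs(r - r_target) <= corr_atol),
            }
        )
    corr = pd.DataFrame(crows)

    cat = sum(to_meq(dataset[i].to_numpy(dtype=float), i) for i in CATIONS if i in dataset)
    an = sum(to_meq(dataset[i].to_numpy(dtype=float), i) for i in ANIONS if i in dataset)
    total = cat + an
    with np.errstate(invalid="ignore", divide="ignore"):
        cbe = np.where(total > 0, 100.0 * (cat - an) / total, 0.0)
    cbe_frac = float(np.mean(np.abs(cbe) <= cbe_tolerance))

    passed = bool(
        marg["mean_ok"].all()
        and marg["sd_ok"].all()
        and (corr["r_ok"].all() if len(corr) else True)
        and (cbe_frac >= 0.99 if config.cbe_repair else True)
    )
    return ValidationReport(
        marginals=marg, correlations=corr, cbe_pass_fraction=cbe_frac, passed=passed
    )
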