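"""Hydrochemical facies classification and source-attribution diagnostics.

Implements the classical graphical/ratio toolkit for attributing the
origin of dissolved ions in groundwater: Piper trilinear coordinates,
Shchukarev facies naming, Gibbs mechanism ratios, weathering endmember
ratios, chloro-alkaline (cation exchange) indices, anthropogenic-input
ratios and a Pearson correlation screen.  All ratios are computed on
meq/L unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemistry import WaterSample, samples_to_frame

__all__ = [
    "PiperPoint",
    "RatioDiagnostics",
    "CAIResult",
    "piper_coordinates",
    "shchukarev_classify",
    "gibbs_classify",
    "ratio_diagnostics",
    "cation_exchange_slope",
    "cai_indices",
    "pearson_matrix",
    "nitrate_exceedance",
    "facies_report",
]

_SQRT3_2 = math.sqrt(3.0) / 2.0
#: horizontal gap between the cation and anion ternary triangles (unit edge)
_TRIANGLE_OFFSET = 1.2


@dataclass(frozen=True)
class PiperPoint:
    """Piper ternary fractions (% of meq) and projected diamond point.

    ``cation_fractions`` orders (Ca, Mg, Na+K); ``anion_fractions``
    orders (HCO3+CO3, SO4, Cl).  Each triple sums to 100.
    """

    cation_fractions: tuple[float, float, float]
    anion_fractions: tuple[float, float, float]
    cation_xy: tuple[float, float]
    anion_xy: tuple[float, float]
    diamond_xy: tuple[float, float]


@dataclass(frozen=True)
class RatioDiagnostics:
    """Per-sample diagnostic ratios on meq/L; NaN marks an undefined ratio."""

    gibbs_cation: float  # Na/(Na+Ca)
    gibbs_anion: float  # Cl/(Cl+HCO3)
    mg_na: float
    ca_na: float
    hco3_na: float
    carb_index: float  # (Ca+Mg)/HCO3
    evap_index: float  # (Cl+SO4)/HCO3
    exch_x: float  # Na+K-Cl
    exch_y: float  # Mg+Ca-SO4-HCO3
    cl_na: float
    no3_na: float

    @property
    def carb_label(self) -> str:
        if math.isnan(self.carb_index):
            return "undefined"
        if self.carb_index > 1:
            return "carbonate_dominant"
        if self.carb_index < 1:
            return "silicate_evaporite_dominant"
        return "boundary"


@dataclass(frozen=True)
class CAIResult:
    """Chloro-alkaline indices.  Negative values: Ca/Mg in water traded
    for Na/K on the aquifer matrix (forward exchange); positive: reverse."""

    cai_1: float
    cai_2: float
    direction: str  # forward_exchange / reverse_exchange / none


def _ternary_xy(left: float, right: float, top: float, x0: float = 0.0) -> tuple[float, float]:
    """Barycentric (fractions of 1) to planar xy on a unit triangle at x0."""
    total = left + right + top
    r, t = right / total, top / total
    return (x0 + r + 0.5 * t, _SQRT3_2 * t)


def piper_coordinates(sample: WaterSample) -> PiperPoint:
    """Piper trilinear coordinates for one sample.

    Cation triangle: Ca (left vertex), Na+K (right), Mg (top).  Anion
    triangle: HCO3+CO3 (left), Cl (right), SO4 (top).  The diamond
    point is the intersection of the 60-degree projection rays from the
    two ternary points, per the standard construction.
    """
    cat = {i: sample.meq(i) for i in ("ca", "mg", "na", "k")}
    an = {i: sample.meq(i) for i in ("hco3", "co3", "so4", "cl")}
    cat_total = sum(cat.values())
    an_total = sum(an.values())
    if cat_total <= 0 or an_total <= 0:
        raise ValueError(f"{sample.sample_id}: zero ionic strength; Piper point undefined")

    ca_f = 100.0 * cat["ca"] / cat_total
    mg_f = 100.0 * cat["mg"] / cat_total
    nak_f = 100.0 * (cat["na"] + cat["k"]) / cat_total
    alk_f = 100.0 * (an["hco3"] + an["co3"]) / an_total
    so4_f = 100.0 * an["so4"] / an_total
    cl_f = 100.0 * an["cl"] / an_total

    p_cat = _ternary_xy(ca_f, nak_f, mg_f)
    p_an = _ternary_xy(alk_f, cl_f, so4_f, x0=_TRIANGLE_OFFSET)

    # Rays: from the cation point at +60 deg, from the anion point at +120 deg.
    # Solve p_cat + t*(0.5, s) = p_an + u*(-0.5, s) with s = sqrt(3)/2.
    t = (p_an[0] - p_cat[0]) + (p_an[1] - p_cat[1]) / (2.0 * _SQRT3_2)
    diamond = (p_cat[0] + 0.5 * t, p_cat[1] + _SQRT3_2 * t)

    return PiperPoint(
        cation_fractions=(ca_f, mg_f, nak_f),
        anion_fractions=(alk_f, so4_f, cl_f),
        cation_xy=p_cat,
        anion_xy=p_an,
        diamond_xy=diamond,
    )


_SHCHUKAREV_ANIONS = (("HCO3", ("hco3", "co3")), ("Cl", ("cl",)), ("SO4", ("so4",)))
_SHCHUKAREV_CATIONS = (("Na", ("na", "k")), ("Ca", ("ca",)), ("Mg", ("mg",)))


def shchukarev_classify(sample: WaterSample, threshold: float = 25.0) -> str:
    """Facies label from ions holding >= ``threshold`` % of their class meq.

    Classical Shchukarev typing over the three major anions (CO3
    grouped with HCO3) and three major cations (K grouped with Na):
    qualifying anions first, then cations, each ordered by decreasing
    meq fraction and joined with en-dashes, e.g. ``"HCO3–Cl–Na"``.
    """
    parts: list[str] = []
    for groups in (_SHCHUKAREV_ANIONS, _SHCHUKAREV_CATIONS):
        totals = {label: sum(sample.meq(i) for i in ions) for label, ions in groups}
        class_total = sum(totals.values())
        if class_total <= 0:
            raise ValueError(f"{sample.sample_id}: zero meq total; facies undefined")
        fracs = {label: 100.0 * v / class_total for label, v in totals.items()}
        keep = sorted(
            (label for label, f in fracs.items() if f >= threshold),
            key=lambda label: -fracs[label],
        )
        parts.extend(keep)
    return "–".join(parts)


#: Gibbs mechanism regions as (tds_lo, tds_hi, ratio_lo, ratio_hi) boxes;
#: heuristic defaults — the classical figure draws the envelopes by eye.
GIBBS_REGIONS: dict[str, tuple[float, float, float, float]] = {
    "rock_dominance": (70.0, 1000.0, 0.0, 0.7),
    "precipitation_dominance": (0.0, 70.0, 0.5, 1.0),
    "evaporation_dominance": (1000.0, math.inf, 0.5, 1.0),
}


def gibbs_classify(
    sample: WaterSample,
    which: str = "cation",
    regions: dict[str, tuple[float, float, float, float]] | None = None,
) -> str:
    """Assign a Gibbs mechanism region from (weight ratio, TDS).

    ``which`` selects the cation ratio Na/(Na+Ca) or the anion ratio
    Cl/(Cl+HCO3).  Points outside every region (commonly
    anthropogenically disturbed samples) return ``"outside"``.
    """
    d = ratio_diagnostics(sample)
    ratio = d.gibbs_cation if which == "cation" else d.gibbs_anion
    if math.isnan(ratio) or sample.tds <= 0:
        raise ValueError(f"{sample.sample_id}: Gibbs ratio or TDS undefined")
    for name, (t_lo, t_hi, r_lo, r_hi) in (regions or GIBBS_REGIONS).items():
        if t_lo <= sample.tds <= t_hi and r_lo <= ratio <= r_hi:
            return name
    return "outside"


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def ratio_diagnostics(sample: WaterSample) -> RatioDiagnostics:
    """All source-attribution ratios for one sample, on meq/L."""
    na, k, ca, mg = (sample.meq(i) for i in ("na", "k", "ca", "mg"))
    cl, so4, hco3, no3 = (sample.meq(i) for i in ("cl", "so4", "hco3", "no3"))
    return RatioDiagnostics(
        gibbs_cation=_ratio(na, na + ca),
        gibbs_anion=_ratio(cl, cl + hco3),
        mg_na=_ratio(mg, na),
        ca_na=_ratio(ca, na),
        hco3_na=_ratio(hco3, na),
        carb_index=_ratio(ca + mg, hco3),
        evap_index=_ratio(cl + so4, hco3),
        exch_x=na + k - cl,
        exch_y=mg + ca - so4 - hco3,
        cl_na=_ratio(cl, na),
        no3_na=_ratio(no3, na),
    )


def cation_exchange_slope(samples: Sequence[WaterSample]) -> tuple[float, float]:
    """OLS slope and intercept of (Mg+Ca−SO4−HCO3) on (Na+K−Cl), meq/L.

    A slope near −1 is the signature of alternate cation adsorption:
    every equivalent of Na+K gained balances an equivalent of Ca+Mg
    lost.  Requires >= 3 samples and nondegenerate x variance.
    """
    pts = [ratio_diagnostics(s) for s in samples]
    x = np.array([p.exch_x for p in pts], dtype=float)
    y = np.array([p.exch_y for p in pts], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 samples with defined exchange coordinates")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x variance; exchange slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def cai_indices(sample: WaterSample) -> CAIResult:
    """Schoeller chloro-alkaline indices CAI-I and CAI-II (meq/L).

    CAI-I  = [Cl − (Na+K)] / Cl
    CAI-II = [Cl − (Na+K)] / (SO4 + HCO3 + CO3 + NO3)

    Both positive: reverse exchange (water gains Ca/Mg); both negative:
    forward exchange (water gains Na/K).  Undefined denominators give NaN.
    """
    cl = sample.meq("cl")
    nak = sample.meq("na") + sample.meq("k")
    denom2 = sum(sample.meq(i) for i in ("so4", "hco3", "co3", "no3"))
    num = cl - nak
    if abs(num) <= 1e-12 * max(cl, nak, 1e-300):  # balanced to rounding
        num = 0.0
    cai_1 = num / cl if cl > 0 else float("nan")
    cai_2 = num / denom2 if denom2 > 0 else float("nan")
    if num > 0:
        direction = "reverse_exchange"
    elif num < 0:
        direction = "forward_exchange"
    else:
        direction = "none"
    if math.isnan(cai_1) and math.isnan(cai_2):
        direction = "none"
    return CAIResult(cai_1=cai_1, cai_2=cai_2, direction=direction)


def pearson_matrix(
    data: pd.DataFrame | Sequence[WaterSample],
    variables: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p-values and significance stars.

    Returns (r, p, stars) DataFrames.  p-values come from the t
    transform of r with n−2 degrees of freedom; stars mark p < 0.10
    (*), p < 0.05 (**) and p < 0.01 (***).  Zero-variance variables
    yield NaN for their pairs.
    """
    if not isinstance(data, pd.DataFrame):
        data = samples_to_frame(data)
    if variables is None:
        variables = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    df = data[list(variables)].astype(float)
    n = len(df)
    if n < 3:
        raise ValueError("Pearson screen needs at least 3 samples")

    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xi, xj = df.iloc[:, i].to_numpy(), df.iloc[:, j].to_numpy()
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue

    def star(pv: float) -> str:
        if not np.isfinite(pv):
            return ""
        if pv < 0.01:
            return "***"
        if pv < 0.05:
            return "**"
        if pv < 0.10:
            return "*"
        return ""

    stars = pd.DataFrame(
        [[star(p[i, j]) for j in range(k)] for i in range(k)],
        index=variables,
        columns=variables,
    )
    return (
        pd.DataFrame(r, index=variables, columns=variables),
        pd.DataFrame(p, index=variables, columns=variables),
        stars,
    )


def nitrate_exceedance(
    samples: Iterable[WaterSample], threshold: float = 20.0
) -> tuple[int, float]:
    """Count and percentage of samples with NO3 strictly above ``threshold``.

    The default 20 mg/L is the Chinese class-III groundwater nitrate
    limit.  Percentage is rounded to 2 decimals.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = [s.no3 for s in samples]
    if not values:
        return 0, 0.0
    count = sum(v > threshold for v in values)
    return count, round(100.0 * count / len(values), 2)


def facies_report(samples: Sequence[WaterSample]) -> pd.DataFrame:
    """Per-sample facies table: Piper fractions, label, ratios, CAI."""
    rows = []
    for s in samples:
        pp = piper_coordinates(s)
        d = ratio_diagnostics(s)
        cai = cai_indices(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "pct_ca": pp.cation_fractions[0],
                "pct_mg": pp.cation_fractions[1],
                "pct_na_k": pp.cation_fractions[2],
                "pct_hco3_co3": pp.anion_fractions[0],
                "pct_so4": pp.anion_fractions[1],
                "pct_cl": pp.anion_fractions[2],
                "facies": shchukarev_classify(s),
                "gibbs_region": gibbs_classify(s),
                "gibbs_cation": d.gibbs_cation,
                "gibbs_anion": d.gibbs_anion,
                "mg_na": d.mg_na,
                "ca_na": d.ca_na,
                "hco3_na": d.hco3_na,
                "carb_index": d.carb_index,
                "evap_index": d.evap_index,
                "exch_x": d.exch_x,
                "exch_y": d.exch_y,
                "cl_na": d.cl_na,
                "no3_na": d.no3_na,
                "cai_1": cai.cai_1,
                "cai_2": cai.cai_2,
                "exchange_direction": cai.direction,
            }
        )
    return pd.DataFrame(rows)
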