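"""Drinking-water quality index (WQI) and irrigation-suitability indices.

The WQI aggregates per-parameter concentration-to-standard ratios into
one score::

    W_i  = w_i / sum(w_j)                  (relative weight)
    WQI  = sum(W_i * (C_i / S_i) * 100)
    EW_i = W_i * (C_i / S_i) / WQI * 100   (effective weight, %)

Irrigation suitability uses the sodium adsorption ratio
SAR = Na / sqrt((Ca + Mg) / 2), the soluble sodium percentage
%Na = 100 * (Na + K) / (Na + K + Ca + Mg) and the residual sodium
carbonate RSC = (CO3 + HCO3) - (Ca + Mg), all on meq/L, plus the
Wilcox (EC vs %Na) and USSL (EC vs SAR) classifications.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .chemistry import WaterSample

__all__ = [
    "WeightTable",
    "WQIResult",
    "IrrigationIndices",
    "DEFAULT_WEIGHT_TABLE",
    "relative_weights",
    "wqi",
    "classify_wqi",
    "sar",
    "percent_na",
    "rsc",
    "classify_sar",
    "classify_percent_na",
    "wilcox_classify",
    "ussl_classify",
    "irrigation_indices",
    "quality_report",
    "DEFAULT_WILCOX_POLYGONS",
]

logger = logging.getLogger(__name__)

#: EC estimated from TDS when not measured (typical freshwater factor)
TDS_TO_EC_FACTOR = 0.64


@dataclass(frozen=True)
class WeightTable:
    """Per-parameter WQI weights w_i and permissible standards S_i.

    ``ph_standard_mode`` controls how pH enters the score: with
    ``"deviation"`` the rating is |pH - 7| / (S_pH - 7), so neutral
    water contributes nothing and the rating reaches 1 at the
    permissible bound; ``"ratio"`` uses the plain C/S ratio.
    """

    weights: Mapping[str, float]
    standards: Mapping[str, float]
    ph_standard_mode: str = "deviation"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("weight table is empty")
        if set(self.weights) != set(self.standards):
            raise ValueError("weights and standards must cover the same parameters")
        for k, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"nonpositive weight for {k}")
        for k, s in self.standards.items():
            if s <= 0:
                raise ValueError(f"nonpositive standard for {k}")


# Standards follow the Chinese class-III groundwater limits (GB/T
# 14848-2017) where the standard defines one (pH upper bound 8.5, TDS
# 1000, TH 450, Na 200, Cl 250, SO4 250, NO3 20 as reported) and common
# drinking-water guideline values for the rest (Ca 75, Mg 50, K 12,
# HCO3 250).  Weights put nitrate and pH first, the salinity/hardness
# block next and the geogenic majors last.
DEFAULT_WEIGHT_TABLE = WeightTable(
    weights={
        "ph": 4, "tds": 4, "th": 3, "ca": 3, "mg": 3, "na": 3,
        "k": 2, "cl": 4, "so4": 4, "hco3": 2, "no3": 5,
    },
    standards={
        "ph": 8.5, "tds": 1000.0, "th": 450.0, "ca": 75.0, "mg": 50.0,
        "na": 200.0, "k": 12.0, "cl": 250.0, "so4": 250.0,
        "hco3": 250.0, "no3": 20.0,
    },
)


@dataclass(frozen=True)
class WQIResult:
    wqi: float
    effective_weights: Mapping[str, float]  # percent, sums to 100
    wqi_class: str


@dataclass(frozen=True)
class IrrigationIndices:
    sample_id: str
    sar: float
    percent_na: float
    rsc: float
    sar_band: str
    na_band: str
    wilcox_class: str
    ussl_class: str
    ec_estimated: bool = False


def relative_weights(table: WeightTable) -> dict[str, float]:
    """W_i = w_i / sum(w_j); sums to 1 by construction."""
    total = sum(table.weights.values())
    return {k: w / total for k, w in table.weights.items()}


def _rating(sample: WaterSample, param: str, table: WeightTable) -> float | None:
    """C_i/S_i for one parameter; None when not measurable on the sample."""
    from .chemistry import total_hardness

    s_i = table.standards[param]
    if param == "ph":
        if table.ph_standard_mode == "deviation":
            return abs(sample.ph - 7.0) / (s_i - 7.0)
        return sample.ph / s_i
    if param == "th":
        return total_hardness(sample.ca, sample.mg) / s_i
    value = getattr(sample, param, None)
    if value is None:
        return None
    return value / s_i


def wqi(sample: WaterSample, table: WeightTable = DEFAULT_WEIGHT_TABLE) -> WQIResult:
    """Water quality index with per-parameter effective weights.

    Parameters absent from the sample are excluded and the remaining
    relative weights renormalized (logged).  Raises if nothing is
    measurable.
    """
    ratings: dict[str, float] = {}
    for param in table.weights:
        r = _rating(sample, param, table)
        if r is None:
            logger.info("%s: parameter %s missing; weight renormalized", sample.sample_id, param)
            continue
        ratings[param] = r
    if not ratings:
        raise ValueError(f"{sample.sample_id}: no WQI parameter measurable")

    w_total = sum(table.weights[p] for p in ratings)
    rel = {p: table.weights[p] / w_total for p in ratings}
    contributions = {p: rel[p] * ratings[p] * 100.0 for p in ratings}
    score = sum(contributions.values())
    if score > 0:
        ew = {p: 100.0 * c / score for p, c in contributions.items()}
    else:
        ew = {p: 100.0 * rel[p] for p in ratings}  # all-zero water: weight shares
    return WQIResult(wqi=score, effective_weights=ew, wqi_class=classify_wqi(score))


def classify_wqi(value: float) -> str:
    """Band a WQI score: <50 excellent, <100 good, <200 poor,
    <300 very_poor, >=300 non_drinkable (lower bounds inclusive)."""
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"WQI must be finite and nonnegative, got {value}")
    if value < 50:
        return "excellent"
    if value < 100:
        return "good"
    if value < 200:
        return "poor"
    if value < 300:
        return "very_poor"
    return "non_drinkable"


def sar(sample: WaterSample) -> float:
    """Sodium adsorption ratio Na/sqrt((Ca+Mg)/2) on meq/L; NaN if Ca+Mg=0."""
    ca_mg = sample.meq("ca") + sample.meq("mg")
    if ca_mg <= 0:
        return float("nan")
    return sample.meq("na") / math.sqrt(ca_mg / 2.0)


def percent_na(sample: WaterSample) -> float:
    """Soluble sodium percentage 100*(Na+K)/(Na+K+Ca+Mg) on meq/L."""
    na_k = sample.meq("na") + sample.meq("k")
    total = na_k + sample.meq("ca") + sample.meq("mg")
    if total <= 0:
        return float("nan")
    return 100.0 * na_k / total


def rsc(sample: WaterSample) -> float:
    """Residual sodium carbonate (CO3+HCO3)-(Ca+Mg) in meq/L; may be negative."""
    return (sample.meq("co3") + sample.meq("hco3")) - (sample.meq("ca") + sample.meq("mg"))


_SAR_EDGES = (10.0, 18.0, 26.0)
_SAR_BANDS = ("<10", "10–18", "18–26", ">26")
_PNA_EDGES = (20.0, 40.0, 60.0, 80.0)
_PNA_BANDS = ("<20", "20–40", "40–60", "60–80", ">80")


def _band(value: float, edges: Sequence[float], labels: Sequence[str]) -> str:
    """Half-open bands, lower bound inclusive."""
    for edge, label in zip(edges, labels):
        if value < edge:
            return label
    return labels[-1]


def classify_sar(value: float) -> str:
    return _band(value, _SAR_EDGES, _SAR_BANDS)


def classify_percent_na(value: float) -> str:
    return _band(value, _PNA_EDGES, _PNA_BANDS)


# Wilcox diagram (EC uS/cm on x, %Na on y) region polygons, ordered
# best to worst.  The classical figure draws sloped boundaries; these
# are documented straight-edge approximations stored in config.  A
# point on a shared boundary falls to the worse (safer) class because
# better classes use strict interior containment.
DEFAULT_WILCOX_POLYGONS: tuple[tuple[str, tuple[tuple[float, float], ...]], ...] = (
    ("excellent_to_good", ((0, 0), (1000, 0), (1000, 20), (0, 80))),
    ("good_to_permissible", ((0, 0), (2000, 0), (2000, 25), (0, 90))),
    ("permissible_to_doubtful", ((0, 0), (3000, 0), (3000, 25), (0, 95))),
    ("doubtful_to_unsuitable", ((0, 0), (3500, 0), (3500, 30), (0, 100))),
)


def wilcox_classify(
    ec: float,
    pna: float,
    polygons: Sequence[tuple[str, Sequence[tuple[float, float]]]] = DEFAULT_WILCOX_POLYGONS,
) -> str:
    """Wilcox irrigation class from EC (uS/cm) and %Na.

    Checks the region polygons best-first; anything outside them all is
    ``"unsuitable"`` (logged as a warning for sanity).
    """
    if ec < 0 or not 0 <= pna <= 100:
        raise ValueError("EC must be >= 0 and %Na in [0, 100]")
    pt = Point(ec, pna)
    for name, verts in polygons:
        if Polygon(verts).contains(pt):
            return name
    logger.warning("point (EC=%.1f, %%Na=%.1f) outside all Wilcox regions", ec, pna)
    return "unsuitable"


_USSL_C_EDGES = (250.0, 750.0, 2250.0)
# S-class boundaries in sloped mode: SAR bound decreases linearly in
# log10(EC) from its value at EC=100 to the diagram's value at EC=5000.
_USSL_SLOPED = ((10.0, 2.5), (18.0, 6.5), (26.0, 11.0))


def ussl_classify(ec: float, sar_value: float, sloped: bool = False) -> str:
    """USSL hazard grid class, e.g. ``"S1C2"``.

    Salinity: C1 <250, C2 250–750, C3 750–2250, C4 >2250 uS/cm (lower
    bound inclusive).  Sodium: fixed SAR bands <10/10–18/18–26/>26 by
    default; ``sloped=True`` uses EC-dependent boundary lines
    approximating the original diagram.
    """
    if ec < 0 or sar_value < 0:
        raise ValueError("EC and SAR must be nonnegative")
    c_class = "C" + str(1 + sum(ec >= e for e in _USSL_C_EDGES))
    if sloped:
        logec = math.log10(max(ec, 100.0))
        frac = min(max((logec - 2.0) / (math.log10(5000.0) - 2.0), 0.0), 1.0)
        edges = [hi + frac * (lo - hi) for hi, lo in _USSL_SLOPED]
    else:
        edges = list(_SAR_EDGES)
    s_class = "S" + str(1 + sum(sar_value >= e for e in edges))
    return s_class + c_class


def irrigation_indices(sample: WaterSample, sloped_ussl: bool = False) -> IrrigationIndices:
    """All irrigation-suitability indices and classes for one sample.

    EC falls back to TDS/0.64 when not measured (flagged in the result).
    """
    ec_estimated = sample.ec is None
    ec = sample.ec if sample.ec is not None else sample.tds / TDS_TO_EC_FACTOR
    if ec_estimated:
        logger.info("%s: EC estimated from TDS", sample.sample_id)
    s = sar(sample)
    p = percent_na(sample)
    return IrrigationIndices(
        sample_id=sample.sample_id,
        sar=s,
        percent_na=p,
        rsc=rsc(sample),
        sar_band=classify_sar(s),
        na_band=classify_percent_na(p),
        wilcox_class=wilcox_classify(ec, p),
        ussl_class=ussl_classify(ec, s, sloped=sloped_ussl),
        ec_estimated=ec_estimated,
    )


def quality_report(
    samples: Sequence[WaterSample], table: WeightTable = DEFAULT_WEIGHT_TABLE
) -> pd.DataFrame:
    """Per-sample quality table: WQI, class, top-3 effective weights,
    SAR/%Na/RSC and the Wilcox/USSL classes."""
    rows = []
    for s in samples:
        res = wqi(s, table)
        irr = irrigation_indices(s)
        top3 = sorted(res.effective_weights, key=res.effective_weights.get, reverse=True)[:3]
        rows.append(
            {
                "sample_id": s.sample_id,
                "wqi": res.wqi,
                "wqi_class": res.wqi_class,
                "top_ew": ",".join(top3),
                "sar": irr.sar,
                "percent_na": irr.percent_na,
                "rsc": irr.rsc,
                "sar_band": irr.sar_band,
                "na_band": irr.na_band,
                "wilcox_class": irr.wilcox_class,
                "ussl_class": irr.ussl_class,
            }
        )
    return pd.DataFrame(rows)
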