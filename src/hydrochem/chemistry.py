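"""Core water-chemistry data model, unit conversions and QC.

Concentrations are carried in mg/L and converted to milliequivalents per
liter (meq/L) for every charge-based calculation.  The charge-balance
error (CBE) is the standard analytical QC statistic: a signed percentage
imbalance between total cation and total anion equivalents, with |CBE|
<= 5% the conventional acceptance limit for a major-ion analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IonMeta",
    "ION_METADATA",
    "CATIONS",
    "ANIONS",
    "WaterSample",
    "SummaryRow",
    "to_meq",
    "from_meq",
    "charge_balance_error",
    "total_hardness",
    "classify_tds",
    "classify_hardness",
    "classify_depth",
    "descriptive_stats",
    "samples_to_frame",
    "frame_to_samples",
]


@dataclass(frozen=True)
class IonMeta:
    """Molar mass and charge of one ionic species, for mg/L <-> meq/L."""

    symbol: str
    molar_mass: float  # g/mol
    charge: int  # signed equivalents per mole

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.symbol}: molar mass must be positive")
        if self.charge == 0:
            raise ValueError(f"{self.symbol}: charge must be nonzero")


# IUPAC 2021 atomic weights; polyatomic masses are the sum of constituents.
ION_METADATA: dict[str, IonMeta] = {
    "k": IonMeta("k", 39.098, +1),
    "na": IonMeta("na", 22.990, +1),
    "ca": IonMeta("ca", 40.078, +2),
    "mg": IonMeta("mg", 24.305, +2),
    "cl": IonMeta("cl", 35.453, -1),
    "so4": IonMeta("so4", 96.06, -2),
    "hco3": IonMeta("hco3", 61.016, -1),
    "co3": IonMeta("co3", 60.008, -2),
    "no3": IonMeta("no3", 62.004, -1),
}

CATIONS: tuple[str, ...] = ("k", "na", "ca", "mg")
ANIONS: tuple[str, ...] = ("cl", "so4", "hco3", "co3", "no3")

#: mg/L of CaCO3 per meq/L (molar mass 100.09 / 2 equivalents)
CACO3_MG_PER_MEQ = 50.04


@dataclass
class WaterSample:
    """One well or spring measurement with major-ion chemistry in mg/L."""

    sample_id: str
    ph: float
    tds: float
    k: float
    na: float
    ca: float
    mg: float
    cl: float
    so4: float
    hco3: float
    no3: float
    co3: float = 0.0
    depth_m: float | None = None
    ec: float | None = None  # uS/cm

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"{self.sample_id}: pH {self.ph} outside [0, 14]")
        for ion in (*CATIONS, *ANIONS):
            value = getattr(self, ion)
            if value < 0:
                raise ValueError(f"{self.sample_id}: negative {ion} ({value} mg/L)")
        if self.tds < 0:
            raise ValueError(f"{self.sample_id}: negative TDS")
        if self.ec is not None and self.ec < 0:
            raise ValueError(f"{self.sample_id}: negative EC")
        if self.depth_m is not None and self.depth_m < 0:
            raise ValueError(f"{self.sample_id}: negative depth")

    def meq(self, ion: str) -> float:
        """Concentration of ``ion`` in meq/L."""
        return to_meq(getattr(self, ion), ion)

    def cation_meq(self) -> float:
        return sum(self.meq(i) for i in CATIONS)

    def anion_meq(self) -> float:
        return sum(self.meq(i) for i in ANIONS)


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics for one analyte (units of the analyte)."""

    analyte: str
    mean: float
    sd: float
    cv: float
    min: float
    median: float
    max: float


def _ion_meta(ion: str | IonMeta) -> IonMeta:
    if isinstance(ion, IonMeta):
        return ion
    try:
        return ION_METADATA[ion.lower()]
    except KeyError:
        raise KeyError(f"unknown ion symbol {ion!r}; known: {sorted(ION_METADATA)}") from None


def to_meq(conc_mg_per_l, ion: str | IonMeta):
    """Convert mg/L to meq/L: conc * |charge| / molar_mass.  Array-safe."""
    meta = _ion_meta(ion)
    return np.multiply(conc_mg_per_l, abs(meta.charge) / meta.molar_mass)


def from_meq(conc_meq_per_l, ion: str | IonMeta):
    """Inverse of :func:`to_meq`."""
    meta = _ion_meta(ion)
    return np.multiply(conc_meq_per_l, meta.molar_mass / abs(meta.charge))


def charge_balance_error(sample: WaterSample) -> float:
    """Signed charge-balance error in percent.

    CBE = 100 * (sum cations - sum anions) / (sum cations + sum anions),
    all in meq/L.  Raises ``ValueError`` when every ion is zero (the
    ratio is undefined).
    """
    cations = sample.cation_meq()
    anions = sample.anion_meq()
    total = cations + anions
    if total == 0:
        raise ValueError(f"{sample.sample_id}: all ion concentrations zero; CBE undefined")
    return 100.0 * (cations - anions) / total


def total_hardness(ca_mg_per_l, mg_mg_per_l):
    """Total hardness as mg/L CaCO3 equivalent: 2.497*Ca + 4.118*Mg."""
    ca = np.asarray(ca_mg_per_l, dtype=float)
    mg = np.asarray(mg_mg_per_l, dtype=float)
    if np.any(ca < 0) or np.any(mg < 0):
        raise ValueError("negative concentration in hardness calculation")
    out = 2.497 * ca + 4.118 * mg
    return float(out) if out.ndim == 0 else out


def classify_tds(tds: float) -> str:
    """Fresh (< 1000 mg/L) vs brackish; the 1000 boundary is brackish."""
    if tds < 0:
        raise ValueError("TDS must be nonnegative")
    return "fresh" if tds < 1000.0 else "brackish"


def classify_hardness(th: float) -> str:
    """Soft (< 150 mg/L as CaCO3) vs hard; the 150 boundary is hard."""
    if th < 0:
        raise ValueError("hardness must be nonnegative")
    return "soft" if th < 150.0 else "hard"


def classify_depth(depth_m: float) -> str:
    """Shallow [0, 20] m, middle (20, 50] m, deep > 50 m."""
    if depth_m < 0:
        raise ValueError("depth must be nonnegative")
    if depth_m <= 20.0:
        return "shallow"
    if depth_m <= 50.0:
        return "middle"
    return "deep"


def samples_to_frame(samples: Iterable[WaterSample]) -> pd.DataFrame:
    """Tabulate samples; adds derived th / cbe / depth_class columns."""
    rows = []
    for s in samples:
        row = {f.name: getattr(s, f.name) for f in fields(s)}
        row["th"] = total_hardness(s.ca, s.mg)
        try:
            row["cbe"] = charge_balance_error(s)
        except ValueError:
            row["cbe"] = np.nan
        row["depth_class"] = classify_depth(s.depth_m) if s.depth_m is not None else None
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_samples(df: pd.DataFrame) -> list[WaterSample]:
    """Build typed samples from a table with the standard column schema."""
    samples = []
    for _, row in df.iterrows():
        kwargs = dict(
            sample_id=str(row["sample_id"]),
            ph=float(row["ph"]),
            tds=float(row["tds"]),
            k=float(row["k"]),
            na=float(row["na"]),
            ca=float(row["ca"]),
            mg=float(row["mg"]),
            cl=float(row["cl"]),
            so4=float(row["so4"]),
            hco3=float(row["hco3"]),
            no3=float(row["no3"]),
        )
        for opt in ("co3", "depth_m", "ec"):
            if opt in row.index and pd.notna(row[opt]):
                kwargs[opt] = float(row[opt])
        samples.append(WaterSample(**kwargs))
    return samples


def descriptive_stats(
    data: pd.DataFrame | Sequence[WaterSample],
    analytes: Sequence[str] | None = None,
) -> list[SummaryRow]:
    """Per-analyte mean, sample SD (n-1), CV, min, median, max.

    ``data`` may be a DataFrame of analyte columns or a sequence of
    :class:`WaterSample` (derived th/cbe columns are then available).
    CV = SD/mean is reported rounded to 2 decimals; analytes missing
    from the table are skipped with a warning.
    """
    if not isinstance(data, pd.DataFrame):
        data = samples_to_frame(data)
    if len(data) < 2:
        raise ValueError("descriptive statistics need at least 2 samples")
    if analytes is None:
        analytes = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]

    rows: list[SummaryRow] = []
    for name in analytes:
        if name not in data.columns or data[name].dropna().empty:
            warnings.warn(f"analyte {name!r} absent; skipped", stacklevel=2)
            continue
        x = data[name].dropna().to_numpy(dtype=float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        cv = round(sd / mean, 2) if mean > 0 else float("nan")
        rows.append(
            SummaryRow(
                analyte=name,
                mean=mean,
                sd=sd,
                cv=cv,
                min=float(np.min(x)),
                median=float(np.median(x)),
                max=float(np.max(x)),
            )
        )
    return rows


def summary_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Summary rows as a table mirroring a field report (Mean..Max)."""
    return pd.DataFrame(
        [
            {
                "analyte": r.analyte,
                "mean": r.mean,
                "sd": r.sd,
                "cv": r.cv,
                "min": r.min,
                "median": r.median,
                "max": r.max,
            }
            for r in rows
        ]
    )
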