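"""CSV readers/writers for the standard sample schema.

Schema (header names exactly): sample_id, depth_m, ph, tds, ec, k, na,
ca, mg, cl, so4, hco3, co3, no3 — mg/L for ions, uS/cm for ec.  The
columns depth_m, ec and co3 are optional.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chemistry import WaterSample, samples_to_frame

__all__ = ["read_samples", "write_samples", "SchemaError", "SAMPLE_COLUMNS"]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "sample_id", "ph", "tds", "k", "na", "ca", "mg", "cl", "so4", "hco3", "no3",
)
OPTIONAL_COLUMNS = ("depth_m", "ec", "co3")
SAMPLE_COLUMNS = ("sample_id", "depth_m", "ph", "tds", "ec",
                  "k", "na", "ca", "mg", "cl", "so4", "hco3", "co3", "no3")


class SchemaError(ValueError):
    """The input table does not follow the documented column schema."""


def read_samples(path: str | Path, strict: bool = False) -> list[WaterSample]:
    """Read samples from CSV; malformed rows are reported and skipped.

    With ``strict=True`` any malformed row raises instead.  Missing
    mandatory columns raise :class:`SchemaError` listing them.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if df.empty:
        logger.warning("%s: header-only file, no samples", path)
        return []

    samples: list[WaterSample] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based + header
        try:
            kwargs = {c: row[c] for c in MANDATORY_COLUMNS}
            kwargs = {k: (str(v) if k == "sample_id" else float(v)) for k, v in kwargs.items()}
            for opt in OPTIONAL_COLUMNS:
                if opt in df.columns and pd.notna(row[opt]):
                    kwargs[opt] = float(row[opt])
            samples.append(WaterSample(**kwargs))
        except (ValueError, TypeError) as exc:
            if strict:
                raise SchemaError(f"{path}: line {pos}: {exc}") from exc
            logger.warning("%s: line %d rejected: %s", path, pos, exc)
    return samples


def write_samples(samples: Sequence[WaterSample], path: str | Path) -> None:
    """Write samples to CSV in the standard schema (round-trips cleanly)."""
    df = samples_to_frame(samples) if samples else pd.DataFrame(columns=SAMPLE_COLUMNS)
    cols = [c for c in SAMPLE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)
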