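"""Time-scan and configuration I/O.

Canonical units used throughout the package: seconds (time), litres
(volume), grams (tissue mass), micrograms (analyte mass), nanometres
(diameter), integer counts per dwell (raw signal) and counts per second
(rates).  All unit conversion happens in this layer and in the
configuration helpers; the numerical modules never convert units.

Time scans are stored as plain CSV with optional ``#key=value`` header
lines carrying the acquisition metadata, followed by a header row
``index,counts`` (optionally ``,time_s``) and one row per dwell.  A trace
file is therefore self-describing and survives a round trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMeta",
    "TimeScan",
    "read_timescan",
    "write_timescan",
    "read_calibration_csv",
    "write_calibration_csv",
    "load_config",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition and sample metadata attached to a time scan.

    Parameters
    ----------
    dwell_time:
        Integration window per data point, in seconds.  Microsecond
        dwells resolve single-particle ion clouds as multi-dwell pulses.
    total_time:
        Acquisition length in seconds.
    isotope_label:
        Monitored isotope, e.g. ``"56Fe"``.
    sample_id:
        Free-text sample identifier.
    dilution_factor:
        Dilution applied to the extract before measurement (>= 1).
    extract_volume:
        Volume of the digestion extract in litres (default 8.5 mL: 7 mL
        citrate buffer + 1.5 mL enzyme solution).
    tissue_mass:
        Digested tissue mass in grams.
    """

    dwell_time: float = 1e-4
    total_time: float = 120.0
    isotope_label: str = "56Fe"
    sample_id: str = ""
    dilution_factor: float = 1.0
    extract_volume: float = 8.5e-3
    tissue_mass: float = 0.015

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.total_time < self.dwell_time:
            raise ValueError("total_time must be >= dwell_time")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def n_dwells(self) -> int:
        return int(round(self.total_time / self.dwell_time))


@dataclass(frozen=True)
class TimeScan:
    """A counts-per-dwell trace plus its acquisition metadata."""

    counts: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if abs(counts.size - self.meta.n_dwells) > 1:
            raise ValueError(
                f"trace has {counts.size} dwells but metadata declares "
                f"{self.meta.n_dwells} (total_time/dwell_time)"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def n_dwells(self) -> int:
        return int(self.counts.size)

    @property
    def times(self) -> np.ndarray:
        """Start time of each dwell, seconds."""
        return np.arange(self.n_dwells) * self.meta.dwell_time


_META_FLOAT_FIELDS = {
    "dwell_time",
    "total_time",
    "dilution_factor",
    "extract_volume",
    "tissue_mass",
}


def _meta_to_header(meta: AcquisitionMeta) -> str:
    lines = []
    for f in dataclasses.fields(meta):
        value = getattr(meta, f.name)
        if f.name in _META_FLOAT_FIELDS:
            value = repr(float(value))
        lines.append(f"#{f.name}={value}")
    return "\n".join(lines)


def _meta_from_header(pairs: dict[str, str]) -> AcquisitionMeta:
    kwargs: dict[str, object] = {}
    for name, raw in pairs.items():
        if name in _META_FLOAT_FIELDS:
            kwargs[name] = float(raw)
        elif name in ("isotope_label", "sample_id"):
            kwargs[name] = raw
        # unknown keys are ignored so files from newer versions still load
    return AcquisitionMeta(**kwargs)  # type: ignore[arg-type]


def write_timescan(scan: TimeScan, path: Union[str, Path]) -> None:
    """Write a time scan as self-describing CSV (see module docstring)."""
    if scan.counts.size == 0:
        raise ValueError("refusing to write an empty time scan")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_meta_to_header(scan.meta))
        fh.write("\nindex,counts\n")
        # int index + int counts; writing via pandas keeps this fast
        df = pd.DataFrame(
            {"index": np.arange(scan.counts.size), "counts": scan.counts}
        )
        df.to_csv(fh, index=False, header=False)


def read_timescan(
    path: Union[str, Path],
    meta_override: Optional[AcquisitionMeta] = None,
) -> TimeScan:
    """Read a time-scan CSV written by :func:`write_timescan`.

    Header ``#key=value`` lines populate the metadata unless
    ``meta_override`` is given, which then takes precedence entirely.
    Raises on a missing counts column, negative or non-integer counts,
    or a dwell count inconsistent with the declared total time.
    """
    path = Path(path)
    header_pairs: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                header_pairs[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(body_lines)))
    if "counts" not in df.columns:
        raise ValueError(f"{path}: no 'counts' column")
    counts = df["counts"].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError(f"{path}: counts must be integers")
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative counts")
    meta = meta_override if meta_override is not None else _meta_from_header(header_pairs)
    return TimeScan(counts=counts, meta=meta)


def read_calibration_csv(path: Union[str, Path]) -> list[tuple[float, float]]:
    """Read ionic-calibration points: columns concentration_ug_L, response_cps."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        conc = df[cols["concentration_ug_l"]]
        resp = df[cols["response_cps"]]
    except KeyError as exc:
        raise ValueError(
            f"{path}: expected columns concentration_ug_L, response_cps"
        ) from exc
    return list(zip(conc.astype(float), resp.astype(float)))


def write_calibration_csv(
    points: list[tuple[float, float]], path: Union[str, Path]
) -> None:
    pd.DataFrame(points, columns=["concentration_ug_L", "response_cps"]).to_csv(
        path, index=False
    )


def load_config(path: Union[str, Path]) -> dict:
    """Load a run configuration (JSON or YAML by extension).

    Expected blocks: ``instrument`` (dwell_time, total_time, uptake_rate,
    transport_efficiency or reference-standard paths), ``element``
    (density, mass_fraction, isotope_abundance, molar_mass) and
    ``sample`` (dilution_factor, extract_volume, tissue_mass).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
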