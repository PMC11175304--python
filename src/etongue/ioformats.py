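"""Round-trippable long-format CSV serialization of CV datasets.

Schema (one row per sampled point)::

    measurement_id,sensor,cultivar,electrode_id,scan_index,point_index,potential,current

with potential in volts and current in microamperes, written as plain decimal
text with 12 significant digits.  A JSON manifest summarizes the files, the
class-label inventory and the per-(cultivar, sensor) scan counts, optionally
echoing the generator configuration for synthetic datasets.
"""

from __future__ import annotations

import dataclasses
import gzip as _gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .syndata import SENSOR_NAMES, GeneratorConfig, Measurement, VoltammetricScan

__all__ = ["SchemaError", "COLUMNS", "MANIFEST_NAME", "write_dataset", "read_dataset"]

COLUMNS = [
    "measurement_id", "sensor", "cultivar", "electrode_id",
    "scan_index", "point_index", "potential", "current",
]
MANIFEST_NAME = "manifest.json"
_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A file does not conform to the scan-table schema."""


def _measurement_frame(m: Measurement) -> pd.DataFrame:
    frames = []
    for scan in m.scans:
        n = scan.current.size
        frames.append(pd.DataFrame({
            "measurement_id": m.measurement_id,
            "sensor": scan.sensor,
            "cultivar": scan.cultivar,
            "electrode_id": scan.electrode_id,
            "scan_index": scan.scan_index,
            "point_index": np.arange(n),
            "potential": scan.potential,
            "current": scan.current,
        }))
    return pd.concat(frames, ignore_index=True)


def write_dataset(
    measurements: list[Measurement],
    path: str | Path,
    *,
    per_sensor: bool = False,
    gzip: bool = False,
    config: GeneratorConfig | None = None,
) -> dict:
    """Write a dataset directory: scan CSV file(s) plus ``manifest.json``.

    Parameters
    ----------
    measurements
        Non-empty collection of measurements.
    path
        Output directory (created if absent).
    per_sensor
        Write one ``scans_<SENSOR>.csv`` per sensor instead of a combined
        ``scans.csv``.
    gzip
        Gzip-compress the CSV files.
    config
        Generator configuration to echo into the manifest (synthetic data).

    Returns
    -------
    dict
        The manifest, also written to ``<path>/manifest.json``.
    """
    if not measurements:
        raise ValueError("cannot write an empty dataset")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    frame = pd.concat(
        [_measurement_frame(m) for m in measurements], ignore_index=True
    )
    suffix = ".csv.gz" if gzip else ".csv"
    files: list[str] = []
    if per_sensor:
        for sensor, sub in frame.groupby("sensor", sort=True):
            name = f"scans_{sensor}{suffix}"
            sub.to_csv(out / name, index=False, float_format=_FLOAT_FMT)
            files.append(name)
    else:
        name = f"scans{suffix}"
        frame.to_csv(out / name, index=False, float_format=_FLOAT_FMT)
        files.append(name)

    counts = (
        frame.drop_duplicates(["measurement_id", "scan_index"])
        .groupby(["cultivar", "sensor"], sort=True)
        .size()
    )
    manifest = {
        "files": files,
        "n_measurements": len(measurements),
        "n_scans": int(sum(len(m.scans) for m in measurements)),
        "classes": sorted(frame["cultivar"].unique()),
        "scan_counts": {
            f"{cultivar}/{sensor}": int(n)
            for (cultivar, sensor), n in counts.items()
        },
        "generator_config": dataclasses.asdict(config) if config else None,
    }
    with open(out / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _open_text(path: Path):
    if path.suffix == ".gz":
        return _gzip.open(path, "rt")
    return open(path)


def _load_frames(path: Path) -> pd.DataFrame:
    if path.is_dir():
        manifest_path = path / MANIFEST_NAME
        if manifest_path.exists():
            with open(manifest_path) as fh:
                files = [path / f for f in json.load(fh)["files"]]
        else:
            files = sorted(path.glob("scans*.csv")) + sorted(path.glob("scans*.csv.gz"))
        if not files:
            raise SchemaError(f"no scan CSV files found under {path}")
    else:
        files = [path]
    frames = []
    for f in files:
        with _open_text(Path(f)) as fh:
            frames.append(pd.read_csv(fh))
    return pd.concat(frames, ignore_index=True)


def read_dataset(path: str | Path) -> list[Measurement]:
    """Read a dataset written by :func:`write_dataset`.

    ``path`` may be a dataset directory (with manifest) or a single CSV file.
    Measurements are reconstructed with scans ordered by ``scan_index``;
    schema violations (missing columns, unknown sensor names, non-contiguous
    ``point_index``, mixed sensors inside one measurement) raise
    :class:`SchemaError` naming the offending rows.
    """
    frame = _load_frames(Path(path))

    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    bad_sensor = set(frame["sensor"].unique()) - set(SENSOR_NAMES)
    if bad_sensor:
        raise SchemaError(
            f"unknown sensor name(s) {sorted(bad_sensor)}; "
            f"allowed sensors are {list(SENSOR_NAMES)}"
        )

    measurements: list[Measurement] = []
    for mid, group in frame.groupby("measurement_id", sort=True):
        if group["sensor"].nunique() > 1:
            raise SchemaError(
                f"measurement {mid!r} mixes sensors "
                f"{sorted(group['sensor'].unique())}"
            )
        scans = []
        for scan_idx, sub in group.groupby("scan_index", sort=True):
            pts = sub["point_index"].to_numpy()
            order = np.argsort(pts, kind="stable")
            pts = pts[order]
            if not np.array_equal(pts, np.arange(len(pts))):
                raise SchemaError(
                    f"measurement {mid!r} scan {scan_idx}: point_index is not "
                    "contiguous from 0 (first gap near "
                    f"{int(pts[np.flatnonzero(pts != np.arange(len(pts)))[0]])})"
                )
            row = sub.iloc[0]
            scans.append(VoltammetricScan(
                potential=sub["potential"].to_numpy()[order],
                current=sub["current"].to_numpy()[order],
                sensor=str(row["sensor"]),
                cultivar=str(row["cultivar"]),
                electrode_id=str(row["electrode_id"]),
                scan_index=int(scan_idx),
                measurement_id=str(mid),
            ))
        try:
            measurements.append(Measurement(scans=scans, measurement_id=str(mid)))
        except ValueError as exc:
            raise SchemaError(str(exc)) from exc
    return measurements
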