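"""File formats: 16-bit TIFF images/masks, POME tables, persistence tables,
lineage CSVs, JSON ground truth/manifests and YAML configs.

Conventions: CSV with header, UTF-8, '.' decimal, floats at 6 significant
digits; JSON for nested records; YAML for configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import lineage as L
from .persistence import PersistenceResult
from .polarity import PeakFit, PolarityRecord

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# images

def write_image(path, image: np.ndarray) -> None:
    """Write a (channels, H, W) image as multi-page 16-bit TIFF."""
    arr = np.round(np.clip(np.asarray(image), 0, 65535)).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a label mask as single-page 16-bit TIFF (0 = background)."""
    tifffile.imwrite(str(path), np.asarray(mask).astype(np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path))


# ---------------------------------------------------------------------------
# JSON / YAML

def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    return json.loads(Path(path).read_text())


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def write_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


# ---------------------------------------------------------------------------
# POME table (per-cell polarity records)

POME_COLUMNS = ["cell_id", "timepoint", "bpi", "crescent_fraction", "peak_height",
                "b", "A", "mu", "sigma", "rmse", "converged"]


def polarity_records_to_frame(records: list[PolarityRecord]) -> pd.DataFrame:
    rows = [{
        "cell_id": r.cell_id, "timepoint": r.timepoint, "bpi": r.bpi,
        "crescent_fraction": r.crescent_fraction, "peak_height": r.peak_height,
        "b": r.fit.baseline, "A": r.fit.amplitude, "mu": r.fit.mu,
        "sigma": r.fit.sigma, "rmse": r.fit.residual_rmse, "converged": r.fit.converged,
    } for r in records]
    return pd.DataFrame(rows, columns=POME_COLUMNS)


def frame_to_polarity_records(df: pd.DataFrame) -> list[PolarityRecord]:
    records = []
    for row in df.itertuples(index=False):
        fit = PeakFit(baseline=float(row.b), amplitude=float(row.A), mu=float(row.mu),
                      sigma=float(row.sigma), residual_rmse=float(row.rmse),
                      converged=bool(row.converged))
        records.append(PolarityRecord(
            cell_id=int(row.cell_id), timepoint=int(row.timepoint), bpi=float(row.bpi),
            crescent_fraction=float(row.crescent_fraction),
            peak_height=float(row.peak_height), fit=fit))
    return records


def write_pome_table(path, records: list[PolarityRecord]) -> None:
    polarity_records_to_frame(records).to_csv(str(path), index=False,
                                              float_format=FLOAT_FORMAT)


def read_pome_table(path) -> list[PolarityRecord]:
    return frame_to_polarity_records(pd.read_csv(str(path)))


# ---------------------------------------------------------------------------
# persistence table

def write_persistence_table(path, results: list[PersistenceResult]) -> None:
    df = pd.DataFrame([{
        "cell_id": r.cell_id, "persistence_minutes": r.persistence_minutes,
        "end_frame": r.end_frame, "censored": r.censored, "n_frames": r.n_frames,
        "warning": r.warning or "",
    } for r in results])
    df.to_csv(str(path), index=False, float_format=FLOAT_FORMAT)


def read_persistence_table(path) -> list[PersistenceResult]:
    df = pd.read_csv(str(path), keep_default_na=False)
    return [PersistenceResult(
        cell_id=int(r.cell_id), persistence_minutes=float(r.persistence_minutes),
        end_frame=int(r.end_frame), censored=_to_bool(r.censored),
        n_frames=int(r.n_frames), warning=(str(r.warning) or None))
        for r in df.itertuples(index=False)]


def _to_bool(v) -> bool:
    return v if isinstance(v, (bool, np.bool_)) else str(v).lower() == "true"


# ---------------------------------------------------------------------------
# lineage CSV

def write_lineage(path, record: L.LineageRecord) -> None:
    L.to_frame(record).to_csv(str(path), index=False)


def read_lineage(path) -> L.LineageRecord:
    return L.from_frame(pd.read_csv(str(path)))
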