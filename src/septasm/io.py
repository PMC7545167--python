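"""Readers, writers and provenance records.

Fixed on-disk dialect: comma-separated tables with a header row and '.'
decimals.  Histogram series travel as long-format tables (time, j, value);
topographs either as plain numeric text matrices (exact round-trip) or as
16-bit TIFF/PNG with a YAML sidecar holding the nm calibration (round-trip
within quantization).  Sequences are FASTA via Biopython.  Every pipeline
run can emit a provenance record (config echo, seed, package versions)
next to its outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO

from .image_metrics import FilamentSet, Topograph
from .kinetics import HistogramSeries, normalize_histograms

logger = logging.getLogger("septasm")


# ---------------------------------------------------------------------------
# Histogram tables
# ---------------------------------------------------------------------------

def read_histogram_table(path) -> HistogramSeries:
    """Read a long-format (time, j, value) CSV into a HistogramSeries.

    Rows may appear in any order; times are sorted on read and each time
    slice is normalized to 1 (all-zero slices flagged), so the result is
    independent of row permutation.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty histogram table") from err
    required = {"time", "j", "value"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: histogram table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    bad = df[df[["time", "j", "value"]].isna().any(axis=1)]
    if not bad.empty:
        raise ValueError(
            f"{path}: malformed row at line {int(bad.index[0]) + 2}"
        )
    times = np.sort(df["time"].unique())
    j_max = int(df["j"].max())
    counts = np.zeros((times.size, j_max))
    t_index = {t: i for i, t in enumerate(times)}
    for _, row in df.iterrows():
        j = int(row["j"])
        if j < 1:
            raise ValueError(f"{path}: size index j must be >= 1, got {j}")
        counts[t_index[row["time"]], j - 1] += float(row["value"])
    return normalize_histograms(times, counts)


def write_histogram_table(series: HistogramSeries, path) -> None:
    """Write a HistogramSeries as a long-format (time, j, value) CSV."""
    rows = []
    for i, t in enumerate(series.times):
        for j in range(series.j_max):
            rows.append((float(t), j + 1, float(series.populations[i, j])))
    pd.DataFrame(rows, columns=["time", "j", "value"]).to_csv(path, index=False)


def read_coverage_table(path):
    """Read a (time, coverage) CSV; returns (times, coverage) arrays."""
    df = pd.read_csv(path)
    if not {"time", "coverage"}.issubset(df.columns):
        raise ValueError(f"{path}: coverage table needs columns time, coverage")
    df = df.sort_values("time")
    return df["time"].to_numpy(float), df["coverage"].to_numpy(float)


def write_coverage_table(times, coverage, path) -> None:
    pd.DataFrame({"time": np.asarray(times, float),
                  "coverage": np.asarray(coverage, float)}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Topographs
# ---------------------------------------------------------------------------

def read_topograph(path, pixel_size: float | None = None) -> Topograph:
    """Read a topograph from matrix text or 16-bit TIFF (+ YAML sidecar).

    For images the sidecar ``<path>.yaml`` must provide ``pixel_size_nm``
    and ``nm_per_level`` (plus optional ``height_offset_nm``); matrix text
    (``.txt``/``.csv``/``.dat``) stores nm directly and needs only the
    pixel size (argument or sidecar).
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    meta = {}
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if path.suffix.lower() in (".txt", ".csv", ".dat"):
        heights = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
        ps = pixel_size or meta.get("pixel_size_nm")
        if ps is None:
            raise ValueError(f"{path}: missing pixel size calibration")
        topo = Topograph(heights=heights, pixel_size=float(ps))
    elif path.suffix.lower() in (".tif", ".tiff", ".png"):
        if path.suffix.lower() == ".png":
            from PIL import Image

            raw = np.asarray(Image.open(path), dtype=float)
        else:
            raw = tifffile.imread(path).astype(float)
        ps = pixel_size or meta.get("pixel_size_nm")
        scale = meta.get("nm_per_level")
        if ps is None or scale is None:
            raise ValueError(
                f"{path}: image topographs need pixel_size_nm and nm_per_level "
                f"in the sidecar {sidecar.name}"
            )
        offset = float(meta.get("height_offset_nm", 0.0))
        topo = Topograph(heights=raw * float(scale) + offset, pixel_size=float(ps))
    else:
        raise ValueError(f"{path}: unsupported topograph format {path.suffix!r}")
    expected_shape = meta.get("shape")
    if expected_shape is not None and tuple(expected_shape) != topo.shape:
        raise ValueError(
            f"{path}: sidecar shape {tuple(expected_shape)} does not match "
            f"image shape {topo.shape}"
        )
    return topo


def write_topograph(topo: Topograph, path) -> None:
    """Write matrix text (exact) or 16-bit TIFF + YAML sidecar (quantized).

    16-bit quantization over the height range keeps the error <= 0.01 nm
    for a 10-nm range (range / 65535).
    """
    path = Path(path)
    if path.suffix.lower() in (".txt", ".dat"):
        np.savetxt(path, topo.heights)
        meta = {"pixel_size_nm": topo.pixel_size, "shape": list(topo.shape)}
        path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))
    elif path.suffix.lower() in (".tif", ".tiff"):
        lo = float(topo.heights.min())
        hi = float(topo.heights.max())
        span = max(hi - lo, 1e-12)
        levels = np.round((topo.heights - lo) / span * 65535).astype(np.uint16)
        tifffile.imwrite(path, levels)
        meta = {
            "pixel_size_nm": topo.pixel_size,
            "nm_per_level": span / 65535,
            "height_offset_nm": lo,
            "shape": list(topo.shape),
        }
        path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))
    else:
        raise ValueError(f"unsupported topograph output format {path.suffix!r}")


# ---------------------------------------------------------------------------
# Traces, sequences, configs, provenance
# ---------------------------------------------------------------------------

def write_filament_table(fs: FilamentSet, path) -> None:
    """Write traced centerlines as a long-format polyline CSV."""
    rows = []
    for i, f in enumerate(fs):
        for x, y in f.points:
            rows.append((i, float(x), float(y), f.length, f.orientation))
    pd.DataFrame(
        rows, columns=["filament", "x_nm", "y_nm", "length_nm", "orientation_deg"]
    ).to_csv(path, index=False)


def read_fasta(path) -> dict:
    """FASTA records as {id: sequence} via Biopython."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_config(path) -> dict:
    """YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}


def write_provenance(path, config: dict, seed: int | None = None) -> None:
    """Emit a provenance record (config echo, seed, versions) as JSON."""
    import septasm

    record = {
        "config": config,
        "seed": seed,
        "versions": {
            "septasm": septasm.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
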