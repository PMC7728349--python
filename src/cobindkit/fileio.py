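"""Readers and writers for the plain-text formats the pipelines consume.

* BED3/BED6 and ENCODE narrowPeak (10-column) peak files — tab-separated,
  headerless; only the first three columns (coordinates) are used, the
  remainder is parsed leniently and discarded. The writer emits BED3.
* PSM tables — TSV with a header row and the PSM schema columns.
* BLI traces — one TSV per trace (``time_s``, ``shift_nm``) plus a
  manifest TSV (``trace_file``, ``analyte``, ``concentration_M``,
  ``is_blank``).
* Contaminant lists — one accession per line, ``#`` comments allowed.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .bli import Interferogram
from .intervals import GenomicInterval, IntervalSet, normalize
from .psm import PSM_COLUMNS

__all__ = [
    "read_bed",
    "read_narrowpeak",
    "write_bed",
    "read_psm_table",
    "write_psm_table",
    "read_contaminants",
    "read_bli_manifest",
    "write_trace",
]


def _read_intervals(path: str | Path, min_columns: int) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_columns} tab-separated "
                    f"columns, got {len(fields)}"
                )
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3/BED6 file into a normalized IntervalSet."""
    return normalize(_read_intervals(path, min_columns=3))


def read_narrowpeak(path: str | Path) -> IntervalSet:
    """Read an ENCODE narrowPeak (10-column BED6+4) file; coordinates only."""
    return normalize(_read_intervals(path, min_columns=10))


def read_peaks(path: str | Path) -> IntervalSet:
    """Dispatch on extension: ``.narrowPeak`` else BED."""
    if str(path).lower().endswith(".narrowpeak"):
        return read_narrowpeak(path)
    return read_bed(path)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write an IntervalSet as headerless BED3."""
    with open(path, "w") as handle:
        for iv in s:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a PSM TSV; validates the schema columns are present."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: PSM table missing columns {missing}")
    frame["is_decoy"] = frame["is_decoy"].astype(bool)
    return frame


def write_psm_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_contaminants(path: str | Path) -> frozenset:
    """Accession-per-line contaminant list; blank lines and # comments skipped."""
    accessions = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                accessions.add(line)
    return frozenset(accessions)


def write_trace(trace: Interferogram, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "shift_nm": trace.shift}).to_csv(
        path, sep="\t", index=False
    )


def read_bli_manifest(
    manifest_path: str | Path,
) -> Tuple[Dict[str, List[Interferogram]], Dict[str, List[Interferogram]]]:
    """Load all traces referenced by a manifest TSV.

    Trace paths are resolved relative to the manifest's directory.
    Returns (signals, blanks), each keyed by analyte name.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"trace_file", "analyte", "concentration_M", "is_blank"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")

    signals: Dict[str, List[Interferogram]] = {}
    blanks: Dict[str, List[Interferogram]] = {}
    for row in manifest.itertuples(index=False):
        trace_path = manifest_path.parent / str(row.trace_file)
        table = pd.read_csv(trace_path, sep="\t")
        trace = Interferogram(
            analyte=str(row.analyte),
            concentration=float(row.concentration_M),
            time=table["time_s"].to_numpy(),
            shift=table["shift_nm"].to_numpy(),
        )
        bucket = blanks if bool(row.is_blank) else signals
        bucket.setdefault(trace.analyte, []).append(trace)
    return signals, blanks
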