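"""CSV dialect, configuration files, and run manifests.

Tables travel as long-format UTF-8 CSV: one measurement per row, header
required, days as integers, Cq as decimal with '.'.  A not-detected Cq is
written as the literal ``ND`` (an empty cell also reads as not detected).
Run manifests are flat ``key: value`` text files containing only
deterministic fields — config snapshot, seeds, package version, SHA-256
digests of every output — so a re-run at the same seed reproduces
manifests byte-identically.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cqindex.quantify import PanelConfig, Segment
from cqindex.simulate import RUN_LENGTH_CYCLES

CQ_COLUMNS = ["sample_id", "organoid_type", "treatment", "div", "replicate", "gene", "cq"]


def read_cq_csv(path) -> pd.DataFrame:
    """Read a replicate-level Cq table, validating the dialect.

    Empty or ``ND`` Cq cells parse as not detected (NaN).  Duplicate
    (sample, gene) rows and Cq values outside (0, 40] are rejected with
    the offending row numbers.
    """
    df = pd.read_csv(path, dtype={"cq": str})
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    raw = df["cq"].fillna("ND").str.strip()
    df["cq"] = pd.to_numeric(raw.replace("ND", np.nan), errors="raise")
    df["div"] = df["div"].astype(int)

    dup = df.duplicated(subset=["sample_id", "gene"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based, plus header line
        raise ValueError(f"{path}: duplicate (sample_id, gene) at row(s) {rows}")
    present = df["cq"].notna()
    bad = present & ((df["cq"] <= 0) | (df["cq"] > RUN_LENGTH_CYCLES))
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: Cq outside (0, {RUN_LENGTH_CYCLES:g}] at row(s) {rows}")
    if "detected" in df.columns:
        df["detected"] = df["detected"].map(
            {True: True, False: False, "True": True, "False": False}
        ).astype(bool)
    return df


def write_cq_csv(df: pd.DataFrame, path) -> None:
    """Write a Cq table in the long-format dialect; ND cells as ``ND``."""
    out = df[[c for c in df.columns if c in CQ_COLUMNS + ["detected"]]].copy()
    out["cq"] = out["cq"].map(lambda v: "ND" if pd.isna(v) else format(v, ".6f"))
    if "detected" in out.columns:
        # a flagged row sits on the run-length bound; write it as ND
        out.loc[~df["detected"], "cq"] = "ND"
    out.to_csv(path, index=False)


def read_table_csv(path) -> pd.DataFrame:
    """Read a derived long-format table (expression, index, results)."""
    return pd.read_csv(path)


def write_table_csv(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    df.to_csv(path, index=False, float_format=float_format)


def read_config(path) -> PanelConfig:
    """Load a flat YAML panel configuration.

    Recognized keys mirror PanelConfig; ``segments`` is a list of
    "START-END" day ranges.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("genes", "housekeeping_gene", "calibrator", "alpha",
                "detection_cq_max", "min_detected_fraction"):
        if key in raw:
            kwargs[key] = raw[key]
    if "segments" in raw:
        segs = []
        for item in raw["segments"]:
            start, end = str(item).split("-")
            segs.append(Segment(int(start), int(end)))
        kwargs["segments"] = tuple(segs)
    return PanelConfig(**kwargs)


def write_config(config: PanelConfig, path) -> None:
    doc = {
        "genes": list(config.genes),
        "housekeeping_gene": config.housekeeping_gene,
        "calibrator": config.calibrator,
        "segments": [f"{s.start_div}-{s.end_div}" for s in config.segments],
        "alpha": config.alpha,
        "detection_cq_max": config.detection_cq_max,
        "min_detected_fraction": config.min_detected_fraction,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, entries: dict, outputs=()) -> None:
    """Write a deterministic run manifest.

    ``entries`` are flat key/value pairs (config snapshot, seed, stage
    status); each path in ``outputs`` is recorded with its SHA-256 digest.
    """
    from cqindex import __version__

    lines = [f"cqindex_version: {__version__}"]
    for k in sorted(entries):
        lines.append(f"{k}: {entries[k]}")
    for out in outputs:
        lines.append(f"sha256[{Path(out).name}]: {sha256_of(out)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            out[k.strip()] = v.strip()
    return out
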