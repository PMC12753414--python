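"""Relative quantification of Cq tables: ΔCq, 2^−ΔΔCq fold change,
scaled relative abundance, and group-level detectability filtering.

All operations take and return long-format pandas DataFrames.  A Cq value
is *not detected* in a well when it is missing (NaN) or sits at the
40-cycle run length; not-detected measurements propagate through every
derived quantity as missing, never as zero.  Amplification efficiency is
fixed at 2 (primers validated for efficiency), so fold change is exactly
2^−ΔΔCq with the calibrator ΔΔCq taken against the arithmetic mean of the
calibrator ΔCq values (the geometric mean on the expression scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cqindex.simulate import RUN_LENGTH_CYCLES

META_COLUMNS = ["sample_id", "organoid_type", "treatment", "div", "replicate"]


@dataclass(frozen=True)
class Segment:
    """One developmental interval [start_div, end_div] in days in vitro."""

    start_div: int
    end_div: int
    label: str = ""

    def __post_init__(self):
        if self.start_div >= self.end_div:
            raise ValueError("segment requires start_div < end_div")
        if not self.label:
            object.__setattr__(self, "label", f"DIV{self.start_div}-DIV{self.end_div}")

    def contains(self, div) -> np.ndarray:
        div = np.asarray(div)
        return (div >= self.start_div) & (div <= self.end_div)


def default_segments() -> list:
    """The four consecutive developmental segments of the time course."""
    return [Segment(26, 55), Segment(55, 78), Segment(78, 95), Segment(95, 138)]


@dataclass(frozen=True)
class PanelConfig:
    """Panel, normalization and significance configuration.

    ``calibrator`` is a pandas query selecting the calibrator sample group
    (default: undifferentiated cells at DIV0) against which ΔΔCq is taken.
    """

    genes: tuple = ()
    housekeeping_gene: str = "GAPDH"
    calibrator: str = "div == 0"
    segments: tuple = field(default_factory=lambda: tuple(default_segments()))
    alpha: float = 0.05
    detection_cq_max: float = RUN_LENGTH_CYCLES
    min_detected_fraction: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.housekeeping_gene in self.genes:
            raise ValueError("housekeeping gene must not be part of the panel")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.min_detected_fraction <= 1.0:
            raise ValueError("min_detected_fraction must lie in (0, 1]")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end_div != b.start_div:
                raise ValueError("segments must be contiguous (share boundary days)")


def _nd_mask(cq: pd.Series) -> pd.Series:
    """A well-level measurement counts as not detected when missing or at
    the run length."""
    return cq.isna() | (cq >= RUN_LENGTH_CYCLES)


def compute_dcq(cq: pd.DataFrame, config: PanelConfig) -> pd.DataFrame:
    """ΔCq = Cq_gene − Cq_housekeeping, per sample and gene.

    Raises if any sample lacks a detected housekeeping measurement.
    """
    hk = cq[cq["gene"] == config.housekeeping_gene]
    missing = set(cq["sample_id"]) - set(hk.loc[~_nd_mask(hk["cq"]), "sample_id"])
    if missing:
        raise ValueError(
            f"housekeeping gene {config.housekeeping_gene!r} missing or not "
            f"detected in sample(s): {sorted(missing)}"
        )
    hk_by_sample = hk.set_index("sample_id")["cq"]
    out = cq[cq["gene"] != config.housekeeping_gene].copy()
    value = out["cq"] - out["sample_id"].map(hk_by_sample)
    out["value"] = value.where(~_nd_mask(out["cq"]))
    out["value_kind"] = "dcq"
    return out[META_COLUMNS + ["gene", "value", "value_kind"]].reset_index(drop=True)


def compute_fold_change(dcq: pd.DataFrame, config: PanelConfig) -> pd.DataFrame:
    """Fold change 2^−ΔΔCq relative to the calibrator group mean ΔCq."""
    if not (dcq["value_kind"] == "dcq").all():
        raise ValueError("compute_fold_change expects a ΔCq table")
    calib = dcq.query(config.calibrator)
    if calib.empty:
        raise ValueError(f"calibrator group {config.calibrator!r} selects no samples")
    calib_mean = calib.groupby("gene")["value"].mean()
    absent = calib_mean.index[calib_mean.isna()].tolist()
    absent += sorted(set(dcq["gene"]) - set(calib_mean.index))
    if absent:
        raise ValueError(f"gene(s) absent from calibrator group: {sorted(set(absent))}")
    out = dcq.copy()
    ddcq = out["value"] - out["gene"].map(calib_mean)
    out["value"] = np.exp2(-ddcq)
    out["value_kind"] = "fold_change"
    return out


def scaled_relative_abundance(dcq: pd.DataFrame) -> pd.DataFrame:
    """Expression relative to the housekeeping gene: 2^−ΔCq × 10,000."""
    if not (dcq["value_kind"] == "dcq").all():
        raise ValueError("scaled_relative_abundance expects a ΔCq table")
    out = dcq.copy()
    out["value"] = np.exp2(-out["value"]) * 10_000.0
    out["value_kind"] = "scaled_abundance"
    return out


def detectability_filter(
    cq: pd.DataFrame, config: PanelConfig, group_keys: list
) -> pd.DataFrame:
    """Group-level detectability calls.

    A gene is detected in a group when, at *every* assayed day in the
    group, the fraction of replicate wells with Cq below
    ``detection_cq_max`` is at least ``min_detected_fraction``.
    """
    if cq.empty:
        raise ValueError("empty Cq table")
    bad = [k for k in group_keys if k not in cq.columns]
    if bad:
        raise ValueError(f"unknown group key(s): {bad}")
    work = cq[cq["gene"] != config.housekeeping_gene].copy()
    work["ok"] = (~_nd_mask(work["cq"])) & (work["cq"] < config.detection_cq_max)
    per_day = work.groupby(group_keys + ["gene", "div"], sort=True)["ok"].mean()
    detected = (per_day >= config.min_detected_fraction).groupby(
        level=list(range(len(group_keys) + 1))
    ).all()
    out = detected.rename("detected").reset_index()
    return out


def fold_change_ratio_table(
    expr: pd.DataFrame, arm_a: str, arm_b: str, arm_col: str = "treatment"
) -> pd.DataFrame:
    """Heatmap-ready per-gene per-day ratio of mean fold changes (a over b)."""
    if not (expr["value_kind"] == "fold_change").all():
        raise ValueError("fold_change_ratio_table expects a fold-change table")
    means = (
        expr[expr[arm_col].isin([arm_a, arm_b])]
        .groupby(["gene", "div", arm_col], sort=True)["value"]
        .mean()
        .unstack(arm_col)
    )
    for arm in (arm_a, arm_b):
        if arm not in means.columns:
            raise ValueError(f"arm {arm!r} has no measurements")
    lonely = means.index[means[[arm_a, arm_b]].isna().any(axis=1)].tolist()
    if lonely:
        raise ValueError(f"(gene, day) measured in only one arm: {lonely}")
    out = (means[arm_a] / means[arm_b]).rename("ratio").reset_index()
    return out
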