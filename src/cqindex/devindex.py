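"""Segmented developmental index.

For each developmental segment the control arm defines the trend of each
panel gene (Pearson correlation of replicate-level log2 fold change
against day; two-sided p from the t transform).  Genes significantly
up- or down-regulated form the up- and down-sets; every sample's index is
the ratio of its averaged up-set expression to its averaged down-set
expression, after per-gene rescaling by the control-arm segment mean so
every gene enters with equal weight.  The same gene sets and rescaling
constants are applied to the treated arm.  Per-segment index-versus-day
slopes are fitted by ordinary least squares and arm differences in slope
are tested with the ANCOVA interaction term (index ~ day + arm + day×arm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from cqindex.quantify import PanelConfig, Segment, default_segments

logger = logging.getLogger(__name__)

#: Residual / term sums of squares below this fraction of the total SS are
#: treated as exactly zero (degenerate, noiseless fits).
_DEGENERATE_RTOL = 1e-9


class NonEvaluableSegmentError(ValueError):
    """Raised when a segment has an empty up- or down-set (no silent default)."""


@dataclass(frozen=True)
class SlopeComparison:
    """Per-segment ANCOVA comparison of index slopes between arms."""

    segment: Segment
    slope_control: float = np.nan
    slope_treated: float = np.nan
    interaction_F: float = np.nan
    interaction_p: float = np.nan
    evaluable: bool = False
    degenerate: bool = False
    error: str = ""


@dataclass
class DevIndexResult:
    """Aggregated pipeline report for all segments."""

    classifications: dict        # segment label -> classification DataFrame
    index_series: pd.DataFrame   # replicate-level index values, all segments/arms
    slope_comparisons: list      # list[SlopeComparison], in segment order
    gene_sets: dict              # segment label -> {"up": [...], "down": [...]}
    rescale_constants: dict      # segment label -> {gene: control-arm mean FC}
    alpha: float = 0.05
    index_scale: str = "linear"

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.slope_comparisons:
            rows.append(
                {
                    "segment": c.segment.label,
                    "slope_control": c.slope_control,
                    "slope_treated": c.slope_treated,
                    "interaction_F": c.interaction_F,
                    "interaction_p": c.interaction_p,
                    "evaluable": c.evaluable,
                    "degenerate": c.degenerate,
                    "error": c.error,
                }
            )
        return pd.DataFrame(rows)


def _segment_control(expr: pd.DataFrame, segment: Segment, control_arm: str,
                     arm_col: str) -> pd.DataFrame:
    mask = (expr[arm_col] == control_arm) & segment.contains(expr["div"])
    return expr[mask]


def classify_segment_genes(
    expr: pd.DataFrame,
    segment: Segment,
    control_arm: str = "DMSO",
    alpha: float = 0.05,
    arm_col: str = "treatment",
) -> pd.DataFrame:
    """Per-gene trend call within one segment of the control arm.

    Returns a DataFrame with columns gene, direction ('up'/'down'/'ns'),
    r, p, n_obs.  r is the Pearson correlation of log2(fold change)
    against day over replicate-level control observations inside the
    segment; p is the two-sided t-transform p-value (df = n_obs − 2).
    Genes with fewer than 3 observations or zero variance are 'ns' with
    undefined r.
    """
    if not (expr["value_kind"] == "fold_change").all():
        raise ValueError("classify_segment_genes expects a fold-change table")
    sub = _segment_control(expr, segment, control_arm, arm_col)
    if sub.empty:
        raise ValueError(f"no control-arm data inside segment {segment.label}")

    codes, genes = pd.factorize(sub["gene"], sort=True)
    x = sub["div"].to_numpy(float)
    value = sub["value"].to_numpy(float)
    valid = np.isfinite(value) & (value > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(valid, np.log2(np.where(valid, value, 1.0)), 0.0)
    xv = np.where(valid, x, 0.0)
    w = valid.astype(float)
    m = len(genes)
    n = np.bincount(codes, weights=w, minlength=m)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = np.bincount(codes, weights=xv, minlength=m) / n
        mean_y = np.bincount(codes, weights=y, minlength=m) / n
    cx = np.where(valid, x - mean_x[codes], 0.0)
    cy = np.where(valid, y - mean_y[codes], 0.0)
    varx = np.bincount(codes, weights=cx * cx, minlength=m)
    vary = np.bincount(codes, weights=cy * cy, minlength=m)
    cov = np.bincount(codes, weights=cx * cy, minlength=m)
    # exact range test so that noiseless (bit-identical) replicates are flat
    ymin = np.full(m, np.inf)
    ymax = np.full(m, -np.inf)
    np.minimum.at(ymin, codes[valid], y[valid])
    np.maximum.at(ymax, codes[valid], y[valid])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(varx * vary)
    r = np.clip(r, -1.0, 1.0)
    zero_var = (ymax - ymin <= 0.0) | (varx <= 0.0)
    enough = n >= 3
    defined = enough & ~zero_var
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)), 0.0)
    p = np.where(defined, p, np.nan)
    r = np.where(defined, r, np.nan)
    direction = np.full(m, "ns", dtype=object)
    sig = defined & (p < alpha)
    direction[sig & (r > 0)] = "up"
    direction[sig & (r < 0)] = "down"
    for g in genes[~enough]:
        logger.warning("segment %s gene %s: fewer than 3 observations; marked ns",
                       segment.label, g)
    return pd.DataFrame(
        {"gene": genes, "direction": direction, "r": r, "p": p,
         "n_obs": n.astype(int)}
    )


def compute_index(
    expr: pd.DataFrame,
    classification: pd.DataFrame,
    segment: Segment,
    control_arm: str = "DMSO",
    arms: tuple | None = None,
    arm_col: str = "treatment",
    scale: str = "linear",
) -> pd.DataFrame:
    """Replicate-level developmental index for every arm in a segment.

    Each gene's fold change is first divided by that gene's mean fold
    change over the control arm within the segment (equal-weight
    rescaling); the index of a sample is mean(rescaled up-set) /
    mean(rescaled down-set).  With ``scale='log'`` the means are geometric,
    which makes log2(index) exactly linear in the latent maturation clock
    of the synthetic model.  The control-derived gene sets and rescaling
    constants are applied unchanged to every other arm.
    """
    if scale not in ("linear", "log"):
        raise ValueError("scale must be 'linear' or 'log'")
    up = classification.loc[classification["direction"] == "up", "gene"].tolist()
    down = classification.loc[classification["direction"] == "down", "gene"].tolist()
    if not up or not down:
        raise NonEvaluableSegmentError(
            f"segment {segment.label}: empty {'up' if not up else 'down'}-set"
        )
    ctrl = _segment_control(expr, segment, control_arm, arm_col)
    if scale == "linear":
        rescale = ctrl.groupby("gene")["value"].mean()
    else:
        rescale = np.exp2(ctrl.groupby("gene")["value"].apply(lambda v: np.log2(v).mean()))
    if rescale.reindex(up + down).isna().any():
        raise NonEvaluableSegmentError(
            f"segment {segment.label}: missing control-arm rescaling constant"
        )

    mask = segment.contains(expr["div"]) & expr["gene"].isin(up + down)
    if arms is not None:
        mask &= expr[arm_col].isin(arms)
    sub = expr.loc[mask, [arm_col, "div", "replicate", "gene", "value"]]

    sample_codes, samples = pd.factorize(
        pd.MultiIndex.from_frame(sub[[arm_col, "div", "replicate"]]), sort=True
    )
    in_up = sub["gene"].isin(up).to_numpy()
    rescaled = sub["value"].to_numpy(float) / sub["gene"].map(rescale).to_numpy(float)
    valid = np.isfinite(rescaled)
    contrib = np.log2(np.where(valid, rescaled, 1.0)) if scale == "log" else rescaled
    n_samples = len(samples)
    # group index: sample x {up, down}
    grp = sample_codes * 2 + (~in_up).astype(int)
    w = valid.astype(float)
    sums = np.bincount(grp, weights=np.where(valid, contrib, 0.0), minlength=2 * n_samples)
    counts = np.bincount(grp, weights=w, minlength=2 * n_samples)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = (sums / counts).reshape(n_samples, 2)
    if scale == "log":
        index = np.exp2(means[:, 0] - means[:, 1])
    else:
        index = means[:, 0] / means[:, 1]
    out = pd.DataFrame(
        {
            arm_col: samples.get_level_values(0),
            "segment": segment.label,
            "div": samples.get_level_values(1),
            "replicate": samples.get_level_values(2),
            "index": index,
        }
    )
    out.attrs["gene_sets"] = {"up": up, "down": down}
    out.attrs["rescale_constants"] = rescale.reindex(up + down).to_dict()
    return out


def fit_segment_slopes(
    series: pd.DataFrame,
    arm: str,
    segment: Segment | None = None,
    arm_col: str = "treatment",
    value_col: str = "index",
) -> float:
    """OLS slope of the index against day for one arm within a segment."""
    sub = series[series[arm_col] == arm]
    if segment is not None:
        if "segment" in sub.columns:
            sub = sub[sub["segment"] == segment.label]
        else:
            sub = sub[segment.contains(sub["div"])]
    sub = sub.dropna(subset=[value_col])
    if sub["div"].nunique() < 2:
        raise ValueError("slope requires index values at >= 2 distinct days")
    res = stats.linregress(sub["div"].to_numpy(float), sub[value_col].to_numpy(float))
    return float(res.slope)


def compare_slopes_ancova(
    series: pd.DataFrame,
    segment: Segment,
    control_arm: str = "DMSO",
    treated_arm: str = "ALLO",
    arm_col: str = "treatment",
    value_col: str = "index",
) -> SlopeComparison:
    """F-test of the day×arm interaction in index ~ day + arm + day×arm.

    Slopes per arm are read off the full model.  A fit with (numerically)
    zero residual variance is flagged degenerate: the interaction p is 0
    when the interaction carries real sum of squares, 1 when it does not —
    a noiseless pair of arms with equal slopes is *not* a detection.
    """
    sub = series[series["segment"] == segment.label].dropna(subset=[value_col])
    for arm in (control_arm, treated_arm):
        if sub.loc[sub[arm_col] == arm, "div"].nunique() < 2:
            return SlopeComparison(
                segment=segment, evaluable=False,
                error=f"arm {arm!r} lacks >= 2 distinct days in {segment.label}",
            )
    day = sub["div"].to_numpy(float)
    y = sub[value_col].to_numpy(float)
    treated = (sub[arm_col] == treated_arm).to_numpy(float)
    X_full = np.column_stack([np.ones_like(day), day, treated, day * treated])
    X_red = X_full[:, :3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.OLS(y, X_full).fit()
        red = sm.OLS(y, X_red).fit()
    slope_control = float(full.params[1])
    slope_treated = float(full.params[1] + full.params[3])
    tss = float(np.sum((y - y.mean()) ** 2))
    scale = max(tss, 1.0)
    ss_int = max(float(red.ssr - full.ssr), 0.0)
    if full.ssr <= _DEGENERATE_RTOL * scale:
        if ss_int > _DEGENERATE_RTOL * scale:
            F, p = np.inf, 0.0
        else:
            F, p = 0.0, 1.0
        return SlopeComparison(segment, slope_control, slope_treated, F, p,
                               evaluable=True, degenerate=True)
    df_resid = full.df_resid
    F = ss_int / (full.ssr / df_resid)
    p = float(stats.f.sf(F, 1, df_resid))
    return SlopeComparison(segment, slope_control, slope_treated, float(F), p,
                           evaluable=True)


def run_devindex_pipeline(
    expr: pd.DataFrame,
    config: PanelConfig,
    control_arm: str = "DMSO",
    treated_arm: str = "ALLO",
    arm_col: str = "treatment",
    index_scale: str = "log",
    per_day_mean: bool = False,
) -> DevIndexResult:
    """Classify → index → ANCOVA for every configured segment.

    Segments run independently: an error in one (for example an empty up-
    or down-set) is recorded on its SlopeComparison and the others still
    run.  ``per_day_mean`` averages replicate indices per day before slope
    fitting and testing.

    ``index_scale`` controls the averaging inside the index and the scale
    on which slopes are fitted and compared.  The default ``'log'`` uses
    geometric means and models log2(index) against day: on this scale the
    index is linear in the latent maturation clock, its replicate noise is
    homoscedastic, and the interaction F-test holds its nominal level.
    ``'linear'`` uses arithmetic means and tests the raw ratio.
    """
    segments = list(config.segments) or default_segments()
    classifications, gene_sets, rescale_constants = {}, {}, {}
    all_series, comparisons = [], []
    for seg in segments:
        try:
            cls = classify_segment_genes(expr, seg, control_arm, config.alpha, arm_col)
            classifications[seg.label] = cls
            series = compute_index(
                expr, cls, seg, control_arm,
                arms=(control_arm, treated_arm), arm_col=arm_col, scale=index_scale,
            )
            gene_sets[seg.label] = series.attrs["gene_sets"]
            rescale_constants[seg.label] = series.attrs["rescale_constants"]
            all_series.append(series)
            test_series = series
            value_col = "index"
            if per_day_mean:
                test_series = (
                    series.groupby([arm_col, "segment", "div"], sort=True)["index"]
                    .mean().reset_index()
                )
                test_series["replicate"] = 1
            if index_scale == "log":
                test_series = test_series.assign(log2_index=np.log2(test_series["index"]))
                value_col = "log2_index"
            comparisons.append(
                compare_slopes_ancova(
                    test_series, seg, control_arm, treated_arm, arm_col, value_col
                )
            )
        except (NonEvaluableSegmentError, ValueError) as exc:
            logger.warning("segment %s not evaluable: %s", seg.label, exc)
            comparisons.append(SlopeComparison(segment=seg, evaluable=False,
                                               error=str(exc)))
    index_series = (
        pd.concat(all_series, ignore_index=True) if all_series
        else pd.DataFrame(columns=[arm_col, "segment", "div", "replicate", "index"])
    )
    return DevIndexResult(
        classifications=classifications,
        index_series=index_series,
        slope_comparisons=comparisons,
        gene_sets=gene_sets,
        rescale_constants=rescale_constants,
        alpha=config.alpha,
        index_scale=index_scale,
    )
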