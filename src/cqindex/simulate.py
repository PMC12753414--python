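"""Synthetic Cq-table generator with a latent maturation clock.

The generator emulates an organoid RT-qPCR time course: a panel of
developmentally regulated transcripts plus a housekeeping gene, assayed at
fixed days in vitro (DIV) in two treatment arms, with replicate-level
Gaussian noise on the ΔCq (log-expression) scale.  The treatment phenotype
is a *developmental delay*: after the treatment compound is withdrawn, the
treated arm's latent maturation clock advances at a reduced rate
(slope scaled by 1−δ) inside a recovery window, after which the clock rate
recovers but the accumulated lag persists as a constant offset.  Because
every per-gene trend is linear in the clock, the ground truth "which
segments carry a slope difference" is available in closed form for
recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Treatment-arm labels used in emitted tables.  The control arm carries the
#: vehicle (DMSO); the treated arm the neurosteroid (ALLO).
CONTROL_ARM = "DMSO"
TREATED_ARM = "ALLO"

#: qPCR run length in cycles; a reaction that has not amplified by this
#: cycle is not detected.
RUN_LENGTH_CYCLES = 40.0


@dataclass(frozen=True)
class GeneTrendSpec:
    """Latent linear maturation trend of one transcript.

    ``slope`` is in Cq cycles per maturation unit (one unit = one control-arm
    day).  A *negative* slope means the ΔCq falls over time, i.e. expression
    rises as the culture matures.
    """

    gene: str
    baseline_dcq: float
    slope: float
    flat: bool = None  # type: ignore[assignment]

    def __post_init__(self):
        if not np.isfinite(self.baseline_dcq) or not np.isfinite(self.slope):
            raise ValueError(f"{self.gene}: baseline_dcq and slope must be finite")
        if self.flat is None:
            object.__setattr__(self, "flat", self.slope == 0.0)
        elif self.flat != (self.slope == 0.0):
            raise ValueError(f"{self.gene}: flat flag inconsistent with slope={self.slope}")

    @property
    def direction(self) -> str:
        """Expected trend call: 'up', 'down', or 'ns' for a flat gene."""
        if self.flat:
            return "ns"
        return "up" if self.slope < 0 else "down"


@dataclass(frozen=True)
class SimDesign:
    """Sampling design of the simulated time course."""

    divs: tuple = (0, 26, 55, 78, 95, 138)
    n_reps: int = 3
    exposure_window: tuple = (28, 67)
    delay_window: tuple = (67, 95)
    delta: float = 0.0
    noise_sd: float = 0.3
    seed: int = 0
    housekeeping_gene: str = "GAPDH"
    housekeeping_cq: float = 20.0
    housekeeping_noise_sd: float = 0.0
    organoid_type: str = "VCO"
    n_reps_by_div: Mapping[int, int] | None = None

    def __post_init__(self):
        divs = tuple(self.divs)
        object.__setattr__(self, "divs", divs)
        if any(b <= a for a, b in zip(divs, divs[1:])):
            raise ValueError("divs must be strictly increasing")
        if any(d < 0 for d in divs):
            raise ValueError("divs must be non-negative")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.noise_sd < 0 or self.housekeeping_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        day_on, day_off = self.exposure_window
        off, recover = self.delay_window
        if not (day_on < day_off):
            raise ValueError("exposure_window must satisfy day_on < day_off")
        if not (off < recover):
            raise ValueError("delay_window must satisfy day_off < day_recover")
        if off != day_off:
            raise ValueError("delay window must start at the withdrawal day")

    def reps_at(self, div: int) -> int:
        if self.n_reps_by_div and div in self.n_reps_by_div:
            n = int(self.n_reps_by_div[div])
            if n < 2:
                raise ValueError(f"replicate override at DIV{div} must be >= 2")
            return n
        return self.n_reps


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters and the latent clock, kept as ground truth."""

    gene_specs: tuple
    design: SimDesign

    def __post_init__(self):
        object.__setattr__(self, "gene_specs", tuple(self.gene_specs))
        names = [g.gene for g in self.gene_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in panel")
        if self.design.housekeeping_gene in names:
            raise ValueError("housekeeping gene must not appear in the panel")

    def clock(self, day, arm: str):
        return maturation_clock(day, arm, self.design)

    @property
    def genes(self) -> list:
        return [g.gene for g in self.gene_specs]

    def expected_direction(self) -> dict:
        """gene -> 'up' | 'down' | 'ns' from the latent slopes."""
        return {g.gene: g.direction for g in self.gene_specs}

    def to_params(self) -> dict:
        """Flat, text-serializable record of every generator parameter."""
        d = dataclasses.asdict(self.design)
        d["n_reps_by_div"] = dict(self.design.n_reps_by_div or {})
        d["genes"] = {
            g.gene: {"baseline_dcq": g.baseline_dcq, "slope": g.slope, "flat": g.flat}
            for g in self.gene_specs
        }
        return d


def maturation_clock(day, arm: str, design: SimDesign):
    """Latent maturation units accrued by ``day`` in the given arm.

    Control: identity (one unit per day).  Treated: identity up to the
    withdrawal day; inside (day_off, day_recover] the rate is scaled by
    1−δ; past day_recover the rate is 1 again, so the accumulated lag
    δ·(day_recover−day_off) persists as a constant offset.
    """
    day_arr = np.asarray(day, dtype=float)
    if np.any(day_arr < 0):
        raise ValueError("day must be >= 0")
    if arm not in (CONTROL_ARM, TREATED_ARM, "control", "treated"):
        raise ValueError(f"unknown arm {arm!r}")
    if arm in (CONTROL_ARM, "control"):
        out = day_arr
    else:
        day_off, day_recover = design.delay_window
        slowed = day_off + (1.0 - design.delta) * (day_arr - day_off)
        at_recover = day_off + (1.0 - design.delta) * (day_recover - day_off)
        out = np.where(
            day_arr <= day_off,
            day_arr,
            np.where(day_arr <= day_recover, slowed, at_recover + (day_arr - day_recover)),
        )
    return out.item() if np.isscalar(day) or np.ndim(day) == 0 else out


def simulate_cq_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Draw one replicate-level Cq table from the generative model.

    One row per (arm, day, replicate, gene), housekeeping gene included.
    Gene ΔCq = baseline + slope·clock(day, arm) + N(0, noise_sd²); gene
    Cq = housekeeping Cq + ΔCq, clipped at the 40-cycle run length; clipped
    rows carry ``detected = False`` (and exactly those rows sit on the
    bound).  Identical seeds give identical tables.
    """
    design = truth.design
    rng = np.random.default_rng(design.seed)
    genes = truth.genes
    baselines = np.array([g.baseline_dcq for g in truth.gene_specs])
    slopes = np.array([g.slope for g in truth.gene_specs])

    records = []
    for arm in (CONTROL_ARM, TREATED_ARM):
        for div in design.divs:
            clock = maturation_clock(div, arm, design)
            mean_dcq = baselines + slopes * clock
            for rep in range(1, design.reps_at(div) + 1):
                hk_cq = design.housekeeping_cq
                if design.housekeeping_noise_sd > 0:
                    hk_cq += rng.normal(0.0, design.housekeeping_noise_sd)
                dcq = mean_dcq + rng.normal(0.0, design.noise_sd, size=len(genes))
                sample = f"{design.organoid_type}_{arm}_d{div}_r{rep}"
                records.append((sample, arm, div, rep, design.housekeeping_gene, hk_cq))
                for g, v in zip(genes, hk_cq + dcq):
                    records.append((sample, arm, div, rep, g, v))

    df = pd.DataFrame.from_records(
        records, columns=["sample_id", "treatment", "div", "replicate", "gene", "cq"]
    )
    df.insert(1, "organoid_type", design.organoid_type)
    clipped = df["cq"].to_numpy() >= RUN_LENGTH_CYCLES
    df["cq"] = np.where(clipped, RUN_LENGTH_CYCLES, df["cq"].to_numpy())
    df["detected"] = ~clipped
    return df


def _default_panel() -> tuple:
    """23-transcript neuronal-development panel with mixed trends.

    Slopes (Cq cycles per day) are sized so each regulated transcript
    spans 10–18 cycles (2^10–2^18-fold) across the 138-day course — the
    dynamic range of maturation markers that move between undetectable
    and robustly expressed — which keeps per-gene trend classification
    unambiguous at n = 3 replicates with 0.3-cycle noise even in the
    shortest (17-day) segment.  Baselines keep every Cq inside the
    (0, 40] run window.  Rising genes (negative slope): immature/mature
    neuron and interneuron markers.  Falling genes: proliferation /
    neuroepithelial / radial-glia markers.  Flat genes: region-identity
    markers held constant.
    """
    up = [
        ("DCX", 14.5, -0.115), ("TUBB3", 13.0, -0.100), ("RBFOX3", 16.0, -0.125),
        ("MAP2", 12.5, -0.095), ("ENO2", 14.0, -0.110), ("SYP", 16.5, -0.130),
        ("NEFM", 13.5, -0.105), ("NEFL", 12.0, -0.090), ("DLG4", 11.5, -0.085),
        ("CALB2", 15.5, -0.120), ("GAD1", 14.8, -0.115), ("GAD2", 14.2, -0.108),
        ("SST", 16.2, -0.128), ("PVALB", 11.0, -0.082),
    ]
    down = [
        ("SOX2", 2.0, 0.095), ("PCNA", 1.8, 0.100), ("NES", 2.2, 0.085),
        ("VIM", 1.6, 0.080), ("SLC1A3", 2.5, 0.075), ("ASCL1", 2.8, 0.090),
    ]
    flat = [("FOXG1", 5.0, 0.0), ("NR2F2", 6.0, 0.0), ("TTF1", 7.0, 0.0)]
    return tuple(GeneTrendSpec(g, b, s) for g, b, s in up + down + flat)


PRESETS = ("null", "withdrawal_delay")


def preset(name: str, seed: int = 0, **design_overrides) -> SyntheticTruth:
    """Named study conditions.

    ``null``: the default 23-gene panel with δ = 0 — the two arms are
    exchangeable, for calibration tests.  ``withdrawal_delay``: the same
    panel with δ = 0.5 and the default post-withdrawal delay window
    DIV67–95, emulating a treatment-arm maturation delay that resolves
    (in rate) by the final collection day.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")
    delta = 0.5 if name == "withdrawal_delay" else 0.0
    design = SimDesign(delta=delta, seed=seed, **design_overrides)
    return SyntheticTruth(gene_specs=_default_panel(), design=design)
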