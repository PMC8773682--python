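"""Plate-level quantification and statistics.

Percent NETosis per well is the paper-standard readout: 100 x (NET-forming
cells) / (total Hoechst-positive, non-border cells), with fields pooled
within the well.  Wells are the statistical replicate; group comparisons use
an unpaired two-sample t test (two groups; equal-variance by default, Welch
optional) or a one-way ANOVA F test (more than two groups), with the usual
significance stars at p < 0.05 / 0.01 / 0.001.  p-values are unadjusted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import CellClass
from .features import CellRecord
from .imaging_io import PlateLayout

SUMMARY_COLUMNS = [
    "well_id", "treatment", "n_total", "n_net", "n_other_death", "n_live",
    "pct_net", "pct_other_death", "pct_live",
]


class StatTest(str, enum.Enum):
    UNPAIRED_T = "UNPAIRED_T"
    ONE_WAY_ANOVA = "ONE_WAY_ANOVA"


@dataclass
class WellSummary:
    well_id: str
    treatment: str
    n_total: int
    n_net: int
    n_other_death: int
    n_live: int
    pct_net: Optional[float]
    pct_other_death: Optional[float]
    pct_live: Optional[float]
    n_necrotic: Optional[int] = None
    n_apoptotic: Optional[int] = None
    pct_necrotic: Optional[float] = None
    pct_apoptotic: Optional[float] = None
    fields_used: int = 0


@dataclass
class GroupComparison:
    test: StatTest
    statistic: float
    p_value: float
    stars: str
    group_means: list[float] = field(default_factory=list)
    group_sems: list[float] = field(default_factory=list)
    group_sizes: list[int] = field(default_factory=list)


_NET_CLASSES = {CellClass.TYPE1_NET, CellClass.NET}
_LIVE_CLASSES = {CellClass.TYPE3_LIVE, CellClass.LIVE}


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_well(
    records: Sequence[CellRecord],
    classes: Sequence[CellClass],
    well_id: str,
    treatment: str = "",
) -> WellSummary:
    """Counts and percentages for one well, pooling its fields.

    Border objects are dropped here (their class, if provided, is ignored),
    so ``n_total`` is the Hoechst-positive non-border population.  An empty
    well yields ``n_total = 0`` with percentages flagged undefined (None).
    """
    if len(records) != len(classes):
        raise ValueError("records and classes must be aligned")
    kept = [
        (r, c) for r, c in zip(records, classes)
        if r.well_id == well_id and not r.border
    ]
    n_total = len(kept)
    n_net = sum(1 for _, c in kept if c in _NET_CLASSES)
    n_live = sum(1 for _, c in kept if c in _LIVE_CLASSES)
    n_necrotic = sum(1 for _, c in kept if c is CellClass.NECROTIC)
    n_apoptotic = sum(1 for _, c in kept if c is CellClass.APOPTOTIC)
    n_other = n_total - n_net - n_live
    four_channel = any(
        c in {CellClass.NECROTIC, CellClass.APOPTOTIC, CellClass.NET,
              CellClass.LIVE}
        for _, c in kept
    )

    def pct(k: int) -> Optional[float]:
        return None if n_total == 0 else 100.0 * k / n_total

    fields_used = len({r.field_index for r, _ in kept})
    return WellSummary(
        well_id=well_id,
        treatment=treatment,
        n_total=n_total,
        n_net=n_net,
        n_other_death=n_other,
        n_live=n_live,
        pct_net=pct(n_net),
        pct_other_death=pct(n_other),
        pct_live=pct(n_live),
        n_necrotic=n_necrotic if four_channel else None,
        n_apoptotic=n_apoptotic if four_channel else None,
        pct_necrotic=pct(n_necrotic) if four_channel else None,
        pct_apoptotic=pct(n_apoptotic) if four_channel else None,
        fields_used=fields_used,
    )


class ResponseAxis(str, enum.Enum):
    CONCENTRATION = "CONCENTRATION"
    TIME = "TIME"


def build_response_table(
    summaries: Sequence[WellSummary],
    layout: PlateLayout,
    axis: ResponseAxis = ResponseAxis.CONCENTRATION,
    axis_values: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Dose- or time-response table: mean +/- SEM of the class percentages
    over replicate wells at each axis value, sorted ascending.

    For a CONCENTRATION axis the value comes from the plate layout; for a
    TIME axis (or any custom grouping) pass ``axis_values`` mapping well_id
    to its axis value.  SEM is sample SD / sqrt(n), NaN for n = 1.
    """
    rows = []
    for s in summaries:
        if axis_values is not None:
            if s.well_id not in axis_values:
                raise KeyError(f"no axis value for well {s.well_id}")
            v = axis_values[s.well_id]
        else:
            try:
                v = layout.well(s.well_id).concentration
            except KeyError:
                raise KeyError(f"well {s.well_id} missing from plate layout")
        rows.append(
            {"axis_value": v, "pct_net": s.pct_net,
             "pct_other_death": s.pct_other_death, "pct_live": s.pct_live}
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("axis_value")
        .agg(
            pct_net_mean=("pct_net", "mean"),
            pct_net_sem=("pct_net", "sem"),
            pct_other_death_mean=("pct_other_death", "mean"),
            pct_other_death_sem=("pct_other_death", "sem"),
            pct_live_mean=("pct_live", "mean"),
            pct_live_sem=("pct_live", "sem"),
            n_wells=("pct_net", "size"),
        )
        .reset_index()
        .sort_values("axis_value", ignore_index=True)
    )
    return out


def compare_groups(
    *group_values: Sequence[float], welch: bool = False
) -> GroupComparison:
    """Unpaired t test (two groups) or one-way ANOVA (more groups) on
    per-well percentages."""
    if len(group_values) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=np.float64) for g in group_values]
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2 replicate wells")
    means = [float(g.mean()) for g in groups]
    sems = [float(stats.sem(g)) for g in groups]
    sizes = [len(g) for g in groups]
    if len(groups) == 2:
        res = stats.ttest_ind(groups[0], groups[1], equal_var=not welch)
        test = StatTest.UNPAIRED_T
    else:
        res = stats.f_oneway(*groups)
        test = StatTest.ONE_WAY_ANOVA
    statistic = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(p):        # identical constant groups: no evidence at all
        statistic, p = 0.0, 1.0
    return GroupComparison(
        test=test, statistic=statistic, p_value=p,
        stars=significance_stars(p),
        group_means=means, group_sems=sems, group_sizes=sizes,
    )
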