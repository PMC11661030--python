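"""Per-animal intensities -> dose-point x gene log2-ratio matrix.

The transformation follows the study's analysis order exactly:

1. log2-transform raw fluorescence intensities (variance stabilization);
2. for each treated animal and gene, subtract the arithmetic mean of the
   matching concurrent vehicle-control group's log2 values (so each control
   group has mean ratio exactly 0 by construction);
3. average the per-rat ratios within each (chemical, dose, time) group.

Step 2 before step 3 matters: plotted points are averages of individual
animal ratios, not ratios of group means.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError
from .types import (
    DoseLevel,
    ExpressionTable,
    GenePanel,
    RatioMatrix,
    Scale,
    TimePoint,
    dose_point_id,
)


def log2_transform(table: ExpressionTable) -> ExpressionTable:
    """Return *table* on the log2 scale; a no-op if it is there already."""
    if table.scale is Scale.LOG2:
        return table
    if (table.data["value"] <= 0).any():
        raise DomainError("cannot log2-transform non-positive intensities")
    df = table.data.copy()
    df["value"] = np.log2(df["value"])
    return ExpressionTable(df, scale=Scale.LOG2)


def ratios_vs_control(
    table: ExpressionTable, shared_control: bool = False
) -> pd.DataFrame:
    """Per-rat log2 ratios against the concurrent control-group mean.

    Returns a long frame with columns ``chemical, dose, time, replicate,
    gene, ratio``, covering control animals too (a control group's ratios
    are its deviations from its own mean, which therefore average to 0).

    With ``shared_control=True`` the control group is matched on time point
    only — for synthetic designs with one common vehicle group.
    """
    table = log2_transform(table)
    df = table.data
    ctrl = df[df["dose"] == DoseLevel.CONTROL]
    if ctrl.empty:
        raise DesignError("no control animals in the table")
    ctrl_key = ["time", "gene"] if shared_control else ["chemical", "time", "gene"]
    ctrl_means = ctrl.groupby(ctrl_key, observed=True)["value"].mean()

    join_key = ctrl_key
    merged = df.merge(
        ctrl_means.rename("control_mean"),
        left_on=join_key,
        right_index=True,
        how="left",
    )
    if merged["control_mean"].isna().any():
        bad = merged.loc[merged["control_mean"].isna()].iloc[0]
        raise DesignError(
            "missing control group for "
            f"(chemical={bad['chemical']}, time={bad['time'].value})"
        )
    merged["ratio"] = merged["value"] - merged["control_mean"]
    return merged[["chemical", "dose", "time", "replicate", "gene", "ratio"]]


def aggregate_replicates(
    ratios: pd.DataFrame, panel: GenePanel | None = None
) -> RatioMatrix:
    """Average per-rat ratios into one row per treated dose point."""
    if ratios.empty:
        raise DomainError("no per-rat ratios to aggregate")
    treated = ratios[ratios["dose"] != DoseLevel.CONTROL]
    if treated.empty:
        raise DomainError("no treated dose groups to aggregate")
    grouped = (
        treated.groupby(["chemical", "dose", "time", "gene"], observed=True)["ratio"]
        .agg(["mean", "count"])
        .reset_index()
    )
    grouped["dose_point"] = [
        dose_point_id(c, d, t)
        for c, d, t in zip(grouped["chemical"], grouped["dose"], grouped["time"])
    ]
    wide = grouped.pivot(index="dose_point", columns="gene", values="mean")
    wide.columns.name = None
    # preserve first-appearance row order rather than alphabetical
    order = list(dict.fromkeys(grouped["dose_point"]))
    wide = wide.loc[order]
    n_rep = (
        grouped.groupby("dose_point", observed=True)["count"].min().loc[order].astype(int)
    )
    matrix = RatioMatrix(wide, n_replicates=n_rep)
    if panel is not None:
        matrix = matrix.reorder_to_panel(panel)
    return matrix


def expression_to_ratios(
    table: ExpressionTable,
    panel: GenePanel | None = None,
    time_point: TimePoint | None = None,
    shared_control: bool = False,
) -> RatioMatrix:
    """Full preprocessing: log2 -> per-rat ratios -> dose-group means."""
    if time_point is not None:
        df = table.data[table.data["time"] == TimePoint(time_point)]
        table = ExpressionTable(df, scale=table.scale)
    if panel is not None:
        table.require_panel(panel)
        keep = {g.lower() for g in panel.genes}
        df = table.data[table.data["gene"].str.lower().isin(keep)].copy()
        canon = {g.lower(): g for g in panel.genes}
        df["gene"] = df["gene"].str.lower().map(canon)
        table = ExpressionTable(df, scale=table.scale)
    ratios = ratios_vs_control(table, shared_control=shared_control)
    return aggregate_replicates(ratios, panel=panel)
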