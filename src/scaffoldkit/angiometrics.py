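"""Angiogenesis and histomorphometry measurement arithmetic.

Covers the quantitative endpoints of a chorioallantoic-membrane (CAM)
implantation assay — vascular index (fold change in vessel count 72 h after
implantation relative to the 0 h baseline), vessel length / network area
fold changes expressed as percent of baseline, and laser-speckle perfusion
change — plus the per-field histomorphometry summaries used on histological
sections: vessel density per mm^2, lamina propria thickness (mean of five
measurements taken 400 um apart), cell density, and relative membrane area
(red-stained collagen pixels as a percent of the field of view).

Vessel segmentation/counting itself is out of scope: these functions consume
already-counted tables.  Group-level hypothesis tests are delegated to
standard routines (scipy/statsmodels) and merely echoed in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VesselObservation",
    "PerfusionObservation",
    "HistoField",
    "vascular_index",
    "foldchange_percent",
    "perfusion_change_percent",
    "vessel_density",
    "lamina_thickness",
    "relative_membrane_area",
    "summarize_vessel_table",
    "compare_groups",
]

#: canonical column names for CAM observation tables
VESSEL_COLUMNS = [
    "group",
    "vessel_count_0h",
    "vessel_count_72h",
    "total_length_0h",
    "total_length_72h",
    "network_area_0h",
    "network_area_72h",
]


@dataclass(frozen=True)
class VesselObservation:
    """Paired 0 h / 72 h CAM vessel measurements for one embryo.

    Counts are dimensionless; lengths in mm; areas in mm^2.
    """

    vessel_count_0h: float
    vessel_count_72h: float
    total_length_0h: float
    total_length_72h: float
    network_area_0h: float
    network_area_72h: float
    group: str = ""

    def __post_init__(self) -> None:
        vals = (
            self.vessel_count_0h, self.vessel_count_72h,
            self.total_length_0h, self.total_length_72h,
            self.network_area_0h, self.network_area_72h,
        )
        if any(v < 0 for v in vals):
            raise ValueError("vessel measurements must be nonnegative")


@dataclass(frozen=True)
class PerfusionObservation:
    """Paired laser-speckle blood-flow velocities for one ROI (arbitrary
    perfusion units, identical at both time points)."""

    velocity_0h: float
    velocity_72h: float
    roi: str = ""

    def __post_init__(self) -> None:
        if self.velocity_0h < 0 or self.velocity_72h < 0:
            raise ValueError("velocities must be nonnegative")


@dataclass(frozen=True)
class HistoField:
    """Per-sample histomorphometry inputs.

    Only the fields a given metric needs must be provided; the rest default
    to None.  ``vessel_counts`` expects 10 fields of view and
    ``thickness_measurements_um`` 5 probes (400 um apart) unless explicitly
    overridden in the metric call.
    """

    vessel_counts: tuple | None = None
    field_area_mm2: float | None = None
    thickness_measurements_um: tuple | None = None
    cell_count: float | None = None
    red_pixel_area_mm2: float | None = None
    field_of_view_area_mm2: float | None = None
    label: str = ""


def _require_positive(name: str, value: float) -> None:
    if value is None or not (value > 0):
        raise ValueError(f"{name} must be > 0, got {value}")


def vascular_index(obs: VesselObservation) -> float:
    """Fold change in vessel count: count_72h / count_0h."""
    _require_positive("vessel_count_0h (baseline)", obs.vessel_count_0h)
    return obs.vessel_count_72h / obs.vessel_count_0h


def foldchange_percent(value_0h: float, value_72h: float) -> float:
    """Value at 72 h as a percent of the 0 h baseline (baseline = 100%)."""
    _require_positive("baseline value", value_0h)
    return 100.0 * value_72h / value_0h


def perfusion_change_percent(obs: PerfusionObservation) -> float:
    """Percent change in perfusion velocity: 100*(v72 - v0)/v0."""
    _require_positive("velocity_0h (baseline)", obs.velocity_0h)
    return 100.0 * (obs.velocity_72h - obs.velocity_0h) / obs.velocity_0h


def vessel_density(field: HistoField, n_fields: int = 10) -> float:
    """Mean vessel count per mm^2 over ``n_fields`` fields of view."""
    if field.vessel_counts is None:
        raise ValueError("vessel_counts missing")
    counts = np.asarray(field.vessel_counts, dtype=float)
    if counts.size != n_fields:
        raise ValueError(
            f"expected {n_fields} field counts, got {counts.size} "
            f"(missing fields: {max(n_fields - counts.size, 0)})"
        )
    if np.any(counts < 0):
        raise ValueError("vessel counts must be nonnegative")
    _require_positive("field_area_mm2", field.field_area_mm2)
    return float(np.mean(counts / field.field_area_mm2))


def lamina_thickness(field: HistoField, n_measurements: int = 5, allow_other_n: bool = False) -> float:
    """Mean lamina propria / submucosa thickness (um) over the standard five
    probes.  A different number of probes is rejected unless
    ``allow_other_n`` is set (a warning-level override)."""
    if field.thickness_measurements_um is None:
        raise ValueError("thickness_measurements_um missing")
    vals = np.asarray(field.thickness_measurements_um, dtype=float)
    if vals.size != n_measurements and not allow_other_n:
        raise ValueError(
            f"expected {n_measurements} thickness measurements, got {vals.size} "
            "(set allow_other_n=True to override)"
        )
    if vals.size == 0:
        raise ValueError("no thickness measurements")
    return float(vals.mean())


def relative_membrane_area(field: HistoField) -> float:
    """Residual membrane material as a percent of the field of view:
    100 * red-stained area / field-of-view area."""
    _require_positive("field_of_view_area_mm2", field.field_of_view_area_mm2)
    red = field.red_pixel_area_mm2
    if red is None or red < 0:
        raise ValueError(f"red_pixel_area_mm2 must be >= 0, got {red}")
    if red > field.field_of_view_area_mm2:
        raise ValueError("red pixel area exceeds the field of view area")
    return 100.0 * red / field.field_of_view_area_mm2


def _row_to_observation(row: pd.Series) -> VesselObservation:
    return VesselObservation(
        vessel_count_0h=row["vessel_count_0h"],
        vessel_count_72h=row["vessel_count_72h"],
        total_length_0h=row["total_length_0h"],
        total_length_72h=row["total_length_72h"],
        network_area_0h=row["network_area_0h"],
        network_area_72h=row["network_area_72h"],
        group=str(row.get("group", "")),
    )


def summarize_vessel_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row CAM metrics for a table with :data:`VESSEL_COLUMNS`.

    Returns the input plus ``vascular_index``, ``length_percent`` and
    ``area_percent`` columns (baseline = 100%).
    """
    missing = [c for c in VESSEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"vessel table is missing columns: {missing}")
    out = table.copy()
    obs = [_row_to_observation(r) for _, r in table.iterrows()]
    out["vascular_index"] = [vascular_index(o) for o in obs]
    out["length_percent"] = [
        foldchange_percent(o.total_length_0h, o.total_length_72h) for o in obs
    ]
    out["area_percent"] = [
        foldchange_percent(o.network_area_0h, o.network_area_72h) for o in obs
    ]
    return out


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    method: str = "kruskal",
) -> dict:
    """Omnibus group comparison on one metric column via standard routines.

    ``method='kruskal'`` runs the Kruskal–Wallis H test with pairwise
    Mann–Whitney U post hocs (Holm-adjusted); ``method='anova'`` runs a
    one-way ANOVA with pairwise Welch t post hocs (Holm-adjusted).
    """
    groups = {g: sub[metric].to_numpy(float) for g, sub in table.groupby(group_col)}
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    samples = [groups[g] for g in names]
    if method == "kruskal":
        stat, p = stats.kruskal(*samples)
        pair_test = lambda a, b: stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    elif method == "anova":
        stat, p = stats.f_oneway(*samples)
        pair_test = lambda a, b: stats.ttest_ind(a, b, equal_var=False).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw = [pair_test(groups[a], groups[b]) for a, b in pairs]
    adj = multipletests(raw, method="holm")[1] if raw else np.array([])
    return {
        "method": method,
        "metric": metric,
        "statistic": float(stat),
        "p_value": float(p),
        "groups": {g: int(len(groups[g])) for g in names},
        "pairwise": {f"{a} vs {b}": float(adj[i]) for i, (a, b) in enumerate(pairs)},
    }
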