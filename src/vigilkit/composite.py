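"""Integrated behavioral z-score composites.

Each raw behavioral variable is standardized against the control group,
z = (X - mu_control) / sd_control (sample, n-1, convention), for every
animal including controls.  A dimension composite is the mean over its
variables of direction * z, where the direction map encodes whether larger
raw values mean *more* of the dimension's construct (e.g. higher escape
probability -> more defensive behavior, direction +1; longer escape
latency -> less, direction -1).  Directions ship as explicit,
user-overridable configuration so sign conventions are never silent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

#: Default composite dimensions and their ordered variable lists.
DEFAULT_COMPOSITES: dict[str, list[str]] = {
    "nrem_active": [
        "time_in_nrem_active",
        "spindle_duration_active",
        "spindle_density_active",
        "nrem_bout_length_active",
    ],
    "nrem_inactive": [
        "time_in_nrem_inactive",
        "spindle_duration_inactive",
        "spindle_density_inactive",
        "nrem_bout_length_inactive",
    ],
    "risk_assessment": [
        "pct_protected_sap_epm",
        "nosepokes_light_ldb",
        "rearings_vlt",
        "pct_protected_headdips_epm",
    ],
    "defensive_behavior": [
        "escape_probability_vlt",
        "max_escape_speed_vlt",
        "immobility_duration_vlt",
        "escape_latency_vlt",
    ],
    "anxiety": [
        "pct_time_open_arms_epm",
        "latency_to_light_ldb",
        "entries_light_ldb",
        "time_in_light_ldb",
        "pct_time_center_oft",
        "time_in_trigger_zone_vlt_d2",
    ],
    "locomotion": [
        "distance_vlt_hab_d1",
        "distance_ldb",
        "closed_arm_entries_epm",
        "distance_epm",
        "distance_oft",
    ],
}

#: Whether larger raw values mean more of the dimension's construct.
DEFAULT_DIRECTIONS: dict[str, int] = {
    # more NREM sleep / longer, denser spindles / longer bouts -> more sleep
    "time_in_nrem_active": +1,
    "spindle_duration_active": +1,
    "spindle_density_active": +1,
    "nrem_bout_length_active": +1,
    "time_in_nrem_inactive": +1,
    "spindle_duration_inactive": +1,
    "spindle_density_inactive": +1,
    "nrem_bout_length_inactive": +1,
    # cautious information-gathering -> more risk assessment
    "pct_protected_sap_epm": +1,
    "nosepokes_light_ldb": +1,
    "rearings_vlt": +1,
    "pct_protected_headdips_epm": +1,
    # stronger/faster escape and more freezing -> more defensive behavior;
    # longer latency -> less
    "escape_probability_vlt": +1,
    "max_escape_speed_vlt": +1,
    "immobility_duration_vlt": +1,
    "escape_latency_vlt": -1,
    # open/lit/exposed-space avoidance -> more anxiety
    "pct_time_open_arms_epm": -1,
    "latency_to_light_ldb": +1,
    "entries_light_ldb": -1,
    "time_in_light_ldb": -1,
    "pct_time_center_oft": -1,
    "time_in_trigger_zone_vlt_d2": -1,
    # distance and entries -> more locomotion
    "distance_vlt_hab_d1": +1,
    "distance_ldb": +1,
    "closed_arm_entries_epm": +1,
    "distance_epm": +1,
    "distance_oft": +1,
}


def zscore_variables(
    table: pd.DataFrame,
    control_label: str = "control",
    group_column: str = "group",
) -> pd.DataFrame:
    """Standardize every numeric variable against the control group.

    Returns a table of the same shape (non-variable columns preserved)
    with z = (X - mu_control) / sd_control for all animals.  Variables
    whose control sd is zero, or with fewer than two non-missing control
    values, are excluded with a warning.
    """
    if group_column not in table.columns:
        raise ValidationError(f"table lacks a {group_column!r} column")
    control = table[table[group_column] == control_label]
    if control.empty:
        raise ValidationError(f"no rows with {group_column} == {control_label!r}")
    meta_cols = [c for c in table.columns if not pd.api.types.is_numeric_dtype(table[c])]
    out = table[meta_cols].copy()
    for col in table.columns:
        if col in meta_cols:
            continue
        cvals = control[col].dropna()
        if len(cvals) < 2:
            warnings.warn(
                f"variable {col!r}: fewer than 2 control values; excluded",
                stacklevel=2,
            )
            continue
        sd = cvals.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"variable {col!r}: control sd is 0; excluded", stacklevel=2
            )
            continue
        out[col] = (table[col] - cvals.mean()) / sd
    return out


def composite_scores(
    z_table: pd.DataFrame,
    composites: dict[str, list[str]] | None = None,
    directions: dict[str, int] | None = None,
    group_column: str = "group",
) -> pd.DataFrame:
    """Per-animal composite per dimension: the mean over available
    variables of direction * z (pairwise deletion of missing values; the
    count of contributing variables is reported).  An animal with every
    variable missing gets a missing composite."""
    composites = composites or DEFAULT_COMPOSITES
    directions = directions or DEFAULT_DIRECTIONS
    meta_cols = [c for c in z_table.columns if not pd.api.types.is_numeric_dtype(z_table[c])]
    out = z_table[meta_cols].copy()
    for dim, variables in composites.items():
        missing_dir = [v for v in variables if v not in directions]
        if missing_dir:
            raise ValidationError(
                f"dimension {dim!r}: no direction for {missing_dir}"
            )
        present = [v for v in variables if v in z_table.columns]
        if not present:
            continue
        directed = pd.DataFrame(
            {v: directions[v] * z_table[v] for v in present}
        )
        out[dim] = directed.mean(axis=1, skipna=True)
        out[f"{dim}_n_variables"] = directed.notna().sum(axis=1)
    return out


def compare_groups(
    scores: pd.DataFrame,
    dimensions: list[str],
    control_label: str = "control",
    treated_label: str | None = None,
    group_column: str = "group",
    method: str = "t",
) -> pd.DataFrame:
    """Two-group comparison per dimension (unpaired t or Mann-Whitney),
    with Cohen's d and group means.  Method selection from normality
    checks is left to the caller."""
    groups = scores[group_column].unique().tolist()
    if treated_label is None:
        others = [g for g in groups if g != control_label]
        if len(others) != 1:
            raise ValidationError(f"cannot infer treated group from {groups}")
        treated_label = others[0]
    rows = []
    for dim in dimensions:
        a = scores.loc[scores[group_column] == control_label, dim].dropna()
        b = scores.loc[scores[group_column] == treated_label, dim].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(f"dimension {dim!r}: each group needs >= 2 animals")
        if method == "t":
            stat, p = stats.ttest_ind(a, b)
        elif method == "mann_whitney":
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise ValidationError(f"unknown method {method!r}")
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        d = (b.mean() - a.mean()) / pooled if pooled > 0 else 0.0
        rows.append(
            {
                "dimension": dim,
                "method": method,
                "statistic": float(stat),
                "p_value": float(p),
                "control_mean": float(a.mean()),
                "treated_mean": float(b.mean()),
                "cohens_d": float(d),
            }
        )
    return pd.DataFrame(rows)
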