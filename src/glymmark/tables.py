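"""Printed cohort summary tables shipped as recomputable fixtures.

Two study cohorts are bundled: the ALPS-analysis cohort (21 PD with
anxiety / 47 PD without anxiety / 38 healthy controls) and the smaller
combined coupling+ALPS cohort (16/36/34).  Each table stores per-group
sample sizes, male/female counts and per-variable (mean, sd) pairs; the
summary-statistic layer in :mod:`glymmark.cohort_stats` can recompute
ANOVA F, two-sample t and chi-square statistics directly from them, and
the cohort generator in :mod:`glymmark.synthetic` uses them as defaults.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import yaml

GROUPS = ("PD-A", "PD-NA", "HC")
PD_GROUPS = ("PD-A", "PD-NA")

#: HAMA cut-off separating PD with anxiety from PD without anxiety.
HAMA_ANXIETY_CUTOFF = 14.0


def load_table(name: str) -> dict[str, Any]:
    """Load a bundled summary table (``"table1"`` or ``"table2"``)."""
    if name not in ("table1", "table2"):
        raise ValueError(f"unknown table {name!r}; expected 'table1' or 'table2'")
    text = resources.files("glymmark.data").joinpath(f"{name}.yaml").read_text()
    table = yaml.safe_load(text)
    _validate(table)
    return table


def _validate(table: dict[str, Any]) -> None:
    for g, n in table["groups"].items():
        if n < 2:
            raise ValueError(f"group {g} has n={n} < 2")
    for var, per_group in table["variables"].items():
        for g, (mean, sd) in per_group.items():
            if g not in table["groups"]:
                raise ValueError(f"{var}: unknown group {g}")
            if sd <= 0:
                raise ValueError(f"{var}/{g}: sd must be positive, got {sd}")


def group_summary(table: dict[str, Any], variable: str, group: str):
    """Return a :class:`~glymmark.cohort_stats.GroupSummary` for one cell."""
    from .cohort_stats import GroupSummary

    mean, sd = table["variables"][variable][group]
    return GroupSummary(label=group, n=table["groups"][group], mean=mean, sd=sd)


def group_summaries(table: dict[str, Any], variable: str) -> list:
    """All available group summaries for one variable, in table order."""
    return [
        group_summary(table, variable, g)
        for g in GROUPS
        if g in table["variables"][variable]
    ]


def sex_contingency(table: dict[str, Any]) -> list[list[int]]:
    """Male/female counts as a (groups x 2) contingency table."""
    return [list(table["sex_mf"][g]) for g in GROUPS if g in table["sex_mf"]]
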