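"""Published reference tables from the restraint-stress rat cohort.

The original study deposited no raw spectra; its printed tables are the
available data.  They ship here as small CSV files so the package's
biochemical and filtering operations can be exercised against the actual
published numbers:

* serum biochemistry panel: per-analyte group means ± SD for the
  non-stressed (n = 6) and stressed (n = 7) groups;
* per-metabolite OPLS-DA correlation coefficients across the eight
  tissue/biofluid comparisons (the discriminating-metabolite overview);
* serum XOR and XO enzyme-activity summaries per group.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .biochem import GroupSummary

__all__ = [
    "load_serum_biochemistry",
    "load_reported_correlations",
    "load_enzyme_activities",
    "serum_group_summaries",
    "N_CONTROL",
    "N_STRESSED",
]

#: Group sizes of the study design (non-stressed vs stressed).
N_CONTROL = 6
N_STRESSED = 7


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("stressnmr.data") / name) as path:
        return pd.read_csv(path)


def load_serum_biochemistry() -> pd.DataFrame:
    """Serum biochemistry panel: analyte, unit, per-group mean and SD."""
    return _read("serum_biochemistry.csv")


def load_reported_correlations() -> pd.DataFrame:
    """Long-format discriminating-metabolite correlations.

    Columns ``metabolite, comparison, r``: one row per non-empty entry of
    the published metabolite x comparison overview (comparisons are the
    stressed-vs-control contrasts per tissue/biofluid, e.g. ``brain_48h``,
    ``urine_24h``).  All printed entries exceed the 0.755 cutoff.
    """
    return _read("reported_correlations.csv")


def load_enzyme_activities() -> pd.DataFrame:
    """Serum XOR and XO activity summaries (U/mL) per group."""
    return _read("enzyme_activities.csv")


def serum_group_summaries(analyte: str) -> tuple[GroupSummary, GroupSummary]:
    """(control, stressed) summary statistics for one serum analyte."""
    df = load_serum_biochemistry().set_index("analyte")
    row = df.loc[analyte]
    return (
        GroupSummary(float(row["control_mean"]), float(row["control_sd"]), N_CONTROL),
        GroupSummary(float(row["stressed_mean"]), float(row["stressed_sd"]), N_STRESSED),
    )
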