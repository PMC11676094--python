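"""Significance cutoff on correlation loadings and the discriminating table.

A bin's correlation loading r (Pearson correlation between the OPLS-DA
predictive score and the bin intensity) is declared significant when |r|
exceeds a critical value; the default cutoff is the study-standard 0.755
(two-tailed p < 0.05 at 5 degrees of freedom), and a ``computed`` mode
derives the cutoff from any (alpha, df) via the t distribution.
Significant bins are collapsed to metabolites through a ppm-window
annotation, yielding a table of discriminating metabolites with signed r
(positive = elevated in the case group), plus recovery metrics against
synthetic ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignificanceRule",
    "DiscriminatingTable",
    "RecoveryReport",
    "critical_r",
    "annotation_from_templates",
    "assign_bins",
    "select_discriminating",
    "filter_correlation_table",
    "recovery_report",
]

#: Fixed cutoff adopted in the source study (|r| > 0.755 at df = 5, p < 0.05).
STUDY_R_CUTOFF = 0.755


def critical_r(alpha: float, df: int) -> float:
    """Two-tailed critical value of the Pearson correlation coefficient.

    Inverts the t test of a correlation: ``r_crit = t / sqrt(t^2 + df)``
    with ``t = t_{1 - alpha/2, df}``.  For alpha = 0.05 and df = 5 this is
    0.7545, the basis of the conventional 0.755 cutoff.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t / np.sqrt(t**2 + df))


@dataclass(frozen=True)
class SignificanceRule:
    """|r| threshold for declaring a bin/metabolite discriminating."""

    alpha: float = 0.05
    df: int = 5
    r_cutoff: float = STUDY_R_CUTOFF
    cutoff_source: str = "published_fixed"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not 0 < self.r_cutoff < 1:
            raise ValueError("r_cutoff must be in (0, 1)")

    @classmethod
    def computed(cls, alpha: float = 0.05, df: int = 5) -> "SignificanceRule":
        """Derive the cutoff from (alpha, df) instead of the fixed 0.755."""
        return cls(alpha=alpha, df=df, r_cutoff=critical_r(alpha, df),
                   cutoff_source="computed")

    def is_significant(self, r: np.ndarray | float) -> np.ndarray | bool:
        return np.abs(r) > self.r_cutoff


@dataclass
class DiscriminatingTable:
    """Discriminating metabolites for one comparison.

    ``rows`` has columns ``metabolite, comparison, r, bin_ppm`` where
    ``r`` is the signed correlation of maximal magnitude among the
    metabolite's significant bins and ``bin_ppm`` that bin's center (the
    auditable linkage back to the spectrum).
    """

    rows: pd.DataFrame
    rule: SignificanceRule = field(default_factory=SignificanceRule)
    unassigned: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["label", "comparison", "r", "bin_ppm"]))

    def __post_init__(self) -> None:
        for df in (self.rows, self.unassigned):
            if len(df):
                r = df["r"].to_numpy(dtype=float)
                if np.any(np.abs(r) > 1):
                    raise ValueError("correlations must lie in [-1, 1]")
                if np.any(np.abs(r) <= self.rule.r_cutoff):
                    raise ValueError("stored rows must all exceed the |r| cutoff")

    @property
    def metabolites(self) -> set[str]:
        return set(self.rows["metabolite"]) if len(self.rows) else set()

    def write(self, path) -> None:
        out = self.rows
        if len(self.unassigned):
            extra = self.unassigned.rename(columns={"label": "metabolite"})
            out = pd.concat([out, extra], ignore_index=True)
        out.to_csv(path, sep="\t", index=False)


def annotation_from_templates(
    templates: Sequence, half_window_ppm: float = 0.01
) -> pd.DataFrame:
    """Build a bin-to-metabolite annotation from the template library.

    One row per template peak: ``metabolite, center_ppm, ppm_low, ppm_high``
    with windows of ``+/- half_window_ppm`` around each line center.
    """
    rows = []
    for t in templates:
        for center, _height, _hw in t.peaks:
            rows.append(
                {
                    "metabolite": t.name,
                    "center_ppm": center,
                    "ppm_low": center - half_window_ppm,
                    "ppm_high": center + half_window_ppm,
                }
            )
    return pd.DataFrame(rows)


def assign_bins(bin_centers: np.ndarray, annotation: pd.DataFrame) -> list[str | None]:
    """Assign each bin center to at most one metabolite.

    A bin inside several (overlapping) windows goes to the window whose
    ``center_ppm`` is nearest — a deterministic tie-break for crowded
    regions.  Bins outside every window map to ``None``.
    """
    bin_centers = np.asarray(bin_centers, dtype=float)
    lows = annotation["ppm_low"].to_numpy(dtype=float)
    highs = annotation["ppm_high"].to_numpy(dtype=float)
    centers = annotation["center_ppm"].to_numpy(dtype=float)
    names = annotation["metabolite"].tolist()
    out: list[str | None] = []
    for c in bin_centers:
        inside = np.flatnonzero((c >= lows) & (c < highs))
        if inside.size == 0:
            out.append(None)
        else:
            nearest = inside[np.argmin(np.abs(centers[inside] - c))]
            out.append(names[nearest])
    return out


def select_discriminating(
    corr_loadings: np.ndarray,
    bin_centers: np.ndarray,
    annotation: pd.DataFrame,
    rule: SignificanceRule | None = None,
    comparison: str = "case_vs_control",
) -> DiscriminatingTable:
    """Collapse significant correlation loadings to a metabolite table.

    A metabolite is reported when any of its annotated bins has
    ``|r| > r_cutoff``; its reported r is the signed value of maximal
    magnitude among those bins.  Significant bins outside every annotation
    window are retained too — under ``unassigned δ x.xxx`` labels in the
    table's ``unassigned`` frame, with a warning — so nothing silently
    disappears, while the metabolite table proper stays interpretable.
    """
    rule = rule or SignificanceRule()
    r = np.asarray(corr_loadings, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if r.shape != bin_centers.shape:
        raise ValueError("corr_loadings and bin_centers must align")
    owners = assign_bins(bin_centers, annotation)

    best: dict[str, tuple[float, float]] = {}  # name -> (r, bin_ppm)
    orphans: list[dict] = []
    for ri, ci, owner in zip(r, bin_centers, owners):
        if not rule.is_significant(ri):
            continue
        if owner is None:
            orphans.append(
                {"label": f"unassigned δ {ci:.3f}", "comparison": comparison,
                 "r": float(ri), "bin_ppm": float(ci)}
            )
            continue
        if owner not in best or abs(ri) > abs(best[owner][0]):
            best[owner] = (float(ri), float(ci))
    if orphans:
        warnings.warn(
            f"{len(orphans)} significant bin(s) had no metabolite annotation",
            stacklevel=2,
        )
    rows = pd.DataFrame(
        [
            {"metabolite": name, "comparison": comparison, "r": rv, "bin_ppm": ppm}
            for name, (rv, ppm) in sorted(best.items())
        ],
        columns=["metabolite", "comparison", "r", "bin_ppm"],
    )
    unassigned = pd.DataFrame(
        orphans, columns=["label", "comparison", "r", "bin_ppm"]
    )
    return DiscriminatingTable(rows=rows, rule=rule, unassigned=unassigned)


def filter_correlation_table(
    table: pd.DataFrame, rule: SignificanceRule | None = None
) -> pd.DataFrame:
    """Apply the |r| cutoff to a transcribed per-metabolite correlation table.

    ``table`` needs columns ``metabolite`` and ``r`` (one row per metabolite
    x comparison entry); rows at or below the cutoff are dropped.  Used to
    re-derive the published discriminating-metabolite list from its printed
    correlations.
    """
    rule = rule or SignificanceRule()
    r = table["r"].to_numpy(dtype=float)
    return table.loc[np.abs(r) > rule.r_cutoff].reset_index(drop=True)


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the simulated ground truth."""

    true_positive_rate: float
    false_positive_count: int
    recovered: list[str]
    missed: list[str]
    false_positives: list[str]

    def as_dict(self) -> dict:
        return {
            "true_positive_rate": self.true_positive_rate,
            "false_positive_count": self.false_positive_count,
            "recovered": self.recovered,
            "missed": self.missed,
            "false_positives": self.false_positives,
        }


def recovery_report(
    table: DiscriminatingTable,
    ground_truth: pd.DataFrame | Mapping[str, float] | Sequence[str],
) -> RecoveryReport:
    """Score a discriminating table against known perturbed metabolites.

    TPR is the fraction of truly perturbed metabolites that appear in the
    table; the false-positive count is the number of reported *named*
    metabolites that were not perturbed (unassigned-bin entries are kept
    on the table's ``unassigned`` frame and do not enter either count).
    """
    if isinstance(ground_truth, pd.DataFrame):
        truth = set(ground_truth["metabolite"])
    elif isinstance(ground_truth, Mapping):
        truth = {m for m, fc in ground_truth.items() if fc != 1.0}
    else:
        truth = set(ground_truth)
    found = table.metabolites
    recovered = sorted(truth & found)
    missed = sorted(truth - found)
    false_pos = sorted(found - truth)
    tpr = len(recovered) / len(truth) if truth else 1.0
    return RecoveryReport(
        true_positive_rate=tpr,
        false_positive_count=len(false_pos),
        recovered=recovered,
        missed=missed,
        false_positives=false_pos,
    )
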