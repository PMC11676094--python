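"""Closed-form biochemical calculations.

Three small computations accompany the spectral pipeline:

* xanthine-oxidoreductase enzyme activity from paired 290-nm absorbance
  readings (Beer–Lambert based; XDH activity = total XOR − XO);
* unpaired two-tailed Student's t-tests computed directly from per-group
  summary statistics (mean, SD, n), as published tables report them;
* relative qPCR gene expression by the 2^−ΔΔCt method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EnzymeAssayConstants",
    "AbsorbanceReading",
    "GroupSummary",
    "CtQuartet",
    "TTestResult",
    "enzyme_activity",
    "xdh_from_xor_xo",
    "pooled_t_test",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class EnzymeAssayConstants:
    """Physical constants of the uric-acid formation assay.

    Defaults: 260 µL total reaction volume, uric-acid molar extinction
    1.22e4 L·mol⁻¹·cm⁻¹ at 290 nm, 0.6 cm optical path (96-well plate),
    10 µL serum sample, 30 min reaction.
    """

    v_total: float = 2.6e-4  # L
    epsilon: float = 1.22e4  # L / mol / cm
    d: float = 0.6  # cm
    v_sample: float = 0.01  # mL
    t: float = 30.0  # min

    def __post_init__(self) -> None:
        for name in ("v_total", "epsilon", "d", "v_sample", "t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class AbsorbanceReading:
    """Start/end absorbance pair at 290 nm for one well."""

    a_start: float
    a_end: float
    role: str = "test"  # "blank" or "test"
    with_nad: bool = True

    @property
    def delta_a(self) -> float:
        return self.a_end - self.a_start


def enzyme_activity(
    delta_a_test: float,
    delta_a_blank: float,
    constants: EnzymeAssayConstants | None = None,
) -> float:
    """Enzyme activity in U/mL from test and blank absorbance changes.

    activity = (ΔA_test − ΔA_blank) · V_total · 10⁶ / (ε · d · V_sample · T)

    One unit forms 1 µM of uric acid (in the reaction volume) per minute.
    A negative result is returned as-is with a warning — it signals an
    assay problem worth seeing, not a value to clip.
    """
    c = constants or EnzymeAssayConstants()
    if not (np.isfinite(delta_a_test) and np.isfinite(delta_a_blank)):
        raise ValueError("absorbance changes must be finite")
    activity = (
        (delta_a_test - delta_a_blank) * c.v_total * 1e6
        / (c.epsilon * c.d * c.v_sample * c.t)
    )
    if activity < 0:
        warnings.warn(f"negative enzyme activity ({activity:.4g} U/mL)", stacklevel=2)
    return activity


def xdh_from_xor_xo(xor_activity: float, xo_activity: float) -> float:
    """Xanthine dehydrogenase activity as total XOR minus XO.

    XOR is assayed with NAD⁺ (both forms active), XO without; the
    difference is the NAD-dependent dehydrogenase share.  Negative results
    are flagged but returned.
    """
    if not (np.isfinite(xor_activity) and np.isfinite(xo_activity)):
        raise ValueError("activities must be finite")
    xdh = xor_activity - xo_activity
    if xdh < 0:
        warnings.warn(f"negative XDH activity ({xdh:.4g} U/mL)", stacklevel=2)
    return xdh


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean, standard deviation and sample size for one analyte."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def pooled_t_test(
    g1: GroupSummary, g2: GroupSummary, welch: bool = False
) -> TTestResult:
    """Unpaired two-tailed Student's t-test from summary statistics.

    Default is the pooled-variance (equal-variance) Student test with
    df = n1 + n2 − 2, matching the convention of the statistics packages
    most wet-lab tables are computed with; ``welch=True`` switches to the
    unequal-variance Welch test with Satterthwaite df.
    """
    if g1.n + g2.n < 3:
        raise ValueError("need at least 3 observations in total")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            raise ValueError("both SDs are zero and means equal: t undefined")
        return TTestResult(t=np.inf if g1.mean > g2.mean else -np.inf,
                           df=g1.n + g2.n - 2, p=0.0)
    v1, v2 = g1.sd**2, g2.sd**2
    if welch:
        se2 = v1 / g1.n + v2 / g2.n
        df = se2**2 / (
            (v1 / g1.n) ** 2 / (g1.n - 1) + (v2 / g2.n) ** 2 / (g2.n - 1)
        )
        t = (g1.mean - g2.mean) / np.sqrt(se2)
    else:
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        t = (g1.mean - g2.mean) / np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


@dataclass(frozen=True)
class CtQuartet:
    """qPCR cycle thresholds for target and reference gene in both groups."""

    ct_target_case: float
    ct_ref_case: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_case", "ct_ref_case", "ct_target_control", "ct_ref_control"
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def ddct_fold_change(q: CtQuartet) -> float:
    """Relative expression fold change by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_ref)_case − (Ct_target − Ct_ref)_control,
    normalising the target gene to a housekeeping reference and the case
    condition to the control; one PCR cycle corresponds to a factor of 2.
    """
    ddct = (q.ct_target_case - q.ct_ref_case) - (
        q.ct_target_control - q.ct_ref_control
    )
    return float(2.0 ** (-ddct))
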