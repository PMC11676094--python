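"""Spectral preprocessing: referencing, binning, region exclusion, normalization.

Raw 1D spectra are converted into the sample-by-bin intensity matrix that
the chemometric models consume: the ppm axis is rigidly calibrated to a
reference signal (TSP at 0.00 ppm, or the lactate CH3 at 1.33 ppm for
plasma), the spectrum is integrated over fixed 0.005-ppm buckets, solvent
and urea regions are removed, and each sample row is rescaled to a common
total area (or by a probabilistic quotient).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import Spectrum

__all__ = [
    "ExclusionScheme",
    "BinnedMatrix",
    "reference_calibrate",
    "bin_spectrum",
    "bin_cohort",
    "apply_exclusions",
    "normalize_rows",
    "DEFAULT_SCHEMES",
]

DEFAULT_BIN_WIDTH = 0.005


class CalibrationError(RuntimeError):
    """Raised when a reference peak cannot be located."""


class DegenerateSampleError(ValueError):
    """Raised when a sample row cannot be normalized (e.g. zero total area)."""


@dataclass(frozen=True)
class ExclusionScheme:
    """Set of half-open ppm windows removed before analysis.

    The built-in schemes drop the urea and residual-water regions of plasma
    and urine spectra and the residual water/methanol regions of tissue
    extracts.
    """

    matrix_type: str
    windows: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        wins = sorted(self.windows)
        for lo, hi in wins:
            if not lo < hi:
                raise ValueError(f"window ({lo}, {hi}) must have low < high")
        for (_, hi_prev), (lo_next, _) in zip(wins, wins[1:]):
            if lo_next < hi_prev:
                raise ValueError("exclusion windows overlap")
        object.__setattr__(self, "windows", tuple(wins))

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside any window (half-open)."""
        ppm = np.asarray(ppm, dtype=float)
        mask = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in self.windows:
            mask |= (ppm >= lo) & (ppm < hi)
        return mask


#: Exclusion windows per sample matrix: urea + residual water for biofluids,
#: residual water + methanol for tissue extracts.
DEFAULT_SCHEMES: dict[str, ExclusionScheme] = {
    "plasma": ExclusionScheme("plasma", ((5.40, 5.90), (4.20, 5.10))),
    "urine": ExclusionScheme("urine", ((5.35, 5.90), (4.14, 5.25))),
    "tissue": ExclusionScheme("tissue", ((4.67, 5.22), (3.31, 3.40))),
}


@dataclass
class BinnedMatrix:
    """Samples x retained-bins intensity table.

    ``values[i, j]`` is the integral of sample ``i`` over the bin centered
    at ``bin_centers[j]``.  ``normalization_tag`` records the row scaling
    applied ("raw" until :func:`normalize_rows` runs); ``exclusions`` lists
    the windows already removed.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    sample_ids: list[str]
    groups: list[str]
    normalization_tag: str = "raw"
    exclusions: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), self.bin_centers.size):
            raise ValueError("values shape does not match sample_ids x bin_centers")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("groups and sample_ids lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("binned values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{c:.4f}" for c in self.bin_centers],
        )
        df.insert(0, "group", self.groups)
        return df

    def write(self, path: str | Path) -> Path:
        """Write the matrix as CSV with a JSON header sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path)
        meta = {
            "bin_centers": [float(c) for c in self.bin_centers],
            "normalization_tag": self.normalization_tag,
            "exclusions": [list(w) for w in self.exclusions],
        }
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=2) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "BinnedMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        groups = df.pop("group").astype(str).tolist()
        return cls(
            bin_centers=np.asarray(meta["bin_centers"], dtype=float),
            values=df.to_numpy(dtype=float),
            sample_ids=[str(s) for s in df.index],
            groups=groups,
            normalization_tag=meta["normalization_tag"],
            exclusions=tuple(tuple(w) for w in meta["exclusions"]),
        )


def reference_calibrate(
    spectrum: Spectrum,
    reference_ppm: float,
    search_window: tuple[float, float],
) -> Spectrum:
    """Rigidly shift the ppm axis so the tallest in-window point sits at
    ``reference_ppm``.

    This is peak-position calibration against a reference signal (TSP at
    0.00 ppm; the lactate CH3 at 1.33 ppm for plasma).  Intensities are
    untouched; only the axis translates.
    """
    lo, hi = min(search_window), max(search_window)
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not mask.any():
        raise CalibrationError(
            f"search window ({lo}, {hi}) contains no points of the axis"
        )
    seg = spectrum.intensity[mask]
    if np.ptp(seg) == 0:
        raise CalibrationError(
            f"spectrum {spectrum.sample_id!r} is flat inside ({lo}, {hi}); "
            "no reference peak found"
        )
    peak_ppm = spectrum.ppm[mask][np.argmax(seg)]
    shift = reference_ppm - peak_ppm
    return Spectrum(
        spectrum.ppm + shift, spectrum.intensity.copy(), spectrum.sample_id, spectrum.group
    )


def _bin_edges(lo: float, hi: float, width: float) -> np.ndarray:
    # Half-open [low, low + width) bins anchored at the axis minimum, tiling
    # the full range; a tiny tolerance keeps e.g. 1.0/0.005 at exactly 200 bins.
    n_bins = int(np.ceil((hi - lo) / width - 1e-9))
    return lo + width * np.arange(n_bins + 1)


def bin_spectrum(
    spectrum: Spectrum,
    bin_width_ppm: float = DEFAULT_BIN_WIDTH,
    ppm_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a spectrum over fixed-width buckets.

    Bins are half-open ``[low, low + width)`` intervals anchored at the
    axis minimum (or at ``ppm_range[0]`` when given).  Each bin value is
    the trapezoid integral of the intensity over the bin, computed from the
    cumulative integral so that the bin total equals the whole-axis
    integral exactly (up to floating round-off).

    Returns ``(bin_centers, bin_integrals)``.
    """
    if bin_width_ppm <= 0:
        raise ValueError("bin_width_ppm must be strictly positive")
    ppm, intensity = spectrum.ppm, spectrum.intensity
    if ppm[0] > ppm[-1]:  # store ascending
        ppm, intensity = ppm[::-1], intensity[::-1]
    lo, hi = ppm_range if ppm_range is not None else (ppm[0], ppm[-1])
    if hi - lo < bin_width_ppm:
        raise ValueError("axis range must cover at least one bin")
    edges = _bin_edges(lo, hi, bin_width_ppm)
    # cumulative trapezoid on the native grid, interpolated at bin edges
    cum = np.concatenate(
        [[0.0], np.cumsum(np.diff(ppm) * (intensity[1:] + intensity[:-1]) / 2.0)]
    )
    cum_at_edges = np.interp(edges, ppm, cum)
    integrals = np.diff(cum_at_edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, integrals


def bin_cohort(
    spectra: Sequence[Spectrum],
    bin_width_ppm: float = DEFAULT_BIN_WIDTH,
    ppm_range: tuple[float, float] | None = None,
) -> BinnedMatrix:
    """Bin every spectrum of a cohort onto one shared bin grid.

    The shared range defaults to the intersection of all sample axes, so
    rigid calibration shifts never push bins outside any sample's support.
    """
    if not spectra:
        raise ValueError("empty cohort")
    if ppm_range is None:
        ppm_range = (
            max(min(s.ppm[0], s.ppm[-1]) for s in spectra),
            min(max(s.ppm[0], s.ppm[-1]) for s in spectra),
        )
    rows, centers = [], None
    for s in spectra:
        centers, vals = bin_spectrum(s, bin_width_ppm, ppm_range)
        rows.append(vals)
    return BinnedMatrix(
        bin_centers=centers,
        values=np.vstack(rows),
        sample_ids=[s.sample_id for s in spectra],
        groups=[s.group for s in spectra],
    )


def apply_exclusions(binned: BinnedMatrix, scheme: ExclusionScheme) -> BinnedMatrix:
    """Drop every bin whose center lies inside any exclusion window.

    Membership is decided by the bin center (not overlap fraction), which
    is deterministic and order-independent.  Column order is preserved.
    """
    keep = ~scheme.contains(binned.bin_centers)
    if not keep.any():
        warnings.warn("exclusion scheme removed every bin", stacklevel=2)
    return BinnedMatrix(
        bin_centers=binned.bin_centers[keep],
        values=binned.values[:, keep],
        sample_ids=list(binned.sample_ids),
        groups=list(binned.groups),
        normalization_tag=binned.normalization_tag,
        exclusions=binned.exclusions + scheme.windows,
    )


def normalize_rows(
    binned: BinnedMatrix,
    method: str = "total_area",
    target: float = 100.0,
) -> BinnedMatrix:
    """Rescale each sample row to remove dilution/amount differences.

    ``total_area`` scales every row to sum to ``target`` (the historical
    default for binned biofluid spectra).  ``probabilistic_quotient`` (PQN)
    divides each row by the median ratio to the cohort's median spectrum,
    which is robust when a few metabolites change strongly.
    """
    values = binned.values.copy()
    if method == "total_area":
        sums = values.sum(axis=1)
        bad = np.flatnonzero(sums <= 0)
        if bad.size:
            raise DegenerateSampleError(
                f"sample(s) {[binned.sample_ids[i] for i in bad]} have non-positive "
                "total area; cannot normalize"
            )
        values *= (target / sums)[:, None]
        tag = f"total_area:{target:g}"
    elif method == "probabilistic_quotient":
        reference = np.median(values, axis=0)
        usable = reference > 0
        if not usable.any():
            raise DegenerateSampleError("cohort median spectrum is non-positive everywhere")
        quotients = values[:, usable] / reference[usable]
        divisors = np.median(quotients, axis=1)
        bad = np.flatnonzero(~(divisors > 0))
        if bad.size:
            raise DegenerateSampleError(
                f"sample(s) {[binned.sample_ids[i] for i in bad]} have non-positive "
                "median quotient; cannot normalize"
            )
        values /= divisors[:, None]
        tag = "probabilistic_quotient"
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return replace(
        binned,
        bin_centers=binned.bin_centers.copy(),
        values=values,
        sample_ids=list(binned.sample_ids),
        groups=list(binned.groups),
        normalization_tag=tag,
    )
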