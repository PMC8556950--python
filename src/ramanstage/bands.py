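"""Band-area semi-quantification and group comparison.

Integrates named wavenumber windows (trapezoid rule with interpolated window
endpoints) on preprocessed spectra, reports per-group medians, and compares
groups band-by-band with two-sided pooled-variance Student's t-tests using
the conventional star annotation (ns / * / ** / *** / ****).  No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import Spectrum, SpectraSet
from .synthetic import BAND_ASSIGNMENTS

#: half-width (cm^-1) of the default single-center integration windows
DEFAULT_HALF_WIDTH = 10.0


@dataclass(frozen=True)
class BandDefinition:
    """A named closed wavenumber window [lo, hi] with its assignment."""

    name: str
    lo: float
    hi: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    @property
    def window(self) -> tuple[float, float]:
        return (self.lo, self.hi)


def default_bands() -> list[BandDefinition]:
    """The 13 reported bands.

    Single-center bands get center +/- 10 cm^-1 windows; the polysaccharide
    band is the stated range [840, 860]; the 831 window is truncated to
    [821, 839] so it does not double-count channels with its neighbour.
    """
    bands = []
    for center, assignment in BAND_ASSIGNMENTS.items():
        if center == 850.0:
            bands.append(BandDefinition("840-860", 840.0, 860.0, assignment))
        elif center == 831.0:
            bands.append(BandDefinition("831", 821.0, 839.0, assignment))
        else:
            name = f"{center:.0f}"
            bands.append(
                BandDefinition(name, center - DEFAULT_HALF_WIDTH, center + DEFAULT_HALF_WIDTH, assignment)
            )
    return sorted(bands, key=lambda b: b.lo)


def bands_from_frame(frame: pd.DataFrame) -> list[BandDefinition]:
    """Band set from a (name, lo, hi, assignment) table (CSV override)."""
    return [
        BandDefinition(str(r["name"]), float(r["lo"]), float(r["hi"]), str(r.get("assignment", "")))
        for _, r in frame.iterrows()
    ]


def integrate_band(spectrum: Spectrum, band: BandDefinition) -> float:
    """Trapezoidal integral of intensity over the band window.

    Window endpoints falling between channels contribute linearly
    interpolated intensities, so integration is exactly additive over
    adjacent windows.
    """
    x, y = spectrum.wavenumbers, spectrum.intensities
    if band.lo < x[0] or band.hi > x[-1]:
        raise ValueError(
            f"band {band.name} window [{band.lo}, {band.hi}] outside the axis "
            f"[{x[0]}, {x[-1]}]"
        )
    inside = (x > band.lo) & (x < band.hi)
    grid = np.concatenate(([band.lo], x[inside], [band.hi]))
    vals = np.concatenate(
        ([np.interp(band.lo, x, y)], y[inside], [np.interp(band.hi, x, y)])
    )
    return float(np.trapezoid(vals, grid))


def star_annotation(p: float) -> str:
    """Significance stars: ns for p >= 0.05, up to **** for p < 0.0001."""
    if not np.isfinite(p) or p < 0:
        raise ValueError(f"invalid p-value {p}")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t; degenerate zero-variance inputs
    map to (0, 1) when the means agree and (inf, 0) when they differ."""
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return (0.0, 1.0) if mx == my else (np.inf, 0.0)
    t = (mx - my) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * scipy.stats.t.sf(abs(t), nx + ny - 2)
    return float(t), float(p)


@dataclass
class BandAreaTable:
    """Per-spectrum band areas with group medians and pairwise comparisons."""

    areas: pd.DataFrame  # index spectrum_id, one column per band
    labels: pd.Series  # group label per spectrum (aligned to areas.index)
    medians: pd.DataFrame  # group x band
    bands: list[BandDefinition]
    n_unlabelled: int = 0

    def groups(self) -> list[str]:
        return self.medians.index.tolist()

    def group_means(self) -> pd.DataFrame:
        """Group means (the default summary is the median)."""
        means = self.areas.groupby(self.labels.to_numpy()).mean()
        means.index.name = "group"
        return means


def band_table(
    spectra_set: SpectraSet, bands: list[BandDefinition] | None = None
) -> BandAreaTable:
    """Integrate every band for every labelled spectrum; unlabelled spectra
    are excluded (their count is reported on the table)."""
    bands = bands if bands is not None else default_bands()
    labels = pd.Series(spectra_set.labels, index=spectra_set.spectrum_ids)
    labelled = labels.notna().to_numpy()
    n_unlabelled = int((~labelled).sum())
    sub = spectra_set.subset(labelled) if n_unlabelled else spectra_set

    rows = np.empty((len(sub), len(bands)))
    for i in range(len(sub)):
        s = sub.spectrum(i)
        rows[i] = [integrate_band(s, b) for b in bands]
    areas = pd.DataFrame(rows, index=pd.Index(sub.spectrum_ids, name="spectrum_id"),
                         columns=[b.name for b in bands])
    lab = pd.Series(sub.labels, index=areas.index, name="label")
    medians = areas.groupby(lab.to_numpy()).median()
    medians.index.name = "group"
    return BandAreaTable(areas=areas, labels=lab, medians=medians, bands=bands,
                         n_unlabelled=n_unlabelled)


def compare_groups(table: BandAreaTable, group_a: str, group_b: str) -> pd.DataFrame:
    """Band-by-band Student's t comparison of two groups.

    Returns one row per band with the t statistic, two-sided p, star
    annotation and both group medians.  Positive t means group_a > group_b.
    """
    for g in (group_a, group_b):
        if g not in set(table.labels):
            raise ValueError(f"group {g!r} not present")
        if int((table.labels == g).sum()) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 spectra")
    a_mask = (table.labels == group_a).to_numpy()
    b_mask = (table.labels == group_b).to_numpy()
    rows = []
    for band in table.areas.columns:
        x = table.areas.loc[a_mask, band].to_numpy()
        y = table.areas.loc[b_mask, band].to_numpy()
        t, p = _pooled_t(x, y)
        rows.append(
            {
                "band": band,
                "group_a": group_a,
                "group_b": group_b,
                "median_a": float(np.median(x)),
                "median_b": float(np.median(y)),
                "t": t,
                "p": p,
                "star": star_annotation(p),
            }
        )
    return pd.DataFrame(rows)


def all_pairwise_comparisons(table: BandAreaTable) -> pd.DataFrame:
    """compare_groups for every unordered pair of groups, concatenated."""
    groups = table.groups()
    frames = [
        compare_groups(table, a, b)
        for i, a in enumerate(groups)
        for b in groups[i + 1:]
    ]
    return pd.concat(frames, ignore_index=True)
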