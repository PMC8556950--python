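"""Synthetic single-cell Raman spectra with the class structure of hepatocyte staging.

Generates labelled fingerprint-region (300-1800 cm^-1) spectra for three cell
populations — primary human hepatocytes (PHH) and proliferating hepatocytes at
passages 1 and 4 (P1, P4) — as a sum of Gaussian bands with class-dependent
amplitudes, a smooth nonnegative fluorescence baseline, additive Gaussian
noise, and sparse cosmic-ray spikes.  Every stochastic component is recorded
in a ground-truth record so downstream stages can be tested by parameter
recovery.

The encoded biology: band amplitudes fall monotonically with passage at the
polysaccharide/lipid/protein bands (850, 1080, 1265, 1300, 1440, 1658,
1744 cm^-1), rise monotonically at phenylalanine/hydroxyproline/amide-III
(1003, 1206, 1337 cm^-1), are highest in PHH at 480 and 831 cm^-1, and are
elevated only at passage 4 at 1172 cm^-1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import Spectrum, SpectraSet

CLASS_LABELS = ("PHH", "P1", "P4")

#: trend codes: "dec" PHH>P1>P4, "inc" PHH<P1<P4,
#: "phh_high" PHH > (P1 = P4), "p4_high" (PHH = P1) < P4
BAND_TRENDS: dict[float, str] = {
    480.0: "phh_high",
    831.0: "phh_high",
    850.0: "dec",
    1003.0: "inc",
    1080.0: "dec",
    1172.0: "p4_high",
    1206.0: "inc",
    1265.0: "dec",
    1300.0: "dec",
    1337.0: "inc",
    1440.0: "dec",
    1658.0: "dec",
    1744.0: "dec",
}

BAND_ASSIGNMENTS: dict[float, str] = {
    480.0: "glycogen",
    831.0: "tyrosine",
    850.0: "polysaccharide structure",
    1003.0: "phenylalanine",
    1080.0: "amide II, typical phospholipid",
    1172.0: "C-H in-plane bending mode of tyrosine",
    1206.0: "hydroxyproline, tyrosine",
    1265.0: "alpha-helix, collagen, tryptophan",
    1300.0: "lipids",
    1337.0: "amide III",
    1440.0: "lipids",
    1658.0: "amide I",
    1744.0: "carbonyl feature of lipid spectra",
}

# Mid-class (P1-level) relative peak heights.  Chosen so the increasing and
# decreasing band groups carry comparable total intensity: area normalization
# then dilutes no trend below a ~13% between-class margin (see docs/methods.md).
_BASE_AMPLITUDE: dict[float, float] = {
    480.0: 0.6,
    831.0: 0.7,
    850.0: 0.8,
    1003.0: 1.6,
    1080.0: 0.9,
    1172.0: 0.5,
    1206.0: 1.2,
    1265.0: 0.8,
    1300.0: 1.0,
    1337.0: 1.4,
    1440.0: 1.2,
    1658.0: 1.4,
    1744.0: 0.5,
}

#: amplitude ratio between adjacent classes on trending bands
TREND_RATIO = 1.35

DEFAULT_FWHM = 15.0  # cm^-1, typical solid-phase biological Raman linewidth

_GAUSS_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian band: center and width in cm^-1 plus its assignment."""

    center: float
    fwhm: float = DEFAULT_FWHM
    assignment: str = ""

    def __post_init__(self) -> None:
        if not 300.0 <= self.center <= 1800.0:
            raise ValueError(f"peak center {self.center} outside 300-1800 cm^-1")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")

    @property
    def sigma(self) -> float:
        return self.fwhm * _GAUSS_SIGMA_PER_FWHM


@dataclass
class ClassProfile:
    """Mean relative peak heights for one cell population.

    ``amplitudes`` maps peak center (cm^-1) to mean relative height (> 0);
    ``amplitude_cv`` is the coefficient of variation of the per-cell lognormal
    amplitude jitter.
    """

    label: str
    amplitudes: dict[float, float]
    amplitude_cv: float = 0.15

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.amplitudes.values()):
            raise ValueError("all amplitudes must be positive")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")

    @property
    def max_amplitude(self) -> float:
        return max(self.amplitudes.values())


def default_profiles(amplitude_cv: float = 0.15) -> list[ClassProfile]:
    """The three default class profiles (PHH, P1, P4) over the 13 bands.

    Trend directions follow the staged-hepatocyte band behaviour described in
    the module docstring; the between-class ratio on trending bands is
    :data:`TREND_RATIO`.
    """
    r = TREND_RATIO
    per_class: dict[str, dict[float, float]] = {c: {} for c in CLASS_LABELS}
    for center, trend in BAND_TRENDS.items():
        m = _BASE_AMPLITUDE[center]
        if trend == "dec":
            phh, p1, p4 = m * r, m, m / r
        elif trend == "inc":
            phh, p1, p4 = m / r, m, m * r
        elif trend == "phh_high":
            phh, p1, p4 = m * r, m, m
        else:  # p4_high
            phh, p1, p4 = m, m, m * r
        per_class["PHH"][center] = phh
        per_class["P1"][center] = p1
        per_class["P4"][center] = p4
    return [
        ClassProfile(label=c, amplitudes=per_class[c], amplitude_cv=amplitude_cv)
        for c in CLASS_LABELS
    ]


@dataclass
class SyntheticConfig:
    """All knobs of the generator; identical configs give bit-identical data.

    Scales are relative: ``baseline_scale`` is the mean baseline level and
    ``noise_sd`` the noise standard deviation, both in multiples of the
    spectrum's maximum peak height; spike amplitudes are drawn uniformly from
    ``spike_amplitude_range`` (same units).
    """

    axis_start: float = 300.0
    axis_stop: float = 1800.0
    axis_step: float = 1.0
    n_per_class: int | Sequence[int] = 600
    profiles: list[ClassProfile] | None = None
    peak_fwhm: float = DEFAULT_FWHM
    baseline_order: int = 3
    baseline_scale: float = 2.0
    noise_sd: float = 0.05
    spike_rate: float = 0.3
    spike_amplitude_range: tuple[float, float] = (10.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_start >= self.axis_stop:
            raise ValueError("axis_start must be < axis_stop")
        if self.axis_step <= 0:
            raise ValueError("axis_step must be positive")
        ns = self.class_sizes
        if any(n < 1 for n in ns):
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.baseline_scale < 0:
            raise ValueError("baseline_scale must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    def resolved_profiles(self) -> list[ClassProfile]:
        return self.profiles if self.profiles is not None else default_profiles()

    @property
    def class_sizes(self) -> tuple[int, ...]:
        n_classes = len(self.resolved_profiles())
        if isinstance(self.n_per_class, (int, np.integer)):
            return (int(self.n_per_class),) * n_classes
        sizes = tuple(int(n) for n in self.n_per_class)
        if len(sizes) != n_classes:
            raise ValueError("n_per_class sequence length must match the profile count")
        return sizes


@dataclass
class SpectrumTruth:
    """Ground truth for one generated spectrum."""

    label: str
    amplitudes: dict[float, float]  # jittered true peak heights
    baseline: np.ndarray  # true baseline at every axis point
    noise_free: np.ndarray  # peaks + baseline (no noise, no spikes)
    spike_channels: list[int]  # flat channel indices hit by spikes
    spike_positions: list[float]  # same, as wavenumbers

    def to_jsonable(self) -> dict:
        return {
            "label": self.label,
            "amplitudes": {str(k): v for k, v in self.amplitudes.items()},
            "baseline": [round(float(v), 6) for v in self.baseline],
            "spike_channels": [int(c) for c in self.spike_channels],
            "spike_positions": [float(w) for w in self.spike_positions],
        }


def write_ground_truth(records: list[SpectrumTruth], path) -> None:
    """Ground truth as a JSON document (baselines rounded to 6 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_jsonable() for r in records], fh, sort_keys=True)


def _gaussian(axis: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((axis - center) / sigma) ** 2)


def generate_spectrum(
    profile: ClassProfile,
    config: SyntheticConfig,
    rng: np.random.Generator,
    meta: dict | None = None,
) -> tuple[Spectrum, SpectrumTruth]:
    """Draw one spectrum from ``profile`` under ``config`` using ``rng``.

    intensity = sum of jittered Gaussian peaks + nonnegative polynomial
    baseline + Gaussian noise + Poisson-count cosmic spikes of width 1-2
    channels.
    """
    axis = config.axis
    sigma_peak = config.peak_fwhm * _GAUSS_SIGMA_PER_FWHM
    for center in profile.amplitudes:
        if not (axis[0] <= center <= axis[-1]):
            raise ValueError(f"peak at {center} cm^-1 lies outside the axis")

    # lognormal jitter with mean 1 and the requested CV
    cv = profile.amplitude_cv
    if cv > 0:
        s2 = np.log1p(cv**2)
        jitter = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=len(profile.amplitudes))
    else:
        jitter = np.ones(len(profile.amplitudes))

    centers = np.array(sorted(profile.amplitudes))
    amps = np.array([profile.amplitudes[c] for c in centers]) * jitter
    true_amps = dict(zip(centers.tolist(), amps.tolist()))
    peaks = np.zeros_like(axis)
    for c, a in zip(centers, amps):
        peaks += a * _gaussian(axis, c, sigma_peak)
    height = float(amps.max())

    if config.baseline_scale > 0:
        t = np.linspace(-1.0, 1.0, axis.size)
        coeffs = rng.standard_normal(config.baseline_order + 1)
        b = np.polyval(coeffs, t)
        b = b - b.min()  # nonnegative over the axis
        level = config.baseline_scale * height * rng.uniform(0.7, 1.3)
        mean_b = b.mean()
        baseline = b * (level / mean_b) if mean_b > 1e-12 else np.full_like(axis, level)
    else:
        baseline = np.zeros_like(axis)

    noise = rng.normal(0.0, config.noise_sd * height, axis.size) if config.noise_sd > 0 else 0.0
    y = peaks + baseline + noise

    spike_channels: list[int] = []
    n_spikes = rng.poisson(config.spike_rate) if config.spike_rate > 0 else 0
    lo, hi = config.spike_amplitude_range
    for _ in range(n_spikes):
        ch = int(rng.integers(0, axis.size))
        width = int(rng.integers(1, 3))
        amp = rng.uniform(lo, hi) * height
        y[ch] += amp
        spike_channels.append(ch)
        if width == 2 and ch + 1 < axis.size:
            y[ch + 1] += amp * rng.uniform(0.4, 1.0)
            spike_channels.append(ch + 1)

    spike_channels = sorted(set(spike_channels))
    truth = SpectrumTruth(
        label=profile.label,
        amplitudes=true_amps,
        baseline=np.asarray(baseline),
        noise_free=peaks + baseline,
        spike_channels=spike_channels,
        spike_positions=[float(axis[c]) for c in spike_channels],
    )
    return Spectrum(axis, y, dict(meta or {})), truth


def generate_dataset(config: SyntheticConfig) -> tuple[SpectraSet, list[SpectrumTruth]]:
    """Full labelled dataset: ``n_per_class`` spectra per profile, shuffled.

    Metadata mimics the acquisition design: 10 spectra per cell, cells split
    round-robin over 3 replicate batches, sampling location alternating
    center/periphery within each cell.
    """
    rng = np.random.default_rng(config.seed)
    profiles = config.resolved_profiles()
    sizes = config.class_sizes

    spectra: list[Spectrum] = []
    truths: list[SpectrumTruth] = []
    for profile, n in zip(profiles, sizes):
        for i in range(n):
            cell = i // 10
            meta = {
                "cell_id": f"{profile.label}_c{cell:03d}",
                "label": profile.label,
                "batch": f"batch{cell % 3 + 1}",
                "location": "center" if i % 2 == 0 else "periphery",
            }
            spec, truth = generate_spectrum(profile, config, rng, meta)
            spectra.append(spec)
            truths.append(truth)

    order = rng.permutation(len(spectra))
    spectra = [spectra[i] for i in order]
    truths = [truths[i] for i in order]
    for i, s in enumerate(spectra):
        s.meta["spectrum_id"] = f"s{i:05d}"
    return SpectraSet.from_spectra(spectra), truths


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a flat mapping (YAML ``simulate:`` block)."""
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(d) - known - {"amplitude_cv"}
    if unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in d.items() if k in known}
    if "spike_amplitude_range" in kwargs:
        kwargs["spike_amplitude_range"] = tuple(kwargs["spike_amplitude_range"])
    if "n_per_class" in kwargs and isinstance(kwargs["n_per_class"], list):
        kwargs["n_per_class"] = tuple(kwargs["n_per_class"])
    if "amplitude_cv" in d and "profiles" not in kwargs:
        kwargs["profiles"] = default_profiles(amplitude_cv=float(d["amplitude_cv"]))
    return SyntheticConfig(**kwargs)


def trend_pairs(trend: str) -> list[tuple[str, str]]:
    """Strict inequalities (higher, lower) encoded by a trend code."""
    if trend == "dec":
        return [("PHH", "P1"), ("P1", "P4")]
    if trend == "inc":
        return [("P1", "PHH"), ("P4", "P1")]
    if trend == "phh_high":
        return [("PHH", "P1"), ("PHH", "P4")]
    if trend == "p4_high":
        return [("P4", "PHH"), ("P4", "P1")]
    raise ValueError(f"unknown trend code {trend!r}")
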