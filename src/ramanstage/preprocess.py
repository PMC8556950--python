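"""The spectral normalization chain: despike -> baseline -> area normalization.

Implements the standard single-spectrum cleanup for cellular Raman data:

* **resample** — linear interpolation onto a common grid (no extrapolation);
* **despike** — cosmic-ray removal by a robust z-score built from first
  differences, with flagged channels replaced by linear interpolation of the
  nearest clean neighbours;
* **baseline_correct** — asymmetric least squares (Whittaker smoother with
  asymmetry ``p`` and smoothness ``lam``) estimating the smooth fluorescence
  background, clipped at zero because the background is physically
  nonnegative;
* **area_normalize** — scale so the trapezoidal integral over the axis equals
  a fixed constant (default 1), making band areas dimensionless fractions of
  total scattering.

``preprocess_set`` applies the chain in that fixed order to every spectrum of
a :class:`~ramanstage.datatypes.SpectraSet`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.linalg
import scipy.sparse

from .datatypes import Spectrum, SpectraSet

# Robust-scale floor for despiking, as a fraction of the intensity range.
# Guards noiseless spectra, where the MAD of the first differences collapses
# and smooth peak flanks would otherwise be flagged.
_SCALE_FLOOR_FRAC = 0.015


@dataclass
class PreprocessConfig:
    """Parameters of the normalization chain.

    ``despike_threshold`` is the robust z cutoff; ``despike_window`` dilates
    each flagged run by ``(window - 1) // 2`` channels per side (1 = no
    dilation, exact spike localization).  ``baseline_lambda``/``baseline_p``/
    ``baseline_iters`` are the asymmetric-least-squares smoothness, asymmetry
    and reweighting passes.  ``target_axis`` is an optional ``(start, stop,
    step)`` resampling grid.
    """

    despike_threshold: float = 8.0
    despike_window: int = 1
    baseline_lambda: float = 1e5
    baseline_p: float = 0.01
    baseline_iters: int = 10
    baseline_min_snr: float = 5.0
    target_axis: tuple[float, float, float] | None = None
    normalization_area: float = 1.0
    baseline_method: str = "als"  # "als" or "polynomial"
    baseline_poly_degree: int = 5

    def __post_init__(self) -> None:
        if self.despike_threshold <= 0:
            raise ValueError("despike_threshold must be positive")
        if not 0.0 < self.baseline_p < 1.0:
            raise ValueError("baseline_p must lie in (0, 1)")
        if self.baseline_iters < 1:
            raise ValueError("baseline_iters must be >= 1")
        if self.normalization_area <= 0:
            raise ValueError("normalization_area must be positive")
        if self.baseline_method not in ("als", "polynomial"):
            raise ValueError("baseline_method must be 'als' or 'polynomial'")


def config_from_dict(d: dict) -> PreprocessConfig:
    known = {f.name for f in dataclasses.fields(PreprocessConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown preprocess config keys: {sorted(unknown)}")
    kwargs = dict(d)
    if kwargs.get("target_axis") is not None:
        kwargs["target_axis"] = tuple(kwargs["target_axis"])
    return PreprocessConfig(**kwargs)


def resample(spectrum: Spectrum, target_axis) -> Spectrum:
    """Linear interpolation onto ``target_axis``; refuses to extrapolate."""
    target = np.asarray(target_axis, dtype=float)
    if target.ndim == 1 and target.size == 3 and not isinstance(target_axis, np.ndarray):
        start, stop, step = target
        n = int(round((stop - start) / step)) + 1
        target = start + step * np.arange(n)
    if np.any(np.diff(target) <= 0):
        raise ValueError("target axis must be strictly ascending")
    if target[0] < spectrum.wavenumbers[0] or target[-1] > spectrum.wavenumbers[-1]:
        raise ValueError(
            f"target axis [{target[0]}, {target[-1]}] extends beyond the spectrum "
            f"range [{spectrum.wavenumbers[0]}, {spectrum.wavenumbers[-1]}]"
        )
    values = np.interp(target, spectrum.wavenumbers, spectrum.intensities)
    return Spectrum(target, values, dict(spectrum.meta))


def _spike_statistic(y: np.ndarray) -> np.ndarray:
    """Directional spike score per channel, in units of the first-difference MAD.

    A cosmic spike (1-2 channels, positive) exceeds both its clean left and
    right neighbourhoods; a channel's score is the smaller of its largest
    lag-1/lag-2 rise on each side, so smooth peaks and the neighbours of a
    spike score low while every spike channel scores high.
    """
    n = y.size
    big = np.full(n, -np.inf)
    l1 = np.concatenate(([np.nan], y[1:] - y[:-1]))  # y[i] - y[i-1]
    l2 = np.concatenate(([np.nan, np.nan], y[2:] - y[:-2]))
    r1 = np.concatenate((y[:-1] - y[1:], [np.nan]))  # y[i] - y[i+1]
    r2 = np.concatenate((y[:-2] - y[2:], [np.nan, np.nan]))
    left = np.fmax(l1, l2)  # ignores NaN edges
    right = np.fmax(r1, r2)
    score = np.where(np.isnan(left), right, np.where(np.isnan(right), left, np.minimum(left, right)))
    return np.where(np.isnan(score), big, score)


def despike(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> tuple[Spectrum, np.ndarray]:
    """Remove cosmic-ray spikes; returns the cleaned spectrum and flagged positions.

    Channels whose spike score (robust z of first differences, see
    :func:`_spike_statistic`) exceeds ``despike_threshold`` are replaced by
    linear interpolation of the nearest unflagged neighbours.  Idempotent on
    its own output.
    """
    config = config or PreprocessConfig()
    y = spectrum.intensities
    if y.size < 5:
        raise ValueError("despike needs at least 5 channels")

    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    floor = _SCALE_FLOOR_FRAC * (y.max() - y.min())
    scale = max(mad / 0.6745, floor, 1e-300)

    z = _spike_statistic(y) / scale
    flagged = z > config.despike_threshold

    pad = (max(int(config.despike_window), 1) - 1) // 2
    if pad and flagged.any():
        idx = np.flatnonzero(flagged)
        for k in range(1, pad + 1):
            flagged[np.clip(idx - k, 0, y.size - 1)] = True
            flagged[np.clip(idx + k, 0, y.size - 1)] = True

    if not flagged.any():
        return spectrum.with_intensities(y.copy()), np.array([], dtype=float)
    if flagged.all():
        raise ValueError("despike flagged every channel; input is pathological")

    clean = y.copy()
    good = ~flagged
    clean[flagged] = np.interp(
        spectrum.wavenumbers[flagged], spectrum.wavenumbers[good], y[good]
    )
    return spectrum.with_intensities(clean), spectrum.wavenumbers[flagged].copy()


@lru_cache(maxsize=8)
def _penalty_bands(n: int) -> np.ndarray:
    """Upper bands (offsets 2, 1, 0) of D'D for the second-difference matrix D."""
    diags = np.array([1.0, -2.0, 1.0])
    D = scipy.sparse.diags(diags, offsets=[0, 1, 2], shape=(n - 2, n))
    DTD = (D.T @ D).todia()
    ab = np.zeros((3, n))
    ab[0, 2:] = DTD.diagonal(2)
    ab[1, 1:] = DTD.diagonal(1)
    ab[2, :] = DTD.diagonal(0)
    return ab


def _als_baseline(y: np.ndarray, lam: float, p: float, iters: int) -> np.ndarray:
    """Asymmetric least squares on a Whittaker smoother (banded Cholesky solves)."""
    n = y.size
    penalty = lam * _penalty_bands(n)
    w = np.ones(n)
    z = y
    for _ in range(iters):
        ab = penalty.copy()
        ab[2, :] += w
        z = scipy.linalg.solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def _poly_baseline(x: np.ndarray, y: np.ndarray, degree: int, p: float, iters: int) -> np.ndarray:
    """Asymmetrically reweighted polynomial fit (fallback baseline estimator)."""
    t = (x - x.mean()) / (x.max() - x.min())
    w = np.ones_like(y)
    z = y
    for _ in range(iters):
        coeffs = np.polyfit(t, y, degree, w=np.sqrt(w))
        z = np.polyval(coeffs, t)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> tuple[Spectrum, np.ndarray]:
    """Estimate and subtract the fluorescence background.

    Returns ``(corrected, baseline)`` with ``corrected + baseline`` equal to
    the input.  Two guards keep the estimate physical and the chain stable
    under reruns: the background is clipped at zero (fluorescence cannot be
    negative), and when the estimate never rises above ``baseline_min_snr``
    times the robust residual-noise scale it is treated as absent (all-zero)
    — subtracting a "baseline" indistinguishable from noise only distorts an
    already-flat spectrum.
    """
    config = config or PreprocessConfig()
    y = spectrum.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    if config.baseline_method == "als":
        z = _als_baseline(y, config.baseline_lambda, config.baseline_p, config.baseline_iters)
    else:
        z = _poly_baseline(
            spectrum.wavenumbers, y, config.baseline_poly_degree,
            config.baseline_p, config.baseline_iters,
        )
    d = np.diff(y)
    noise_scale = np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0)
    if z.max() < config.baseline_min_snr * noise_scale:
        baseline = np.zeros_like(y)
    else:
        baseline = np.maximum(z, 0.0)
    return spectrum.with_intensities(y - baseline), baseline


def area_normalize(spectrum: Spectrum, normalization_area: float = 1.0) -> Spectrum:
    """Scale so the trapezoidal integral over the axis equals ``normalization_area``."""
    if normalization_area <= 0:
        raise ValueError("normalization_area must be positive")
    integral = np.trapezoid(spectrum.intensities, spectrum.wavenumbers)
    if integral <= 0:
        raise ValueError(f"nonpositive spectrum integral ({integral}); cannot normalize")
    return spectrum.with_intensities(spectrum.intensities * (normalization_area / integral))


def preprocess_spectrum(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> tuple[Spectrum, dict]:
    """Apply resample -> despike -> baseline -> normalize to one spectrum.

    Returns the cleaned spectrum and a QC record (spike positions, estimated
    baseline, pre/post integrals).
    """
    config = config or PreprocessConfig()
    s = spectrum
    if config.target_axis is not None:
        s = resample(s, config.target_axis)
    pre_integral = float(np.trapezoid(s.intensities, s.wavenumbers))
    s, spikes = despike(s, config)
    s, baseline = baseline_correct(s, config)
    s = area_normalize(s, config.normalization_area)
    qc = {
        "spike_positions": spikes,
        "n_spikes": int(spikes.size),
        "baseline": baseline,
        "pre_integral": pre_integral,
        "post_integral": float(np.trapezoid(s.intensities, s.wavenumbers)),
    }
    return s, qc


def preprocess_set(
    spectra_set: SpectraSet,
    config: PreprocessConfig | None = None,
    return_details: bool = False,
):
    """Run the chain on every spectrum; spike counts land in the metadata.

    With ``return_details=True`` also returns the per-spectrum QC records
    (spike positions, estimated baselines, integrals) keyed by spectrum id.
    """
    config = config or PreprocessConfig()
    if len(spectra_set) == 0:
        raise ValueError("cannot preprocess an empty SpectraSet")
    cleaned = []
    details: dict[str, dict] = {}
    for i in range(len(spectra_set)):
        sid = str(spectra_set.spectrum_ids[i])
        try:
            s, qc = preprocess_spectrum(spectra_set.spectrum(i), config)
        except ValueError as err:
            raise ValueError(f"spectrum {sid!r}: {err}") from err
        cleaned.append(s)
        details[sid] = qc
    out = SpectraSet.from_spectra(cleaned)
    out.meta["n_spikes"] = [details[str(s)]["n_spikes"] for s in out.spectrum_ids]
    if return_details:
        return out, details
    return out
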