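"""Resolution metrics: particle-gap resolvability statistics and
radially-averaged spatial-frequency analysis.

A gap between two particles is probed along a line profile through their
centres.  The reference intensity is (by default) the smaller of the two
flanking peak intensities; the gap *exists* if the valley minimum falls below
60% of that reference, and its *width* is the distance between the two
sub-sample crossings of the 80% level flanking the valley, located by linear
interpolation.  Both thresholds and the peak policy are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .images import DegenerateInputError, SEMImage


@dataclass
class LineProfile:
    positions: np.ndarray  # nm along the segment, strictly increasing
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.positions.size < 3:
            raise ValueError("a profile needs at least 3 samples")
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have the same length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class GapMeasurement:
    exists: bool
    width_nm: float | None
    min_over_peak: float
    reason: str = ""


def extract_profile(
    image: SEMImage,
    p1: tuple[float, float],
    p2: tuple[float, float],
    step_nm: float | None = None,
) -> LineProfile:
    """Bilinear sampling along a segment; points are (x_nm, y_nm), positions
    measured from ``p1``.  Default step is half a pixel."""
    if step_nm is None:
        step_nm = image.pixel_size_nm / 2
    if step_nm <= 0:
        raise ValueError("step_nm must be > 0")
    m, n = image.shape
    for (x, y) in (p1, p2):
        if not (0 <= x <= (n - 1) * image.pixel_size_nm and 0 <= y <= (m - 1) * image.pixel_size_nm):
            raise ValueError(f"profile endpoint ({x}, {y}) nm outside the image")
    p1a, p2a = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    length = float(np.hypot(*(p2a - p1a)))
    n_steps = max(int(np.floor(length / step_nm)), 2)
    positions = np.linspace(0.0, length, n_steps + 1)
    ts = positions / length if length > 0 else positions
    xs = (p1a[0] + ts * (p2a[0] - p1a[0])) / image.pixel_size_nm
    ys = (p1a[1] + ts * (p2a[1] - p1a[1])) / image.pixel_size_nm
    vals = ndimage.map_coordinates(image.pixels, [ys, xs], order=1, mode="nearest")
    return LineProfile(positions, vals)


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of local maxima, endpoints included, plateaus collapsed to
    their first sample."""
    idx = []
    n = len(y)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok:
            idx.append(i)
        i = j + 1
    return idx


def measure_gap(
    profile: LineProfile,
    exist_frac: float = 0.6,
    width_frac: float = 0.8,
    peak_policy: str = "min-peak",
) -> GapMeasurement:
    """Gap existence and width from a two-peak line profile.

    ``peak_policy`` selects the reference intensity: ``min-peak`` (default)
    and ``max-peak`` use one global reference; ``per-side`` thresholds each
    flank against its own peak (the width is then measured between per-side
    crossings).  The result is invariant to uniform intensity scaling and to
    reversing the profile direction.
    """
    if peak_policy not in ("min-peak", "max-peak", "per-side"):
        raise ValueError("peak_policy must be one of min-peak, max-peak, per-side")
    y = profile.intensities
    x = profile.positions
    maxima = _local_maxima(y)
    if len(maxima) < 2:
        return GapMeasurement(False, None, 1.0, reason="fewer than two peaks")
    # flanking peaks: the pair of maxima bracketing the deepest interior valley
    best = None
    for a_i in range(len(maxima) - 1):
        for b_i in range(a_i + 1, len(maxima)):
            lo, hi = maxima[a_i], maxima[b_i]
            if hi - lo < 2:
                continue
            seg = y[lo + 1:hi]
            v_rel = int(np.argmin(seg)) + lo + 1
            depth = min(y[lo], y[hi]) - y[v_rel]
            if best is None or depth > best[0]:
                best = (depth, lo, hi, v_rel)
    if best is None:
        return GapMeasurement(False, None, 1.0, reason="no valley between peaks")
    _, ipk_l, ipk_r, iv = best
    pk_l, pk_r, v = y[ipk_l], y[ipk_r], y[iv]
    ref = min(pk_l, pk_r) if peak_policy != "max-peak" else max(pk_l, pk_r)
    if ref <= 0:
        return GapMeasurement(False, None, 1.0, reason="non-positive peak reference")
    ratio = v / ref
    exists = ratio < exist_frac
    if not exists:
        return GapMeasurement(False, None, ratio, reason="valley above existence threshold")

    if peak_policy == "per-side":
        thr_l, thr_r = width_frac * pk_l, width_frac * pk_r
    else:
        thr_l = thr_r = width_frac * ref
    left = _cross_left(x, y, iv, thr_l)
    right = _cross_right(x, y, iv, thr_r)
    if left is None or right is None:
        return GapMeasurement(True, None, ratio, reason="width crossing not found")
    return GapMeasurement(True, float(right - left), ratio)


def _cross_left(x: np.ndarray, y: np.ndarray, iv: int, thr: float) -> float | None:
    """Walk left from the valley to the first upward crossing of ``thr``;
    sub-sample position by linear interpolation."""
    for i in range(iv, 0, -1):
        if y[i] < thr <= y[i - 1]:
            t = (thr - y[i]) / (y[i - 1] - y[i])
            return float(x[i] + t * (x[i - 1] - x[i]))
        if y[i] >= thr:
            return float(x[i])
    return float(x[0]) if y[0] >= thr else None


def _cross_right(x: np.ndarray, y: np.ndarray, iv: int, thr: float) -> float | None:
    n = len(y)
    for i in range(iv, n - 1):
        if y[i] < thr <= y[i + 1]:
            t = (thr - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + t * (x[i + 1] - x[i]))
        if y[i] >= thr:
            return float(x[i])
    return float(x[-1]) if y[-1] >= thr else None


# ---------------------------------------------------------------------------
# Gap study over image triples


@dataclass
class GapStudyResult:
    n_gaps: int
    undetected_fraction: dict[str, float]
    mean_abs_diff_nm: dict[str, float]
    gaussian_fit: dict[str, tuple[float, float]]
    widths_nm: dict[str, list[float | None]] = dc_field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "n_gaps": self.n_gaps,
            "undetected_fraction": self.undetected_fraction,
            "mean_abs_diff_nm": self.mean_abs_diff_nm,
            "gaussian_fit": {k: list(v) for k, v in self.gaussian_fit.items()},
        }


def gap_study(
    images: Mapping[str, SEMImage],
    gap_segments: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    exist_frac: float = 0.6,
    width_frac: float = 0.8,
    reference_class: str = "ground_truth",
) -> GapStudyResult:
    """Measure every selected gap in each image class and summarise.

    Classes are typically ``input`` (upsampled low-resolution), ``output``
    (network) and ``ground_truth``.  The mean absolute width difference of a
    class is computed against the reference over gaps resolved in *both*;
    unresolved gaps are excluded from the histograms and Gaussian fits but
    counted in the undetected fraction.
    """
    if len(gap_segments) == 0:
        raise ValueError("gap segment list is empty")
    if reference_class not in images:
        raise ValueError(f"reference class {reference_class!r} missing from images")
    widths: dict[str, list[float | None]] = {}
    for cls, img in images.items():
        w_cls: list[float | None] = []
        for p1, p2 in gap_segments:
            meas = measure_gap(extract_profile(img, p1, p2), exist_frac, width_frac)
            w_cls.append(meas.width_nm if meas.exists else None)
        widths[cls] = w_cls

    n = len(gap_segments)
    undetected = {cls: sum(w is None for w in ws) / n for cls, ws in widths.items()}
    ref = widths[reference_class]
    mean_abs: dict[str, float] = {}
    fits: dict[str, tuple[float, float]] = {}
    for cls, ws in widths.items():
        diffs = [abs(w - r) for w, r in zip(ws, ref) if w is not None and r is not None]
        mean_abs[cls] = float(np.mean(diffs)) if diffs else float("nan")
        resolved = [w for w in ws if w is not None]
        try:
            fits[cls] = gaussian_fit_histogram(resolved)
        except DegenerateInputError:
            fits[cls] = (float("nan"), float("nan"))
    return GapStudyResult(n, undetected, mean_abs, fits, widths)


def gaussian_fit_histogram(widths: Iterable[float], n_bins: int = 20) -> tuple[float, float]:
    """Maximum-likelihood normal fit (sample mean and standard deviation).

    The bin count only affects plotting; the fit is moment-based and hence
    bin-independent and deterministic.
    """
    arr = np.asarray(list(widths), dtype=np.float64)
    if arr.size < 3 or np.unique(arr).size < 2:
        raise DegenerateInputError("need at least 3 values with nonzero spread for a Gaussian fit")
    return float(arr.mean()), float(arr.std())


# ---------------------------------------------------------------------------
# Spatial-frequency analysis


@dataclass
class Spectrum2D:
    magnitude: np.ndarray  # fftshift-centred |FFT|
    freq_y: np.ndarray     # cycles/nm along rows
    freq_x: np.ndarray

    @property
    def nyquist(self) -> float:
        return float(min(self.freq_y.max(), self.freq_x.max()))


@dataclass
class RadialSpectrum:
    frequency: np.ndarray  # bin centres, cycles/nm
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequency) <= 0) or np.any(self.frequency < 0):
            raise ValueError("frequencies must be non-negative and increasing")


def power_spectrum(image: SEMImage, log_scale: bool = False) -> Spectrum2D:
    """Centred 2-D Fourier magnitude with physical frequency axes."""
    m, n = image.shape
    if m < 8 or n < 8:
        raise ValueError("image must be at least 8x8 for spectral analysis")
    mag = np.abs(np.fft.fftshift(np.fft.fft2(image.pixels)))
    if log_scale:
        mag = np.log1p(mag)
    fy = np.fft.fftshift(np.fft.fftfreq(m, d=image.pixel_size_nm))
    fx = np.fft.fftshift(np.fft.fftfreq(n, d=image.pixel_size_nm))
    return Spectrum2D(mag, fy, fx)


def radial_average(spectrum: Spectrum2D, n_bins: int = 64) -> RadialSpectrum:
    """Mean magnitude over annuli of constant spatial frequency, with uniform
    bins from 0 up to the (smaller-axis) Nyquist."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    fy = spectrum.freq_y[:, None]
    fx = spectrum.freq_x[None, :]
    rr = np.hypot(fy, fx)
    nyq = spectrum.nyquist
    edges = np.linspace(0.0, nyq, n_bins + 1)
    which = np.digitize(rr.ravel(), edges) - 1
    mags = spectrum.magnitude.ravel()
    mask = (which >= 0) & (which < n_bins)
    sums = np.bincount(which[mask], weights=mags[mask], minlength=n_bins)
    counts = np.bincount(which[mask], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centres = (edges[:-1] + edges[1:]) / 2
    return RadialSpectrum(centres, means)


def spectrum_study(
    images: Mapping[str, Sequence[SEMImage]],
    n_bins: int = 64,
) -> dict[str, RadialSpectrum]:
    """Average the 2-D magnitude spectra across images per class, then
    radially average.  All images of a class must share shape and pixel size."""
    out: dict[str, RadialSpectrum] = {}
    for cls, imgs in images.items():
        if len(imgs) == 0:
            raise ValueError(f"class {cls!r} has no images")
        shapes = {im.shape for im in imgs}
        if len(shapes) != 1:
            raise ValueError(f"class {cls!r} mixes image shapes: {shapes}")
        spectra = [power_spectrum(im) for im in imgs]
        mean_mag = np.mean([s.magnitude for s in spectra], axis=0)
        avg = Spectrum2D(mean_mag, spectra[0].freq_y, spectra[0].freq_x)
        out[cls] = radial_average(avg, n_bins)
    return out


def highband_exceedance(
    output: RadialSpectrum,
    reference: RadialSpectrum,
    cutoff_cycles_per_nm: float,
) -> float:
    """Fraction of frequency bins above a cutoff where ``output`` magnitude
    exceeds ``reference`` magnitude (the testable restatement of spectral
    recovery above the low-resolution Nyquist)."""
    mask = output.frequency > cutoff_cycles_per_nm
    if not mask.any():
        raise ValueError("no frequency bins above the cutoff")
    return float(np.mean(output.magnitude[mask] > reference.magnitude[mask]))
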