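"""From raw measurements to the ten standardized colour/pattern metrics.

Colour: reflectance spectra are converted to avian photon catches for the UV,
SW, MW and LW single cones (standardized to sum to one, removing absolute
brightness) and the double cone (luminance). The shipped receptor set is an
idealized tetrachromat — Gaussian sensitivity curves at typical passerine peak
wavelengths — not measured cone data for any real species.

Pattern: a granularity analysis decomposes each egg photograph into bandpass
energy at an octave series of marking scales, from which five metrics follow:
predominant marking size, its dominance, overall pattern contrast (energy),
marking coverage, and polar dispersion of markings. Luminance and the five
pattern metrics are standardized within each family as a proportion of the
family maximum, making all ten metrics comparable in scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import PATTERN_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class ReflectanceSpectrum:
    """Reflectance (proportion, per wavelength in nm) on a strictly increasing grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.size == 0:
            raise ValueError("empty wavelength grid")
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.reflectance < 0):
            raise ValueError("reflectance must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "ReflectanceSpectrum":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass
class ReceptorSet:
    """Receptor sensitivities and illuminant on a common wavelength grid.

    ``single_cones`` maps the four colour channels (uv/sw/mw/lw) to sensitivity
    curves; ``double_cone`` drives luminance. The illuminant defaults to flat
    (ideal white) and can be replaced by any measured spectrum.
    """

    wavelengths: np.ndarray
    single_cones: dict[str, np.ndarray]
    double_cone: np.ndarray
    illuminant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name, sens in self.single_cones.items():
            if np.any(np.asarray(sens) < 0):
                raise ValueError(f"negative sensitivity in {name} cone")
        if self.illuminant is None:
            self.illuminant = np.ones_like(self.wavelengths)


def idealized_receptors(wavelengths: np.ndarray | None = None) -> ReceptorSet:
    """An idealized violet-sensitive passerine tetrachromat (synthetic fixture).

    Gaussian sensitivities peaking near 370 (UV), 445 (SW), 508 (MW) and
    565 nm (LW), with a broad double cone near 560 nm; flat illuminant.
    """
    wl = np.arange(300.0, 701.0, 1.0) if wavelengths is None else np.asarray(wavelengths, float)

    def bell(peak: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((wl - peak) / width) ** 2)

    return ReceptorSet(
        wavelengths=wl,
        single_cones={
            "uv": bell(370.0, 25.0),
            "sw": bell(445.0, 30.0),
            "mw": bell(508.0, 35.0),
            "lw": bell(565.0, 40.0),
        },
        double_cone=bell(560.0, 70.0),
    )


@dataclass
class ConeCatches:
    """Sum-standardized single-cone catches plus the raw double-cone (luminance) catch."""

    q_uv: float
    q_sw: float
    q_mw: float
    q_lw: float
    luminance_raw: float

    def as_array(self) -> np.ndarray:
        return np.array([self.q_uv, self.q_sw, self.q_mw, self.q_lw])


def compute_cone_catch(spectrum: ReflectanceSpectrum, receptors: ReceptorSet) -> ConeCatches:
    """Integrate reflectance × sensitivity × illuminant per receptor.

    Receptor curves are linearly interpolated onto the spectrum's grid (zero
    outside their support) and integrated by the trapezoidal rule; the four
    single-cone catches are divided by their sum so they sum to exactly one.
    """
    wl = spectrum.wavelengths
    lo = max(wl[0], receptors.wavelengths[0])
    hi = min(wl[-1], receptors.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectrum and receptor wavelength grids do not overlap")
    sel = (wl >= lo) & (wl <= hi)
    wl_c = wl[sel]
    refl = spectrum.reflectance[sel]
    illum = np.interp(wl_c, receptors.wavelengths, receptors.illuminant)

    def catch(sens: np.ndarray) -> float:
        s = np.interp(wl_c, receptors.wavelengths, sens, left=0.0, right=0.0)
        return float(np.trapezoid(refl * s * illum, wl_c))

    raw = {name: catch(sens) for name, sens in receptors.single_cones.items()}
    total = sum(raw.values())
    if total <= 0.0:
        raise ValueError("zero total catch: dark or non-overlapping input")
    lum = catch(receptors.double_cone)
    return ConeCatches(
        q_uv=raw["uv"] / total,
        q_sw=raw["sw"] / total,
        q_mw=raw["mw"] / total,
        q_lw=raw["lw"] / total,
        luminance_raw=lum,
    )


# ---------------------------------------------------------------------------
# granularity (bandpass energy) analysis
# ---------------------------------------------------------------------------


@dataclass
class GranularitySpectrum:
    """Bandpass energy per marking scale (octave series of pixel periods)."""

    band_scales: np.ndarray  # pixel periods, strictly increasing
    band_energy: np.ndarray  # non-negative energy per band

    def total_energy(self) -> float:
        return float(self.band_energy.sum())

    def dominant_scale(self) -> float:
        return float(self.band_scales[int(np.argmax(self.band_energy))])


def default_band_scales(mask: np.ndarray) -> np.ndarray:
    """Octave series 2, 4, 8, … up to half the shorter mask bounding-box side."""
    ys, xs = np.nonzero(mask)
    shorter = min(np.ptp(ys) + 1, np.ptp(xs) + 1)
    scales = []
    s = 2
    while s <= shorter / 2:
        scales.append(s)
        s *= 2
    if len(scales) < 2:
        raise ValueError("mask too small for a two-band octave series")
    return np.array(scales, dtype=float)


def granularity_analysis(
    image: np.ndarray,
    mask: np.ndarray,
    band_scales: np.ndarray | None = None,
) -> GranularitySpectrum:
    """Decompose the masked image into bandpass energy at octave scales.

    The masked region is mean-centred (zero outside the mask), transformed with
    a 2-D FFT, and filtered with differences of isotropic ideal low-pass
    filters at successive scales: the band at scale ``s_i`` passes spatial
    periods in ``[s_i, s_{i+1})`` (the last band extends to infinity, DC
    excluded). Band energy is the sum of squared filtered pixel values inside
    the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    image = np.asarray(image, dtype=float)
    scales = default_band_scales(mask) if band_scales is None else np.asarray(band_scales, float)
    if scales.size < 2:
        raise ValueError("at least 2 band scales required")
    if np.any(np.diff(scales) <= 0):
        raise ValueError("band scales must be strictly increasing")

    centred = np.zeros_like(image)
    centred[mask] = image[mask] - image[mask].mean()
    spec = np.fft.fft2(centred)
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    freq = np.hypot(fy, fx)  # cycles per pixel; period = 1 / freq

    energies = np.empty(scales.size)
    for i, s in enumerate(scales):
        f_hi = 1.0 / s  # shortest period in band
        f_lo = 1.0 / scales[i + 1] if i + 1 < scales.size else 0.0
        band = (freq > f_lo) & (freq <= f_hi)
        band[0, 0] = False
        filtered = np.real(np.fft.ifft2(np.where(band, spec, 0.0)))
        energies[i] = float(np.sum(filtered[mask] ** 2))
    return GranularitySpectrum(band_scales=scales, band_energy=energies)


# ---------------------------------------------------------------------------
# pattern metrics
# ---------------------------------------------------------------------------


@dataclass
class PatternMetrics:
    """Five pattern metrics; all zero for an immaculate (unmarked) egg."""

    marking_size: float
    dominance: float
    contrast: float
    coverage: float
    dispersion: float

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in PATTERN_COLUMNS}


def _background_mode(values: np.ndarray, bins: int = 256) -> float:
    hist, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2.0)


def segment_markings(image: np.ndarray, mask: np.ndarray, k_mad: float = 3.0) -> np.ndarray:
    """Boolean marking segmentation inside the mask.

    The background level is the intensity histogram mode inside the mask; a
    pixel is marked when it deviates from the mode by more than ``k_mad`` times
    the median absolute deviation. For a noise-free background (MAD = 0) any
    deviation beyond half a grayscale bin counts as marked.
    """
    vals = image[mask]
    mode = _background_mode(vals)
    mad = float(np.median(np.abs(vals - mode)))
    thresh = k_mad * mad if mad > 0 else 1.0 / 512.0
    marked = np.zeros_like(mask)
    marked[mask] = np.abs(image[mask] - mode) > thresh
    return marked


def _pole_axis_halves(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split the mask into two halves along its principal (pole-to-pole) axis.

    Falls back to the image vertical axis, with a warning, when the mask is too
    symmetric for the principal axis to be defined.
    """
    ys, xs = np.nonzero(mask)
    y0, x0 = ys.mean(), xs.mean()
    cyy = np.mean((ys - y0) ** 2)
    cxx = np.mean((xs - x0) ** 2)
    cyx = np.mean((ys - y0) * (xs - x0))
    cov = np.array([[cyy, cyx], [cyx, cxx]])
    evals, evecs = np.linalg.eigh(cov)
    if np.isclose(evals[0], evals[1], rtol=1e-3):
        logger.warning("mask is rotation-symmetric; falling back to the image vertical axis")
        axis = np.array([1.0, 0.0])
    else:
        axis = evecs[:, -1]
    proj = (ys - y0) * axis[0] + (xs - x0) * axis[1]
    half_a = np.zeros_like(mask)
    half_b = np.zeros_like(mask)
    half_a[ys[proj <= 0], xs[proj <= 0]] = True
    half_b[ys[proj > 0], xs[proj > 0]] = True
    return half_a, half_b


def pattern_metrics(
    image: np.ndarray,
    mask: np.ndarray,
    granularity: GranularitySpectrum | None = None,
    k_mad: float = 3.0,
) -> PatternMetrics:
    """Compute the five pattern metrics for one egg photograph.

    marking_size: scale of the maximum-energy band; dominance: its share of
    total band energy; contrast: total band energy per masked pixel; coverage:
    marked-pixel fraction from :func:`segment_markings`; dispersion: normalized
    absolute difference in coverage between the two pole halves. An immaculate
    egg (zero coverage) forces all five metrics to zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if granularity is None:
        granularity = granularity_analysis(image, mask)
    marked = segment_markings(image, mask, k_mad=k_mad)
    n_mask = int(mask.sum())
    coverage = float(marked.sum() / n_mask)
    if coverage == 0.0:
        return PatternMetrics(0.0, 0.0, 0.0, 0.0, 0.0)

    total = granularity.total_energy()
    dominance = float(granularity.band_energy.max() / total) if total > 0 else 0.0
    contrast = total / n_mask
    half_a, half_b = _pole_axis_halves(mask)
    cov_a = marked[half_a].sum() / max(1, half_a.sum())
    cov_b = marked[half_b].sum() / max(1, half_b.sum())
    dispersion = 0.0 if cov_a + cov_b == 0 else float(abs(cov_a - cov_b) / (cov_a + cov_b))
    return PatternMetrics(
        marking_size=granularity.dominant_scale(),
        dominance=dominance,
        contrast=contrast,
        coverage=coverage,
        dispersion=dispersion,
    )


# ---------------------------------------------------------------------------
# within-family standardization
# ---------------------------------------------------------------------------


def standardize_within_family(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    family_column: str = "family",
) -> pd.DataFrame:
    """Express luminance and pattern metrics as proportions of the family maximum.

    Each listed attribute is divided by its maximum within its family (the two
    families are standardized separately), so within every family each
    attribute attains 1 at its family maximum. Cone catches are not listed by
    default: they are already standardized to sum to one. An attribute whose
    family maximum is 0 standardizes to all-zero with a warning.
    """
    columns = ["luminance_raw"] + PATTERN_COLUMNS if columns is None else columns
    out = table.copy()
    for col in columns:
        if (out[col] < 0).any():
            raise ValueError(f"negative raw values in column {col!r}")
        maxima = out.groupby(family_column)[col].transform("max")
        zero = maxima == 0
        if zero.any():
            warnings.warn(f"family maximum of {col!r} is 0; standardizing to 0", stacklevel=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[col] = np.where(zero, 0.0, out[col] / maxima)
    if "luminance_raw" in out.columns:
        out = out.rename(columns={"luminance_raw": "luminance_std"})
    return out
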