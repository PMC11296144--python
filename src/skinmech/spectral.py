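"""Layer-wise strain estimation from image pairs via spectral centroids.

An LC-OCT or ultrasound B-scan of skin is a textured image; stretching the
tissue stretches the texture, scaling its spatial-frequency content.  The
magnitude-weighted mean spatial frequency of the image spectrum (the spectral
centre of gravity) therefore shifts in inverse proportion to the stretch, and
its reciprocal — the centroid wavelength λc — in direct proportion.
Comparing centroid wavelengths of a rest image (λ0) and a stretched image
(λ1) of the same region gives the engineering strain per axis:

    εx = (λx1c - λx0c) / λx0c,    εy = (λy1c - λy0c) / λy0c

and Poisson's ratio ν = -εy/εx.  Axis convention: x is the image column axis
(stretch direction), y the row axis (depth); both are configurable through
the pixel pitches of :class:`ImageGrid`.

The centroid weights are spectral magnitudes over the strictly positive
frequency half-axis (bins up to Nyquist, DC excluded); strains are invariant
to the wavelength convention λ = K/u for any constant K, and λ = 1/u (cycles
per µm) is used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .errors import InvalidInputError, UndefinedCentroidError, UndefinedRatioError

__all__ = [
    "ImageGrid",
    "Spectrum",
    "CentroidResult",
    "LayerROI",
    "StrainPair",
    "RoiStrain",
    "spectrum",
    "centroid_frequencies",
    "strain_from_wavelengths",
    "strains_from_centroids",
    "strains_from_pair",
    "poisson_ratio",
    "autocorrelation",
]

LAYER_NAMES = ("epidermis", "superficial dermis", "deep dermis",
               "hypodermis", "fascia")


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D grayscale image with physical pixel pitch.

    ``intensities``: (N rows × M cols) finite real array; ``pitch_x`` /
    ``pitch_y``: µm per pixel along columns (x) / rows (y).
    """

    intensities: np.ndarray
    pitch_x: float = 1.0
    pitch_y: float = 1.0

    def __post_init__(self) -> None:
        img = np.asarray(self.intensities, dtype=float)
        if img.ndim != 2 or img.shape[0] < 16 or img.shape[1] < 16:
            raise InvalidInputError("image must be 2-D, at least 16x16")
        if not np.all(np.isfinite(img)):
            raise InvalidInputError("image intensities must be finite")
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise InvalidInputError("pixel pitches must be > 0")
        object.__setattr__(self, "intensities", img)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def crop(self, rows: tuple[int, int], cols: tuple[int, int]) -> "ImageGrid":
        r0, r1 = rows
        c0, c1 = cols
        n, m = self.shape
        if not (0 <= r0 < r1 <= n and 0 <= c0 < c1 <= m):
            raise InvalidInputError("crop ranges must be non-empty and inside the image")
        return ImageGrid(self.intensities[r0:r1, c0:c1], self.pitch_x, self.pitch_y)


@dataclass(frozen=True)
class Spectrum:
    """2-D DFT of a (demeaned, optionally windowed) image with its physical
    frequency axes: ``u`` along columns/x, ``v`` along rows/y (cycles/µm,
    numpy fft ordering)."""

    values: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def off_dc_energy(self) -> float:
        """Total squared magnitude outside the DC bin."""
        mag2 = np.abs(self.values) ** 2
        return float(mag2.sum() - mag2[0, 0])


@dataclass(frozen=True)
class CentroidResult:
    """Centroid spatial frequencies (cycles/µm) and wavelengths (µm) of an
    image along x and y."""

    uxc: float
    vyc: float
    lambda_xc: float
    lambda_yc: float


@dataclass(frozen=True)
class LayerROI:
    """Named axis-aligned rectangular region, 0-based half-open pixel ranges."""

    name: str
    rows: tuple[int, int]
    cols: tuple[int, int]

    def __post_init__(self) -> None:
        if self.rows[0] >= self.rows[1] or self.cols[0] >= self.cols[1]:
            raise InvalidInputError(f"ROI '{self.name}': ranges must be non-empty")
        if self.rows[0] < 0 or self.cols[0] < 0:
            raise InvalidInputError(f"ROI '{self.name}': ranges must be >= 0")

    def validate_in(self, img: ImageGrid) -> None:
        n, m = img.shape
        if self.rows[1] > n or self.cols[1] > m:
            raise InvalidInputError(f"ROI '{self.name}' exceeds image bounds")


@dataclass(frozen=True)
class StrainPair:
    """Engineering strains of one layer along x and y (both > -1)."""

    eps_x: float
    eps_y: float

    def __post_init__(self) -> None:
        if self.eps_x <= -1.0 or self.eps_y <= -1.0:
            raise InvalidInputError("strains must exceed -1")

    @property
    def nu(self) -> float | None:
        """Poisson's ratio -εy/εx, or None when εx = 0."""
        return None if self.eps_x == 0.0 else -self.eps_y / self.eps_x


@dataclass(frozen=True)
class RoiStrain:
    """Per-ROI strain outcome; ``error`` is set (and ``strain`` None) when the
    centroid was undefined in either image."""

    name: str
    strain: StrainPair | None
    error: str | None = None


# ---------------------------------------------------------------------------
# spectrum and centroids


def spectrum(img: ImageGrid, window: str | None = "hann",
             demean: bool = True) -> Spectrum:
    """Discrete 2-D Fourier transform of an image region.

    The mean is removed and a separable Hann window applied by default to
    suppress leakage from ROI edges (``window=None`` disables windowing, as
    required when comparing against plain-DFT oracles).  Frequency axes are
    ``u_i = i/(M Δx)`` and ``v_j = j/(N Δy)`` in cycles/µm.
    """
    f = img.intensities
    if demean:
        f = f - f.mean()
    if window is not None:
        if window != "hann":
            raise InvalidInputError("supported windows: 'hann' or None")
        n, m = f.shape
        f = f * np.outer(hann(n, sym=False), hann(m, sym=False))
    values = np.fft.fft2(f)
    u = np.fft.fftfreq(f.shape[1], d=img.pitch_x)
    v = np.fft.fftfreq(f.shape[0], d=img.pitch_y)
    return Spectrum(values=values, u=u, v=v)


def _half_axis_centroid(mag: np.ndarray, freqs: np.ndarray, axis: int) -> float:
    """Magnitude-weighted mean frequency over the strictly positive
    frequency half-axis (all bins of the other axis contribute)."""
    pos = freqs > 0
    w = mag[pos, :] if axis == 0 else mag[:, pos]
    total = w.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise UndefinedCentroidError("no off-DC spectral energy on positive half-axis")
    fw = freqs[pos]
    num = (w * fw[:, None]).sum() if axis == 0 else (w * fw[None, :]).sum()
    return float(num / total)


def centroid_frequencies(spec: Spectrum,
                         wavelength_constant: float = 1.0) -> CentroidResult:
    """Spectral centre of gravity along x and y.

    ``uxc = Σ u |F| / Σ |F|`` over bins with u > 0 (all v), and symmetrically
    for ``vyc``; the DC bin is excluded by construction.  Wavelengths are
    ``λ = K / f`` with ``K = wavelength_constant`` (strains derived from
    wavelength ratios are invariant to K).
    """
    mag = np.abs(spec.values)
    uxc = _half_axis_centroid(mag, spec.u, axis=1)
    vyc = _half_axis_centroid(mag, spec.v, axis=0)
    return CentroidResult(uxc=uxc, vyc=vyc,
                          lambda_xc=wavelength_constant / uxc,
                          lambda_yc=wavelength_constant / vyc)


# ---------------------------------------------------------------------------
# strains


def strain_from_wavelengths(lambda0: float, lambda1: float) -> float:
    """Engineering strain from centroid wavelengths before/after stretch."""
    if lambda0 <= 0:
        raise InvalidInputError("reference wavelength must be > 0")
    return (lambda1 - lambda0) / lambda0


def strains_from_centroids(c0: CentroidResult, c1: CentroidResult) -> StrainPair:
    """Strain pair from rest (c0) and stretched (c1) centroid wavelengths."""
    return StrainPair(
        eps_x=strain_from_wavelengths(c0.lambda_xc, c1.lambda_xc),
        eps_y=strain_from_wavelengths(c0.lambda_yc, c1.lambda_yc),
    )


def strains_from_pair(
    img0: ImageGrid,
    img1: ImageGrid,
    rois: list[LayerROI] | None = None,
    window: str | None = "hann",
) -> list[RoiStrain]:
    """Per-layer strains between a rest image and a stretched image.

    Each ROI must be valid in both images and both images must share pixel
    pitch.  Elongation along x gives εx > 0; thinning along y gives εy < 0.
    A centroid failure in one ROI is reported in that ROI's ``error`` entry;
    the remaining ROIs are unaffected.
    """
    if not (np.isclose(img0.pitch_x, img1.pitch_x)
            and np.isclose(img0.pitch_y, img1.pitch_y)):
        raise InvalidInputError("images must share pixel pitch")
    if rois is None:
        n = min(img0.shape[0], img1.shape[0])
        m = min(img0.shape[1], img1.shape[1])
        rois = [LayerROI("full", (0, n), (0, m))]
    out: list[RoiStrain] = []
    for roi in rois:
        try:
            roi.validate_in(img0)
            roi.validate_in(img1)
            c0 = centroid_frequencies(spectrum(img0.crop(roi.rows, roi.cols), window))
            c1 = centroid_frequencies(spectrum(img1.crop(roi.rows, roi.cols), window))
            out.append(RoiStrain(roi.name, strains_from_centroids(c0, c1)))
        except (UndefinedCentroidError, InvalidInputError) as exc:
            out.append(RoiStrain(roi.name, None, error=str(exc)))
    return out


def poisson_ratio(s: StrainPair) -> float:
    """Poisson's ratio ν = -εy/εx (undefined when εx = 0)."""
    if s.eps_x == 0.0:
        raise UndefinedRatioError("Poisson's ratio undefined for eps_x = 0")
    return -s.eps_y / s.eps_x


# ---------------------------------------------------------------------------
# autocorrelation


def autocorrelation(img: ImageGrid, demean: bool = True) -> np.ndarray:
    """Normalized (periodic) spatial autocorrelation of an image.

    Computed via the Wiener–Khinchin route — inverse transform of the power
    spectrum of the demeaned image — then shifted so zero lag sits at the
    array centre with value 1.  Stretched texture shows up as an elongated
    central lobe, which is how layer stretching is visualized.
    """
    f = img.intensities
    if demean:
        f = f - f.mean()
    power = np.abs(np.fft.fft2(f)) ** 2
    ac = np.real(np.fft.ifft2(power))
    peak = ac.flat[0]
    if peak <= 0.0:
        raise UndefinedCentroidError("autocorrelation undefined for a constant image")
    return np.fft.fftshift(ac / peak)
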