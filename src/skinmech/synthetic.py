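"""Synthetic inputs standing in for the in vivo extension device.

Three generators mirror the pipeline's data sources:

* :func:`simulate_relaxation_record` — ramp-and-hold stress records from
  known Maxwell parameters (the forward hereditary-integral model plus
  additive Gaussian sensor noise);
* :func:`make_bilinear_curve` — piecewise-linear loading curves with
  multiplicative noise, ground truth for the two-slope extractor;
* :func:`make_texture` / :func:`stretch_image` / :func:`make_layered_image`
  — band-limited random textures deformed by known affine stretches,
  optionally stacked into layered LC-OCT/ultrasound-like images.

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

from .errors import InvalidSpecError
from .rheology import (
    MaxwellBranches,
    RelaxationRecord,
    TestProtocol,
    branches_to_prony,
    stress_response,
)
from .spectral import ImageGrid, LayerROI

__all__ = [
    "TextureSpec",
    "LayerSpec",
    "LayeredImageSpec",
    "make_texture",
    "stretch_image",
    "make_layered_image",
    "default_layered_spec",
    "REFERENCE_LAYER_STRAINS",
    "simulate_relaxation_record",
    "make_bilinear_curve",
    "draw_subject_branches",
]

# per-layer (eps_x, eps_y) ground truth used for layered fixtures: elongation
# along the pull axis, thinning in depth, ordered surface to fascia
REFERENCE_LAYER_STRAINS: dict[str, tuple[float, float]] = {
    "epidermis": (0.22, -0.095),
    "superficial dermis": (0.37, -0.15),
    "deep dermis": (0.193, -0.059),
    "hypodermis": (0.0948, -0.044),
    "fascia": (0.0618, -0.025),
}


@dataclass(frozen=True)
class TextureSpec:
    """Band-limited Gaussian random-field texture.

    ``band`` = (low, high) spatial-frequency limits in cycles/µm applied per
    axis (|u| and |v| each inside the band), so the marginal spectral
    centroid of either axis sits mid-band.
    """

    rows: int = 256
    cols: int = 256
    pitch: float = 1.0
    band: tuple[float, float] = (0.04, 0.12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 32 or self.cols < 32:
            raise InvalidSpecError("texture must be at least 32x32")
        if self.pitch <= 0:
            raise InvalidSpecError("pitch must be > 0")
        low, high = self.band
        nyquist = 0.5 / self.pitch
        if not 0.0 < low < high <= nyquist:
            raise InvalidSpecError("band must satisfy 0 < low < high <= Nyquist")


def make_texture(spec: TextureSpec) -> ImageGrid:
    """Deterministic band-limited Gaussian random field, unit variance."""
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((spec.rows, spec.cols))
    u = np.fft.fftfreq(spec.cols, d=spec.pitch)
    v = np.fft.fftfreq(spec.rows, d=spec.pitch)
    low, high = spec.band
    mask = ((low <= np.abs(u))[None, :] & (np.abs(u) <= high)[None, :]
            & (low <= np.abs(v))[:, None] & (np.abs(v) <= high)[:, None])
    if not mask.any():
        raise InvalidSpecError("band contains no frequency bins at this image size")
    field = np.real(np.fft.ifft2(np.fft.fft2(white) * mask))
    field = (field - field.mean()) / field.std()
    return ImageGrid(field, pitch_x=spec.pitch, pitch_y=spec.pitch)


def stretch_image(img: ImageGrid, eps_x: float, eps_y: float,
                  order: int = 3) -> ImageGrid:
    """Resample a texture under the affine map (x, y) → ((1+εx)x, (1+εy)y).

    Cubic-spline interpolation on the same pixel pitch; the output covers the
    mapped support, i.e. shape (⌊N(1+εy)⌋, ⌊M(1+εx)⌋) — an edge crop rather
    than padding, so no out-of-support content contaminates the spectrum.
    """
    if eps_x <= -1.0 or eps_y <= -1.0:
        raise InvalidSpecError("strains must exceed -1")
    n, m = img.shape
    out_shape = (max(int(math.floor(n * (1.0 + eps_y))), 1),
                 max(int(math.floor(m * (1.0 + eps_x))), 1))
    matrix = np.array([1.0 / (1.0 + eps_y), 1.0 / (1.0 + eps_x)])
    warped = affine_transform(img.intensities, matrix, output_shape=out_shape,
                              order=order, mode="mirror")
    return ImageGrid(warped, pitch_x=img.pitch_x, pitch_y=img.pitch_y)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a layered image: row extent (half-open) and imposed strains."""

    name: str
    rows: tuple[int, int]
    eps_x: float
    eps_y: float

    def __post_init__(self) -> None:
        if self.rows[1] - self.rows[0] < 16:
            raise InvalidSpecError(f"layer '{self.name}' must span >= 16 rows")
        if self.eps_x <= -1.0 or self.eps_y <= -1.0:
            raise InvalidSpecError("strains must exceed -1")


@dataclass(frozen=True)
class LayeredImageSpec:
    """Vertical stack of textured layers, each with its own imposed stretch.

    Layer extents must tile [0, total rows) contiguously without overlap.
    """

    layers: tuple[LayerSpec, ...]
    cols: int = 256
    pitch: float = 1.0
    band: tuple[float, float] = (0.04, 0.12)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layers:
            raise InvalidSpecError("need at least one layer")
        edge = 0
        for layer in self.layers:
            if layer.rows[0] != edge:
                raise InvalidSpecError(
                    f"layer '{layer.name}' starts at {layer.rows[0]}, expected {edge}: "
                    "extents must tile without overlap or gap")
            edge = layer.rows[1]
        if self.cols < 32:
            raise InvalidSpecError("image must be at least 32 columns wide")


def default_layered_spec(seed: int = 0) -> LayeredImageSpec:
    """Five-layer stack (epidermis → fascia) carrying the reference strain
    magnitudes of :data:`REFERENCE_LAYER_STRAINS`."""
    thickness = {"epidermis": 96, "superficial dermis": 144, "deep dermis": 144,
                 "hypodermis": 144, "fascia": 96}
    layers = []
    r0 = 0
    for name, (ex, ey) in REFERENCE_LAYER_STRAINS.items():
        r1 = r0 + thickness[name]
        layers.append(LayerSpec(name, (r0, r1), ex, ey))
        r0 = r1
    return LayeredImageSpec(layers=tuple(layers), seed=seed)


def make_layered_image(
    spec: LayeredImageSpec,
) -> tuple[ImageGrid, ImageGrid, list[LayerROI]]:
    """Rest and stretched layered images plus the analysis ROIs.

    Each layer's texture is generated oversized, stretched by the layer's
    (εx, εy), and both states are cropped to the same fixed window, so one
    ROI list is valid for both images (fixed analysis windows over deforming
    texture, as when a probe stares at a stretching tissue).
    """
    rng = np.random.default_rng(spec.seed)
    total_rows = spec.layers[-1].rows[1]
    rest = np.empty((total_rows, spec.cols))
    stretched = np.empty((total_rows, spec.cols))
    rois = []
    for layer in spec.layers:
        r0, r1 = layer.rows
        h = r1 - r0
        base_rows = max(h, int(math.ceil(h / (1.0 + layer.eps_y)))) + 8
        base_cols = max(spec.cols,
                        int(math.ceil(spec.cols / (1.0 + layer.eps_x)))) + 8
        tex_spec = TextureSpec(rows=max(base_rows, 32), cols=max(base_cols, 32),
                               pitch=spec.pitch, band=spec.band,
                               seed=int(rng.integers(0, 2**31 - 1)))
        tex = make_texture(tex_spec)
        rest[r0:r1] = tex.intensities[:h, :spec.cols]
        warped = stretch_image(tex, layer.eps_x, layer.eps_y)
        stretched[r0:r1] = warped.intensities[:h, :spec.cols]
        rois.append(LayerROI(layer.name, (r0, r1), (0, spec.cols)))
    img_rest = ImageGrid(rest, pitch_x=spec.pitch, pitch_y=spec.pitch)
    img_stretched = ImageGrid(stretched, pitch_x=spec.pitch, pitch_y=spec.pitch)
    return img_rest, img_stretched, rois


# ---------------------------------------------------------------------------
# mechanical records


def simulate_relaxation_record(
    b: MaxwellBranches,
    proto: TestProtocol = TestProtocol(),
    noise_frac: float = 0.01,
    seed: int = 0,
    dt: float = 0.02,
    form: str = "standard",
) -> RelaxationRecord:
    """Forward-simulate a ramp-and-hold stress record.

    Each cycle ramps at rate pad_speed/pad_gap to the target strain (4 s with
    the default protocol), holds for the hold time, then releases
    instantaneously to zero strain at the cycle boundary.  Additive Gaussian
    noise with standard deviation ``noise_frac`` × peak stress emulates the
    load cell; the record is deterministic given ``seed``.
    """
    if noise_frac < 0:
        raise InvalidSpecError("noise_frac must be >= 0")
    if dt <= 0:
        raise InvalidSpecError("dt must be > 0")
    cycle_time = proto.ramp_time_s + proto.hold_time_s
    n_steps = int(round(proto.n_cycles * cycle_time / dt))
    t = np.arange(n_steps) * dt
    cycle = np.minimum((t / cycle_time).astype(int), proto.n_cycles - 1) + 1
    tc = t - (cycle - 1) * cycle_time
    in_ramp = tc < proto.ramp_time_s
    phase = np.where(in_ramp, "ramp", "hold")
    strain = np.minimum(proto.strain_rate * tc, proto.target_strain)
    prony = branches_to_prony(b, form=form)
    sigma = stress_response(prony, t, strain)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma + rng.normal(0.0, noise_frac * np.max(np.abs(sigma)), n_steps)
    return RelaxationRecord(t=t, y=sigma, phase=phase, cycle=cycle,
                            strain_history=strain, units="Pa")


def make_bilinear_curve(
    E1: float,
    E2: float,
    break_strain: float = 0.10,
    max_strain: float = 0.20,
    n: int = 200,
    noise_frac: float = 0.01,
    seed: int = 0,
):
    """Continuous piecewise-linear loading curve with multiplicative noise."""
    from .bilinear import LoadingCurve

    if E1 <= 0 or E2 <= 0:
        raise InvalidSpecError("moduli must be > 0")
    if not 0.0 < break_strain < max_strain:
        raise InvalidSpecError("need 0 < break_strain < max_strain")
    if n < 8:
        raise InvalidSpecError("need at least 8 samples")
    strain = np.linspace(0.0, max_strain, n)
    stress = np.where(strain <= break_strain, E1 * strain,
                      E1 * break_strain + E2 * (strain - break_strain))
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        stress = stress * (1.0 + rng.normal(0.0, noise_frac, n))
    return LoadingCurve(strain=strain, stress=stress)


# ---------------------------------------------------------------------------
# cohort draws for demo fixtures

# 135° population values (Pa / s): mean forearm parameters with interindividual
# spread; 45° obtained per subject via anisotropy ratios, so directional
# dominance is built into every subject
_E0_135 = (209.6e3, 80.0e3, 60.0e3, 500.0e3)   # mean, sd, clip lo, clip hi
_E1_135 = (417.2e3, 150.0e3, 120.0e3, 900.0e3)
_TAU_135 = (3.0, 0.8, 1.0, 6.0)
_RATIO_E0 = 680.4 / 209.6
_RATIO_E1 = 1382.5 / 417.2
_RATIO_TAU = (890.3 / 172.1) / _RATIO_E1   # viscosity ratio over stiffness ratio


def _draw(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def draw_subject_branches(rng: np.random.Generator) -> dict[str, MaxwellBranches]:
    """One subject's single-branch Maxwell parameters for both directions.

    The 135° (across natural tension lines) parameters are drawn around the
    population means; the 45° (along the lines) parameters multiply the same
    subject's values by anisotropy ratios jittered ±10%, making the skin
    stiffer and more viscous along the lines for every subject.
    """
    E0 = _draw(rng, *_E0_135)
    E1 = _draw(rng, *_E1_135)
    tau = _draw(rng, *_TAU_135)
    b135 = MaxwellBranches(E0=E0, branches=((E1, tau * E1),))
    r_e0 = _RATIO_E0 * (1.0 + 0.1 * rng.standard_normal())
    r_e1 = _RATIO_E1 * (1.0 + 0.1 * rng.standard_normal())
    r_tau = _RATIO_TAU * (1.0 + 0.1 * rng.standard_normal())
    E1_45 = E1 * max(r_e1, 1.1)
    tau_45 = tau * max(r_tau, 1.1)
    b45 = MaxwellBranches(E0=E0 * max(r_e0, 1.1),
                          branches=((E1_45, tau_45 * E1_45),))
    return {"45": b45, "135": b135}
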