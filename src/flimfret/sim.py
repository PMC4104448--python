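"""Synthetic TCSPC decays, FLIM image stacks and binding series with ground truth.

The generative model is the exact twin of what the fitters assume: a donor
population of which a fraction f_D relaxes through FRET with a shortened
lifetime tau_F while the remainder keeps the unperturbed donor lifetime
tau_D,

    I(t) = I0 [ f_D exp(-t/tau_F) + (1 - f_D) exp(-t/tau_D) ],

convolved with the instrument response, plus a uniform background, with
independent Poisson counting noise per channel. Image stacks place
endosome-like puncta on a diffuse cytosolic background inside a cell mask
and carry their per-pixel ground-truth maps along.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .tcspc import IRFSpec, TCSPCConfig

__all__ = [
    "TwoSpeciesParams",
    "FLIMStack",
    "Punctum",
    "SceneSpec",
    "BindingSeries",
    "model_decay",
    "simulate_decay",
    "build_scene_maps",
    "simulate_flim_image",
    "simulate_binding_series",
    "donor_only_scene",
    "coexpression_scene",
]

# Fixed lifetimes of the donor (mTFP1) and the FRET-quenched species, ns.
DONOR_LIFETIME_NS = 2.65
FRET_LIFETIME_NS = 0.83


@dataclass(frozen=True)
class TwoSpeciesParams:
    """Parameters of the two-species donor decay model.

    f_D is the fraction of interacting donor (amplitude fraction decaying
    with the FRET lifetime); total_intensity is the expected photon count
    I0 integrated over an infinite window; background is the expected count
    per channel from uncorrelated (dark/room) photons.
    """

    f_D: float = 0.0
    tau_D: float = DONOR_LIFETIME_NS
    tau_F: float = FRET_LIFETIME_NS
    total_intensity: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.f_D, self.tau_D, self.tau_F, self.total_intensity, self.background)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite decay parameter")
        if not 0.0 <= self.f_D <= 1.0:
            raise ValueError("f_D must lie in [0, 1]")
        if not 0.0 < self.tau_F < self.tau_D:
            raise ValueError("lifetimes must satisfy 0 < tau_F < tau_D")
        if self.total_intensity < 0 or self.background < 0:
            raise ValueError("total_intensity and background must be >= 0")


@dataclass
class FLIMStack:
    """Per-pixel photon-count histograms with acquisition metadata.

    counts is an integer array indexed (row, col, channel). For synthetic
    stacks, ``truth`` carries the ground-truth per-pixel maps (keys
    ``f_D``, ``tau_D``, ``tau_F``, ``intensity``) and ``provenance`` the
    seed and generator parameters.
    """

    counts: np.ndarray
    config: TCSPCConfig
    irf: IRFSpec
    truth: dict[str, np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be (rows, cols, channels)")
        if c.shape[2] != self.config.n_channels:
            raise ValueError("channel axis does not match config.n_channels")
        if np.any(c < 0):
            raise ValueError("negative photon counts")
        self.counts = c
        if self.truth is not None:
            for key, m in self.truth.items():
                if np.shape(m)[:2] != c.shape[:2]:
                    raise ValueError(f"truth map {key!r} shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    def photon_image(self) -> np.ndarray:
        """Total photons per pixel (sum over the time axis)."""
        return self.counts.sum(axis=2)


def _channel_mass(tau: float, config: TCSPCConfig, wrap: bool) -> np.ndarray:
    """Photon probability mass per channel of a unit-area exponential decay.

    Without wraparound the masses over an infinite window sum to 1 and the
    returned (truncated) vector sums to 1 - exp(-T/tau). With wraparound the
    tail from preceding excitation pulses is folded back in, so the vector
    sums to exactly 1 over one repetition period.
    """
    edges = config.channel_edges()
    mass = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
    if wrap:
        mass /= 1.0 - math.exp(-config.repetition_period / tau)
    return mass


def model_decay(
    params: TwoSpeciesParams,
    config: TCSPCConfig,
    irf: IRFSpec,
    wrap: bool = False,
) -> np.ndarray:
    """Expected photon counts per channel of the two-species decay model.

    f_D is the pre-exponential (amplitude) fraction of the FRET species in
    I(t) = I0 [f_D exp(-t/tau_F) + (1-f_D) exp(-t/tau_D)]; each species
    therefore contributes photons in proportion to amplitude x lifetime,
    and the expectation is scaled so the infinite-window photon total is
    ``total_intensity``. The pure decay (integrated over each channel) is
    convolved with the normalized IRF; with ``wrap=True`` both the decay
    and the convolution are circular over the repetition period
    (incomplete-decay correction). Setting f_D = 0 reduces exactly to the
    single-exponential donor model.
    """
    photon_norm = params.f_D * params.tau_F + (1.0 - params.f_D) * params.tau_D
    mass = (
        params.f_D * params.tau_F * _channel_mass(params.tau_F, config, wrap)
        + (1.0 - params.f_D) * params.tau_D * _channel_mass(params.tau_D, config, wrap)
    ) / photon_norm
    profile = irf.profile(config)
    if wrap:
        conv = np.fft.irfft(
            np.fft.rfft(mass) * np.fft.rfft(profile), n=config.n_channels
        )
    else:
        conv = fftconvolve(mass, profile)[: config.n_channels]
    expected = params.total_intensity * conv + params.background
    # fftconvolve roundoff can leave tiny negatives on empty channels
    return np.clip(expected, 0.0, None)


def simulate_decay(
    params: TwoSpeciesParams,
    config: TCSPCConfig,
    irf: IRFSpec,
    seed: int | np.random.Generator,
    wrap: bool = False,
) -> np.ndarray:
    """Draw one Poisson-noise TCSPC histogram from the model expectation."""
    rng = np.random.default_rng(seed)
    return rng.poisson(model_decay(params, config, irf, wrap=wrap))


# ---------------------------------------------------------------------------
# image scenes


@dataclass(frozen=True)
class Punctum:
    """An endosome-like spot: disk of given center/radius (pixels) adding
    ``intensity`` expected photons per pixel and imposing its own f_D."""

    center: tuple[float, float]
    radius: float
    intensity: float
    f_D: float = 0.0


@dataclass(frozen=True)
class SceneSpec:
    """Spatial layout of a synthetic cell: puncta over a diffuse background.

    Expected photons per pixel are diffuse_background_intensity inside the
    cell mask, plus each punctum's intensity inside its disk; f_D is the
    punctum's value inside puncta and diffuse_f_D elsewhere in the cell.
    """

    image_shape: tuple[int, int]
    puncta: tuple[Punctum, ...] = ()
    diffuse_background_intensity: float = 0.0
    diffuse_f_D: float = 0.0
    cell_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise ValueError("image_shape must be positive")
        for p in self.puncta:
            if not (0 <= p.center[0] < rows and 0 <= p.center[1] < cols):
                raise ValueError("punctum center outside image")
            if p.radius <= 0:
                raise ValueError("punctum radius must be > 0")
            if p.intensity < 0:
                raise ValueError("punctum intensity must be >= 0")
        if self.diffuse_background_intensity < 0:
            raise ValueError("diffuse intensity must be >= 0")
        if not self.puncta and self.diffuse_background_intensity == 0:
            raise ValueError("empty scene: no puncta and no diffuse signal")


def build_scene_maps(scene: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (f_D map, expected-intensity map, cell mask) from the geometry.

    Deterministic; used both by the simulator and by tests that need the
    ground truth before any photon is drawn.
    """
    rows, cols = scene.image_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = (
        np.ones((rows, cols), dtype=bool)
        if scene.cell_mask is None
        else np.asarray(scene.cell_mask, dtype=bool)
    )
    intensity = np.where(mask, scene.diffuse_background_intensity, 0.0)
    f_map = np.where(mask, scene.diffuse_f_D, 0.0)
    for p in scene.puncta:
        disk = ((rr - p.center[0]) ** 2 + (cc - p.center[1]) ** 2) <= p.radius**2
        disk &= mask
        intensity[disk] += p.intensity
        f_map[disk] = p.f_D
    return f_map, intensity, mask


def simulate_flim_image(
    scene: SceneSpec,
    donor_params: TwoSpeciesParams,
    config: TCSPCConfig,
    irf: IRFSpec,
    seed: int | np.random.Generator,
    wrap: bool = False,
) -> FLIMStack:
    """Simulate a FLIM stack for a scene, carrying ground-truth maps.

    ``donor_params`` supplies the lifetimes and per-channel background; the
    scene supplies per-pixel f_D and expected total intensity. Pixels
    sharing an f_D value share one normalized decay shape, scaled by the
    pixel intensity, before per-channel Poisson sampling.
    """
    rng = np.random.default_rng(seed)
    f_map, intensity, mask = build_scene_maps(scene)
    rows, cols = scene.image_shape
    expected = np.zeros((rows, cols, config.n_channels))
    for f in np.unique(f_map):
        shape_params = replace(donor_params, f_D=float(f), total_intensity=1.0, background=0.0)
        shape = model_decay(shape_params, config, irf, wrap=wrap)
        sel = f_map == f
        expected[sel] = intensity[sel, None] * shape[None, :]
    expected += donor_params.background
    counts = rng.poisson(expected)
    truth = {
        "f_D": f_map,
        "tau_D": np.full((rows, cols), donor_params.tau_D),
        "tau_F": np.full((rows, cols), donor_params.tau_F),
        "intensity": intensity,
        "cell_mask": mask,
    }
    provenance = {
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
        "tau_D": donor_params.tau_D,
        "tau_F": donor_params.tau_F,
        "background": donor_params.background,
        "wrap": wrap,
    }
    return FLIMStack(counts=counts, config=config, irf=irf, truth=truth, provenance=provenance)


def _default_cell_mask(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    return ((rr - rows / 2) / (rows / 2.2)) ** 2 + (
        (cc - cols / 2) / (cols / 2.2)
    ) ** 2 <= 1.0


def _preset_puncta(
    shape: tuple[int, int],
    n_puncta: int,
    intensity: float,
    f_D: float,
    rng: np.random.Generator,
) -> tuple[Punctum, ...]:
    rows, cols = shape
    mask = _default_cell_mask(shape)
    puncta = []
    while len(puncta) < n_puncta:
        r = rng.uniform(0.15 * rows, 0.85 * rows)
        c = rng.uniform(0.15 * cols, 0.85 * cols)
        if mask[int(r), int(c)]:
            puncta.append(
                Punctum(center=(r, c), radius=rng.uniform(1.5, 3.0), intensity=intensity, f_D=f_D)
            )
    return tuple(puncta)


def donor_only_scene(
    image_shape: tuple[int, int] = (48, 48),
    n_puncta: int = 12,
    diffuse_intensity: float = 100.0,
    punctum_intensity: float = 120.0,
    seed: int = 0,
) -> SceneSpec:
    """Donor-alone control cell: punctate, f_D identically zero.

    Default intensities give ~400 photons per pixel after 2x2 binning on
    the diffuse background, matching a donor-only acquisition.
    """
    rng = np.random.default_rng(seed)
    return SceneSpec(
        image_shape=image_shape,
        puncta=_preset_puncta(image_shape, n_puncta, punctum_intensity, 0.0, rng),
        diffuse_background_intensity=diffuse_intensity,
        diffuse_f_D=0.0,
        cell_mask=_default_cell_mask(image_shape),
    )


def coexpression_scene(
    image_shape: tuple[int, int] = (48, 48),
    n_puncta: int = 12,
    diffuse_intensity: float = 150.0,
    punctum_intensity: float = 180.0,
    punctum_f_D: float = 0.35,
    diffuse_f_D: float = 0.15,
    seed: int = 0,
) -> SceneSpec:
    """Donor + acceptor co-expression cell with interacting puncta.

    Defaults emulate a co-expression acquisition: ~600 photons per binned
    pixel, puncta at f_D 0.35 on a diffuse f_D 0.15 background.
    """
    rng = np.random.default_rng(seed)
    return SceneSpec(
        image_shape=image_shape,
        puncta=_preset_puncta(image_shape, n_puncta, punctum_intensity, punctum_f_D, rng),
        diffuse_background_intensity=diffuse_intensity,
        diffuse_f_D=diffuse_f_D,
        cell_mask=_default_cell_mask(image_shape),
    )


# ---------------------------------------------------------------------------
# binding


@dataclass(frozen=True)
class BindingSeries:
    """A concentration-response series from an equilibrium binding assay.

    Concentrations in µM, responses in resonance units; condition_label is
    free text (e.g. a buffer additive in a competition experiment).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentrations and responses must be 1-D and equal length")
        if np.any(c < 0):
            raise ValueError("negative analyte concentration")
        order = np.argsort(c, kind="stable")
        object.__setattr__(self, "concentrations", c[order])
        object.__setattr__(self, "responses", r[order])


def simulate_binding_series(
    kd: float,
    rmax: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    condition_label: str = "",
) -> BindingSeries:
    """One-site saturation responses R = rmax*C/(kd + C) plus Gaussian noise."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be > 0")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative analyte concentration")
    rng = np.random.default_rng(seed)
    resp = rmax * c / (kd + c)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=c.shape)
    return BindingSeries(concentrations=c, responses=resp, condition_label=condition_label)
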