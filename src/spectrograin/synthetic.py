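"""Synthetic labeled reflectance spectra for seed-variety classification.

Generates per-seed mean spectra with the statistical structure the analysis
pipeline assumes about soybean seed reflectance in the 373-1043 nm range:

* a shared smooth base curve with reflectance peaks near 638 and 702 nm, a
  chlorophyll absorption valley near 675 nm, and a red-edge rise to a
  near-infrared plateau;
* smooth class-specific deviations (Gaussian bumps, ~15 nm wide) confined to
  the 638-660 nm and 700-980 nm windows where varieties genuinely differ;
* per-sample multiplicative scatter (gain ~ 1 + N(0, sd)) and additive
  baseline offsets, the artefacts SNV/MSC exist to remove;
* additive heteroscedastic noise whose standard deviation ramps up linearly
  from 900 nm toward the long-wavelength detector edge.

The generator works at the per-seed mean-spectrum level; it does not simulate
2-D seed images or imaging optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from .dataset import SpectrumSet
from .exceptions import InvalidArgumentError

__all__ = ["SyntheticConfig", "make_wavelength_grid", "generate_dataset"]

#: Wavelength windows (nm) where class-specific spectral differences live.
CLASS_WINDOWS_NM = ((638.0, 660.0), (700.0, 980.0))

#: Reflectance values are clipped here; calibration against a gray panel can
#: legitimately push reflectance above 1.
CLIP_RANGE = (0.0, 1.5)


def make_wavelength_grid(n_bands: int, wl_min: float, wl_max: float) -> np.ndarray:
    """Evenly spaced band-centre grid from ``wl_min`` to ``wl_max`` inclusive.

    Parameters
    ----------
    n_bands : int
        Number of bands, at least 2.
    wl_min, wl_max : float
        Grid endpoints in nanometres, ``wl_min < wl_max``.

    Returns
    -------
    ndarray of shape (n_bands,)
        Strictly ascending, first element ``wl_min``, last ``wl_max``.
    """
    if n_bands < 2:
        raise InvalidArgumentError(f"n_bands must be >= 2, got {n_bands}")
    if not wl_min < wl_max:
        raise InvalidArgumentError(
            f"wavelength range inverted or empty: [{wl_min}, {wl_max}]"
        )
    return np.linspace(float(wl_min), float(wl_max), int(n_bands))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic spectra generator.

    Defaults mirror the study design this pipeline targets: 10 varieties x
    120 seeds on a 128-band grid spanning 373-1043 nm.

    Parameters
    ----------
    n_classes, samples_per_class, n_bands : int
        Dataset dimensions; all must be >= 1 (n_bands >= 2).
    wavelength_min, wavelength_max : float
        Grid endpoints in nm.
    class_separation : float
        Dimensionless scale of the between-class bump amplitudes inside the
        638-660 / 700-980 nm windows. 0 removes class structure entirely.
    scatter_gain_sd : float
        Per-sample multiplicative gain is ``1 + N(0, scatter_gain_sd)``.
    scatter_offset_sd : float
        Per-sample additive baseline offset ``N(0, scatter_offset_sd)``
        (reflectance units).
    noise_sd_base : float
        Baseline additive noise sd (reflectance units), flat over wavelength.
    noise_sd_edge : float
        Extra noise amplitude ramping linearly from 0 at ``noise_ramp_start``
        (900 nm) to its full value at ``wavelength_max``.
    class_bump_width_nm : float
        Width (Gaussian sigma, nm) of class-specific bumps.
    class_bump_centers_nm : sequence of float, optional
        When given, class effects are Gaussian bumps planted at exactly these
        wavelengths (one amplitude per class per centre) instead of random
        positions inside the class windows. Used to create ground-truth
        informative bands for selector validation.
    rng_seed : int
        Seed for all randomness; equal configs and seeds give bit-identical
        output.
    """

    n_classes: int = 10
    samples_per_class: int = 120
    n_bands: int = 128
    wavelength_min: float = 373.0
    wavelength_max: float = 1043.0
    class_separation: float = 1.0
    scatter_gain_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd_base: float = 0.004
    noise_sd_edge: float = 0.010
    class_bump_width_nm: float = 15.0
    class_bump_centers_nm: Optional[Sequence[float]] = None
    rng_seed: int = 0

    #: Amplitude sd (reflectance units) of one class bump at separation 1.
    bump_amplitude_sd: float = field(default=0.02, repr=False)
    #: Noise ramp onset (nm); fixed to avoid a discontinuity at the edge.
    noise_ramp_start: float = field(default=900.0, repr=False)

    def __post_init__(self) -> None:
        for name in ("n_classes", "samples_per_class"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be >= 1")
        if self.n_bands < 2:
            raise InvalidArgumentError("n_bands must be >= 2")
        if not self.wavelength_min < self.wavelength_max:
            raise InvalidArgumentError("wavelength_min must be < wavelength_max")
        for name in (
            "class_separation",
            "scatter_gain_sd",
            "scatter_offset_sd",
            "noise_sd_base",
            "noise_sd_edge",
        ):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        """Load a config from a YAML (or plain key: value) file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InvalidArgumentError(f"config file {path!r} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["class_bump_centers_nm"] is not None:
            d["class_bump_centers_nm"] = list(d["class_bump_centers_nm"])
        return d


def _base_template(wl: np.ndarray) -> np.ndarray:
    """Shared smooth reflectance curve.

    A logistic red edge centred near 705 nm rising to a NIR plateau, plus
    Gaussian features producing local maxima near 638 and 702 nm and a
    chlorophyll-absorption minimum near 675 nm. Amplitudes are free design
    constants chosen to keep reflectance in a realistic 0.1-0.55 range.
    """
    red_edge = 0.12 + 0.38 / (1.0 + np.exp(-(wl - 705.0) / 45.0))
    peak_638 = 0.060 * np.exp(-0.5 * ((wl - 636.0) / 12.0) ** 2)
    valley_675 = -0.085 * np.exp(-0.5 * ((wl - 676.0) / 9.0) ** 2)
    peak_702 = 0.055 * np.exp(-0.5 * ((wl - 699.0) / 8.0) ** 2)
    return red_edge + peak_638 + valley_675 + peak_702


def _class_effects(cfg: SyntheticConfig, wl: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n_classes, n_bands) matrix of smooth class-specific offsets."""
    effects = np.zeros((cfg.n_classes, wl.size))
    scale = cfg.bump_amplitude_sd * cfg.class_separation
    if scale == 0:
        # Draw anyway so the RNG stream (hence all downstream draws) is
        # identical whether or not separation is zero.
        scale = 0.0
    width = cfg.class_bump_width_nm
    if cfg.class_bump_centers_nm is not None:
        centers = np.asarray(cfg.class_bump_centers_nm, dtype=float)
        for c in range(cfg.n_classes):
            amps = rng.normal(0.0, 1.0, size=centers.size) * scale
            for a, mu in zip(amps, centers):
                effects[c] += a * np.exp(-0.5 * ((wl - mu) / width) ** 2)
        return effects
    # Random bump positions confined to the class-difference windows; a hard
    # window mask guarantees zero between-class variance elsewhere.
    n_bumps = (1, 2)  # bumps per window: narrow window gets 1, broad gets 2
    for c in range(cfg.n_classes):
        for (lo, hi), k in zip(CLASS_WINDOWS_NM, n_bumps):
            mask = (wl >= lo) & (wl <= hi)
            centers = rng.uniform(lo, hi, size=k)
            amps = rng.normal(0.0, 1.0, size=k) * scale
            bump = np.zeros(wl.size)
            for a, mu in zip(amps, centers):
                bump += a * np.exp(-0.5 * ((wl - mu) / width) ** 2)
            effects[c] += bump * mask
    return effects


def generate_dataset(config: SyntheticConfig | None = None) -> SpectrumSet:
    """Generate a labeled synthetic :class:`SpectrumSet`.

    Deterministic given ``config.rng_seed``. Per sample the reflectance is

    ``clip(gain * (base + class_effect) + offset + noise, 0, 1.5)``

    with gain/offset the per-sample multiplicative-scatter artefact and noise
    heteroscedastic, ramping up from 900 nm toward the long-wavelength edge.
    Labels are balanced: ``samples_per_class`` rows per class.
    """
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    wl = make_wavelength_grid(cfg.n_bands, cfg.wavelength_min, cfg.wavelength_max)
    base = _base_template(wl)
    effects = _class_effects(cfg, wl, rng)

    n = cfg.n_classes * cfg.samples_per_class
    ramp = np.clip(
        (wl - cfg.noise_ramp_start)
        / max(cfg.wavelength_max - cfg.noise_ramp_start, 1e-12),
        0.0,
        1.0,
    )
    noise_sd = cfg.noise_sd_base + cfg.noise_sd_edge * ramp

    reflectance = np.empty((n, wl.size))
    labels = np.empty(n, dtype=object)
    sample_ids = np.empty(n, dtype=object)
    row = 0
    for c in range(cfg.n_classes):
        label = f"class{c:02d}"
        clean = base + effects[c]
        gains = 1.0 + rng.normal(0.0, cfg.scatter_gain_sd, size=cfg.samples_per_class)
        offsets = rng.normal(0.0, cfg.scatter_offset_sd, size=cfg.samples_per_class)
        noise = rng.normal(0.0, 1.0, size=(cfg.samples_per_class, wl.size)) * noise_sd
        block = gains[:, None] * clean[None, :] + offsets[:, None] + noise
        for i in range(cfg.samples_per_class):
            labels[row] = label
            sample_ids[row] = f"{label}_s{i:03d}"
            row += 1
        reflectance[row - cfg.samples_per_class : row] = block
    np.clip(reflectance, CLIP_RANGE[0], CLIP_RANGE[1], out=reflectance)
    return SpectrumSet(
        reflectance=reflectance, wavelengths=wl, labels=labels, sample_ids=sample_ids
    )
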