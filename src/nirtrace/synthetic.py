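"""Two-class synthetic NIR spectrum generator.

Emulates diffuse-reflectance absorbance spectra of a powdered botanical with
the statistical structure the analysis pipeline assumes:

* a clean class spectrum built from Gaussian absorption bands at the C–H /
  CH₂ combination, first- and second-overtone positions and the C=O second
  overtone typical of saponin/isoflavone/polysaccharide matrices;
* class-dependent band intensities (origin differences enter as constituent
  concentration differences, i.e. fractional amplitude modulation);
* per-spectrum multiplicative scatter gain, additive offset and linear
  baseline tilt — the particle-size corruption that SNV/MSC/detrending are
  designed to remove — plus white noise;
* optional gross outliers (gain multiplied several-fold).

The generator records per-sample ground truth (class, gain, offset, slope,
outlier flag), and identical seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .spectra import SpectrumSet, WavenumberGrid

LABELS = ("ZJ", "nonZJ")      # class 1 = Zhejiang origin (positive class)
POSITIVE_CLASS = "ZJ"


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``class_effect`` is the fractional amplitude difference of class 1 (ZJ)
    relative to class 0: amplitude₁ = base_amplitude · (1 + class_effect).
    """

    center: float          # cm⁻¹
    width: float           # Gaussian sigma, cm⁻¹
    base_amplitude: float  # absorbance units
    class_effect: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ParameterError("band width must be positive")
        if self.base_amplitude < 0:
            raise ParameterError("band amplitude must be non-negative")


#: Band table at the NIR assignments of the system: (center, sigma, amplitude,
#: relative class-effect weight).  Centers/widths are the midpoints and
#: half-ranges of the assignment intervals; the combination bands and the C=O
#: overtone carry the largest constituent-driven class weight.
_BAND_TABLE = [
    # center, width, amplitude, effect weight
    (4243.0, 153.0, 0.80, 1.0),    # C-H stretch+bend combination
    (4295.0, 155.0, 0.70, 0.6),    # CH2 combination
    (5300.0, 70.0, 0.35, 1.0),     # C=O second overtone
    (5752.5, 132.5, 0.40, 0.8),    # C-H first overtone
    (5870.0, 190.0, 0.35, 0.5),    # CH2 first overtone
    (6937.5, 82.5, 0.15, 0.4),     # C-H second overtone
    (7149.0, 139.0, 0.12, 0.3),    # CH2 second overtone
]

#: named class-separation magnitudes (fractional amplitude effect scale)
SEPARATION_LEVELS = {"none": 0.0, "weak": 0.02, "moderate": 0.1, "strong": 0.3}


def default_bands(class_effect_scale: float = 0.1) -> list[BandSpec]:
    """The standard band table with class effects scaled by one number."""
    return [BandSpec(c, w, a, weight * class_effect_scale)
            for c, w, a, weight in _BAND_TABLE]


@dataclass(frozen=True)
class NoiseModel:
    """Per-spectrum corruption magnitudes.

    Defaults are plausible for powdered-sample diffuse reflectance: ~10%
    multiplicative scatter spread, offsets a few hundredths of an absorbance
    unit, a gentle baseline tilt across the 8,000 cm⁻¹ range, and white
    noise well below band amplitudes.
    """

    multiplicative_scatter: float = 0.10   # lognormal sigma of the gain
    additive_offset: float = 0.02          # AU
    baseline_slope: float = 2.5e-6         # AU per cm⁻¹
    white_noise: float = 0.002             # AU per point
    outlier_fraction: float = 0.0
    outlier_gain: float = 5.0

    def __post_init__(self):
        for name in ("multiplicative_scatter", "additive_offset",
                     "baseline_slope", "white_noise"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0 <= self.outlier_fraction < 1):
            raise ParameterError("outlier_fraction must be in [0, 1)")


def clean_class_spectrum(grid: WavenumberGrid, bands: list[BandSpec],
                         class_code: int) -> np.ndarray:
    """Noise-free class spectrum: the sum of class-adjusted Gaussian bands."""
    v = grid.values
    out = np.zeros_like(v)
    for b in bands:
        amp = b.base_amplitude * (1 + b.class_effect if class_code == 1 else 1.0)
        out += amp * np.exp(-0.5 * ((v - b.center) / b.width) ** 2)
    return out


def generate(n_class0: int, n_class1: int, grid: WavenumberGrid,
             bands: list[BandSpec] | None = None,
             noise: NoiseModel | None = None,
             seed: int = 0) -> tuple[SpectrumSet, pd.DataFrame]:
    """Draw a labeled two-class spectrum set plus its ground-truth record.

    observed = gain·clean + offset + slope·(ν − ν̄) + ε, with gain lognormal,
    offset/slope/ε normal, and designated outliers receiving gain ×
    ``outlier_gain``.  Class 0 is ``nonZJ``, class 1 is ``ZJ``.
    """
    if n_class0 < 0 or n_class1 < 0:
        raise ParameterError("sample counts must be non-negative")
    bands = default_bands() if bands is None else bands
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(seed)

    v = grid.values
    v_centered = v - v.mean()
    clean = {0: clean_class_spectrum(grid, bands, 0),
             1: clean_class_spectrum(grid, bands, 1)}

    n = n_class0 + n_class1
    codes = np.concatenate([np.zeros(n_class0, int), np.ones(n_class1, int)])
    gains = np.exp(rng.normal(0.0, noise.multiplicative_scatter, n))
    offsets = rng.normal(0.0, noise.additive_offset, n)
    slopes = rng.normal(0.0, noise.baseline_slope, n)
    is_outlier = rng.random(n) < noise.outlier_fraction
    gains = np.where(is_outlier, gains * noise.outlier_gain, gains)

    a = np.empty((n, v.size))
    for i in range(n):
        a[i] = gains[i] * clean[codes[i]] + offsets[i] + slopes[i] * v_centered
    if noise.white_noise > 0:
        a += rng.normal(0.0, noise.white_noise, a.shape)

    labels = np.where(codes == 1, LABELS[0], LABELS[1]).astype(object)
    ids = np.array([f"s{i:05d}" for i in range(n)], dtype=object)
    truth = pd.DataFrame({"id": ids, "label": labels, "class_code": codes,
                          "gain": gains, "offset": offsets, "slope": slopes,
                          "outlier": is_outlier})
    return SpectrumSet(grid, a, labels, ids), truth


@dataclass(frozen=True)
class Scenario:
    """A named generation configuration."""

    name: str
    n_class0: int
    n_class1: int
    n_points: int
    separation: str = "moderate"
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def grid(self) -> WavenumberGrid:
        return WavenumberGrid.default(self.n_points)

    @property
    def bands(self) -> list[BandSpec]:
        return default_bands(SEPARATION_LEVELS[self.separation])

    def generate(self, seed: int = 0) -> tuple[SpectrumSet, pd.DataFrame]:
        return generate(self.n_class0, self.n_class1, self.grid, self.bands,
                        self.noise, seed=seed)


def default_scenario(scale: str = "tiny", separation: str = "moderate",
                     noise: NoiseModel | None = None) -> Scenario:
    """Named presets.

    * ``tiny`` — 40 nonZJ + 60 ZJ on a 200-point grid (fast checks; keeps
      the real data's ~1.4 ZJ:nonZJ imbalance);
    * ``balanced`` — 100 + 100 on a 200-point grid (null-calibration runs);
    * ``full`` — 1530 nonZJ + 2127 ZJ on the full 2074-point
      instrument grid (the deposited study's dimensions).

    ``separation`` ∈ {none, weak, moderate, strong} scales the class effect.
    """
    if separation not in SEPARATION_LEVELS:
        raise ParameterError(f"unknown separation level {separation!r}")
    kw = {} if noise is None else {"noise": noise}
    if scale == "tiny":
        return Scenario("tiny", 40, 60, 200, separation, **kw)
    if scale == "balanced":
        return Scenario("balanced", 100, 100, 200, separation, **kw)
    if scale == "full":
        return Scenario("full", 1530, 2127, 2074, separation, **kw)
    raise ParameterError(f"unknown scenario scale {scale!r}")
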