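"""Synthetic two-sensor spectral data with a planted leaf-count signal.

The generator emulates the statistical structure of the tuber study this
package is built around: a right-skewed primordial leaf count (LC)
distribution, two VIS/NIR sensors whose informative wavelength bands are
partially complementary, multiplicative/additive scatter artifacts, and
hyperspectral line-scan cubes whose spatially averaged, radiometrically
corrected spectra recover the underlying spectrum.

The spectral model for sample i on one sensor is

    x_i(lam) = g_i * [ b(lam) + sum_bands e_b * G(lam; c_b, w_b) * t(lc_i)
                                + u_i * G(lam; c_int, w_int) ]
               + o_i + eps_i(lam)

with b a smooth baseline, G Gaussian band profiles, t(lc) = sqrt(lc) the
latent spectral driver, u_i a per-sensor interferent concentration,
g_i ~ N(1, gain_sd), o_i ~ N(0, offset_sd) and white noise eps.  The
interferent bands overlap each sensor's unique LC bands differently, which
is what makes fusing the two sensors genuinely informative rather than a
pure noise-averaging exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .datasets import LineScanCube, SpectralDataset

__all__ = [
    "Band", "LCDistribution", "SensorSpec", "CubeSpec", "SyntheticConfig",
    "SyntheticTruth", "sample_lc", "generate_sensor_spectra", "generate_cube",
    "generate_two_sensor", "default_config",
]


@dataclass
class Band:
    center: float  # nm
    width: float   # nm (Gaussian sigma)
    effect_size: float  # absorbance units per transformed-LC unit


@dataclass
class LCDistribution:
    """Min/max/mean/SD targets for the leaf-count distribution."""
    target_min: float
    target_max: float
    target_mean: float
    target_sd: float


@dataclass
class SensorSpec:
    name: str
    n_wavelengths: int
    wavelength_range: tuple[float, float]
    informative_bands: list[Band]
    gain_sd: float = 0.05
    offset_sd: float = 0.01
    noise_sd: float = 0.004
    # sensor-specific structured interference (nuisance signal uncorrelated
    # with LC); drawn once per sample
    interferent_bands: list[Band] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.wavelength_range
        if hi <= lo:
            raise ValueError("wavelength_range must be increasing")
        for b in self.informative_bands + self.interferent_bands:
            if not (lo <= b.center <= hi):
                raise ValueError(
                    f"band center {b.center} nm outside range {lo}-{hi} nm")
        if min(self.gain_sd, self.offset_sd, self.noise_sd, 0.0) < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_wavelengths)


@dataclass
class CubeSpec:
    n_scan_lines: int = 10
    line_length: int = 50
    spatial_noise_sd: float = 0.01
    background_level: float = 0.0
    reference_level: float = 1.0


@dataclass
class SyntheticConfig:
    n_samples: int = 200
    seed: int = 0
    lc_dist: LCDistribution = field(
        default_factory=lambda: LCDistribution(4.33, 57.66, 13.47, 13.62))
    sensors: list[SensorSpec] = field(default_factory=lambda: _default_sensors())
    cube: CubeSpec = field(default_factory=CubeSpec)

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if len(self.sensors) == 2:
            a = {(b.center, b.width) for b in self.sensors[0].informative_bands}
            b = {(b.center, b.width) for b in self.sensors[1].informative_bands}
            if a == b:
                raise ValueError(
                    "the two sensors' informative bands must not be identical")

    # --- YAML round trip ------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["lc_dist"] = LCDistribution(**d["lc_dist"])
        d["sensors"] = [
            SensorSpec(
                **{**s,
                   "wavelength_range": tuple(s["wavelength_range"]),
                   "informative_bands": [Band(**b) for b in s["informative_bands"]],
                   "interferent_bands": [Band(**b) for b in s.get("interferent_bands", [])]})
            for s in d["sensors"]
        ]
        d["cube"] = CubeSpec(**d["cube"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: LC vector and planted band indices."""
    lc: np.ndarray
    band_indices: dict[str, list[np.ndarray]]  # sensor name -> per-band index arrays
    noise_realization_seed: int


def _default_sensors() -> list[SensorSpec]:
    """Frozen default two-sensor configuration.

    Sensor A stands in for the interactance spectrometer (600 channels,
    400-1000 nm); sensor B for the hyperspectral-imaging mean spectrum
    (256 channels, same range).  Three informative bands each, one shared
    (705 nm) and two unique.  Each band is overlaid by a same-profile,
    sensor-specific interferent, so within one sensor the leaf-count
    signal is partially confounded with independent nuisance variation;
    the confounders are independent across sensors, which is exactly the
    regime in which fusing the two instruments buys real information.
    """
    a = SensorSpec(
        name="interactance",
        n_wavelengths=600,
        wavelength_range=(400.0, 1000.0),
        informative_bands=[
            Band(550.0, 12.0, 0.012),
            Band(705.0, 10.0, 0.016),
            Band(930.0, 18.0, 0.012),
        ],
        interferent_bands=[
            Band(550.0, 12.0, 0.015),
            Band(705.0, 10.0, 0.015),
            Band(930.0, 18.0, 0.015),
        ],
        gain_sd=0.05, offset_sd=0.01, noise_sd=0.006,
    )
    b = SensorSpec(
        name="hyperspectral",
        n_wavelengths=256,
        wavelength_range=(400.0, 1000.0),
        informative_bands=[
            Band(480.0, 15.0, 0.012),
            Band(705.0, 10.0, 0.016),
            Band(850.0, 15.0, 0.012),
        ],
        interferent_bands=[
            Band(480.0, 15.0, 0.015),
            Band(705.0, 10.0, 0.015),
            Band(850.0, 15.0, 0.015),
        ],
        gain_sd=0.05, offset_sd=0.01, noise_sd=0.006,
    )
    return [a, b]


def default_config(n_samples: int = 200, seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------------
# LC sampling
# ---------------------------------------------------------------------------

def sample_lc(n: int, lc_dist: LCDistribution, rng_seed: int) -> np.ndarray:
    """Draw ``n`` leaf counts from a rescaled, clipped log-normal.

    A standard log-normal is moment-matched to the target coefficient of
    variation, affine-rescaled and clipped to [target_min, target_max].
    Because clipping shrinks both moments, the affine constants are
    calibrated (deterministic fixed point on the clipped distribution's
    quadrature moments) so that the *clipped* population matches the
    target mean/SD.  Skew is positive whenever SD is comparable to the
    mean, which is the regime the storage experiment produced.
    """
    if n < 1:
        raise ValueError("n must be positive")
    d = lc_dist
    if d.target_min > d.target_max:
        raise ValueError("target_min must not exceed target_max")
    if d.target_sd < 0:
        raise ValueError("target_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    if d.target_sd == 0 or d.target_min == d.target_max:
        return np.clip(np.full(n, d.target_mean), d.target_min, d.target_max)
    cv = d.target_sd / d.target_mean
    sigma = np.sqrt(np.log1p(cv * cv))
    m = np.exp(sigma * sigma / 2.0)
    s = m * np.sqrt(np.expm1(sigma * sigma))

    # deterministic quadrature over z ~ N(0,1) for the clipped moments
    z = np.linspace(-8.0, 8.0, 4001)
    wgt = np.exp(-0.5 * z * z)
    wgt /= wgt.sum()
    xq = (np.exp(sigma * z) - m) / s  # standardized log-normal nodes

    a, b = d.target_mean, d.target_sd
    for _ in range(60):
        yq = np.clip(a + b * xq, d.target_min, d.target_max)
        mu = float(wgt @ yq)
        sd = float(np.sqrt(wgt @ (yq - mu) ** 2))
        if sd <= 0:
            break
        if abs(mu - d.target_mean) < 1e-10 and abs(sd - d.target_sd) < 1e-10:
            break
        b *= d.target_sd / sd
        a += d.target_mean - mu

    x = (np.exp(sigma * rng.standard_normal(n)) - m) / s
    return np.clip(a + b * x, d.target_min, d.target_max)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _baseline(wl: np.ndarray) -> np.ndarray:
    # smooth relative-reflectance-like baseline in (0, 1)
    z = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.45 + 0.25 * np.sin(2.2 * z + 0.4) + 0.08 * z


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def lc_link(lc: np.ndarray) -> np.ndarray:
    """Latent spectral driver t(lc): the square root of the leaf count."""
    return np.sqrt(lc)


def generate_sensor_spectra(
    lc: np.ndarray, sensor_spec: SensorSpec, rng_seed: int,
) -> tuple[SpectralDataset, SyntheticTruth]:
    """Simulate one sensor's relative spectra for the given LC vector."""
    lc = np.asarray(lc, dtype=float)
    if lc.size == 0:
        raise ValueError("lc must not be empty")
    if np.any(lc <= 0):
        raise ValueError("lc values must be strictly positive")
    rng = np.random.default_rng(rng_seed)
    wl = sensor_spec.wavelengths
    n = lc.size
    t = lc_link(lc)

    clean = np.tile(_baseline(wl), (n, 1))
    band_idx: list[np.ndarray] = []
    for b in sensor_spec.informative_bands:
        prof = _gauss(wl, b.center, b.width)
        clean += b.effect_size * np.outer(t, prof)
        band_idx.append(np.flatnonzero(prof > np.exp(-0.5)))  # within 1 sigma
    for b in sensor_spec.interferent_bands:
        u = rng.standard_normal(n)
        clean += b.effect_size * np.outer(u, _gauss(wl, b.center, b.width))

    gain = 1.0 + sensor_spec.gain_sd * rng.standard_normal(n)
    offset = sensor_spec.offset_sd * rng.standard_normal(n)
    eps = sensor_spec.noise_sd * rng.standard_normal((n, wl.size))
    X = gain[:, None] * clean + offset[:, None] + eps

    ds = SpectralDataset(X, wl, lc, np.arange(n), sensor_spec.name)
    truth = SyntheticTruth(lc=lc, band_indices={sensor_spec.name: band_idx},
                           noise_realization_seed=rng_seed)
    return ds, truth


def generate_two_sensor(
    config: SyntheticConfig, seed: int | None = None,
) -> tuple[list[SpectralDataset], SyntheticTruth]:
    """Sample LC once and simulate every sensor in the config on it."""
    seed = config.seed if seed is None else seed
    lc = sample_lc(config.n_samples, config.lc_dist, rng_seed=seed)
    datasets: list[SpectralDataset] = []
    bands: dict[str, list[np.ndarray]] = {}
    for j, spec in enumerate(config.sensors):
        ds, tr = generate_sensor_spectra(lc, spec, rng_seed=seed * 1000 + j + 1)
        datasets.append(ds)
        bands.update(tr.band_indices)
    return datasets, SyntheticTruth(lc=lc, band_indices=bands,
                                    noise_realization_seed=seed)


# ---------------------------------------------------------------------------
# Cubes
# ---------------------------------------------------------------------------

def generate_cube(spectrum: np.ndarray, cube_spec: CubeSpec, rng_seed: int) -> LineScanCube:
    """Expand a spectrum into a line-scan cube plus background/reference frames.

    Every pixel carries the input spectrum plus white spatial noise, scaled
    between constant background and reference levels, so that the
    mean-then-ratio radiometric correction recovers the input within the
    pooled standard error.
    """
    spec = np.asarray(spectrum, dtype=float)
    cs = cube_spec
    if cs.n_scan_lines < 1 or cs.line_length < 1:
        raise ValueError("cube dimensions must be positive")
    rng = np.random.default_rng(rng_seed)
    nb = spec.size
    shape = (cs.n_scan_lines, cs.line_length, nb)
    span = cs.reference_level - cs.background_level
    frames = cs.background_level + span * spec[None, None, :]
    frames = frames + cs.spatial_noise_sd * rng.standard_normal(shape)
    background = np.full(shape, cs.background_level)
    reference = np.full(shape, cs.reference_level)
    wl = np.linspace(400.0, 1000.0, nb)
    return LineScanCube(frames, background, reference, wl)
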