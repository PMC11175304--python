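"""Seeded synthetic cyclic-voltammetry (CV) datasets for a three-sensor e-tongue.

The emulated instrument is an array of three screen-printed carbon electrodes
(SPCEs) with different chemistries — copper nanoparticles (CNP) and gold
nanoparticles (GNP), both electrocatalytic for glucose/fructose oxidation, and
an Au/PEDOT composite electrocatalytic for ascorbic-acid oxidation — cycled in
tomato purée of three cultivars.  Each electrode is used for a fixed number of
consecutive CV scans and then discarded, so one electrode yields exactly one
*measurement* (an ordered scan sequence).

The signal model is deliberately simple: a Gaussian oxidation peak on a sloped
capacitive baseline, with

* peak amplitude proportional to sensitivity × analyte load × a per-electrode
  factor, decaying with scan index as ``(1 + i)**(-decay_exponent)``
  (diffusion-limited depletion);
* a displaced, attenuated counterpart on the backward branch plus a
  double-layer charging offset of opposite sign on the two branches
  (hysteresis: the scan is not a single-valued function of potential);
* a small concentration-dependent shift of the anodic peak potential
  (Tafel-type behaviour of irreversible electrocatalytic oxidation);
* additive white Gaussian current noise.

The analyte load is glucose + fructose (g/100 g) for CNP and GNP sensors and
ascorbic acid (arbitrary units) for PEDOT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SENSOR_NAMES",
    "ConfigurationError",
    "CultivarSpec",
    "SensorSpec",
    "GeneratorConfig",
    "VoltammetricScan",
    "Measurement",
    "default_config",
    "analyte_load",
    "potential_grid",
    "generate_scan",
    "generate_dataset",
    "simulate_replicate_sums",
]

logger = logging.getLogger("etongue")

#: Sensor chemistries of the array, in concatenation order.
SENSOR_NAMES = ("CNP", "GNP", "PEDOT")


class ConfigurationError(ValueError):
    """Raised for physically or structurally invalid generator settings."""


@dataclass(frozen=True)
class CultivarSpec:
    """Analyte content of one tomato cultivar.

    Glucose and fructose are in g/100 g (as quantified by the IC-PAD
    reference technique); ascorbic acid is in arbitrary units since no
    reference quantification is available.
    """

    name: str
    glucose: float
    fructose: float
    ascorbic_acid: float

    @property
    def monosaccharides(self) -> float:
        """Summed glucose + fructose load in g/100 g."""
        return self.glucose + self.fructose


@dataclass(frozen=True)
class SensorSpec:
    """Electrochemical response model of one sensor chemistry.

    Parameters
    ----------
    name
        One of ``CNP``, ``GNP``, ``PEDOT``.
    v_min, v_max
        Potential window of the triangular sweep, in V.
    n_points
        Samples per scan (forward + backward branch).
    peak_center
        Anodic (forward-branch) peak potential at zero analyte load, V.
    peak_width
        Gaussian peak standard deviation, V.
    sensitivity
        Peak current per unit analyte load, µA per (g/100 g) for the sugar
        sensors, µA per a.u. for PEDOT.
    baseline_slope, baseline_intercept
        Linear (resistive/capacitive) background current, µA/V and µA.
    capacitive_offset
        Double-layer charging current, added on the forward branch and
        subtracted on the backward branch, µA.
    hysteresis_shift
        Cathodic displacement of the backward-branch peak, V.
    hysteresis_attenuation
        Amplitude ratio of the backward- to forward-branch peak.
    peak_shift_per_load
        Anodic shift of the peak potential per unit analyte load, V.
    """

    name: str
    v_min: float
    v_max: float
    n_points: int
    peak_center: float
    peak_width: float
    sensitivity: float
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0
    capacitive_offset: float = 0.0
    hysteresis_shift: float = 0.05
    hysteresis_attenuation: float = 0.6
    peak_shift_per_load: float = 0.0


def _default_cultivars() -> list[CultivarSpec]:
    # Sugar contents are the IC-PAD means; ascorbic acid is unquantified and
    # set to distinct arbitrary units chosen to be class-separating.
    return [
        CultivarSpec("perino", glucose=2.62, fructose=2.41, ascorbic_acid=1.0),
        CultivarSpec("red_datterino", glucose=3.37, fructose=4.02, ascorbic_acid=1.6),
        CultivarSpec("yellow_datterino", glucose=3.92, fructose=4.17, ascorbic_acid=2.2),
    ]


def _default_sensors() -> list[SensorSpec]:
    return [
        SensorSpec(
            "CNP", v_min=0.0, v_max=1.0, n_points=28000,
            peak_center=0.55, peak_width=0.12, sensitivity=8.0,
            baseline_slope=5.0, baseline_intercept=2.0, capacitive_offset=1.5,
            hysteresis_shift=0.08, hysteresis_attenuation=0.6,
            peak_shift_per_load=0.008,
        ),
        SensorSpec(
            "GNP", v_min=-0.5, v_max=0.6, n_points=27650,
            peak_center=0.15, peak_width=0.10, sensitivity=1.5,
            baseline_slope=2.0, baseline_intercept=1.0, capacitive_offset=0.6,
            hysteresis_shift=0.06, hysteresis_attenuation=0.6,
            peak_shift_per_load=0.008,
        ),
        SensorSpec(
            "PEDOT", v_min=-0.5, v_max=0.5, n_points=27650,
            peak_center=0.10, peak_width=0.08, sensitivity=4.0,
            baseline_slope=1.5, baseline_intercept=0.8, capacitive_offset=0.5,
            hysteresis_shift=0.05, hysteresis_attenuation=0.7,
            peak_shift_per_load=0.010,
        ),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic acquisition campaign.

    Defaults reproduce the acquisition protocol of the emulated study:
    3 cultivars × 3 sensors × 6 electrodes × 20 scans = 1080 scans, with the
    stated potential windows and with per-scan lengths whose ``⌊n/35⌋``
    window-averaged lengths sum to the 2380-feature concatenated vector.
    """

    cultivars: list[CultivarSpec] = field(default_factory=_default_cultivars)
    sensors: list[SensorSpec] = field(default_factory=_default_sensors)
    scans_per_electrode: int = 20
    electrodes_per_condition: int = 6
    decay_exponent: float = 0.5
    noise_sd: float = 0.05          # µA
    electrode_sd: float = 0.05      # relative (lognormal sigma)
    seed: int = 0

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def default_config(seed: int = 0) -> GeneratorConfig:
    """The default acquisition campaign with a caller-chosen seed."""
    return GeneratorConfig(seed=seed)


@dataclass
class VoltammetricScan:
    """One CV scan: paired potential/current traces plus provenance.

    ``electrode_id`` labels the electrode *slot* (aliquot), shared by the
    three sensors that measured the same aliquot; ``measurement_id`` is
    unique per (cultivar, sensor, electrode).
    """

    potential: np.ndarray   # V, triangular sweep
    current: np.ndarray     # µA
    sensor: str
    cultivar: str
    electrode_id: str
    scan_index: int
    measurement_id: str

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential.shape != self.current.shape or self.potential.size < 2:
            raise ValueError("potential and current must share length >= 2")


@dataclass
class Measurement:
    """The ordered scan sequence acquired by one electrode on one aliquot."""

    scans: list[VoltammetricScan]
    measurement_id: str

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError(f"measurement {self.measurement_id!r} has no scans")
        indices = [s.scan_index for s in self.scans]
        if indices != list(range(len(self.scans))):
            raise ValueError(
                f"measurement {self.measurement_id!r}: scan_index values {indices} "
                "are not 0..len-1 without gaps"
            )
        first = self.scans[0]
        for s in self.scans[1:]:
            if (s.sensor, s.cultivar, s.electrode_id) != (
                first.sensor, first.cultivar, first.electrode_id
            ):
                raise ValueError(
                    f"measurement {self.measurement_id!r} mixes provenance"
                )
            if not np.array_equal(s.potential, first.potential):
                raise ValueError(
                    f"measurement {self.measurement_id!r}: scans do not share "
                    "one potential grid"
                )

    @property
    def sensor(self) -> str:
        return self.scans[0].sensor

    @property
    def cultivar(self) -> str:
        return self.scans[0].cultivar

    @property
    def electrode_id(self) -> str:
        return self.scans[0].electrode_id


def analyte_load(sensor: SensorSpec | str, cultivar: CultivarSpec) -> float:
    """Analyte load driving a sensor's oxidation peak for a cultivar."""
    name = sensor.name if isinstance(sensor, SensorSpec) else sensor
    if name == "PEDOT":
        return cultivar.ascorbic_acid
    if name in ("CNP", "GNP"):
        return cultivar.monosaccharides
    raise ConfigurationError(
        f"unknown sensor {name!r}; expected one of {SENSOR_NAMES}"
    )


def potential_grid(sensor: SensorSpec) -> np.ndarray:
    """Triangular potential sweep for one scan.

    Starts and ends at ``v_min`` and attains ``v_max`` exactly once (the
    turnaround point at the end of the forward branch).
    """
    n = sensor.n_points
    if n < 3:
        raise ConfigurationError(
            f"sensor {sensor.name!r}: n_points={n} cannot describe a "
            "triangular sweep (need >= 3)"
        )
    if not sensor.v_max > sensor.v_min:
        raise ConfigurationError(
            f"sensor {sensor.name!r}: empty potential window "
            f"[{sensor.v_min}, {sensor.v_max}]"
        )
    n_fwd = (n + 1) // 2
    forward = np.linspace(sensor.v_min, sensor.v_max, n_fwd)
    backward = np.linspace(sensor.v_max, sensor.v_min, n - n_fwd + 1)[1:]
    return np.concatenate([forward, backward])


def _validate_scan_model(sensor: SensorSpec, load: float) -> float:
    """Check the peak geometry and return the load-shifted peak center."""
    if sensor.n_points < 3:
        raise ConfigurationError(
            f"sensor {sensor.name!r}: non-positive or degenerate "
            f"points-per-scan ({sensor.n_points})"
        )
    center = sensor.peak_center + sensor.peak_shift_per_load * load
    if not (sensor.v_min <= sensor.peak_center <= sensor.v_max) or not (
        sensor.v_min <= center <= sensor.v_max
    ):
        raise ConfigurationError(
            f"sensor {sensor.name!r}: peak center {center:.3f} V lies outside "
            f"the window [{sensor.v_min}, {sensor.v_max}] V"
        )
    if sensor.peak_width <= 0:
        raise ConfigurationError(
            f"sensor {sensor.name!r}: non-positive peak width"
        )
    return center


def generate_scan(
    sensor: SensorSpec,
    cultivar: CultivarSpec,
    scan_index: int,
    electrode_factor: float,
    rng: np.random.Generator,
    *,
    decay_exponent: float = 0.5,
    noise_sd: float = 0.05,
    electrode_id: str = "e0",
    measurement_id: str | None = None,
) -> VoltammetricScan:
    """Generate one synthetic CV scan.

    The forward branch carries a Gaussian oxidation peak of amplitude
    ``sensitivity * analyte_load * electrode_factor * (1+scan_index)**(-decay_exponent)``
    above the baseline; the backward branch a displaced, attenuated
    counterpart.  Additive Gaussian noise has standard deviation ``noise_sd``.
    """
    if scan_index < 0:
        raise ValueError("scan_index must be >= 0")
    if electrode_factor <= 0:
        raise ValueError("electrode_factor must be > 0")
    load = analyte_load(sensor, cultivar)
    if load < 0:
        raise ConfigurationError(f"negative analyte load for {cultivar.name!r}")
    center = _validate_scan_model(sensor, load)

    pot = potential_grid(sensor)
    n_fwd = (sensor.n_points + 1) // 2
    height = (
        sensor.sensitivity * load * electrode_factor
        * (1.0 + scan_index) ** (-decay_exponent)
    )
    w2 = 2.0 * sensor.peak_width**2
    current = sensor.baseline_intercept + sensor.baseline_slope * pot
    branch = np.empty_like(pot)
    branch[:n_fwd] = sensor.capacitive_offset
    branch[n_fwd:] = -sensor.capacitive_offset
    current += branch
    current[:n_fwd] += height * np.exp(-((pot[:n_fwd] - center) ** 2) / w2)
    back_center = center - sensor.hysteresis_shift
    current[n_fwd:] += (
        sensor.hysteresis_attenuation
        * height
        * np.exp(-((pot[n_fwd:] - back_center) ** 2) / w2)
    )
    if noise_sd > 0:
        current += rng.normal(0.0, noise_sd, size=current.shape)

    if measurement_id is None:
        measurement_id = f"{cultivar.name}:{sensor.name}:{electrode_id}"
    return VoltammetricScan(
        potential=pot,
        current=current,
        sensor=sensor.name,
        cultivar=cultivar.name,
        electrode_id=electrode_id,
        scan_index=scan_index,
        measurement_id=measurement_id,
    )


def generate_dataset(config: GeneratorConfig) -> list[Measurement]:
    """Generate the full acquisition campaign described by ``config``.

    One measurement per (cultivar, sensor, electrode slot), each of
    ``scans_per_electrode`` consecutive scans; a multiplicative electrode
    factor (lognormal around 1, sigma ``electrode_sd``) is drawn once per
    electrode.  The emission order of the measurements is randomized by the
    seeded generator, emulating the randomized acquisition order; the same
    seed always yields a byte-identical dataset.
    """
    for sensor in config.sensors:
        for cult in config.cultivars:
            _validate_scan_model(sensor, analyte_load(sensor, cult))
    if config.scans_per_electrode < 1 or config.electrodes_per_condition < 1:
        raise ConfigurationError("scan and electrode counts must be >= 1")

    rng = np.random.default_rng(config.seed)
    measurements: list[Measurement] = []
    for cult in config.cultivars:
        for slot in range(config.electrodes_per_condition):
            electrode_id = f"e{slot}"
            for sensor in config.sensors:
                factor = float(np.exp(rng.normal(0.0, config.electrode_sd)))
                mid = f"{cult.name}:{sensor.name}:{electrode_id}"
                scans = [
                    generate_scan(
                        sensor, cult, i, factor, rng,
                        decay_exponent=config.decay_exponent,
                        noise_sd=config.noise_sd,
                        electrode_id=electrode_id,
                        measurement_id=mid,
                    )
                    for i in range(config.scans_per_electrode)
                ]
                measurements.append(Measurement(scans=scans, measurement_id=mid))
    order = rng.permutation(len(measurements))
    return [measurements[i] for i in order]


def simulate_replicate_sums(
    cultivars: list[CultivarSpec],
    n_replicates: int = 3,
    sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Simulated per-replicate glucose+fructose sums for each cultivar.

    Emulates triplicate IC-PAD quantifications: replicate sums are drawn
    normally around each cultivar's glucose+fructose mean with standard
    deviation ``sd`` (g/100 g).  Used to exercise the one-way ANOVA check.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {
        c.name: rng.normal(c.monosaccharides, sd, size=n_replicates)
        for c in cultivars
    }
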