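"""Synthetic multi-technique monitoring datasets with known ground truth.

Every generator composes a reactant lineshape sum and a product lineshape
sum with a kinetic law for the reactant fraction c_R(t):

* ``first_order``   c_R = exp(-k·t)
* ``sigmoid``       c_R = 1 / (1 + exp((t - t0)/w))   (autocatalytic step)
* ``oscillation``   c_R = (1 + cos(2π·t/P)) / 2       (BZ-like cycling,
  starting from pure reactant so a trace against the first spectrum
  oscillates at the chemical period P)
* ``blank``         both fractions zero (noise-only run)

plus i.i.d. Gaussian point noise from one seeded RNG stream per run, so a
single integer reproduces a whole dataset bit-for-bit.  Gaussian peaks are
parameterized by their standard deviation, Lorentzian peaks by their
half-width at half-maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np

from .datatypes import ComplexSeries, Mode, Spectrum, SpectrumSeries, Technique
from .errors import ValidationError

__all__ = [
    "PeakSpec",
    "RunSpec",
    "simulate_reaction",
    "bz_preset",
    "first_order_preset",
    "sigmoid_preset",
    "blank_preset",
    "simulate_fid",
    "simulate_epr",
]


class PeakShape(str, Enum):
    GAUSSIAN = "gaussian"
    LORENTZIAN = "lorentzian"


class KineticsLaw(str, Enum):
    FIRST_ORDER = "first_order"
    SIGMOID = "sigmoid"
    OSCILLATION = "oscillation"
    BLANK = "blank"


@dataclass
class PeakSpec:
    """One spectral line: Gaussian (width = sigma) or Lorentzian (width = HWHM)."""

    center: float
    width: float
    amplitude: float
    shape: PeakShape = PeakShape.GAUSSIAN

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("peak width must be > 0")
        self.shape = PeakShape(self.shape)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        u = x - self.center
        if self.shape == PeakShape.GAUSSIAN:
            return self.amplitude * np.exp(-(u**2) / (2 * self.width**2))
        return self.amplitude * self.width**2 / (u**2 + self.width**2)

    def evaluate_derivative(self, x: np.ndarray) -> np.ndarray:
        """Analytic first derivative (EPR lock-in lineshape)."""
        u = x - self.center
        if self.shape == PeakShape.GAUSSIAN:
            return -self.amplitude * u / self.width**2 * np.exp(-(u**2) / (2 * self.width**2))
        return -2 * self.amplitude * self.width**2 * u / (u**2 + self.width**2) ** 2


@dataclass
class RunSpec:
    """Full description of one simulated monitoring run."""

    kinetics: KineticsLaw
    reactant_peaks: list[PeakSpec] = field(default_factory=list)
    product_peaks: list[PeakSpec] = field(default_factory=list)
    rate: float | None = None        # first_order: k in 1/s
    period: float | None = None      # oscillation: P in s
    midpoint: float | None = None    # sigmoid: t0 in s
    width: float | None = None       # sigmoid: w in s
    n_frames: int = 2
    dt: float = 1.0
    noise_sigma: float = 0.0
    axis_lo: float = 0.0
    axis_hi: float = 10.0
    axis_points: int = 200
    axis_unit: str = ""
    technique: Technique = Technique.OTHER
    seed: int = 0

    def __post_init__(self) -> None:
        self.kinetics = KineticsLaw(self.kinetics)
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.axis_points < 2 or self.axis_hi <= self.axis_lo:
            raise ValidationError("invalid axis definition")
        if self.kinetics == KineticsLaw.FIRST_ORDER and (self.rate is None or self.rate <= 0):
            raise ValidationError("first_order kinetics needs rate > 0")
        if self.kinetics == KineticsLaw.OSCILLATION and (self.period is None or self.period <= 0):
            raise ValidationError("oscillation kinetics needs period > 0")
        if self.kinetics == KineticsLaw.SIGMOID and (
            self.midpoint is None or self.width is None or self.width <= 0
        ):
            raise ValidationError("sigmoid kinetics needs midpoint and width > 0")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_lo, self.axis_hi, self.axis_points)

    def reactant_fraction(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kinetics == KineticsLaw.FIRST_ORDER:
            return np.exp(-self.rate * t)
        if self.kinetics == KineticsLaw.SIGMOID:
            return 1.0 / (1.0 + np.exp(np.clip((t - self.midpoint) / self.width, -500, 500)))
        if self.kinetics == KineticsLaw.OSCILLATION:
            return 0.5 * (1.0 + np.cos(2 * np.pi * t / self.period))
        return np.zeros_like(t)

    def to_json(self) -> str:
        d = asdict(self)
        d["kinetics"] = self.kinetics.value
        d["technique"] = self.technique.value
        for key in ("reactant_peaks", "product_peaks"):
            for p in d[key]:
                p["shape"] = PeakShape(p["shape"]).value
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunSpec":
        d = json.loads(text)
        d["reactant_peaks"] = [PeakSpec(**p) for p in d.get("reactant_peaks", [])]
        d["product_peaks"] = [PeakSpec(**p) for p in d.get("product_peaks", [])]
        return cls(**d)


def _peak_sum(peaks: list[PeakSpec], x: np.ndarray) -> np.ndarray:
    total = np.zeros_like(x)
    for p in peaks:
        total += p.evaluate(x)
    return total


def simulate_reaction(spec: RunSpec) -> SpectrumSeries:
    """Generate the spectral time series a monitored reaction would produce.

    Frame at time t carries ``c_R(t)·(reactant peaks) + c_P(t)·(product
    peaks)`` plus i.i.d. Gaussian noise, with ``c_P = 1 - c_R`` (blank runs:
    both zero).
    """
    x = spec.axis
    reactant = _peak_sum(spec.reactant_peaks, x)
    product = _peak_sum(spec.product_peaks, x)
    times = np.arange(spec.n_frames) * spec.dt
    c_r = spec.reactant_fraction(times)
    c_p = np.zeros_like(c_r) if spec.kinetics == KineticsLaw.BLANK else 1.0 - c_r
    rng = np.random.default_rng(spec.seed)
    spectra = []
    for t, cr, cp in zip(times, c_r, c_p):
        y = cr * reactant + cp * product
        if spec.noise_sigma > 0:
            y = y + rng.normal(0.0, spec.noise_sigma, size=x.size)
        spectra.append(
            Spectrum(axis=x, intensity=y, time=float(t),
                     technique=spec.technique, axis_unit=spec.axis_unit)
        )
    return SpectrumSeries(spectra=spectra)


def bz_preset(seed: int = 42, noise_sigma: float | None = None) -> RunSpec:
    """BZ-like oscillating UV/Vis run: period 7.25 s, 0.25 s sampling,
    1160 frames (exactly 40 cycles, leakage-free), one reactant and one
    product Gaussian band on a 200-point wavelength-like axis, noise 1% of
    the maximum amplitude."""
    return RunSpec(
        kinetics=KineticsLaw.OSCILLATION,
        reactant_peaks=[PeakSpec(center=350.0, width=20.0, amplitude=1.0)],
        product_peaks=[PeakSpec(center=550.0, width=25.0, amplitude=0.6)],
        period=7.25,
        n_frames=1160,
        dt=0.25,
        noise_sigma=0.01 if noise_sigma is None else noise_sigma,
        axis_lo=250.0,
        axis_hi=700.0,
        axis_points=200,
        axis_unit="nm",
        technique=Technique.UVVIS,
        seed=seed,
    )


def first_order_preset(seed: int = 0, noise_sigma: float | None = None) -> RunSpec:
    """First-order reactant decay followed for about five half-lives:
    k = 1/120 s⁻¹ sampled every 10 s for 600 s, noise 1% of peak height.

    The product is spectroscopically silent in the monitored window (a
    common situation), which makes the noiseless Jaccard trace equal
    exp(-k·t) exactly — a sharp ground-truth recovery test."""
    return RunSpec(
        kinetics=KineticsLaw.FIRST_ORDER,
        reactant_peaks=[PeakSpec(center=3.0, width=0.15, amplitude=1.0)],
        product_peaks=[],
        rate=1.0 / 120.0,
        n_frames=60,
        dt=10.0,
        noise_sigma=0.01 if noise_sigma is None else noise_sigma,
        axis_lo=0.0,
        axis_hi=10.0,
        axis_points=400,
        axis_unit="ppm",
        technique=Technique.NMR,
        seed=seed,
    )


def sigmoid_preset(seed: int = 0, noise_sigma: float | None = None) -> RunSpec:
    """Autocatalytic (sigmoidal) decay: midpoint 300 s, width 30 s, 2 s
    sampling for 600 s, noise 2% of peak height.  The product is silent in
    the monitored window, so the noiseless Jaccard trace is the logistic
    step itself."""
    return RunSpec(
        kinetics=KineticsLaw.SIGMOID,
        reactant_peaks=[PeakSpec(center=525.0, width=30.0, amplitude=1.0)],
        product_peaks=[],
        midpoint=300.0,
        width=30.0,
        n_frames=300,
        dt=2.0,
        noise_sigma=0.02 if noise_sigma is None else noise_sigma,
        axis_lo=250.0,
        axis_hi=700.0,
        axis_points=200,
        axis_unit="nm",
        technique=Technique.UVVIS,
        seed=seed,
    )


def blank_preset(seed: int = 0, noise_sigma: float = 0.01) -> RunSpec:
    """Noise-only (solvent blank) run: no peaks, 60 frames at 10 s."""
    return RunSpec(
        kinetics=KineticsLaw.BLANK,
        n_frames=60,
        dt=10.0,
        noise_sigma=noise_sigma,
        axis_lo=0.0,
        axis_hi=10.0,
        axis_points=400,
        axis_unit="ppm",
        technique=Technique.NMR,
        seed=seed,
    )


def simulate_fid(
    components: list[tuple[float, float, float, float]],
    dwell: float,
    n: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
    time: float = 0.0,
) -> ComplexSeries:
    """Decaying complex FID: sum of (frequency Hz, T2 s, amplitude, phase rad)
    components ``A·exp(iφ)·exp(2πi·ν·t - t/T2)`` plus complex Gaussian noise."""
    if n < 2:
        raise ValidationError("n must be >= 2")
    if dwell <= 0:
        raise ValidationError("dwell must be > 0")
    t = np.arange(n) * dwell
    samples = np.zeros(n, dtype=complex)
    for nu, t2, amp, phase in components:
        if t2 <= 0:
            raise ValidationError("T2 must be > 0")
        samples += amp * np.exp(1j * phase) * np.exp(2j * np.pi * nu * t - t / t2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0, noise_sigma, n) + 1j * rng.normal(0, noise_sigma, n)
    return ComplexSeries(samples=samples, dwell=dwell, time=time)


def simulate_epr(
    lines: list[PeakSpec],
    growth_tau: float,
    n_frames: int,
    dt: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    axis_lo: float = 330.0,
    axis_hi: float = 340.0,
    axis_points: int = 400,
) -> SpectrumSeries:
    """Time-resolved EPR run: derivative lineshapes growing as 1 - exp(-t/tau).

    Emulates photochemical signal build-up; frame 0 (noiseless) is all
    zeros, and a record shorter than ``growth_tau`` never plateaus — the
    compare-against-last-spectrum scenario.
    """
    if growth_tau <= 0:
        raise ValidationError("growth_tau must be > 0")
    if n_frames < 2 or dt <= 0:
        raise ValidationError("need n_frames >= 2 and dt > 0")
    x = np.linspace(axis_lo, axis_hi, axis_points)
    deriv = np.zeros_like(x)
    for p in lines:
        deriv += p.evaluate_derivative(x)
    rng = np.random.default_rng(seed)
    spectra = []
    for i in range(n_frames):
        t = i * dt
        y = (1.0 - np.exp(-t / growth_tau)) * deriv
        if noise_sigma > 0:
            y = y + rng.normal(0.0, noise_sigma, size=x.size)
        spectra.append(
            Spectrum(axis=x, intensity=y, time=float(t), technique=Technique.EPR,
                     mode=Mode.DERIVATIVE, axis_unit="mT")
        )
    return SpectrumSeries(spectra=spectra)
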