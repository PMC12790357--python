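"""Core in-memory containers for monitored spectroscopic data.

A :class:`Spectrum` is one 1-D acquisition (intensity versus chemical shift,
wavenumber, wavelength or magnetic field).  A :class:`SpectrumSeries` is a
time-ordered set of spectra on one common axis grid, the unit that similarity
traces are computed from.  A :class:`ComplexSeries` is a raw NMR free
induction decay.  A :class:`SimilarityTrace` is the (time, similarity) series
that endpoint detection and kinetic profiling consume.

Axes are always stored ascending, whatever the acquisition convention (NMR
ppm is conventionally plotted descending); readers normalize on the way in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger("specmon")


class Technique(str, Enum):
    NMR = "NMR"
    IR = "IR"
    UVVIS = "UVVIS"
    EPR = "EPR"
    OTHER = "OTHER"


class Mode(str, Enum):
    ABSORPTION = "absorption"
    DERIVATIVE = "derivative"


@dataclass
class Spectrum:
    """One 1-D spectrum on a strictly ascending axis.

    Parameters
    ----------
    axis
        Sample positions (ppm, cm⁻¹, nm or mT).  Accepted in either monotonic
        direction; stored ascending with intensities co-sorted.
    intensity
        Intensities, same length as ``axis``.
    time
        Acquisition timestamp in seconds from run start, or ``None`` when the
        source carries no timestamp (a series will then assign ordinals).
    """

    axis: np.ndarray
    intensity: np.ndarray
    time: float | None = None
    technique: Technique = Technique.OTHER
    mode: Mode = Mode.ABSORPTION
    axis_unit: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("axis and intensity must be 1-D")
        if self.axis.size != self.intensity.size:
            raise ValidationError(
                f"axis length {self.axis.size} != intensity length {self.intensity.size}"
            )
        if self.axis.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        d = np.diff(self.axis)
        if np.all(d < 0):  # descending acquisition: normalize
            self.axis = self.axis[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            if np.any(d == 0):
                raise ValidationError("duplicate axis values")
            raise ValidationError("axis must be strictly monotonic")
        if self.time is not None and self.time < 0:
            raise ValidationError("time must be >= 0")
        self.technique = Technique(self.technique)
        self.mode = Mode(self.mode)

    def __len__(self) -> int:
        return self.axis.size

    def with_intensity(self, intensity: np.ndarray, **overrides) -> "Spectrum":
        """Copy of this spectrum with replaced intensities (same axis)."""
        kw = dict(
            axis=self.axis,
            intensity=intensity,
            time=self.time,
            technique=self.technique,
            mode=self.mode,
            axis_unit=self.axis_unit,
            meta=dict(self.meta),
        )
        kw.update(overrides)
        return Spectrum(**kw)


@dataclass
class SpectrumSeries:
    """Time-ordered spectra sharing one axis grid (bitwise-equal)."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValidationError("series must contain at least one spectrum")
        ref = self.spectra[0].axis
        for i, s in enumerate(self.spectra):
            if s.axis.size != ref.size or not np.array_equal(s.axis, ref):
                raise ValidationError(f"spectrum {i} is not on the common axis grid")
        missing = [s.time is None for s in self.spectra]
        if any(missing):
            logger.warning(
                "series has spectra without timestamps; assigning ordinal indices"
            )
            self.spectra = [
                s.with_intensity(s.intensity, time=float(i)) if s.time is None else s
                for i, s in enumerate(self.spectra)
            ]
        t = self.times
        if np.any(np.diff(t) <= 0):
            raise ValidationError("acquisition times must be strictly increasing")

    @property
    def axis(self) -> np.ndarray:
        return self.spectra[0].axis

    @property
    def axis_unit(self) -> str:
        return self.spectra[0].axis_unit

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.spectra], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        """(n_spectra, n_points) matrix of intensities."""
        return np.stack([s.intensity for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]


@dataclass
class ComplexSeries:
    """A raw FID: complex samples at a uniform dwell time."""

    samples: np.ndarray
    dwell: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("FID needs at least 2 complex samples")
        if self.dwell <= 0:
            raise ValidationError("dwell must be positive")
        if self.time < 0:
            raise ValidationError("time must be >= 0")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class SimilarityTrace:
    """(time, similarity) pairs with metric and reference provenance."""

    times: np.ndarray
    values: np.ndarray
    metric: str = ""
    reference: str = ""
    epsilon: float = 0.0
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.values.size:
            raise ValidationError("times and values must be 1-D and equal length")
        if self.times.size == 0:
            raise ValidationError("trace must be nonempty")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr
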