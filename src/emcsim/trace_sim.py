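"""Synthetic lab-on-a-chip electropherograms for digested duplex mixes.

Fragments are rendered as Gaussian peaks on a fixed log-spaced
apparent-size axis (10-2000 bp, the working range of a dsDNA chip with
an intercalating dye).  Peak area is mass-proportional: molar abundance
times apparent size, times a fluorescence scale.  Internal sizing
markers at 15 and 1500 bp bracket the trace.  Enzyme presets add their
characteristic noise: a flat low baseline for T7E1, an elevated jittery
baseline plus a sub-25-bp exonuclease degradation spectrum for Surveyor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .digestion import EnzymeProfile, NoisePreset

__all__ = [
    "Trace",
    "NoiseModel",
    "PeakShape",
    "synthesize_trace",
    "degrade_mass",
    "size_sigma",
    "DEFAULT_FU_SCALE",
    "MARKER_SIZES",
    "MARKER_AREAS",
    "AXIS_RANGE",
    "AXIS_POINTS",
]

NoiseModel = NoisePreset  # the noise preset doubles as the rendering noise model

MARKER_SIZES = (15.0, 1500.0)
#: Canonical marker areas in FU*bp; markers are excluded from quantification.
MARKER_AREAS = (120.0, 1600.0)
AXIS_RANGE = (10.0, 2000.0)
AXIS_POINTS = 2000
#: FU*bp of peak area per unit of (molar fraction x bp) of duplex mass.
#: Calibrated so a 250-ng 50:50 exon-3 digest shows a main peak of ~50 FU,
#: the magnitude seen on a DNA 1000 chip at this load.
DEFAULT_FU_SCALE = 4.8
#: Fragments shorter than this are not resolved on the chip and count as
#: degradation background.
MIN_RENDER_BP = 10.0


@dataclass(frozen=True)
class PeakShape:
    """Sizing spread of the chip: sigma(size) = sigma0 + slope * size.

    The default 2% relative spread is the chip's nominal sizing accuracy;
    it is what merges a 20-bp homoduplex size difference at ~500-570 bp
    into one peak while resolving the same difference below ~300 bp.
    """

    sigma0: float = 1.0
    slope: float = 0.02

    def sigma(self, size):
        return self.sigma0 + self.slope * np.asarray(size, dtype=float)


def size_sigma(size, shape: PeakShape | None = None):
    return (shape or PeakShape()).sigma(size)


@dataclass(frozen=True)
class Trace:
    """An electropherogram: apparent-size axis (bp) and fluorescence (FU)."""

    axis: np.ndarray
    signal: np.ndarray
    marker_sizes: tuple[float, float] = MARKER_SIZES
    seed: int | None = None
    axis_units: str = "bp"  # "bp" once calibrated, "raw" before

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if axis.ndim != 1 or axis.shape != signal.shape:
            raise ValueError("axis and signal must be 1-D arrays of equal length")
        if np.any(np.diff(axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if np.any(signal < 0):
            raise ValueError("signal must be non-negative")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "signal", signal)

    def with_axis(self, axis: np.ndarray, units: str = "bp") -> "Trace":
        return replace(self, axis=np.asarray(axis, dtype=float), axis_units=units)


def default_axis() -> np.ndarray:
    return np.geomspace(AXIS_RANGE[0], AXIS_RANGE[1], AXIS_POINTS)


def _gaussian_area(axis: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    z = (axis - center) / sigma
    return area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * z * z)


def degrade_mass(
    fragments: dict[float, float] | dict[int, float],
    enzyme: EnzymeProfile,
    rng: np.random.Generator | None = None,
) -> tuple[dict[float, float], float]:
    """Apply the enzyme's 5' exonuclease activity to a fragment multiset.

    Each fragment loses nucleotides from both 5' ends (mean
    ``exo_nibbling_rate`` per end; Poisson draws when *rng* is given,
    the expectation otherwise — the per-molecule randomness averages out
    over the molecular population), and a further
    ``background_small_fragment_mass`` fraction of the surviving mass is
    routed to the sub-25-bp degradation pool.  Total mass (abundance x
    size) is conserved between retained fragments and the returned pool.
    """
    rate = enzyme.exo_nibbling_rate
    beta = enzyme.background_small_fragment_mass
    out: dict[float, float] = {}
    pool = 0.0
    for size, ab in fragments.items():
        if rng is not None and rate > 0:
            lost = float(rng.poisson(rate) + rng.poisson(rate))
        else:
            lost = 2.0 * rate
        new_size = float(size) - lost
        if new_size < MIN_RENDER_BP:
            pool += ab * float(size)
            continue
        pool += ab * lost
        retained = ab * (1.0 - beta)
        pool += ab * beta * new_size
        if retained > 0.0:
            out[new_size] = out.get(new_size, 0.0) + retained
    return out, pool


def synthesize_trace(
    fragments: dict[float, float] | dict[int, float],
    enzyme: EnzymeProfile | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = 0,
    *,
    fu_scale: float = DEFAULT_FU_SCALE,
    shape: PeakShape | None = None,
    background_mass: float | None = None,
    axis: np.ndarray | None = None,
) -> Trace:
    """Render a fragment multiset as an electropherogram.

    ``fragments`` maps apparent size (bp) to molar abundance.  Each
    fragment contributes a Gaussian peak of area
    ``fu_scale * abundance * size`` (mass-proportional dye response).
    *noise* defaults to the enzyme preset's noise; *background_mass*
    (mass units, from :func:`degrade_mass`) is rendered as the sub-25-bp
    spectrum — when it is None the noise model's ``exo_background_mass``
    fraction is skimmed off the fragments instead.  Deterministic for a
    given seed.
    """
    if noise is None:
        noise = enzyme.noise if enzyme is not None else NoiseModel()
    shape = shape or PeakShape()
    x = default_axis() if axis is None else np.asarray(axis, dtype=float)
    y = np.zeros_like(x)

    total_mass = sum(float(s) * a for s, a in fragments.items())
    frag_scale = 1.0
    if background_mass is None:
        background_mass = noise.exo_background_mass * total_mass
        frag_scale = 1.0 - noise.exo_background_mass

    clipped = []
    for size, ab in sorted(fragments.items()):
        size = float(size)
        if not AXIS_RANGE[0] <= size <= AXIS_RANGE[1]:
            clipped.append(size)
            continue
        area = fu_scale * frag_scale * ab * size
        y += _gaussian_area(x, size, float(shape.sigma(size)), area)
    if clipped:
        import warnings

        warnings.warn(f"fragments outside the renderable 10-2000 bp range clipped: {clipped}")

    for msize, marea in zip(MARKER_SIZES, MARKER_AREAS):
        y += _gaussian_area(x, msize, float(shape.sigma(msize)), marea)

    if background_mass > 0.0:
        # exponential degradation spectrum below ~25 bp
        decay = noise.exo_background_decay_nt
        lo, hi = AXIS_RANGE[0], 30.0
        w = np.where((x >= lo) & (x <= hi), np.exp(-(x - lo) / decay), 0.0)
        norm = np.trapezoid(w, x)
        if norm > 0:
            y += fu_scale * background_mass * w / norm

    y += noise.baseline_fu
    if noise.baseline_jitter_fu > 0.0:
        rng = np.random.default_rng(seed)
        y += rng.normal(0.0, noise.baseline_jitter_fu, size=x.shape)
    np.clip(y, 0.0, None, out=y)
    return Trace(axis=x, signal=y, seed=seed)
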