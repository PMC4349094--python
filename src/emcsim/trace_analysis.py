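"""Electropherogram analysis: calibration, peak calling, quantification.

The inverse of trace synthesis: anchor the size axis on the 15/1500-bp
markers, call peaks above a detection threshold, integrate their areas
(mass, via the intercalating dye, is the quantification currency — not
height), classify them against the fragment sizes expected from the
digestion model, and reduce to the cleaved-fraction statistic reported
per mix: cleaved area over total non-marker, non-background area.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks, savgol_filter

from .digestion import DigestResult
from .reanneal import DuplexPopulation
from .trace_sim import MARKER_SIZES, PeakShape, Trace

__all__ = [
    "Peak",
    "PeakTable",
    "CleavageQuant",
    "calibrate_size",
    "call_peaks",
    "classify_peaks",
    "cleaved_fraction",
    "expected_from_digests",
    "CLEAVED_LABELS",
    "LABEL_SYMBOLS",
]

CLEAVED_LABELS = ("cleaved", "cleaved_small", "cleaved_large")
#: Figure-legend symbols: * uncleaved, smaller cleavage product •, larger ⬥.
LABEL_SYMBOLS = {
    "uncleaved": "*",
    "cleaved_small": "•",
    "cleaved_large": "⬥",
}

MARKER_TOLERANCE = 0.10
BACKGROUND_MAX_BP = 25.0

# peak-calling defaults: detection threshold in FU above the estimated
# baseline, and the rolling-percentile baseline estimator
DEFAULT_MIN_HEIGHT_FU = 2.0
DEFAULT_MIN_SEPARATION_BP = 5.0
#: limit-of-detection multiplier: a peak must rise at least 3.3 robust
#: noise sd above the baseline (the conventional LOD = 3.3 sigma rule),
#: in addition to the fixed FU floor.
DEFAULT_MIN_SNR_SD = 3.3
BASELINE_WINDOW = 201
BASELINE_PERCENTILE = 10
SMOOTH_WINDOW = 7


@dataclass(frozen=True)
class Peak:
    apparent_size: float
    height: float
    area: float
    label: str = "unassigned"


@dataclass(frozen=True)
class PeakTable:
    peaks: tuple[Peak, ...]

    def __init__(self, peaks: Iterable[Peak]) -> None:
        object.__setattr__(self, "peaks", tuple(peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def with_labels(self, labels: Sequence[str]) -> "PeakTable":
        return PeakTable(replace(p, label=l) for p, l in zip(self.peaks, labels))

    def select(self, *labels: str) -> list[Peak]:
        return [p for p in self.peaks if p.label in labels]

    @property
    def non_marker(self) -> list[Peak]:
        return [p for p in self.peaks if p.label != "marker"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size_bp": [p.apparent_size for p in self.peaks],
                "height_fu": [p.height for p in self.peaks],
                "area": [p.area for p in self.peaks],
                "label": [p.label for p in self.peaks],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path) -> "PeakTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            Peak(r.size_bp, r.height_fu, r.area, r.label) for r in df.itertuples()
        )


@dataclass(frozen=True)
class CleavageQuant:
    """Mass-fraction summary of one digest trace."""

    cleaved_mass_fraction: float
    hetero_cleaved_fraction: float


def _find_marker_positions(trace: Trace) -> tuple[float, float]:
    y = trace.signal
    idx, _ = find_peaks(y, prominence=0.2 * float(y.max()))
    if len(idx) < 2:
        raise ValueError("markers not detectable: trace is uninterpretable")
    return float(trace.axis[idx[0]]), float(trace.axis[idx[-1]])


def calibrate_size(trace: Trace) -> Trace:
    """Two-point log-linear size calibration anchored at the 15/1500 markers.

    The outermost prominent peaks are taken as the lower and upper
    markers; they map exactly to 15 and 1500 bp.  A trace whose axis is
    already in bp (markers within 10% of nominal) passes through with an
    identity mapping.
    """
    lo, hi = trace.marker_sizes
    r1, r2 = _find_marker_positions(trace)
    if trace.axis_units == "bp" and abs(r1 - lo) / lo <= MARKER_TOLERANCE and abs(r2 - hi) / hi <= MARKER_TOLERANCE:
        if (r1, r2) == (lo, hi):
            return trace
        # snap: anchor the two marker apexes exactly
    if r1 <= 0 or r2 <= r1:
        raise ValueError("marker positions not usable for log-linear calibration")
    log_axis = np.log(trace.axis)
    slope = np.log(hi / lo) / (np.log(r2) - np.log(r1))
    bp = lo * np.exp(slope * (log_axis - np.log(r1)))
    return trace.with_axis(bp, units="bp")


def _baseline_subtracted(trace: Trace) -> np.ndarray:
    y = savgol_filter(trace.signal, SMOOTH_WINDOW, 2)
    base = percentile_filter(y, BASELINE_PERCENTILE, size=BASELINE_WINDOW)
    return y - base


def call_peaks(
    trace: Trace,
    min_height_fu: float = DEFAULT_MIN_HEIGHT_FU,
    min_separation_bp: float = DEFAULT_MIN_SEPARATION_BP,
    min_snr_sd: float = DEFAULT_MIN_SNR_SD,
) -> PeakTable:
    """Call, size and integrate peaks on a calibrated trace.

    The signal is lightly smoothed, a rolling 10th-percentile baseline is
    subtracted (Surveyor's irregular baseline must not inflate areas),
    and local maxima above the detection threshold are kept, the highest
    first, subject to a ``min_separation_bp`` spacing.  The threshold is
    ``min_height_fu`` or ``min_snr_sd`` robust noise sd, whichever is
    larger (the conventional 3.3-sigma limit of detection) — on a noisy
    Surveyor-like baseline a peak must clear the noise band, not just
    the nominal floor.  Areas are trapezoidal
    integrals of the baseline-subtracted signal between flanking minima.
    Marker peaks are labelled and excluded from quantification
    downstream.
    """
    if trace.axis_units != "bp":
        raise ValueError("trace must be size-calibrated before peak calling")
    x = trace.axis
    b = _baseline_subtracted(trace)
    # robust noise scale: peaks are sparse, so the MAD of the
    # baseline-subtracted signal tracks the noise, not the signal
    noise_sd = 1.4826 * float(np.median(np.abs(b - np.median(b))))
    threshold = max(min_height_fu, min_snr_sd * noise_sd)
    idx, _ = find_peaks(b, height=threshold)
    if len(idx) == 0:
        return PeakTable([])
    # enforce minimum separation, keeping the higher peak.  Maxima closer
    # than 1.5 sizing-model sigma are one unresolved peak: overlapping
    # fragments at the 2-sigma resolution limit already pull their
    # observed maxima inward, so the threshold on *measured* separation
    # must sit below 2 sigma to avoid over-merging
    sigma_model = PeakShape()
    order = sorted(idx, key=lambda i: -b[i])
    kept: list[int] = []
    for i in order:
        sep = max(min_separation_bp, 1.5 * float(sigma_model.sigma(x[i])))
        if all(abs(x[i] - x[j]) >= sep for j in kept):
            kept.append(i)
    kept.sort()

    # integration boundaries: minima between consecutive peaks, further
    # capped at +-4 sizing-model sigma around each apex so flat noise
    # between distant peaks is not booked as peak area
    bounds = [0]
    for a, c in zip(kept, kept[1:]):
        bounds.append(a + int(np.argmin(b[a:c])))
    bounds.append(len(x) - 1)

    peaks = []
    for n, i in enumerate(kept):
        half_width = 4.0 * float(sigma_model.sigma(x[i]))
        left = max(bounds[n], int(np.searchsorted(x, x[i] - half_width)))
        right = min(bounds[n + 1], int(np.searchsorted(x, x[i] + half_width)))
        seg = np.clip(b[left : right + 1], 0.0, None)
        area = float(np.trapezoid(seg, x[left : right + 1]))
        size = float(x[i])
        label = "unassigned"
        for m in trace.marker_sizes:
            if abs(size - m) / m <= MARKER_TOLERANCE:
                label = "marker"
        peaks.append(Peak(size, float(b[i]), area, label))
    return PeakTable(peaks)


def expected_from_digests(
    digests: Mapping[str, DigestResult],
    wt_len: int,
    mut_len: int,
    size_shift: float = 0.0,
) -> list[tuple[float, str]]:
    """Expected (size, label) entries for classification.

    Uncleaved entries are the two homoduplex sizes and the uncut
    heteroduplex apparent size.  For a single-lesion digest the two
    products per orientation are labelled by the figure convention
    (smaller product •, larger ⬥); multi-lesion digests label every
    partial product plainly "cleaved".  ``size_shift`` (negative under
    exonuclease nibbling) moves every expected size by a constant.
    """
    expected: dict[float, str] = {}
    for s in {float(wt_len), float(mut_len), float(max(wt_len, mut_len))}:
        expected[s + size_shift] = "uncleaved"
    n_sites = max(len(st.cut_sites) for d in digests.values() for st in d.states)
    for d in digests.values():
        for st in d.states:
            if not st.cut_sites:
                continue
            sizes = sorted(fr.apparent_size for fr in st.fragments)
            for rank, s in enumerate(sizes):
                if n_sites == 1 and len(sizes) == 2:
                    lab = "cleaved_small" if rank == 0 else "cleaved_large"
                else:
                    lab = "cleaved"
                # a product that aliases a parent size keeps the
                # uncleaved label (it is indistinguishable on the trace)
                expected.setdefault(float(s) + size_shift, lab)
    return sorted(expected.items())


def classify_peaks(
    table: PeakTable,
    expected: Sequence[tuple[float, str]],
    tolerance_pct: float = 5.0,
) -> PeakTable:
    """Match called peaks to expected fragment sizes.

    Greedy nearest-match within ``tolerance_pct`` relative size error;
    each expected entry labels at most one peak.  Unmatched peaks below
    25 bp are degradation background, others stay unassigned.
    """
    tol = tolerance_pct / 100.0
    labels = [p.label for p in table.peaks]
    candidates = []
    for pi, p in enumerate(table.peaks):
        if p.label == "marker":
            continue
        for ei, (size, _) in enumerate(expected):
            rel = abs(p.apparent_size - size) / size
            if rel <= tol:
                candidates.append((rel, pi, ei))
    used_peaks: set[int] = set()
    used_expected: set[int] = set()
    for rel, pi, ei in sorted(candidates):
        if pi in used_peaks or ei in used_expected:
            continue
        labels[pi] = expected[ei][1]
        used_peaks.add(pi)
        used_expected.add(ei)
    for pi, p in enumerate(table.peaks):
        if p.label == "marker" or pi in used_peaks:
            continue
        labels[pi] = "background" if p.apparent_size < BACKGROUND_MAX_BP else "unassigned"
    return table.with_labels(labels)


def cleaved_fraction(
    table: PeakTable,
    duplexes: DuplexPopulation | None = None,
) -> CleavageQuant:
    """Cleaved mass over total non-marker, non-background mass.

    ``hetero_cleaved_fraction`` additionally divides by the heteroduplex
    fraction of the mix, expressing cleavage per heteroduplex.
    """
    cleaved = sum(p.area for p in table.select(*CLEAVED_LABELS))
    total = sum(p.area for p in table.non_marker if p.label != "background")
    if total <= 0.0:
        raise ValueError("zero total peak area: nothing to quantify")
    cmf = cleaved / total
    hcf = float("nan")
    if duplexes is not None:
        hcf = cmf / duplexes.f_hetero if duplexes.f_hetero > 0 else 0.0
    return CleavageQuant(cleaved_mass_fraction=cmf, hetero_cleaved_fraction=hcf)
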