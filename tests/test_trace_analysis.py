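import numpy as np
import pytest

from emcsim.alleles import apply_variants, map_mismatches
from emcsim.digestion import heteroduplex_digests, population_fragments
from emcsim.reanneal import MixSpec, reanneal
from emcsim.trace_analysis import (
    PeakTable,
    calibrate_size,
    call_peaks,
    classify_peaks,
    cleaved_fraction,
    expected_from_digests,
)
from emcsim.trace_sim import NoiseModel, Trace, synthesize_trace

NOISELESS = NoiseModel()


def _noiseless_trace(frags, seed=0):
    return synthesize_trace(frags, None, NOISELESS, seed)


# ---------------------------------------------------------------- calibration


def test_bp_axis_passes_through_with_markers_anchored():
    tr = _noiseless_trace({300: 1.0})
    cal = calibrate_size(tr)
    assert cal.axis_units == "bp"
    table = call_peaks(cal)
    markers = sorted(p.apparent_size for p in table.peaks if p.label == "marker")
    assert markers[0] == pytest.approx(15.0, rel=0.05)
    assert markers[-1] == pytest.approx(1500.0, rel=0.05)


def test_known_axis_distortion_is_inverted():
    tr = _noiseless_trace({120: 0.5, 480: 0.5})
    distorted = Trace(
        axis=tr.axis**1.1, signal=tr.signal, axis_units="raw", seed=tr.seed
    )
    cal = calibrate_size(distorted)
    table = call_peaks(cal)
    sizes = sorted(p.apparent_size for p in table.non_marker)
    assert sizes[0] == pytest.approx(120, rel=0.01)
    assert sizes[1] == pytest.approx(480, rel=0.01)


def test_missing_markers_reject_trace():
    flat = Trace(axis=np.linspace(10, 2000, 500), signal=np.zeros(500))
    with pytest.raises(ValueError, match="uninterpretable"):
        calibrate_size(flat)


def test_uncalibrated_trace_cannot_be_peak_called():
    tr = _noiseless_trace({300: 1.0})
    raw = Trace(axis=tr.axis, signal=tr.signal, axis_units="raw")
    with pytest.raises(ValueError, match="calibrated"):
        call_peaks(raw)


# --------------------------------------------------------------- peak calling


def test_three_peak_digest_pattern():
    """Uncut parent plus the two cleavage products: three peaks."""
    frags = {570: 0.5, 200: 0.25, 370: 0.25}
    table = call_peaks(calibrate_size(_noiseless_trace(frags)))
    assert len(table.non_marker) == 3


def test_pure_noise_trace_has_no_nonmarker_peaks(t7e1):
    tr = synthesize_trace({}, t7e1, seed=5)
    table = call_peaks(calibrate_size(tr))
    assert table.non_marker == []


def test_nearby_fragments_merge_below_resolution():
    # 10 bp apart at ~490 bp: within 2 sigma of the sizing spread
    frags = {485: 0.5, 495: 0.5}
    table = call_peaks(calibrate_size(_noiseless_trace(frags)))
    assert len(table.non_marker) == 1
    # the same separation is resolvable at small sizes relative to sigma
    frags = {80: 0.5, 110: 0.5}
    table = call_peaks(calibrate_size(_noiseless_trace(frags)))
    assert len(table.non_marker) == 2


def test_flat_trace_gives_empty_table():
    tr = Trace(axis=np.geomspace(10, 2000, 500), signal=np.zeros(500))
    assert len(call_peaks(tr)) == 0


# ------------------------------------------------------------- classification


def _exon3_pipeline(exon3, del20_exon3, enzyme, p=0.5, seed=0, noise=NOISELESS):
    mut = apply_variants(exon3, del20_exon3)
    mmap = map_mismatches(exon3, del20_exon3)
    pop = reanneal(MixSpec(p))
    frags = population_fragments(pop, mmap, enzyme, exon3.length, mut.length)
    trace = calibrate_size(synthesize_trace(frags, enzyme, noise, seed))
    digests = heteroduplex_digests(mmap, enzyme, exon3.length, mut.length)
    expected = expected_from_digests(digests, exon3.length, mut.length)
    table = classify_peaks(call_peaks(trace), expected)
    return frags, pop, table


def test_full_pipeline_labels_all_expected_classes(exon3, del20_exon3, t7e1):
    _, _, table = _exon3_pipeline(exon3, del20_exon3, t7e1)
    labels = {p.label for p in table.non_marker}
    assert {"uncleaved", "cleaved_small", "cleaved_large"} <= labels


def test_empty_expected_set_leaves_peaks_unassigned():
    table = call_peaks(calibrate_size(_noiseless_trace({300: 1.0})))
    table = classify_peaks(table, [])
    assert all(p.label == "unassigned" for p in table.non_marker)


def test_unmatched_small_peaks_are_background():
    from emcsim.trace_analysis import Peak

    table = PeakTable([Peak(18.0, 5.0, 10.0), Peak(300.0, 5.0, 10.0)])
    table = classify_peaks(table, [])
    assert [p.label for p in table.peaks] == ["background", "unassigned"]


def test_each_expected_size_labels_at_most_one_peak():
    from emcsim.trace_analysis import Peak

    table = PeakTable([Peak(198.0, 5.0, 10.0), Peak(202.0, 5.0, 10.0)])
    table = classify_peaks(table, [(200.0, "cleaved_small")])
    labels = sorted(p.label for p in table.peaks)
    assert labels.count("cleaved_small") == 1


# -------------------------------------------------------------- quantification


def test_undigested_control_reports_zero_cleavage(exon3, del20_exon3, t7e1):
    _, pop, table = _exon3_pipeline(exon3, del20_exon3, t7e1, p=0.0)
    quant = cleaved_fraction(table, pop)
    assert quant.cleaved_mass_fraction == 0.0
    assert quant.hetero_cleaved_fraction == 0.0


def test_roundtrip_recovers_sizes_and_cleaved_fraction(exon3, del20_exon3, t7e1):
    """Noiseless synthesize -> analyze round trip: sizes within 2%,
    cleaved mass fraction within 0.01 of the simulated truth."""
    frags, pop, table = _exon3_pipeline(exon3, del20_exon3, t7e1)
    called = sorted(p.apparent_size for p in table.non_marker)
    truth_sizes = sorted(frags)
    # the 552/572 parents merge into one apparent peak; products resolve
    for size in truth_sizes[:-2]:
        assert min(abs(c - size) / size for c in called) <= 0.02
    truth_cleaved = sum(
        s * a for s, a in frags.items() if s not in (exon3.length, exon3.length - 20)
    ) / sum(s * a for s, a in frags.items())
    quant = cleaved_fraction(table, pop)
    assert quant.cleaved_mass_fraction == pytest.approx(truth_cleaved, abs=0.01)
    assert quant.hetero_cleaved_fraction <= 1.0


def test_cleaved_fraction_invariant_to_fu_rescaling(exon3, del20_exon3, t7e1):
    mut = apply_variants(exon3, del20_exon3)
    mmap = map_mismatches(exon3, del20_exon3)
    pop = reanneal(MixSpec(0.5))
    frags = population_fragments(pop, mmap, t7e1, exon3.length, mut.length)
    tr = calibrate_size(synthesize_trace(frags, t7e1, NOISELESS, 0))
    digests = heteroduplex_digests(mmap, t7e1, exon3.length, mut.length)
    expected = expected_from_digests(digests, exon3.length, mut.length)

    def quantify(trace):
        return cleaved_fraction(
            classify_peaks(call_peaks(trace), expected), pop
        ).cleaved_mass_fraction

    doubled = Trace(axis=tr.axis, signal=2.0 * tr.signal)
    assert quantify(doubled) == pytest.approx(quantify(tr), rel=1e-6)


def test_zero_total_area_rejected():
    with pytest.raises(ValueError, match="zero total"):
        cleaved_fraction(PeakTable([]))
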