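"""XIC extraction, peak detection and spectral averaging."""

import numpy as np
import pytest

from aiflipid.chromatography import (
    Trace,
    average_spectrum,
    detect_peaks,
    extract_xic,
)
from aiflipid.io import Run, Spectrum


def gaussian_trace(apex=5.0, sigma=0.05, height=1e5, step=0.01, span=1.0):
    rt = np.arange(apex - span, apex + span + step / 2, step)
    y = height * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)
    return Trace(500.0, 5.0, "full", rt, y)


def test_single_gaussian_area_within_one_percent():
    sigma, height = 0.05, 1e5
    trace = gaussian_trace(sigma=sigma, height=height)
    peaks = detect_peaks(trace)
    assert len(peaks) == 1
    analytic = height * sigma * np.sqrt(2 * np.pi)
    assert peaks[0].area == pytest.approx(analytic, rel=0.01)
    assert peaks[0].apex_rt == pytest.approx(5.0, abs=0.011)
    assert peaks[0].rt_start < peaks[0].apex_rt < peaks[0].rt_end


def test_flat_zero_trace_has_no_peaks():
    trace = Trace(500.0, 5.0, "full", np.linspace(0, 1, 50), np.zeros(50))
    assert detect_peaks(trace) == []


def test_two_gaussians_split_at_the_valley():
    rt = np.arange(0.0, 2.0, 0.01)
    y = 1e5 * np.exp(-0.5 * ((rt - 0.8) / 0.05) ** 2) + 8e4 * np.exp(
        -0.5 * ((rt - 0.95) / 0.05) ** 2
    )
    peaks = detect_peaks(Trace(500.0, 5.0, "full", rt, y))
    assert len(peaks) == 2
    first, second = sorted(peaks, key=lambda p: p.apex_rt)
    assert first.rt_end <= second.rt_start + 1e-9
    # total area conserved against the trace integral
    total = sum(p.area for p in peaks)
    assert total == pytest.approx(np.trapezoid(y, rt), rel=0.01)


def test_xic_window_does_not_cross_contaminate():
    # two species 0.02 m/z apart; 5 ppm of 750 is ~0.004
    spectra = [
        Spectrum(
            0.01 * i,
            -1,
            "full",
            np.array([750.000, 750.020]),
            np.array([1000.0, 500.0]),
        )
        for i in range(5)
    ]
    run = Run(spectra)
    a = extract_xic(run, 750.000, 5.0, "full")
    b = extract_xic(run, 750.020, 5.0, "full")
    assert np.all(a.intensity == 1000.0)
    assert np.all(b.intensity == 500.0)


def test_xic_is_linear_in_intensities(standard_run):
    run, gt = standard_run
    mz = gt.species[0]["mz"]
    base = extract_xic(run, mz, 5.0, "full")
    scaled = extract_xic(run.scale_intensities(3.0), mz, 5.0, "full")
    assert np.allclose(scaled.intensity, 3.0 * base.intensity, rtol=1e-12)


def test_missing_scan_kind_gives_empty_trace():
    run = Run([Spectrum(0.0, -1, "full", np.array([500.0]), np.array([1.0]))])
    trace = extract_xic(run, 500.0, 5.0, "AIF")
    assert len(trace) == 0


def test_average_of_identical_spectra_is_identity():
    mz = np.array([200.0, 300.0, 400.0])
    inten = np.array([10.0, 20.0, 30.0])
    run = Run([Spectrum(0.01 * i, -1, "AIF", mz, inten) for i in range(5)])
    avg = average_spectrum(run, (0.0, 0.05), "AIF")
    assert np.allclose(avg.mz, mz, atol=1e-9)
    assert np.allclose(avg.intensity, inten, rtol=1e-12)


def test_average_single_scan_window_is_that_scan():
    mz = np.array([200.0, 300.0])
    run = Run(
        [
            Spectrum(0.0, -1, "AIF", mz, np.array([1.0, 2.0])),
            Spectrum(1.0, -1, "AIF", mz, np.array([5.0, 6.0])),
        ]
    )
    avg = average_spectrum(run, (-0.1, 0.1), "AIF")
    assert np.allclose(avg.intensity, [1.0, 2.0])


def test_average_disjoint_window_errors():
    run = Run([Spectrum(0.0, -1, "AIF", np.array([200.0]), np.array([1.0]))])
    with pytest.raises(ValueError, match="5"):
        average_spectrum(run, (5.0, 6.0), "AIF")


def test_average_absent_scans_count_as_zero():
    mz = np.array([200.0])
    run = Run(
        [
            Spectrum(0.0, -1, "AIF", mz, np.array([10.0])),
            Spectrum(0.01, -1, "AIF", np.array([]), np.array([])),
        ]
    )
    avg = average_spectrum(run, (0.0, 0.02), "AIF")
    assert avg.intensity[0] == pytest.approx(5.0)
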