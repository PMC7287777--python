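"""Extracted-ion chromatograms, peak detection and spectral averaging.

These are the primitives every downstream analysis is assembled from: a
narrow-window XIC per target m/z, local-maximum peak detection with
valley-split bounds and trapezoidal areas, and the averaging of centroid
spectra under a retention-time window (how class-band AIF spectra are
produced).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .io import Run, ScanKind, Spectrum

__all__ = ["Trace", "ChromPeak", "extract_xic", "detect_peaks", "average_spectrum"]


@dataclass
class Trace:
    """An XIC: one intensity point per scan of the requested kind."""

    target_mz: float
    tol_ppm: float
    scan_kind: ScanKind
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity series must have equal length")

    def __len__(self) -> int:
        return int(self.rt.size)

    def integral(self) -> float:
        """Trapezoidal integral of the whole trace (intensity · minutes)."""
        if len(self) < 2:
            return 0.0
        return float(np.trapezoid(self.intensity, self.rt))

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame({"rt_min": self.rt, "intensity": self.intensity}).to_csv(
            path, index=False
        )
        return path


@dataclass(frozen=True)
class ChromPeak:
    """A detected chromatographic peak with trapezoidal area."""

    apex_rt: float
    rt_start: float
    rt_end: float
    area: float
    height: float
    signal_to_noise: float

    @property
    def rt_bounds(self) -> tuple[float, float]:
        return self.rt_start, self.rt_end


def extract_xic(
    run: Run, mz: float, tol_ppm: float = 5.0, scan_kind: ScanKind = "full"
) -> Trace:
    """XIC of ``mz`` ± ``tol_ppm`` over all scans of one kind.

    Each point sums the centroid intensities falling inside the window; a
    scan with no matching centroid contributes zero (the trace always has
    one point per scan).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = mz * tol_ppm * 1e-6
    rts, vals = [], []
    for spec in run.scans(scan_kind):
        lo = np.searchsorted(spec.mz, mz - half, side="left")
        hi = np.searchsorted(spec.mz, mz + half, side="right")
        rts.append(spec.rt)
        vals.append(float(spec.intensity[lo:hi].sum()))
    return Trace(mz, tol_ppm, scan_kind, np.asarray(rts), np.asarray(vals))


def noise_level(intensity: np.ndarray) -> float:
    """Robust noise estimate: 1.4826 x MAD of the lower-intensity half."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.size == 0:
        return 0.0
    low = np.sort(intensity)[: max(1, intensity.size // 2)]
    return float(1.4826 * np.median(np.abs(low - np.median(low))))


def detect_peaks(
    trace: Trace, min_snr: float = 5.0, min_points: int = 3
) -> list[ChromPeak]:
    """Detect peaks as local maxima above ``min_snr`` x noise.

    Bounds extend to the nearest valley (local minimum) or noise crossing;
    overlapping peaks are split at the valley between them.  Area is the
    trapezoidal integral between the bounds.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    y = trace.intensity
    noise = noise_level(y)
    threshold = max(min_snr * noise, np.finfo(float).tiny)
    idx, _ = find_peaks(y, height=threshold)
    baseline = noise  # descend until the signal falls back into the noise
    peaks: list[ChromPeak] = []
    for i in idx:
        lo = i
        while lo > 0 and y[lo - 1] <= y[lo] and y[lo - 1] > baseline:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi + 1] <= y[hi] and y[hi + 1] > baseline:
            hi += 1
        if hi - lo + 1 < min_points:
            continue
        area = float(np.trapezoid(y[lo : hi + 1], trace.rt[lo : hi + 1]))
        if area <= 0:
            continue
        snr = float(y[i] / noise) if noise > 0 else float("inf")
        peaks.append(
            ChromPeak(
                apex_rt=float(trace.rt[i]),
                rt_start=float(trace.rt[lo]),
                rt_end=float(trace.rt[hi]),
                area=area,
                height=float(y[i]),
                signal_to_noise=snr,
            )
        )
    return peaks


def average_spectrum(
    run: Run,
    rt_window: tuple[float, float],
    scan_kind: ScanKind = "AIF",
    cluster_mz: float = 0.003,
) -> Spectrum:
    """Average the centroid spectra of one scan kind inside an RT window.

    Centroids from member scans are clustered within ± ``cluster_mz``; each
    cluster's intensity is the mean over the member scans (scans where the
    ion is absent contribute zero), its m/z the intensity-weighted mean.
    """
    lo, hi = rt_window
    members = [s for s in run.scans(scan_kind) if lo <= s.rt <= hi]
    if not members:
        raise ValueError(f"no {scan_kind} scans inside RT window ({lo:g}, {hi:g}) min")
    if len(members) == 1:
        return members[0]
    all_mz = np.concatenate([s.mz for s in members])
    all_int = np.concatenate([s.intensity for s in members])
    if all_mz.size == 0:
        return Spectrum(
            rt=float(np.mean([s.rt for s in members])),
            polarity=members[0].polarity,
            scan_kind=scan_kind,
            mz=all_mz,
            intensity=all_int,
            collision_energy=members[0].collision_energy,
        )
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int = all_mz[order], all_int[order]
    breaks = np.flatnonzero(np.diff(all_mz) > cluster_mz) + 1
    groups = np.split(np.arange(all_mz.size), breaks)
    n = len(members)
    out_mz = np.array(
        [np.average(all_mz[g], weights=np.maximum(all_int[g], 1e-30)) for g in groups]
    )
    out_int = np.array([all_int[g].sum() / n for g in groups])
    order = np.argsort(out_mz, kind="stable")
    return Spectrum(
        rt=float(np.mean([s.rt for s in members])),
        polarity=members[0].polarity,
        scan_kind=scan_kind,
        mz=out_mz[order],
        intensity=out_int[order],
        collision_energy=members[0].collision_energy,
    )


def spectrum_intensity_at(
    spectrum: Spectrum, mz: float, tol: float = 0.005
) -> float:
    """Summed centroid intensity within ± ``tol`` m/z of a target."""
    lo = np.searchsorted(spectrum.mz, mz - tol, side="left")
    hi = np.searchsorted(spectrum.mz, mz + tol, side="right")
    return float(spectrum.intensity[lo:hi].sum())
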