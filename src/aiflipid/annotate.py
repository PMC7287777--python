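"""Class-band location, species annotation, FA profiling and XIC alignment.

The analysis chain mirrors how a HILIC + all-ion-fragmentation run is read:

1. class-diagnostic fragment traces on the AIF scans locate each class's
   retention band (:func:`locate_class_bands`);
2. the full-scan spectrum averaged under a band is matched against a
   combinatorial candidate list by accurate mass (:func:`annotate_species`);
3. the AIF spectrum averaged under the band, read at the fatty-acyl
   carboxylate masses, gives the class's acyl-chain profile
   (:func:`fa_profile`), optionally in retention sub-slices
   (:func:`band_slices`);
4. carboxylate product traces are tied back to intact precursors by
   retention-time and peak-shape agreement (:func:`align_precursor_product`);
5. replicate agreement is enforced with an RSD filter and class-normalised
   areas (:func:`replicate_filter`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatography import (
    ChromPeak,
    Trace,
    average_spectrum,
    detect_peaks,
    extract_xic,
    noise_level,
    spectrum_intensity_at,
)
from .io import Run, Spectrum
from .lipids import (
    IonType,
    LipidClass,
    LipidSpecies,
    carboxylate_mz,
    elution_rank,
    format_shorthand,
)
from .rules import DiagnosticIon, diagnostic_table

__all__ = [
    "ClassBand",
    "SpeciesAnnotation",
    "FAProfile",
    "PrecursorProductLink",
    "locate_class_bands",
    "annotate_species",
    "fa_profile",
    "combine_profiles",
    "band_slices",
    "align_precursor_product",
    "ratio_trace",
    "replicate_filter",
    "DEFAULT_CHAIN_UNIVERSE",
    "MATCH_TOL_MZ",
]

# Accurate-mass annotation tolerance (m/z units) — distinct from the ppm
# window used for XIC extraction.
MATCH_TOL_MZ = 0.005

# Acyl chains routinely profiled in plasma phospholipid classes.
DEFAULT_CHAIN_UNIVERSE: tuple[tuple[int, int], ...] = (
    (14, 0), (16, 0), (16, 1), (17, 0), (17, 1),
    (18, 0), (18, 1), (18, 2), (18, 3),
    (20, 1), (20, 2), (20, 3), (20, 4), (20, 5),
    (22, 3), (22, 4), (22, 5), (22, 6),
)


@dataclass
class ClassBand:
    """A retention window attributed to one or more lipid classes."""

    classes: tuple[LipidClass, ...]
    polarity: int
    rt_window: tuple[float, float]
    evidence: list[tuple[float, ChromPeak]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.rt_window
        if not hi > lo:
            raise ValueError("band window must have positive width")

    @property
    def lipid_class(self) -> LipidClass:
        return self.classes[0]

    @property
    def apex_rt(self) -> float:
        if self.evidence:
            return float(np.mean([p.apex_rt for _, p in self.evidence]))
        return 0.5 * (self.rt_window[0] + self.rt_window[1])


@dataclass(frozen=True)
class SpeciesAnnotation:
    species: LipidSpecies
    ion: IonType
    theoretical_mz: float
    observed_mz: float
    apex_rt: float
    area: float
    band: ClassBand
    ambiguous: bool = False

    @property
    def mass_error(self) -> float:
        return self.observed_mz - self.theoretical_mz

    @property
    def name(self) -> str:
        return format_shorthand(self.species)


@dataclass
class FAProfile:
    """Relative fatty-acyl composition of one class band (percent)."""

    lipid_class: LipidClass
    rows: list[dict]  # chain, mz, relative_pct, sd_pct, intensity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def pct(self, chain: tuple[int, int]) -> float:
        for row in self.rows:
            if row["chain"] == chain:
                return row["relative_pct"]
        raise KeyError(f"chain {chain} not in profile")

    def total_pct(self) -> float:
        return float(sum(r["relative_pct"] for r in self.rows))


@dataclass(frozen=True)
class PrecursorProductLink:
    product_mz: float
    product_peak: ChromPeak
    precursor: SpeciesAnnotation
    rt_delta: float
    shape_correlation: float


def locate_class_bands(
    run: Run,
    diagnostics: Sequence[DiagnosticIon] | None = None,
    expected_classes: Iterable[LipidClass] | None = None,
    tol_ppm: float = 10.0,
    min_snr: float = 5.0,
    min_points: int = 3,
    merge_gap: float = 0.05,
    min_rel_height: float = 0.05,
) -> list[ClassBand]:
    """Locate class bands from diagnostic-ion XIC peaks on the AIF scans.

    Each diagnostic trace yields one band per detected peak, labelled with
    every class sharing that diagnostic (restricted to ``expected_classes``
    when given).  When one diagnostic produces as many bands as it has
    candidate classes, the classes are assigned to bands in HILIC
    head-group elution order; otherwise the ambiguity is kept.
    Bands are returned sorted by retention time.
    """
    if not any(True for _ in run.scans("AIF")):
        raise ValueError("run contains no AIF scans")
    if diagnostics is None:
        diagnostics = diagnostic_table()
    expected = set(expected_classes) if expected_classes is not None else None

    bands: list[ClassBand] = []
    for diag in diagnostics:
        if diag.polarity != run.polarity:
            continue
        classes = sorted(diag.lipid_classes, key=elution_rank)
        if expected is not None:
            classes = [c for c in classes if c in expected]
        if not classes:
            continue
        trace = extract_xic(run, diag.mz, tol_ppm, "AIF")
        peaks = detect_peaks(trace, min_snr=min_snr, min_points=min_points)
        if peaks:
            # noise spurs at band edges are not bands of their own
            top = max(p.height for p in peaks)
            peaks = [p for p in peaks if p.height >= min_rel_height * top]
        peaks.sort(key=lambda p: p.apex_rt)
        peaks = _merge_adjacent_peaks(peaks, gap=merge_gap)
        if len(peaks) == len(classes) and len(peaks) > 1:
            assigned = [(cls,) for cls in classes]  # one class per band, in RT order
        else:
            assigned = [tuple(classes)] * len(peaks)
        for peak, cls_tuple in zip(peaks, assigned):
            bands.append(
                ClassBand(
                    classes=cls_tuple,
                    polarity=run.polarity,
                    rt_window=peak.rt_bounds,
                    evidence=[(diag.mz, peak)],
                )
            )
    bands = _merge_bands(bands)
    bands.sort(key=lambda b: b.apex_rt)
    if expected is not None:
        covered = {c for b in bands for c in b.classes}
        for cls in sorted(expected - covered, key=elution_rank):
            import warnings

            warnings.warn(
                f"no diagnostic-ion band found for {cls.value}; "
                "the class can only be annotated mass-only (manual band)",
                stacklevel=2,
            )
    return bands


def _merge_adjacent_peaks(peaks: list[ChromPeak], gap: float) -> list[ChromPeak]:
    """Fuse diagnostic-trace peaks whose bounds touch within ``gap`` minutes.

    A class band is a train of species peaks offset within the band, so the
    class-diagnostic trace is multi-apex; for band location those apexes
    are one chromatographic feature.
    """
    if not peaks:
        return peaks
    merged = [peaks[0]]
    for p in peaks[1:]:
        last = merged[-1]
        if p.rt_start <= last.rt_end + gap:
            apex, height = ((last.apex_rt, last.height) if last.height >= p.height
                            else (p.apex_rt, p.height))
            merged[-1] = ChromPeak(
                apex_rt=apex,
                rt_start=last.rt_start,
                rt_end=max(last.rt_end, p.rt_end),
                area=last.area + p.area,
                height=height,
                signal_to_noise=max(last.signal_to_noise, p.signal_to_noise),
            )
        else:
            merged.append(p)
    return merged


def _merge_bands(bands: list[ClassBand]) -> list[ClassBand]:
    """Merge bands with identical class assignment and overlapping windows
    (one class can be evidenced by several diagnostics)."""
    merged: list[ClassBand] = []
    for band in sorted(bands, key=lambda b: b.rt_window[0]):
        for m in merged:
            if m.classes == band.classes and (
                band.rt_window[0] <= m.rt_window[1] and m.rt_window[0] <= band.rt_window[1]
            ):
                m.rt_window = (
                    min(m.rt_window[0], band.rt_window[0]),
                    max(m.rt_window[1], band.rt_window[1]),
                )
                m.evidence.extend(band.evidence)
                break
        else:
            merged.append(band)
    return merged


def annotate_species(
    run: Run,
    bands: Sequence[ClassBand],
    candidates: Sequence[tuple[LipidSpecies, IonType, float]],
    tol: float = MATCH_TOL_MZ,
    xic_tol_ppm: float = 5.0,
    min_snr: float = 5.0,
) -> list[SpeciesAnnotation]:
    """Annotate intact species by accurate mass within located class bands.

    The full-scan spectrum averaged under each band is matched against the
    candidate (species, ion, m/z) list within ± ``tol``; every match must be
    backed by a full-scan XIC peak whose apex lies inside the band window.
    Candidates matching the same observed centroid are flagged ambiguous
    and all reported.
    """
    annotations: list[SpeciesAnnotation] = []
    for band in bands:
        try:
            avg = average_spectrum(run, band.rt_window, "full")
        except ValueError:
            continue
        band_classes = set(band.classes)
        matched: list[tuple[int, LipidSpecies, IonType, float]] = []
        for species, ion, mz_t in candidates:
            if species.lipid_class not in band_classes:
                continue
            if ion.charge_sign != run.polarity:
                continue
            lo = np.searchsorted(avg.mz, mz_t - tol, side="left")
            hi = np.searchsorted(avg.mz, mz_t + tol, side="right")
            if hi <= lo:
                continue
            local = slice(lo, hi)
            best = lo + int(np.argmax(avg.intensity[local]))
            matched.append((best, species, ion, mz_t))

        centroid_hits: dict[int, int] = {}
        for idx, *_ in matched:
            centroid_hits[idx] = centroid_hits.get(idx, 0) + 1
        for idx, species, ion, mz_t in matched:
            trace = extract_xic(run, mz_t, xic_tol_ppm, "full")
            peaks = [
                p
                for p in detect_peaks(trace, min_snr=min_snr)
                if band.rt_window[0] <= p.apex_rt <= band.rt_window[1]
            ]
            if not peaks:
                continue
            peak = max(peaks, key=lambda p: p.height)
            annotations.append(
                SpeciesAnnotation(
                    species=species,
                    ion=ion,
                    theoretical_mz=mz_t,
                    observed_mz=float(avg.mz[idx]),
                    apex_rt=peak.apex_rt,
                    area=peak.area,
                    band=band,
                    ambiguous=centroid_hits[idx] > 1,
                )
            )
    return annotations


def fa_profile(
    run: Run,
    band: ClassBand,
    chain_universe: Sequence[tuple[int, int]] | None = None,
    tol: float = MATCH_TOL_MZ,
    mode: str = "spectrum",
    xic_tol_ppm: float = 5.0,
) -> FAProfile:
    """Fatty-acyl profile of one class band from its AIF carboxylate signals.

    ``mode="spectrum"`` (default) reads intensities off the AIF spectrum
    averaged under the band; ``mode="area"`` integrates each carboxylate's
    AIF XIC peak inside the band instead.  Percentages are normalised over
    the detected chains and sum to 100.
    """
    chains = tuple(chain_universe) if chain_universe is not None else DEFAULT_CHAIN_UNIVERSE
    if mode not in ("spectrum", "area"):
        raise ValueError("mode must be 'spectrum' or 'area'")
    intensities: dict[tuple[int, int], float] = {}
    if mode == "spectrum":
        avg = average_spectrum(run, band.rt_window, "AIF")
        for c, d in chains:
            mz = carboxylate_mz(c, d)
            intensities[(c, d)] = spectrum_intensity_at(avg, mz, tol)
    else:
        for c, d in chains:
            mz = carboxylate_mz(c, d)
            trace = extract_xic(run, mz, xic_tol_ppm, "AIF")
            peaks = [
                p
                for p in detect_peaks(trace)
                if band.rt_window[0] <= p.apex_rt <= band.rt_window[1]
            ]
            intensities[(c, d)] = max((p.area for p in peaks), default=0.0)

    total = sum(v for v in intensities.values() if v > 0)
    rows = []
    if total <= 0:
        import warnings

        warnings.warn(
            f"no carboxylate signal in band {band.classes} "
            f"{band.rt_window}; empty profile",
            stacklevel=2,
        )
        return FAProfile(band.lipid_class, rows)
    for (c, d), v in intensities.items():
        if v > 0:
            rows.append(
                {
                    "chain": (c, d),
                    "mz": carboxylate_mz(c, d),
                    "intensity": v,
                    "relative_pct": 100.0 * v / total,
                    "sd_pct": None,
                }
            )
    rows.sort(key=lambda r: r["mz"])
    return FAProfile(band.lipid_class, rows)


def combine_profiles(profiles: Sequence[FAProfile]) -> FAProfile:
    """Combine replicate profiles as mean ± sd of the relative percentages,
    renormalised so the means sum to 100."""
    if not profiles:
        raise ValueError("no profiles to combine")
    cls = profiles[0].lipid_class
    chains = sorted({r["chain"] for p in profiles for r in p.rows})
    rows = []
    means = {}
    for ch in chains:
        vals = []
        for p in profiles:
            try:
                vals.append(p.pct(ch))
            except KeyError:
                vals.append(0.0)
        means[ch] = float(np.mean(vals))
    norm = 100.0 / sum(means.values())
    for ch in chains:
        vals = []
        for p in profiles:
            try:
                vals.append(p.pct(ch))
            except KeyError:
                vals.append(0.0)
        rows.append(
            {
                "chain": ch,
                "mz": carboxylate_mz(*ch),
                "intensity": None,
                "relative_pct": means[ch] * norm,
                "sd_pct": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            }
        )
    return FAProfile(cls, rows)


def band_slices(
    run: Run, band: ClassBand, n_slices: int
) -> list[tuple[tuple[float, float], Spectrum]]:
    """Split a band into equal-width RT sub-windows with averaged AIF spectra,
    exposing the within-band composition gradient."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    lo, hi = band.rt_window
    n_scans = sum(1 for s in run.scans("AIF") if lo <= s.rt <= hi)
    if n_slices > n_scans:
        raise ValueError(
            f"{n_slices} slices requested but the band holds {n_scans} AIF scans"
        )
    edges = np.linspace(lo, hi, n_slices + 1)
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        out.append(((float(a), float(b)), average_spectrum(run, (a, b), "AIF")))
    return out


def align_precursor_product(
    run: Run,
    product_mz: float,
    annotations: Sequence[SpeciesAnnotation],
    rt_tol: float = 0.1,
    min_corr: float = 0.8,
    tol_ppm: float = 5.0,
) -> list[PrecursorProductLink]:
    """Link an AIF product-ion trace to precursor annotations by XIC alignment.

    A link requires the precursor's full-scan apex within ``rt_tol`` minutes
    of a product peak apex and a Pearson correlation of the two traces over
    the product peak bounds of at least ``min_corr``.  All qualifying
    precursors are reported, ranked by correlation.
    """
    product = extract_xic(run, product_mz, tol_ppm, "AIF")
    links: list[PrecursorProductLink] = []
    for peak in detect_peaks(product):
        sel = (product.rt >= peak.rt_start) & (product.rt <= peak.rt_end)
        if sel.sum() < 3:
            continue
        for ann in annotations:
            delta = abs(ann.apex_rt - peak.apex_rt)
            if delta > rt_tol:
                continue
            prec = extract_xic(run, ann.theoretical_mz, tol_ppm, "full")
            prec_on_grid = np.interp(product.rt[sel], prec.rt, prec.intensity)
            prod_vals = product.intensity[sel]
            if np.std(prec_on_grid) == 0 or np.std(prod_vals) == 0:
                continue
            corr = float(np.corrcoef(prod_vals, prec_on_grid)[0, 1])
            if corr >= min_corr:
                links.append(
                    PrecursorProductLink(product_mz, peak, ann, delta, corr)
                )
    links.sort(key=lambda l: l.shape_correlation, reverse=True)
    return links


def ratio_trace(
    run: Run,
    mz_num: float,
    mz_den: float,
    scan_kind: str = "AIF",
    tol_ppm: float = 5.0,
    den_snr: float = 3.0,
) -> Trace:
    """Point-wise intensity ratio of two XICs (e.g. FA C20:3 over C20:4).

    Points where the denominator does not rise above its noise floor are
    emitted as NaN gaps, not zeros.
    """
    num = extract_xic(run, mz_num, tol_ppm, scan_kind)
    den = extract_xic(run, mz_den, tol_ppm, scan_kind)
    floor = max(den_snr * noise_level(den.intensity), np.finfo(float).tiny)
    ratio = np.full_like(num.intensity, np.nan)
    ok = den.intensity > floor
    ratio[ok] = num.intensity[ok] / den.intensity[ok]
    return Trace(mz_num, tol_ppm, scan_kind, num.rt, ratio)


def replicate_filter(
    annotation_sets: Sequence[Sequence[SpeciesAnnotation]],
    max_rsd_pct: float = 20.0,
) -> pd.DataFrame:
    """Keep species reproducible across replicates; normalise within class.

    A species (identified by shorthand + ion) must appear in every
    replicate with a relative standard deviation of its chromatographic
    peak areas at or below ``max_rsd_pct``.  Surviving species' mean areas
    are converted to percentages of their lipid-class total.
    """
    if len(annotation_sets) < 2:
        raise ValueError("replicate filtering needs >= 2 replicate sets")
    n_rep = len(annotation_sets)
    table: dict[tuple[str, str], dict] = {}
    for rep_idx, anns in enumerate(annotation_sets):
        for ann in anns:
            key = (ann.name, ann.ion.name)
            row = table.setdefault(
                key,
                {
                    "species": ann.name,
                    "ion": ann.ion.name,
                    "lipid_class": ann.species.lipid_class.value,
                    "areas": {},
                },
            )
            # keep the largest peak if a replicate annotates the species twice
            prev = row["areas"].get(rep_idx, 0.0)
            row["areas"][rep_idx] = max(prev, ann.area)

    rows = []
    for row in table.values():
        if len(row["areas"]) < n_rep:
            continue
        areas = np.array([row["areas"][i] for i in range(n_rep)])
        mean = float(areas.mean())
        rsd = float(areas.std(ddof=1) / mean * 100.0) if mean > 0 else np.inf
        if rsd <= max_rsd_pct:
            rows.append(
                {
                    "species": row["species"],
                    "ion": row["ion"],
                    "lipid_class": row["lipid_class"],
                    "mean_area": mean,
                    "rsd_pct": rsd,
                }
            )
    df = pd.DataFrame(rows, columns=["species", "ion", "lipid_class", "mean_area", "rsd_pct"])
    if not df.empty:
        df["class_pct"] = df.groupby("lipid_class")["mean_area"].transform(
            lambda a: 100.0 * a / a.sum()
        )
        df = df.sort_values(["lipid_class", "species"]).reset_index(drop=True)
    else:
        df["class_pct"] = pd.Series(dtype=float)
    return df
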