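"""Synthetic HILIC-ESI full-MS + AIF run generator with ground truth.

The generator emulates the MS/AIF alternating acquisition of a q-orbitrap
instrument coupled to HILIC class separation: each lipid class elutes as a
Gaussian band at a characteristic retention time (PG 7.2, PE 10.2, LPE 14.0,
PC 15.3, LPC 17.3 min), species within a band are offset so that longer
acyl chains elute slightly earlier and more unsaturated ones slightly
later, full scans carry the precursor envelopes, and AIF scans carry the
fragment chemistry (carboxylates with an sn-2/sn-1 intensity bias, FA and
ketene neutral losses, head-group diagnostics, residual precursor).
Noise is multiplicative (per-centroid Gaussian CV) plus an additive floor
scaled to the largest centroid, and every m/z receives ppm-level jitter.
Runs are exactly reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import Run, Spectrum
from .lipids import (
    IonType,
    ION_TYPES,
    LipidClass,
    LipidSpecies,
    format_shorthand,
    ion_mz,
    parse_shorthand,
)
from .rules import FragmentKind, PredictedFragment, SN_BIAS_RANGE, predict_fragments

__all__ = [
    "SimSpecies",
    "SimConfig",
    "GroundTruth",
    "simulate_run",
    "five_standard_config",
    "plasma_like_config",
    "pd_comparison_configs",
    "DEFAULT_BAND_CENTERS",
    "PLASMA_FA_PCT",
]

# HILIC class-band apex times, minutes.  PG/PE/LPE/PC/LPC are the observed
# standard-mix values; PI and SM are not stated for this gradient and are
# placed consistently with the head-group elution order (PI between PG and
# PE, SM between PC and LPC).
DEFAULT_BAND_CENTERS: dict[LipidClass, float] = {
    LipidClass.PG: 7.2,
    LipidClass.PI: 8.8,
    LipidClass.PE: 10.2,
    LipidClass.LPE: 14.0,
    LipidClass.PC: 15.3,
    LipidClass.SM: 16.3,
    LipidClass.LPC: 17.3,
}


@dataclass(frozen=True)
class SimSpecies:
    """One simulated precursor: species, ion, apex intensity and elution."""

    species: LipidSpecies
    ion: IonType
    abundance: float
    rt_apex: float
    rt_sigma: float = 0.03

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")


@dataclass
class SimConfig:
    """Full description of a simulated acquisition; ``seed`` is mandatory."""

    species: list[SimSpecies]
    seed: int
    polarity: int = -1
    cycle_time: float = 0.02  # min between full scans; AIF interleaved
    rt_pad: float = 0.4       # grid extension beyond extreme apexes, min
    rt_range: tuple[float, float] | None = None
    # AIF yields, as fractions of the precursor envelope
    carboxylate_yield: float = 0.35
    fa_loss_yield: float = 0.03
    ketene_loss_yield: float = 0.04
    head_fragment_yield: float = 0.15
    residual_precursor_fraction: float = 0.30
    inositol_followup_factor: float = 0.5  # relative to the parent loss ion
    sn_bias: float = 1.3
    # noise model
    mz_jitter_ppm: float = 1.0
    intensity_cv: float = 0.05
    baseline_frac: float = 0.001
    nce: float = 20.0
    sid_energy: float = 40.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        ys = (
            self.carboxylate_yield,
            self.fa_loss_yield,
            self.ketene_loss_yield,
            self.head_fragment_yield,
            self.residual_precursor_fraction,
        )
        if any(not 0 <= y <= 1 for y in ys):
            raise ValueError("yields must be within [0, 1]")
        if sum(ys) > 1 + 1e-9:
            raise ValueError("fragment yields + residual fraction must not exceed 1")
        if not SN_BIAS_RANGE[0] <= self.sn_bias <= SN_BIAS_RANGE[1]:
            raise ValueError(f"sn_bias must lie in {SN_BIAS_RANGE}")


@dataclass
class GroundTruth:
    """What the generator put into a run, for parameter-recovery tests."""

    species: list[dict]                       # name, ion, mz, rt_apex, abundance
    class_fa_fractions: dict[str, dict[str, float]]   # class -> "c:d" -> %
    fragments: dict[str, list[dict]]          # species name -> fragment table

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {
                "species": self.species,
                "class_fa_fractions": self.class_fa_fractions,
                "fragments": self.fragments,
            },
            indent=1,
        ))
        return path


def _fragment_factors(cfg: SimConfig, sp: SimSpecies) -> list[tuple[float, float]]:
    """(m/z, yield factor) pairs for the AIF scan of one precursor."""
    base = {
        FragmentKind.carboxylate: cfg.carboxylate_yield,
        FragmentKind.FA_loss: cfg.fa_loss_yield,
        FragmentKind.ketene_loss: cfg.ketene_loss_yield,
        FragmentKind.inositol_loss_after_FA: cfg.fa_loss_yield * cfg.inositol_followup_factor,
        FragmentKind.inositol_loss_after_ketene: cfg.ketene_loss_yield * cfg.inositol_followup_factor,
        FragmentKind.head_fragment: cfg.head_fragment_yield,
        FragmentKind.sphingoid_fragment: cfg.head_fragment_yield,
    }
    out: list[tuple[float, float]] = []
    for frag in predict_fragments(sp.species, sp.ion):
        factor = base[frag.kind]
        if frag.sn_hint == "sn2":
            factor *= cfg.sn_bias
        if factor > 0:
            out.append((frag.mz, factor))
    out.append((ion_mz(sp.species, sp.ion), cfg.residual_precursor_fraction))
    return out


def _ground_truth(cfg: SimConfig) -> GroundTruth:
    species_rows = []
    frag_rows: dict[str, list[dict]] = {}
    class_chain_weight: dict[str, dict[str, float]] = {}
    for sp in cfg.species:
        name = format_shorthand(sp.species)
        mz = ion_mz(sp.species, sp.ion)
        species_rows.append(
            {
                "name": name,
                "ion": sp.ion.name,
                "mz": mz,
                "rt_apex": sp.rt_apex,
                "abundance": sp.abundance,
            }
        )
        frag_rows[name] = [
            {"mz": fmz, "expected_apex_intensity": sp.abundance * f}
            for fmz, f in _fragment_factors(cfg, sp)
        ]
        cls = sp.species.lipid_class.value
        chains = class_chain_weight.setdefault(cls, {})
        for c, d in sp.species.chains:
            key = f"{c}:{d}"
            chains[key] = chains.get(key, 0.0) + sp.abundance
    fractions = {
        cls: {k: 100.0 * v / sum(w.values()) for k, v in w.items()}
        for cls, w in class_chain_weight.items()
    }
    return GroundTruth(species_rows, fractions, frag_rows)


def simulate_run(config: SimConfig) -> tuple[Run, GroundTruth]:
    """Generate an alternating full/AIF run plus its ground truth.

    Full scans sit on the cycle grid, AIF scans half a cycle later.  Every
    centroid is the sum of the co-eluting theoretical contributions at that
    m/z, then jittered in m/z and perturbed in intensity.  Identical config
    and seed give identical output.
    """
    cfg = config
    if not cfg.species:
        raise ValueError("no species configured")
    rng = np.random.default_rng(cfg.seed)
    apexes = [sp.rt_apex for sp in cfg.species]
    if cfg.rt_range is not None:
        t0, t1 = cfg.rt_range
    else:
        t0 = max(0.0, min(apexes) - cfg.rt_pad)
        t1 = max(apexes) + cfg.rt_pad
    if any(not (t0 <= a <= t1) for a in apexes):
        bad = [format_shorthand(s.species) for s in cfg.species if not (t0 <= s.rt_apex <= t1)]
        raise ValueError(f"species elute outside the scan grid: {bad}")

    precursors = [(sp, ion_mz(sp.species, sp.ion)) for sp in cfg.species]
    fragments = [(sp, _fragment_factors(cfg, sp)) for sp in cfg.species]
    # additive-floor scale: fraction of the largest theoretical centroid
    max_centroid = max(sp.abundance for sp in cfg.species)
    floor_sd = cfg.baseline_frac * max_centroid

    n_cycles = int(np.floor((t1 - t0) / cfg.cycle_time)) + 1
    spectra: list[Spectrum] = []

    def envelope(sp: SimSpecies, t: float) -> float:
        z = (t - sp.rt_apex) / sp.rt_sigma
        if abs(z) > 5.0:
            return 0.0
        return float(np.exp(-0.5 * z * z))

    for k in range(n_cycles):
        t_full = t0 + k * cfg.cycle_time
        t_aif = t_full + 0.5 * cfg.cycle_time
        # full scan: precursor envelopes
        peaks: dict[float, float] = {}
        for sp, mz in precursors:
            e = envelope(sp, t_full)
            if e > 0:
                peaks[mz] = peaks.get(mz, 0.0) + sp.abundance * e
        spectra.append(_make_spectrum(t_full, "full", peaks, cfg, rng, floor_sd, None))
        # AIF scan: fragment chemistry of whatever co-elutes
        peaks = {}
        for sp, frags in fragments:
            e = envelope(sp, t_aif)
            if e > 0:
                for fmz, factor in frags:
                    peaks[fmz] = peaks.get(fmz, 0.0) + sp.abundance * e * factor
        spectra.append(_make_spectrum(t_aif, "AIF", peaks, cfg, rng, floor_sd, cfg.nce))

    run = Run(
        spectra,
        polarity=cfg.polarity,
        nce=cfg.nce,
        sid_energy=cfg.sid_energy if cfg.polarity < 0 else None,
    )
    return run, _ground_truth(cfg)


def _make_spectrum(
    rt: float,
    kind: str,
    peaks: Mapping[float, float],
    cfg: SimConfig,
    rng: np.random.Generator,
    floor_sd: float,
    ce: float | None,
) -> Spectrum:
    if not peaks:
        return Spectrum(rt, cfg.polarity, kind, np.array([]), np.array([]), collision_energy=ce)
    mz = np.array(sorted(peaks))
    inten = np.array([peaks[m] for m in sorted(peaks)])
    # noise draws depend only on the number of centroids, never their values,
    # so scaling every abundance scales every output centroid exactly
    if cfg.mz_jitter_ppm > 0:
        mz = mz * (1.0 + 1e-6 * cfg.mz_jitter_ppm * rng.standard_normal(mz.size))
    if cfg.intensity_cv > 0:
        inten = inten * (1.0 + cfg.intensity_cv * rng.standard_normal(inten.size))
    if floor_sd > 0:
        inten = inten + floor_sd * rng.standard_normal(inten.size)
    keep = inten > 0
    mz, inten = mz[keep], inten[keep]
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # collapse centroids the jitter may have collided (pathological only)
    if mz.size > 1:
        dup = np.diff(mz) <= 0
        if dup.any():
            keep_idx = np.concatenate(([True], ~dup))
            inten = np.add.reduceat(inten, np.flatnonzero(keep_idx))
            mz = mz[keep_idx]
    return Spectrum(rt, cfg.polarity, kind, mz, inten, collision_energy=ce)


# ---------------------------------------------------------------------------
# canned configurations

_STANDARD_MIX = [
    ("PG 18:0/20:4", "[M-H]-"),
    ("PE 14:0/14:0", "[M-H]-"),
    ("LPE 13:0/0:0", "[M-H]-"),
    ("PC 16:0/18:0", "[M-CH3]-"),
    ("LPC 17:0/0:0", "[M-CH3]-"),
]


def five_standard_config(seed: int = 0, abundance: float = 1.0e6) -> SimConfig:
    """The five-class standard mixture: one species per HILIC band."""
    species = []
    for name, ion in _STANDARD_MIX:
        sp = parse_shorthand(name)
        species.append(
            SimSpecies(
                species=sp,
                ion=ION_TYPES[ion],
                abundance=abundance,
                rt_apex=DEFAULT_BAND_CENTERS[sp.lipid_class],
                rt_sigma=0.05,
            )
        )
    return SimConfig(species=species, seed=seed, polarity=-1)


# Fatty-acyl composition (%) of the four most abundant plasma PL classes,
# used as generator ground truth for plasma-like simulations.  Chains absent
# from a class carry None.
PLASMA_FA_PCT: dict[str, dict[tuple[int, int], float]] = {
    "PI": {
        (16, 0): 11.7, (18, 0): 29.2, (18, 1): 9.8, (18, 2): 6.64,
        (18, 3): 0.11, (20, 2): 0.22, (20, 3): 4.16, (20, 4): 34.4,
        (22, 4): 0.34, (22, 5): 0.99, (22, 6): 2.44,
    },
    "PE": {
        (14, 0): 0.14, (16, 0): 4.79, (16, 1): 0.79, (17, 0): 0.18,
        (17, 1): 0.33, (18, 0): 4.85, (18, 1): 14.7, (18, 2): 21.7,
        (18, 3): 0.36, (20, 1): 0.20, (20, 2): 0.15, (20, 3): 4.30,
        (20, 4): 33.9, (20, 5): 1.17, (22, 3): 0.06, (22, 4): 1.89,
        (22, 5): 4.00, (22, 6): 6.53,
    },
    "PC": {
        (14, 0): 1.65, (16, 0): 19.43, (16, 1): 1.66, (17, 0): 0.44,
        (17, 1): 0.31, (18, 0): 6.07, (18, 1): 14.55, (18, 2): 29.2,
        (18, 3): 0.46, (20, 1): 0.11, (20, 2): 0.29, (20, 3): 4.56,
        (20, 4): 15.8, (20, 5): 0.58, (22, 3): 0.01, (22, 4): 0.48,
        (22, 5): 1.25, (22, 6): 3.12,
    },
    "LPC": {
        (14, 0): 0.27, (16, 0): 40.0, (16, 1): 0.71, (17, 0): 1.21,
        (17, 1): 0.21, (18, 0): 26.51, (18, 1): 16.55, (18, 2): 12.1,
        (18, 3): 0.11, (20, 1): 0.22, (20, 2): 0.21, (20, 3): 1.14,
        (20, 4): 0.77,
    },
}

# within-band retention offsets: longer chains elute earlier, unsaturation
# delays slightly; centred on the class abundance-weighted mean composition
RT_OFFSET_PER_CARBON = 0.010   # min per carbon below the class mean
RT_OFFSET_PER_DB = 0.004       # min per double bond above the class mean


def _band_offset(total_c: float, total_d: float, ref_c: float, ref_d: float) -> float:
    return RT_OFFSET_PER_CARBON * (ref_c - total_c) + RT_OFFSET_PER_DB * (total_d - ref_d)


def plasma_like_config(
    seed: int = 0,
    class_abundance: float = 1.0e6,
    rt_sigma: float = 0.03,
) -> SimConfig:
    """A plasma-like negative-mode run over the PI/PE/PC/LPC classes.

    Each class's fatty-acyl ground truth equals its plasma composition
    table by construction: diacyl classes get one symmetric c:d/c:d species
    per chain (so the sn-2 bias cancels out of class totals), LPC one lyso
    species per chain, with abundance proportional to the chain percentage.
    """
    species: list[SimSpecies] = []
    for cls_name, table in PLASMA_FA_PCT.items():
        cls = LipidClass(cls_name)
        total = sum(table.values())
        band = DEFAULT_BAND_CENTERS[cls]
        diacyl = cls not in (LipidClass.LPC, LipidClass.LPE)
        mult = 2 if diacyl else 1
        ref_c = sum((c * mult) * p for (c, d), p in table.items()) / total
        ref_d = sum((d * mult) * p for (c, d), p in table.items()) / total
        ion = ION_TYPES["[M-CH3]-"] if cls in (LipidClass.PC, LipidClass.LPC) else ION_TYPES["[M-H]-"]
        for (c, d), pct in table.items():
            if diacyl:
                sp = LipidSpecies(cls, ((c, d), (c, d)), sn_known=True)
            else:
                sp = LipidSpecies(cls, ((c, d),), sn_known=True)
            rt = band + _band_offset(c * mult, d * mult, ref_c, ref_d)
            species.append(
                SimSpecies(
                    species=sp,
                    ion=ion,
                    abundance=class_abundance * pct / total,
                    rt_apex=rt,
                    rt_sigma=rt_sigma,
                )
            )
    return SimConfig(species=species, seed=seed, polarity=-1)


def pd_comparison_configs(
    seed: int = 0, abundance: float = 1.0e6
) -> tuple[SimConfig, SimConfig]:
    """Control vs Parkinson-like fibroblast pair for the C20:3/C20:4 ratio.

    Both runs carry PI 18:0/20:3 and PI 18:0/20:4; the disease-like run
    drops the relative share of the C20:3-bearing species from 75% to 20%.
    """
    def build(frac_203: float, seed_: int) -> SimConfig:
        rt = DEFAULT_BAND_CENTERS[LipidClass.PI]
        sp203 = parse_shorthand("PI 18:0/20:3")
        sp204 = parse_shorthand("PI 18:0/20:4")
        species = [
            SimSpecies(sp203, ION_TYPES["[M-H]-"], abundance * frac_203, rt, 0.04),
            SimSpecies(sp204, ION_TYPES["[M-H]-"], abundance * (1 - frac_203), rt + 0.01, 0.04),
        ]
        return SimConfig(species=species, seed=seed_, polarity=-1)

    return build(0.75, seed), build(0.20, seed + 1)
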