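"""Band location, annotation, FA profiling, alignment and filtering."""

import numpy as np
import pytest

from aiflipid.annotate import (
    ClassBand,
    SpeciesAnnotation,
    align_precursor_product,
    annotate_species,
    band_slices,
    combine_profiles,
    fa_profile,
    locate_class_bands,
    ratio_trace,
    replicate_filter,
)
from aiflipid.chromatography import (
    average_spectrum,
    detect_peaks,
    extract_xic,
    spectrum_intensity_at,
)
from aiflipid.lipids import (
    ION_TYPES,
    LipidClass,
    carboxylate_mz,
    ion_mz,
    parse_shorthand,
)
from aiflipid.simulate import (
    DEFAULT_BAND_CENTERS,
    SimConfig,
    SimSpecies,
    pd_comparison_configs,
    simulate_run,
)
from conftest import PLASMA_CLASSES


# --------------------------------------------------------------------- bands

def test_pe_and_lpe_bands_from_ethanolamine_diagnostic(standard_run):
    run, _ = standard_run
    bands = locate_class_bands(
        run, expected_classes=[LipidClass.PE, LipidClass.LPE, LipidClass.PC, LipidClass.LPC]
    )
    pe = [b for b in bands if b.classes == (LipidClass.PE,)]
    lpe = [b for b in bands if b.classes == (LipidClass.LPE,)]
    assert len(pe) == 1 and len(lpe) == 1
    assert pe[0].apex_rt == pytest.approx(10.2, abs=0.1)
    assert lpe[0].apex_rt == pytest.approx(14.0, abs=0.1)


def test_no_pi_species_means_no_pi_band(standard_run):
    run, _ = standard_run
    bands = locate_class_bands(run)
    assert not any(LipidClass.PI in b.classes for b in bands)


def test_missing_class_warns_mass_only(standard_run):
    run, _ = standard_run
    with pytest.warns(UserWarning, match="PG"):
        locate_class_bands(run, expected_classes=[LipidClass.PG, LipidClass.PE])


def test_two_choline_bands_are_ordered_pc_then_sm():
    species = [
        SimSpecies(parse_shorthand("PC 16:0/18:0"), ION_TYPES["[M+H]+"], 1e6,
                   DEFAULT_BAND_CENTERS[LipidClass.PC], 0.05),
        SimSpecies(parse_shorthand("SM d18:1/16:0"), ION_TYPES["[M+H]+"], 1e6,
                   DEFAULT_BAND_CENTERS[LipidClass.SM], 0.05),
    ]
    run, _ = simulate_run(SimConfig(species=species, seed=21, polarity=+1))
    bands = locate_class_bands(run, expected_classes=[LipidClass.PC, LipidClass.SM])
    choline = [b for b in bands if set(b.classes) & {LipidClass.PC, LipidClass.SM}]
    assert [b.classes for b in choline] == [(LipidClass.PC,), (LipidClass.SM,)]
    assert choline[0].apex_rt < choline[1].apex_rt


def test_elution_order_of_default_simulator(standard_run):
    run, gt = standard_run
    apex = {}
    for row in gt.species:
        trace = extract_xic(run, row["mz"], 5.0, "full")
        apex[row["name"].split()[0]] = max(
            detect_peaks(trace), key=lambda p: p.height
        ).apex_rt
    assert apex["PG"] < apex["PE"] < apex["LPE"] < apex["PC"] <= apex["LPC"]


# ---------------------------------------------------------------- annotation

def test_full_recall_zero_false_positives_on_clean_run(plasma_run_clean, candidates):
    run, gt = plasma_run_clean
    bands = locate_class_bands(run, expected_classes=PLASMA_CLASSES)
    anns = annotate_species(run, bands, candidates)
    truth = {(r["name"].split()[0], round(r["mz"], 4)) for r in gt.species}
    got = {(a.species.lipid_class.value, round(a.theoretical_mz, 4)) for a in anns}
    assert got == truth
    assert max(abs(a.mass_error) for a in anns) < 1e-9


def test_annotation_mass_error_within_tolerance(plasma_run, candidates):
    run, _ = plasma_run
    bands = locate_class_bands(run, expected_classes=PLASMA_CLASSES)
    anns = annotate_species(run, bands, candidates)
    assert anns
    assert max(abs(a.mass_error) for a in anns) <= 0.005
    for a in anns:
        assert a.band.rt_window[0] <= a.apex_rt <= a.band.rt_window[1]


def test_candidate_without_band_confined_peak_is_excluded(plasma_run, candidates):
    run, gt = plasma_run
    # restrict to the PI band only: LPC candidates must not be annotated there
    bands = [
        b
        for b in locate_class_bands(run, expected_classes=PLASMA_CLASSES)
        if b.classes == (LipidClass.PI,)
    ]
    anns = annotate_species(run, bands, candidates)
    assert anns
    assert {a.species.lipid_class for a in anns} == {LipidClass.PI}


def test_isobaric_ether_species_resolved_by_band():
    """PC O-38:6 and PE O-41:6 protonated ions share one formula; HILIC
    band separation assigns each to its own class without cross-talk."""
    pc = parse_shorthand("PC O-38:6")
    pe = parse_shorthand("PE O-41:6")
    ion = ION_TYPES["[M+H]+"]
    assert ion_mz(pc, ion) == pytest.approx(ion_mz(pe, ion), abs=1e-9)
    species = [
        SimSpecies(pe, ion, 8e5, DEFAULT_BAND_CENTERS[LipidClass.PE], 0.05),
        SimSpecies(pc, ion, 1e6, DEFAULT_BAND_CENTERS[LipidClass.PC], 0.05),
    ]
    run, _ = simulate_run(SimConfig(species=species, seed=22, polarity=+1))
    bands = [
        ClassBand((LipidClass.PE,), +1, (10.0, 10.4)),
        ClassBand((LipidClass.PC,), +1, (15.1, 15.5)),
    ]
    cands = [(pe, ion, ion_mz(pe, ion)), (pc, ion, ion_mz(pc, ion))]
    anns = annotate_species(run, bands, cands)
    assert len(anns) == 2
    by_class = {a.species.lipid_class: a for a in anns}
    assert by_class[LipidClass.PE].band.classes == (LipidClass.PE,)
    assert by_class[LipidClass.PC].band.classes == (LipidClass.PC,)


# ---------------------------------------------------------------- FA profile

def test_fa_profiles_normalise_to_100(plasma_run):
    run, _ = plasma_run
    bands = locate_class_bands(run, expected_classes=PLASMA_CLASSES)
    for band in bands:
        prof = fa_profile(run, band)
        assert prof.total_pct() == pytest.approx(100.0, abs=0.1)


def test_lpc_profile_recovers_generator_fractions(plasma_run):
    run, gt = plasma_run
    bands = locate_class_bands(run, expected_classes=PLASMA_CLASSES)
    lpc = next(b for b in bands if b.classes == (LipidClass.LPC,))
    prof = fa_profile(run, lpc)
    for key, truth_pct in gt.class_fa_fractions["LPC"].items():
        c, d = map(int, key.split(":"))
        est = prof.pct((c, d)) if any(r["chain"] == (c, d) for r in prof.rows) else 0.0
        assert est == pytest.approx(truth_pct, abs=2.0)


def test_area_mode_profile_agrees_with_spectrum_mode(plasma_run):
    run, _ = plasma_run
    bands = locate_class_bands(run, expected_classes=PLASMA_CLASSES)
    lpc = next(b for b in bands if b.classes == (LipidClass.LPC,))
    spec_prof = fa_profile(run, lpc, mode="spectrum")
    area_prof = fa_profile(run, lpc, mode="area")
    assert area_prof.pct((16, 0)) == pytest.approx(spec_prof.pct((16, 0)), abs=3.0)


def test_empty_band_profile_warns():
    run, _ = simulate_run(
        SimConfig(
            species=[
                SimSpecies(parse_shorthand("PC 16:0/18:0"), ION_TYPES["[M-CH3]-"],
                           1e6, 15.3, 0.05)
            ],
            seed=23,
        )
    )
    far_band = ClassBand((LipidClass.PI,), -1, (14.92, 15.02))  # outside the band
    with pytest.warns(UserWarning, match="empty profile"):
        prof = fa_profile(run, far_band)
    assert prof.rows == []


def test_combine_profiles_mean_sd_and_renormalisation(plasma_run, plasma_run_clean):
    run_a, _ = plasma_run
    run_b, _ = plasma_run_clean
    profs = []
    for run in (run_a, run_b):
        bands = locate_class_bands(run, expected_classes=PLASMA_CLASSES)
        lpc = next(b for b in bands if b.classes == (LipidClass.LPC,))
        profs.append(fa_profile(run, lpc))
    combined = combine_profiles(profs)
    assert combined.total_pct() == pytest.approx(100.0, abs=0.1)
    row = next(r for r in combined.rows if r["chain"] == (16, 0))
    assert row["sd_pct"] is not None and row["sd_pct"] >= 0


# --------------------------------------------------------------- band slices

def test_band_slices_show_long_chain_gradient():
    """Species with longer chains elute on the early side of the band, so
    the C22:6 carboxylate appears in the first slice and vanishes by the last."""
    ion = ION_TYPES["[M-CH3]-"]
    species = [
        SimSpecies(parse_shorthand("PC 22:6/22:6"), ion, 1e6, 15.25, 0.02),
        SimSpecies(parse_shorthand("PC 16:0/16:0"), ion, 1e6, 15.35, 0.02),
    ]
    cfg = SimConfig(species=species, seed=24, mz_jitter_ppm=0, intensity_cv=0,
                    baseline_frac=0)
    run, _ = simulate_run(cfg)
    band = ClassBand((LipidClass.PC,), -1, (15.20, 15.40))
    slices = band_slices(run, band, 4)
    assert len(slices) == 4
    c226 = carboxylate_mz(22, 6)
    first = spectrum_intensity_at(slices[0][1], c226)
    last = spectrum_intensity_at(slices[3][1], c226)
    assert first > 0
    assert last < 0.01 * first


def test_single_slice_equals_band_average(plasma_run):
    run, _ = plasma_run
    bands = locate_class_bands(run, expected_classes=PLASMA_CLASSES)
    band = bands[0]
    ((window, sliced),) = band_slices(run, band, 1)
    avg = average_spectrum(run, band.rt_window, "AIF")
    assert np.allclose(sliced.mz, avg.mz)
    assert np.allclose(sliced.intensity, avg.intensity)


def test_band_slices_validation(plasma_run):
    run, _ = plasma_run
    band = ClassBand((LipidClass.PC,), -1, (15.2, 15.4))
    with pytest.raises(ValueError):
        band_slices(run, band, 0)
    with pytest.raises(ValueError, match="slices"):
        band_slices(run, band, 10_000)


# ---------------------------------------------------------------- alignment

@pytest.fixture(scope="module")
def shared_chain_run():
    """PC 16:0/22:6 and PC 18:0/22:6 co-eluting: one product, two precursors."""
    ion = ION_TYPES["[M-CH3]-"]
    sp1 = parse_shorthand("PC 16:0/22:6")
    sp2 = parse_shorthand("PC 18:0/22:6")
    species = [
        SimSpecies(sp1, ion, 1e6, 15.20, 0.03),
        SimSpecies(sp2, ion, 8e5, 15.30, 0.03),
    ]
    run, _ = simulate_run(SimConfig(species=species, seed=25))
    band = ClassBand((LipidClass.PC,), -1, (15.1, 15.5))
    cands = [(sp1, ion, ion_mz(sp1, ion)), (sp2, ion, ion_mz(sp2, ion))]
    anns = annotate_species(run, [band], cands)
    return run, anns


def test_shared_product_links_to_both_precursors(shared_chain_run):
    run, anns = shared_chain_run
    assert len(anns) == 2
    links = align_precursor_product(run, carboxylate_mz(22, 6), anns)
    assert len(links) >= 2
    assert {l.precursor.name for l in links} == {"PC 16:0/22:6", "PC 18:0/22:6"}
    assert all(l.shape_correlation >= 0.8 for l in links)
    assert all(l.rt_delta <= 0.1 for l in links)
    # ranked by correlation
    corrs = [l.shape_correlation for l in links]
    assert corrs == sorted(corrs, reverse=True)


def test_rt_offset_beyond_tolerance_breaks_the_link(shared_chain_run):
    run, anns = shared_chain_run
    decoys = [
        SpeciesAnnotation(
            species=a.species, ion=a.ion, theoretical_mz=a.theoretical_mz,
            observed_mz=a.observed_mz, apex_rt=a.apex_rt + 1.0, area=a.area,
            band=a.band,
        )
        for a in anns
    ]
    assert align_precursor_product(run, carboxylate_mz(22, 6), decoys) == []


def test_product_without_precursor_gives_no_links(shared_chain_run):
    run, anns = shared_chain_run
    # a product m/z nothing in the run produces
    assert align_precursor_product(run, 401.123, anns) == []


# -------------------------------------------------------------- ratio trace

def test_ratio_of_identical_traces_is_one(plasma_run):
    run, _ = plasma_run
    mz = carboxylate_mz(18, 1)
    trace = ratio_trace(run, mz, mz)
    defined = trace.intensity[~np.isnan(trace.intensity)]
    assert defined.size > 0
    assert np.allclose(defined, 1.0)


def test_zero_denominator_gives_gaps_not_zeros(plasma_run):
    run, _ = plasma_run
    trace = ratio_trace(run, carboxylate_mz(18, 1), 399.999)
    assert np.all(np.isnan(trace.intensity))


def test_pd_run_shows_lower_c20_3_ratio_at_pi_band():
    ctrl_cfg, pd_cfg = pd_comparison_configs(seed=26)
    ctrl, _ = simulate_run(ctrl_cfg)
    pd, _ = simulate_run(pd_cfg)
    num, den = carboxylate_mz(20, 3), carboxylate_mz(20, 4)
    def band_ratio(run):
        trace = ratio_trace(run, num, den)
        sel = (np.abs(trace.rt - DEFAULT_BAND_CENTERS[LipidClass.PI]) < 0.1)
        vals = trace.intensity[sel]
        return np.nanmean(vals)
    assert band_ratio(pd) < band_ratio(ctrl)


# --------------------------------------------------------- replicate filter

def _ann(name, area, band):
    sp = parse_shorthand(name)
    ion = ION_TYPES["[M-CH3]-"] if sp.info.choline else ION_TYPES["[M-H]-"]
    return SpeciesAnnotation(
        species=sp, ion=ion, theoretical_mz=ion_mz(sp, ion),
        observed_mz=ion_mz(sp, ion), apex_rt=band.rt_window[0] + 0.05,
        area=area, band=band,
    )


def test_replicate_filter_oracle_cases():
    band = ClassBand((LipidClass.PC,), -1, (15.2, 15.4))
    reps = [
        [_ann("PC 34:0", 100, band), _ann("PC 36:2", 100, band), _ann("PC 38:4", 50, band)],
        [_ann("PC 34:0", 110, band), _ann("PC 36:2", 160, band)],
        [_ann("PC 34:0", 90, band), _ann("PC 36:2", 40, band)],
    ]
    out = replicate_filter(reps, max_rsd_pct=20.0)
    # (100, 110, 90): RSD 10% -> kept; (100, 160, 40): RSD 60% -> dropped;
    # PC 38:4 missing in two replicates -> dropped
    assert out["species"].tolist() == ["PC 34:0"]
    assert out["rsd_pct"].iloc[0] == pytest.approx(10.0)
    assert out["class_pct"].iloc[0] == pytest.approx(100.0)


def test_replicate_filter_class_percentages_sum_to_100():
    band_pc = ClassBand((LipidClass.PC,), -1, (15.2, 15.4))
    band_pe = ClassBand((LipidClass.PE,), -1, (10.1, 10.3))
    reps = [
        [_ann("PC 34:0", 100, band_pc), _ann("PC 36:2", 300, band_pc),
         _ann("PE 34:1", 200, band_pe)],
        [_ann("PC 34:0", 105, band_pc), _ann("PC 36:2", 290, band_pc),
         _ann("PE 34:1", 210, band_pe)],
    ]
    out = replicate_filter(reps)
    sums = out.groupby("lipid_class")["class_pct"].sum()
    assert np.allclose(sums.values, 100.0)


def test_replicate_filter_needs_two_sets():
    with pytest.raises(ValueError):
        replicate_filter([[]])
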