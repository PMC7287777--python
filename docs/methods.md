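# Methods

## Exact-mass chemistry

All m/z values are computed from embedded monoisotopic atomic masses
(C 12 exact, H 1.00782503, N 14.00307400, O 15.99491462, P 30.97376163,
Na 22.98976928) with an electron-mass correction of 0.00054858 Da per
charge. Neutral species formulas are built constructively:

* glycerophospholipid = class core + one condensed acyl residue per chain,
  where the core is the glycero-phospho-X backbone (GPA C3H9O6P, GPC
  C8H20NO6P, GPE C5H14NO6P, GPG C6H15O8P, GPI C9H19O11P, GPS C6H14NO8P)
  and a condensed acyl residue is the fatty acid CcH(2c−2d)O2 minus H2O;
* an ether (O-) species swaps one ester linkage for an alkyl/alkenyl one:
  net −O +2H relative to the diacyl formula;
* sphingolipids: ceramide = dihydroxy base CcH(2c+3−2d)NO2 + FA − H2O;
  SM adds phosphocholine C5H14NO4P − H2O; cerebrosides add n anhydro-
  hexoses C6H10O5. A sum-composition sphingolipid assumes a d18:1 base.

Ion deltas are likewise derived from formulas (e.g. [M−CH3]⁻ = loss of a
methyl radical plus an electron, −15.02293 Da), never typed in as numbers.
[M−CH3]⁻ is restricted to choline-bearing classes (PC, LPC, SM), where it
arises from in-source dissociation of the formate/acetate adduct.

Sum compositions (e.g. `PC 34:0`) map directly to a formula from the class
total carbons/double bonds without enumerating chain splits; chain-level
resolution belongs to annotation and fragment evidence.

## Fragmentation rules

Negative-mode diacyl phospholipid anions yield, per chain: the carboxylate
[R-COO]⁻, the FA neutral loss and the ketene neutral loss (FA − H2O); PI
ions additionally lose dehydrated inositol (162.0528 Da) from either loss
ion. Positive-mode ions yield class head fragments; sphingolipids yield
the doubly dehydrated sphingoid-base cation (264.2686 for d18:1 — stored
as computed, which agrees with the usually quoted 264.269/264.270 within
the matching tolerance — plus the 236.237 d16:1 and 262.253 d18:2
variants as independent traces). PG/PS/PA have no negative-mode
diagnostic ion and are handled mass-only (precursor accurate mass +
retention band; bands suppliable manually).

The sn-position heuristic: signals for losses of the sn-1 chain are weaker
than for the sn-2 chain; carboxylate intensities show an sn-2/sn-1 bias of
1.1–1.5 (default 1.3 everywhere in this package). The assignment rule puts
the chain with the lower combined FA+ketene loss intensity at sn-1, ties
as unknown, lyso chains at sn-1 by convention.

## mzML encoding of AIF scans

There is no single community convention for writing DIA scans, so the
writer encodes an AIF scan as an MS-level-2 spectrum whose precursor
isolation window spans the whole acquired m/z range (no precursor
selection) with a beam-type CID activation and collision-energy term; the
reader accepts any MS2 scan whose isolation window is at least 100 m/z
wide (configurable), or whose vendor filter string matches a configurable
pattern. Retention times are minutes everywhere. Binary arrays are
zlib-compressed little-endian, 64-bit m/z and 32-bit intensity, in an
indexed mzML wrapper. Reading and writing are self-contained (lxml),
keyed on PSI-MS controlled-vocabulary accessions.

## Chromatographic machinery

* XIC: per scan of the requested kind, the summed centroid intensity
  within ± tol_ppm (default 5 ppm) of the target; one point per scan.
  The accurate-mass *annotation* tolerance is a separate knob, 0.005 m/z.
* Peak detection: local maxima above min_snr × noise, where noise is
  1.4826 × MAD of the lower-intensity half of the trace; bounds extend to
  the nearest valley or noise crossing (overlapping peaks split at the
  valley — no model fitting, since band-slice analyses use manual windows
  anyway); areas are trapezoidal. On an all-zero or noise-free trace the
  MAD collapses to zero and any positive local maximum qualifies.
* Spectral averaging under an RT window clusters centroids within
  ±0.003 m/z; cluster intensity is the mean over member scans (absence
  counts as zero), cluster m/z the intensity-weighted mean.

## Band location and annotation

Each diagnostic ion's AIF trace is peak-picked; peaks below 5% of the
trace's largest peak are treated as edge spurs, adjacent peaks whose
bounds touch within 0.05 min are fused (a class band is a train of
species peaks). When a diagnostic shared by several classes produces as
many bands as candidate classes, classes are assigned to bands in HILIC
head-group elution order (PG < PI < PE < LPE < PC < SM < LPC); otherwise
the ambiguity is preserved on each band. Expected classes with no
diagnostic band trigger a mass-only warning.

Annotation matches the full-scan spectrum averaged under a band against a
combinatorial sum-composition candidate list (both even and odd total
carbons) within 0.005 m/z; every match must be backed by a full-scan XIC
peak apexing inside the band. Multiple candidates hitting one observed
centroid are all reported, flagged ambiguous — there is no database
frequency to rank by.

FA profiles read the band-averaged AIF spectrum at each carboxylate mass
(default chain universe: the 18 chains commonly profiled in plasma) and
normalise over detected chains to 100%. An XIC-peak-area mode exists as an
option because replicate statistics are naturally area-based; the
spectrum mode is the default. No sn-bias correction is applied to
reported percentages (an optional divide-by-bias would assume known
regiochemistry); the bias is instead documented and read back in tests.

Precursor-product alignment links an AIF product peak to any annotation
whose full-scan apex lies within rt_tol = 0.1 min and whose trace
correlates (Pearson, precursor trace interpolated onto the product's RT
grid over the peak bounds) at ≥ 0.8; both defaults chosen to accept clean
co-elution while rejecting minute-scale decoys, and both configurable.
Ratio traces emit NaN gaps wherever the denominator stays within its
noise floor.

The replicate filter keeps species present in every replicate with area
RSD ≤ 20% (sample standard deviation over mean), then normalises mean
areas within each lipid class to percentages.

## Simulator

The generator emulates the alternating full/AIF cycle (default 0.02 min,
AIF half a cycle after the full scan — the approximate q-orbitrap
alternation cadence). Species elute as Gaussians (default σ 0.03–0.05
min) centred on their class band; within a band, retention shifts by
+0.010 min per carbon *below* and +0.004 min per double bond *above* the
class's abundance-weighted mean composition, implementing the qualitative
rule that longer chains elute earlier and unsaturation delays slightly.
These offsets are centred per class so lyso classes keep their nominal
band time; they claim no quantitative retention model.

AIF yields (fractions of the precursor envelope) default to: carboxylate
0.35 per chain (sn-2 chain multiplied by the 1.3 bias), FA loss 0.03,
ketene loss 0.04, inositol follow-ups at half their parent loss ion,
head fragments 0.15, residual precursor 0.30. The magnitudes are free
parameters — the qualitative facts they encode are that carboxylates
dominate AIF spectra of phospholipid bands while neutral-loss ions are
minor. Noise: per-centroid multiplicative Gaussian (CV 5%), plus an
additive Gaussian floor with σ = 0.1% of the run's largest theoretical
centroid, plus 1 ppm m/z jitter. Noise draws depend only on centroid
counts, so scaling all abundances scales every output centroid exactly;
a fixed seed reproduces a run bit for bit.

`plasma_like_config` turns a per-class acyl-chain percentage table into
species: diacyl classes get one *symmetric* c:d/c:d species per chain and
LPC one lyso species per chain, abundance proportional to the percentage.
With symmetric chains the sn-2 bias cancels from class totals, so the
generator's class FA fractions equal the table exactly — which is the
point: the table is the recoverable ground truth. The cost is that the
simulated precursors are not the naturally occurring mixed-chain species;
annotation still exercises realistic masses, bands and interferences.
`pd_comparison_configs` builds a control/disease pair in which the
C20:3-bearing PI species falls from 75% to 20% of the class.

What the simulator does *not* emulate — and hence what passing tests do
not demonstrate about real data: isotope envelopes, ion suppression and
matrix effects, chimeric background chemistry, retention drift between
runs, profile-mode peak shapes, and in-source fragmentation beyond the
choline [M−CH3]⁻ convention.

## Problem sizes and numerical notes

The test suite and the acceptance script run simulations of roughly
500–550 full/AIF cycles (about 1000 spectra, 60 species, ~10-minute
simulated gradients) — large enough that band location, averaging and
alignment operate in their intended regime, and small enough to iterate
quickly. A species whose apex intensity lies below the additive noise
floor (e.g. a 0.01%-of-class species against a 0.1%-of-base floor) is
below the detection limit the noise model defines; its recovery is
seed-dependent and is not asserted at default noise (it is at zero
noise). Degenerate inputs fail loudly: empty runs, mixed polarity,
unsorted centroids, RT windows containing no scans, slice counts
exceeding scan counts, chains violating the double-bond bound.
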