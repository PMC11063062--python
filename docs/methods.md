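# Methods

This note documents the models, parameter choices and numerical decisions
behind ms2deconv, and what the synthetic fixtures do and do not establish
about real data.

## Spectra and units

A spectrum is a centroided peak list with precursor metadata. Fragment m/z
is stored in double precision (Th); ppm deviations are computed as
1e6·Δm/z ÷ reference m/z. Retention time is seconds internally; MSP
`RETENTIONTIME` fields (the MS-DIAL dialect) are treated as minutes and
converted on read, MGF `RTINSECONDS` as seconds. Centroids closer than
1e-4 Th within one spectrum are merged by intensity sum on construction
(split-centroid artifacts). Intensity normalization sets the base peak to
100; all similarity metrics are scale-invariant, so this choice only fixes
the reporting convention.

## Chimera assessment

An MS2 scan is assigned to a feature when its precursor m/z and RT fall in
the feature's ranges (explicit ranges, else mz_med ± ppm_tol and rt_med ±
rt_tol; defaults 10 ppm, 15 s — typical Orbitrap/QTOF tolerances). Multiple
scans per feature are merged MZmine-style: fragments grouped at mz_tol
(default 0.01 Th), group m/z the intensity-weighted mean, group intensity
the sum. The single MS1 scan nearest in RT (ties to the earlier scan)
decides chimerism: more than one in-window centroid above the acquisition
threshold (default absolute 1e4 counts; a relative mode is available
because vendor thresholds differ) makes the spectrum chimeric. Isolation
bounds come from an explicit override, then the scan's recorded metadata,
then a ±0.75 Th fallback (a common DDA quadrupole default). Centroids
within 1e-3 Th of the main ion are treated as the same peak (instrument
merge artifact).

## Candidate spectra

Candidates resolve in class order I → II → III → IV; an ion gets exactly
one candidate or is dropped from the regression with a warning.

- **Class I (orphan isotopologue).** A contaminant is an isotope peak when
  a centroid sits n·1.003355/z below it (n ∈ {1, 2}, z ≤ charge_max,
  default 2) with at least its intensity. The parent's MS2 spectrum is
  split per fragment into unshifted and shifted peaks; the shifted fraction
  is the probability the heavy isotope is retained in the fragment,
  approximated by the fragment/precursor carbon-count ratio when formulas
  are available and by the m/z ratio otherwise. This is an approximation in
  the spirit of isotope-aware deconvolution tools; the exact per-fragment
  weighting used elsewhere in the literature is not reproduced.
- **Class II (in-data clean spectrum).** The two precursor-matching MS2
  scans nearest in RT are assessed; the nearer clean one wins. An RT cap of
  2·rt_tol keeps the borrowed spectrum within the chromatographic
  neighborhood — whether the original method bounds this is unstated, and
  an uncapped search would happily borrow spectra from unrelated peaks.
- **Class III (library).** Among precursor-matching records, the spectrum
  most similar to Spectrum 0 (dot product by default); ties break to the
  lower record_id for reproducibility.
- **Class IV (transformation-network prediction).** The ion's formula is
  predicted by bounded CHNOPS enumeration (defaults C≤40, H≤80, N≤10,
  O≤20, P≤5, S≤5; RDBE ≥ 0; element-ratio plausibility; ranked by |Δppm|).
  A one-hop network of common transformation deltas (±H2, ±CH2, ±O, ±H2O,
  ±NH3, ±CO, ±CO2, ±C2H2O, ±SO3, ±C6H8O6, ±C2H4, ±HPO3; editable TSV
  resource) supplies neighbor formulas; their library spectra are cleaned
  of fragments whose composition cannot fit inside the predicted formula
  (element-wise sub-multiset test) and the most similar cleaned spectrum
  wins. The penalty is the linear map 10·(1 − similarity), interpolating
  the stated endpoints (0 = perfect match, 10 = negative match).

## Elastic-net deconvolution

The design matrix aligns Spectrum 0 and all candidates on the merged m/z
axis (union of fragments grouped at mz_tol); columns are scaled to unit
Euclidean norm with the norms retained so coefficients can be reported on
the original intensity scale. The MAIN column is the main ion's best
library spectrum when one exists, else Spectrum 0 itself — this guarantees
the column exists and makes the no-contamination case exact.

Coefficients are constrained non-negative: spectra are physical mixtures,
and negative mixture weights have no interpretation. The solver is cyclic
coordinate descent with closed-form non-negative soft-threshold updates;
convergence when the largest per-sweep coefficient change drops below 1e-6,
capped at 10⁴ sweeps (non-convergence flags the solution rather than
raising). Per-column penalty factors are 1 for MAIN and classes I–III and
(1 + penalty) for class IV, injecting the prediction penalty as coefficient-
specific shrinkage — the "10 times penalty" reading.

The grid evaluates 11 α values (0, 0.1, …, 1) × 10 λ values log-spaced
over three decades down from λ_max = max_j |x_jᵀy|/n (the largest
column–response correlation, the value at which every coefficient of the
pure-LASSO problem is zero). Grid selection uses the **unpenalized RSS**:
penalized objectives at different λ are not commensurable, so comparing
them across the grid would systematically favor small λ for the wrong
reason. Ties prefer larger λ, then larger α (the sparser model). Warm
starts carry along each λ path; solutions are deterministic, so identical
inputs give bit-identical results.

Subtraction removes Σ_contaminants β_c·x_c per bin, clips at zero, drops
bins below 0.5% of the surviving base peak, and normalizes. The
deconvolution fails — returning Spectrum 0 unchanged, flagged — when the
MAIN coefficient is zero or no fragment survives.

## SWATH-DIA reconstruction

A feature's precursor maps to exactly one SWATH window (overlapping windows
resolve to the nearest center). Fragment EICs are binned at mz_tol over the
feature's RT range padded by roughly one peak width. Peak detection uses
Savitzky–Golay smoothing (window 7, order 2) and scipy's prominence-based
peak finder with prominence ≥ max(3× the MAD-estimated noise, 2% of the
trace maximum) — the original detector is not published, so a standard
robust rule is used. Peaks cluster greedily from the most intense seed:
members must agree in apex within rt_tol (default 5 s) and correlate in
shape (Pearson ≥ 0.8 inside the seed's peak bounds). The model peak is the
cluster's most intense member. Every EIC is then decomposed over the
model-peak traces by non-negative least squares on a common RT grid, and
the cluster whose apex is nearest the feature's rt_med is exported:
fragment intensity = decomposition weight × model-peak apex intensity
(apex rather than area; area is an easy switch), zero-weight fragments
omitted, result normalized.

## Replicate consensus

Fragments are grouped across replicates at mz_tol. A group is kept when its
replicate frequency reaches the threshold (≥, so 1/2 replicates passes a
50% threshold), or — with database assistance — when it occurs in at least
two replicates *and* matches a fragment of any library spectrum of the
precursor. The count-≥-2 reading resolves an ambiguity between "over 2"
and "detected only once … excluded" in the method's description; exclusion
of singletons is the consistent interpretation. Kept groups take the
intensity-weighted mean m/z and the arithmetic mean of the contributing
replicates' normalized intensities. A single input spectrum passes through
(the step is skipped without replicates).

## Scoring and search

Dot-product similarity is the cosine of square-root-transformed aligned
intensity vectors (the square root tempers base-peak dominance; a
plain-intensity mode exists). Spectral-entropy similarity is
1 − (2·S_merged − S_a − S_b)/ln 4 on probability-normalized vectors,
clipped to [0, 1]. MS1 and RT agreement use exp(−|Δ|/tol). Isotope
agreement is max(0, 1 − Σ|obs − theo| / Σ theo) over M+1 and M+2 only
(M+3 and beyond are too weak and variable to help); theoretical patterns
come from truncated polynomial expansion of per-element isotope abundances
(NIST values via pyteomics), cross-checked against a brute-force
convolution oracle in the tests. A missing observed pattern scores 0 by
default (conservative); an optional mode drops the term and renormalizes
the denominator. The composite score is (MS2 + MS1 + RT + 0.5·Iso)/3.5·100
with RT, (MS2 + MS1 + 0.5·Iso)/2.5·100 without; RT matching is off by
default since library retention times are rarely populated. Ranking ties
break to the lower record_id everywhere. Export collapses records with the
same InChIKey to the highest-scoring one and keeps the top N per query.

Neutral-loss fallback (triggered below score 10, or forced): the query
precursor's predicted formula seeds a one-hop transformation network; the
neighbors' records in the pre-computed neutral-loss library are scored
against the query's neutral-loss mirror, with MS1 agreement measured
against the transformation-shifted precursor.

## Decoys and null evaluation

Decoy runs shift every MS1 centroid by a uniformly drawn 10–30 ppm error
with random sign (symmetric, avoiding systematic bias), multiply every
intensity by a coefficient uniform in [0.01, 50.0], and leave RT untouched.
DDA MS2 spectra are replaced by the spectrum of an isobaric library
compound (different InChIKey when the original identity is supplied) with
fragment intensities jittered ×[0.5, 2] and renormalized; scans without an
isobaric partner are perturbed like MS1 with a log note. DIA MS2 spectra
are perturbed like MS1 with window and RT preserved. The default set size
is 18 decoys per replicate, seeds base_seed + k. Null evaluation takes each
decoy query's top hit; a hit equal to the original identity is a false
positive, with per-run, pooled, and per-score-bin rates reported.

## Synthetic fixtures

The generators emulate: reference libraries of random CHNO compounds with
consistent [M+H]+ masses and reproducible fragment sets (optionally with
near-isobaric chimera partners — a CH4-for-O swap, +0.0364 Da, co-isolated
by any realistic window yet resolved as a separate centroid — and isomeric
partners for the decoy replacement branch); DDA runs with Gaussian
chromatographic peaks (σ 4 s, base width within the typical 6–20 s range),
M+1/M+2 isotope satellites from the theoretical pattern, two MS2 scans per
feature, and chimeric scans built as weight-blended fragment unions with
multiplicative log-normal noise at a stated CV (5% in the standard
conditions, mid-range for modern instruments); SWATH runs as cycles of one
MS1 scan plus one scan per window with the customary 1 Th edge overlap.
All generators are seed-deterministic.

What passing fixtures does **not** show: real chimeras involve more than
two components with unknown library coverage, real chromatographic peaks
tail, real noise is heteroscedastic and includes m/z drift, and real
libraries contain collision-energy and instrument heterogeneity. The
fixtures establish algorithmic correctness (weight recovery, fragment-set
recovery, rule tables, envelopes), not field performance.

## Problem sizes

Default test and acceptance workloads are deliberately desk-scale: tens of
compounds per library, 8–20 features per run, 100 simulated two-ion
chimeras for the recovery study, 18 decoys × 20 features for the null
evaluation. These sizes make every property cheap to re-verify while
leaving the algorithms identical to what larger inputs would exercise.

## Known limitations

- Formula prediction is a self-contained CHNOPS enumeration; dedicated
  formula-annotation tools with isotope/fragment scoring will rank
  candidates better on real data.
- Class-I prediction approximates isotope retention by carbon count or m/z
  ratio; fragments that lose disproportionately many heavy-atom positions
  are mis-weighted.
- The DIA peak detector assumes roughly Gaussian, baseline-resolved peaks;
  shoulders and strong tailing will merge or split clusters.
- mzML/mzXML support covers centroided spectra with the standard CV terms;
  exotic vendor extensions and profile data are rejected rather than
  handled.
- No FDR calibration is attempted; the decoy machinery is a validation
  experiment, not an error-rate estimator.
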