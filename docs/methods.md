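# Methods

## The model

A cellulose microfibril cross-section is represented as a stack of
sheets of glucan chains — a *habit*, written as the ordered list of
sheet sizes (e.g. `234432` = 18 chains over six sheets).  Sheets are
mutually centered on a common axis; within a sheet, chains sit at unit
lattice spacing, so coordinates are integers or half-integers.  This
abstracts away the true monoclinic stagger, which the NMR data do not
constrain.

**Interior rule.** A chain is interior iff (i) both of its intra-sheet
neighbours at |Δx| = 1 exist and (ii) each adjacent sheet contains a
chain within `coverage_threshold` (default 0.5 lattice spacings) of its
x position; chains in the first and last sheet are surface by
construction.  The threshold is exposed because "interior" is not
defined geometrically by the experiments; the default reproduces the
accepted chain counts for the two 18-chain reference habits (6 interior
/ 12 surface for both `234432` and `34443`) and is cross-checked in the
tests against an independent brute-force neighbour-search oracle on raw
coordinates for every convex habit up to 12 chains.

**Origin/center labelling.** Cellulose Iβ places its two
crystallographically distinct chain types in alternating sheets.  Which
sheet parity is "origin" is not physically determined, so both parities
are always computed.  Under the 0-based convention used here (sheets
with index ≡ parity mod 2 are origin), `234432` splits its interior
chains 3:3 under both parities, while `34443` splits 2:4 / 4:2 — the
combinatorial reason the five-sheet habit cannot carry equal amounts of
the origin (a) and center (c) environments.

**Enumeration.** Habits are ordered compositions of the chain count
into at most `max_sheets` parts; by default only unimodal ("convex")
sheet-size profiles are kept, mimicking crystal-habit cross-sections,
and reflected duplicates collapse to the lexicographically smaller
form.  Convexity can be disabled.

## Forward simulation (the synthetic-data generator)

The generator emulates the observables the analysis consumes:

* **1D spectra** — sums of unit-height Lorentzians (default) or
  Gaussians at the table positions, default FWHM 0.5 ppm for every
  site: the major domain-1 and domain-2 environments have comparable
  linewidths, and per-site supplementary values can be supplied as a
  mapping when available.  Additive Gaussian noise is seeded
  (`numpy.random.default_rng`); noise 0 is exactly deterministic and
  identical seeds are bit-identical.
* **INADEQUATE peak lists** — for each bonded pair (C1–C2 … C5–C6) two
  peaks at (SQ = δᵢ, DQ = δᵢ+δⱼ) and (SQ = δⱼ, same DQ).
* **PDSD peak lists** — all intra-ring carbon pairs at any mixing time
  (the ≈30 ms regime correlates only carbons within one glucose ring);
  inter-site contacts from a packaged contact map switch on at their
  threshold mixing time: a↔c at C1 from 200 ms; C4 contacts from a and
  b to the domain-2 sites from 400 ms, with the c→domain-2 contacts at
  0.4 relative amplitude.  Thresholds and amplitudes are free
  parameters ordered to match the observed contrasts; they are not
  measured values.
* **Water-edited variants** — per-site enhancement factors (packaged:
  a = c = 1.0; f = j = 1.8, g = 1.9, b = 1.5 with carbon overrides
  b:C1 = b:C4 = 1.8, b:C6 = 1.3).  A 2D cross-peak scales by the
  geometric mean of its two (site, carbon) factors.  Again free
  parameters encoding qualitative ordering only: surface sites and b
  enhanced, b's C6 less so (its hydroxymethyl faces inward), g
  marginally the most hydrated domain-2 site.

Amplitudes ignore cross-polarisation dynamics and relaxation: the
C1-region intensity ratios the analysis relies on are empirically
stable across CP, DP and DQ-filtered acquisition, and nothing else in
the pipeline depends on absolute intensities.  Chain multiplicities
derived from a habit may be fractional (surface intensity split over
sites b, f, g, j by a user policy, default 2:4:3:3 out of 12): NMR
averages over an ensemble of fibrils.

### What the generator does not emulate

No hemicellulose/lignin background, no minor-site intensity, no
lineshape heterogeneity or field-dependent effects, no t₁ noise or
baseline artifacts, and 2D experiments are idealised into discrete peak
lists rather than full planes.  Passing round-trip tests therefore
demonstrates the internal consistency and correctness of the estimators
under the stated noise model, not their robustness to the full
complexity of wood spectra — in particular, blind deconvolution of
real, overlapped 1D spectra remains out of scope by design.

## Analysis choices

* **Packaged shift table.** The domain-1 rows carry the reported poplar
  values (±0.1 ppm).  The domain-2 rows (f, g, j and minor k) are
  seeded defaults chosen to satisfy every published constraint — C4
  cluster maxima at ≈83.5 and ≈84.5 ppm, C4 ∈ [80, 86.5],
  C6 ∈ [60, 63.5], anomeric C1 near 104–106 ppm, linewidths comparable
  to domain 1 — and are user-replaceable; they should be treated as
  placeholders, not measurements.  Site e's C2 is genuinely unreported
  and loads as NaN.  The Iα reference is likewise an editable seed; the
  only structurally asserted value is the second environment's C4 at
  90.3 ppm.  The Iβ reference equals sites a and c, which match the
  tunicate Iβ shifts within error.
* **Domain boundary.** C4 = 86.5 ppm (midway between the ~89 and ~84
  clusters), configurable; C4 exactly on the boundary goes to domain 2.
* **Spin-system tracing.** (SQ, DQ) entries are first re-paired into
  bonded-pair rows by greedy minimum-error matching (DQ agreement and
  SQ-sum consistency within tolerance, default 0.1 ppm).  Walks start
  from C1 candidates (SQ > 100 ppm), proceed closest-shift-first with
  ties broken toward lower DQ, gate each partner by a per-carbon ppm
  window, and consume each row at most once globally — so two sites
  sharing a C2 shift are still separated, because each system claims
  its own rows.  Branches within tolerance are all explored
  (depth-first with backtracking) and the surviving system is flagged
  ambiguous.
* **C1 fitting.** Positions are fixed at the traced (or tabulated) C1
  shifts and only non-negative amplitudes are solved (NNLS), optionally
  with one shared linewidth floating within ±50%.  Free-position,
  free-width deconvolution is deliberately avoided: with 0.2–0.4 ppm
  peak spacings it is ill-conditioned, and small linewidth changes can
  produce large apparent composition changes.  The i:s uncertainty
  band is propagated from the NNLS covariance; the experimental ±0.1
  on the published ratio is an acquisition-level error, not a model
  output.
* **Allomorph matching.** Max absolute deviation over carbons (not
  RMS), tolerance 0.1 ppm, with C1 excludable to reproduce the
  "apart from C1" comparison.  Iα is called present only if both Iα
  environments match distinct systems with amplitude ratio in
  [0.5, 2] (the "similar quantities" band, configurable).  The C1
  pairing resolver scores candidate pairings against short-mixing PDSD
  peaks only — the DQ-only INADEQUATE geometry is exactly what caused
  the historical C1 misassignment when the two C2 shifts coincide.
* **Hydration threshold.** A (site, carbon) is classified hydrated when
  its normalised enhancement factor exceeds 1.2 — an arbitrary,
  configurable cut; no numeric criterion exists in the literature.
* **Peak picking.** 3-point parabolic refinement (better sub-grid bias
  than a centroid for symmetric lines); at exactly equal heights the
  lower-ppm peak wins.
* **Crystallinity index.** Reported with its critique attached: CI
  exceeds i/(i+s) whenever any domain-1 intensity (site b) comes from
  the surface, so it overestimates interior content and is not a
  crystallinity measure.

## Numerical details and problem sizes

Default ppm grid 0.02 ppm/point (3001 points over 55–115 ppm; C1
analyses use 98–112 ppm).  Trapezoidal window integration.  Lorentzian
window areas follow the truncated closed form
γ·[arctan((hi−p)/γ) − arctan((lo−p)/γ)].  Round-trip tests run the
noisy i:s recovery at 1% of the spectrum maximum over 20 seeds;
enumeration tests cover all convex habits to 12 chains (oracle
comparison) and the complete 18- and 24-chain convex families.  These
sizes keep the whole suite within seconds while exercising every
branch; all are package-level defaults that scale up freely.

## Known limitations

* The interior rule is one consistent geometric choice; corner chains
  covered by only one adjacent sheet are always surface, which the
  data neither confirm nor refute.
* Which surface positions correspond to sites b vs f vs g vs j is
  unresolved; the model only ever splits interior vs surface, and b is
  treated as surface only inside the explicit multiplicity policy,
  never by the matcher.
* Minor sites d, e, k are carried as labels with no structural
  assignment.
* No energetics: habit enumeration is purely combinatorial and does not
  rank habits by stability or surface chemistry.
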