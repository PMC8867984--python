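# Methods

This note documents the models behind each module, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Poisson encapsulation model

Cell loading into droplets is modelled as homogeneous Poisson arrivals: the
number of cells per droplet is k ~ Poisson(λ), with λ the mean cells per
droplet set by the suspension density and droplet volume.  The model assumes
a well-mixed, non-aggregating suspension; clumped cells violate it and push
the real co-encapsulation rate above the analytic one, which is why the
Monte-Carlo twin (`simulate_droplets`) exists as an independent check rather
than as the primary calculator.

- **Co-culture probability** is the *unconditional* P(k ≥ 2) = 1 − e^−λ(1+λ).
  The alternative reading — conditional on the droplet being occupied,
  P(k ≥ 2)/(1 − e^−λ) — is ≈ 4.9 % at λ = 0.1 and would not satisfy a
  sub-0.5 % design target; the unconditional reading is the operative design
  quantity and the one implemented.
- The occupancy distribution is truncated at `k_max` (default 10) with the
  tail mass reported explicitly, so the probabilities always sum to 1.
- Droplet volume converts as 1 µm³ = 1 fl, so V_pl = (4/3)π(d/2)³/1000; a
  `floor` flag truncates to whole picolitres for presentation (40 µm →
  33 pl).  The throughput report prints the exact product rate × 3600 × λ
  and leaves rounding to the reader.

## Diversity statistics

Shannon diversity is computed in nats (natural log) by default — the
convention of the ecology tooling this module replaces — with the base
exposed as an option.  The rarity filter pools counts over the *whole*
table: a taxon is dropped from every sample when its share of the grand
total is strictly below the threshold, so per-sample composition cannot
rescue a globally rare taxon.  The filter is idempotent by construction.

Kruskal–Wallis is delegated to `scipy.stats.kruskal` (midranks, standard tie
correction); an all-constant input returns H = 0 by convention rather than
an error.  Dunn's post hoc test is implemented directly (no maintained
implementation exists in the installed stack): z-statistics on pooled
midranks with the tie term Σ(t³−t)/(12(N−1)), two-sided normal p-values,
Bonferroni adjustment by default (Holm and none available).  The comparison
set can be all pairs or every group versus a control, matching the common
"versus starting material" design.  Significance stars map adjusted
p-values as ***< 0.001, **< 0.01, *< 0.1, ns otherwise — note the wide
third band, kept for compatibility with the presentation this mirrors.

## LC-MS bucketing and metabolic grouping

Features are summed onto a fixed grid: linear RT bins (default 12 s over
30–1080 s) and constant-ppm m/z bins (default 5 ppm over 100–1600), i.e.
bin edges at mz_min·(1+5·10⁻⁶)ᵏ, so bin width scales with m/z as TOF mass
error does.  Vendor "advanced bucketing" implementations are proprietary;
this fixed log-spaced grid is documented and deterministic, and the
validation surface is planted-structure recovery, not bit-compatibility
with any vendor tool.  Intensities enter raw (no transformation); an
optional sqrt transform exists but is off by default.

Samples with fewer than 50 features are excluded before similarity — too
little signal for a stable cosine.  Cosine similarity is the plain
normalised dot product of bucket vectors.  The linear order required by the
sequential grouping rule comes from hierarchical clustering on 1 − cosine
(average linkage by default; single/complete/ward configurable); leaf order
is made deterministic by sorting sample labels before clustering.  Group
assignment then walks the leaf order and starts a new group wherever the
adjacent-pair similarity falls below the threshold; pairs at exactly the
threshold stay together ("0.9 or higher").  Group count is monotone
non-increasing as the threshold drops.

## Fingerprint curation

Electrophoretic band sizes are noisy, so raw sizes are first registered
onto a shared band registry by single-linkage over the sorted pooled sizes:
adjacent sizes within a relative tolerance (default 2 %) share a registry
band.  This approximates the proprietary binning of commercial gel-analysis
software; the tolerance is configurable and should be set from the sizing
CV of the instrument at hand.  Dice similarity is then computed on band
sets, and strains are clustered with Ward's method on 1 − Dice.  Ward on a
non-Euclidean dissimilarity is mathematically informal; it is implemented
as the standard Lance–Williams update on the given dissimilarities (scipy),
which is common fingerprint-analysis practice, and the merge history is
returned in full so users can re-cut.  The default flat cut is 0.15
distance and is a config parameter, not a calibrated constant.

Redundancy calling crosses the two groupings: strains sharing a genotype
cluster *and* a metabolic group are declared redundant, and the
lexicographically smallest strain id in each cell is nominated as its
representative (deterministic under input permutation).  Strains unique in
either dimension — same genotype but different chemistry, or vice versa —
are all retained.  Strains lacking a metabolic group are flagged and kept
as their own cell rather than dropped.

## Dereplication

Percent inhibition normalises a readout linearly between the growth control
(0 %) and the medium control (100 %); the same formula serves OD and
luminescence endpoints.  Values are clipped to [−10, 110] with the clipping
flagged — growth promotion is information, not noise.  Fractions at or
above the threshold (default 70 %, inclusive) are active, and contiguous
runs are reported as activity windows.  Fraction i (1-based) maps to the
half-open RT window [offset + (i−1)·dur, offset + i·dur); the collection
start offset defaults to 30 s and is configurable because detector-to-
collector dead volume shifts it in practice.

Monoisotopic masses use most-abundant-isotope atomic masses (CODATA/AME
values embedded as constants; C, H, N, O, P, S plus common halogens and
Na/K/Se).  Protonated adducts are (M + n·1.00727646)/n, the proton mass
being the hydrogen-atom mass minus the electron mass; `ion_mz` computes the
same quantity directly from a cation formula by subtracting electron
masses.  Display rounding is round-half-even at 4 decimals, full precision
retained internally.  Matching is inclusive at the ppm tolerance boundary
(default ± 2 ppm); each feature may hit several (compound, adduct) pairs
and hits are ranked by |ppm|.  Unmatched active-window features are
returned as candidate novel compounds — an empty hit list is a valid and
interesting result.

## Molecular networking

Fragment matching is a greedy one-to-one pairing: all peak pairs within the
tolerance, sorted by intensity product descending, accepted when both peaks
are unused.  On small instances this matches the exhaustive optimal
pairing (verified in tests against a brute-force oracle).  The default
tolerance is 0.05 Da; a ppm mode exists because the tolerance convention of
upstream tooling is ambiguous at this scale — 0.05 ppm would be ~25 µDa at
m/z 500, tighter than a QTOF delivers, so the Da reading is the default
and the ambiguity is documented here rather than resolved.

The spectral cosine weights peaks by square-root intensity (standard
networking practice; damps base-peak dominance) normalised to unit norm
over the full spectrum, so unmatched peaks dilute the score and
cos(a, a) = 1 exactly.  Raw-intensity weighting is a flag; the recovery
properties hold under both.  An edge requires cosine > 0.7 *and* ≥ 6
matched fragments — a conjunction, so a high cosine on five shared peaks
does not connect.  Plain cosine is the default; a modified-cosine mode
additionally admits peak pairs offset by the precursor mass difference,
linking homologues whose fragments carry the neutral-loss shift.  Isolated
nodes are kept and flagged.  MGF read applies an absolute intensity floor
of 1000 (mirroring common conversion settings) and drops emptied spectra
with the floor applied strictly (< 1000 removed).

## Synthetic data

Each generator plants a known answer and returns it beside the data;
recovery tests consume only the data files until assertion time.

- **Communities**: symmetric Dirichlet proportions, multinomial reads; the
  generating distribution's Shannon index is the truth.  Default 60 taxa,
  10⁵ reads, concentration 50 (H ≈ 4.05, the scale of a diverse soil-derived
  community).
- **Feature tables**: each group owns a template of 200 bucket positions of
  which 5 % come from a pool shared across groups; every sample carries the
  group core (95 % of the template, identical within the group — so any two
  group members share 95 % of their buckets by construction) plus 5 %
  private noise buckets, with log-normal intensity jitter (CV 0.1).
  Default 8 groups over 60 samples (sizes 20, 10, 8, 7, 5, 4, 3, 3, one
  dominant group as real campaigns show) plus 4 sparse samples the
  feature-count filter must remove.
- **Fingerprints**: 3 clones × 3 copies over a 30-band registry spaced
  > 4 % apart (safely beyond the 2 % registration tolerance); copies flip
  each band with probability 0.05 and sizes get ± 0.5 % sub-tolerance noise.
- **Spectral families**: 7 derivatives sharing 10 exact scaffold fragment
  masses with per-derivative intensities, precursors spaced by CH₂
  (14.01565 Da), plus 3 low-intensity derivative-specific peaks each;
  background spectra live in a disjoint fragment m/z region.
- **Plates**: 159 fractions of 7 s, growth OD 1.0, medium OD 0.08, Gaussian
  noise at 2 % of the growth OD, one window (fractions 84–87) spiked at
  95 % inhibition by default.

What the generators do **not** emulate: chromatographic peak shape and RT
drift between batches, isotope envelopes and adduct clusters, sequencing
error and chimeras, plate edge effects, and any correlation between a
strain's genotype and its chemistry.  A green recovery test therefore
establishes that the algorithms do what they claim on data satisfying their
assumptions — not that those assumptions hold on any given instrument's
output.

## Numerical choices

- Co-culture probability uses `expm1` to avoid cancellation at small λ.
- Cosine matrices are symmetrised and clipped to [0, 1] against floating-
  point drift; zero-norm rows are a named error, not a NaN.
- Dendrogram determinism: sample labels are sorted before linkage so ties
  break identically across runs and input orders.
- Degenerate inputs are errors where silence would mislead (empty profile,
  empty fingerprint, assay with growth ≤ medium control) and tolerated
  where they are routine (features outside the bucket grid: dropped and
  counted; spectra emptied by the intensity floor: dropped with a warning).
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical scenario files.
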