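# Methods

## Mass arithmetic

All masses are monoisotopic. The residue table carries 6-decimal masses
(Da); water is 18.010565 Da and the proton 1.007276 Da. Six decimals
matter: with a 5-decimal table the doubly charged LTALEPTNR precursor
rounds to 507.7825 rather than the correct 507.7826. Rounding to the
4 decimals conventional on transition lists happens only at the reporting
boundary; all internal arithmetic is full-precision float.

Only fixed modifications are supported, with carbamidomethyl-cysteine
(+57.021464 Da) on by default — the standard iodoacetamide alkylation of
bottom-up sample preparation. Variable modifications such as methionine or
tryptophan oxidation are not modeled as mass variants; oxidation proneness
enters the workflow as a ranking penalty instead (below). b/y ions follow
the usual conventions (b: N-terminal fragment without water; y: C-terminal
fragment plus water); a/c/x/z ions, neutral losses, and isotope envelopes
are out of scope for a unit-resolution QQQ workflow.

## Digestion

Trypsin: cleavage after K/R, suppressed before proline by default (Keil
rule — the common software default; the flag `proline_rule=False` gives
strict cleavage). Defaults: 0 missed cleavages, length 5–30. N-terminal
methionine is not removed — database sequences are digested as-is.
Peptides containing ambiguity letters (B/J/Z/X/U/O) have undefined mass
and are excluded from digests by default, while parsing retains them so no
data is silently dropped. Digestion is verified in the test suite against
an independent brute-force substring enumerator.

## Uniqueness screening

Uniqueness is assessed by exact tryptic-peptide identity against the
*union* of all loaded species proteomes, via a peptide → (species,
accession) index built from a full digest of every background protein.
This is deterministic and offline; similarity-level (mismatch-tolerant)
homology search is deliberately out of scope — a peptide that matches
another species exactly is disqualified, which is the decision the screen
must support.

Because Ile and Leu are isobaric and indistinguishable by low-energy CID
m/z, the index is also kept in I/L-collapsed form. A peptide whose exact
sequence is species-specific but whose I/L isomer occurs in another
species is reported as `il_ambiguous` (with the full species set) rather
than silently `unique` or `shared`; the caller decides whether
chromatographic separation justifies keeping it. Collapsing is on by
default.

## Marker ranking

Candidates are scored as

    score = w1·log10(median normalized area)  −  w2·#C − w3·#W − w4·#M
          + w5·(transition-distribution evenness)

with defaults w1 = 1, w2 = 2, w3 = w4 = 0.5, w5 = 0.5. The intensity term
is 0 without measurement data. The distribution term is the normalized
Shannon entropy of per-transition intensity shares (1 = perfectly even),
rewarding peptides whose signal is not carried by a single fragile
transition. Cysteine carries the heaviest penalty (most oxidation-prone
and carbamidomethylation-dependent); tryptophan and methionine are
penalized at half a log10-intensity decade each. The half-decade choice
keeps the penalties meaningful without letting a single Trp overturn an
order-of-magnitude intensity advantage — with full-decade penalties a
high-abundance Trp-containing peptide (the flaxseed conlinin case) would
lose its quantifier role to a peptide ~10× weaker, which contradicts how
such panels are assigned in practice. Weights are configurable
(`ScoreWeights`).

Roles: per parent protein, the top-scoring unique peptide is the
quantifier; the next one or two are qualifiers (≤ 3 markers per protein).
Non-unique peptides are disqualified outright. Ties break
deterministically: fewer Cys, then fewer Trp+Met, then longer peptide,
then lexicographic.

## Transitions

Per peptide, all singly charged b/y ions are generated at the default
precursor charge 2 and filtered to the monitored window (200–1200 m/z).
If more than 10 survive, the list is truncated by the default preference
order — y ions before b ions, longer fragments first (the y series
dominates CID spectra of tryptic peptides on QQQ instruments); if fewer
than 8 survive, all are kept and a warning is raised. Final selection
keeps the 4 most intense transitions once measured intensities exist, with
the preference order as tie-break and as the fallback without data.
Collision energy is a passthrough column (optionally prefilled by a linear
ramp in precursor m/z, coefficients configurable); instruments optimize it
empirically. The export format is a plain CSV with one row per transition
and m/z at 4 decimals, importable into vendor tools.

## Validation statistics

* Normalization: peak area / mg defatted flour, applied before any
  statistic.
* RSD: 100·s/mean with the n−1 (sample) standard deviation.
* Repeatability (intra-day): mean over days of the within-day RSD.
* Reproducibility (inter-day): RSD of the day means. Day means (rather
  than pooling all injections) keep a systematic day shift from being
  conflated with within-day scatter; with ≥ 2 replicates per day the
  day-mean RSD also absorbs a small within-day component
  (≈ CV_intra/√n_reps in quadrature), which is visible in the recovery
  test's acceptance band.
* IS recovery: 100·mean(spiked)/mean(reference) with sd propagated from
  the spiked replicates, computed on raw areas (the standard is spiked at
  a fixed amount, so flour normalization does not apply). "Reference" is
  the standard measured in neutral matrix; both record classes are
  explicit in the data model.
* Linearity: ordinary least squares of normalized area on dilution level
  (scipy), R² = squared Pearson r; ≥ 3 distinct levels required. A
  perfectly flat response reports slope 0, R² 0. The x-variable is the
  dilution level as given; converting to concentration is the caller's
  bookkeeping.
* Metrics that cannot be computed from the available grouping (single
  day, too few replicates) are reported as absent with a reason, not as
  an error.

## Authentication calls

A species is called **positive** in a sample iff its quantifier's
normalized area clears the species threshold AND at least one qualifier is
detected above the qualifier threshold; a cleared quantifier with no
qualifier support is **inconclusive**; everything else is **negative**.
Thresholds are explicit per-species configuration (defaults: 1000 area
units/mg for both roles) — the workflow reports no detection limits of its
own, so inference of thresholds from data is deliberately not attempted.
An optional qualifier/quantifier area-ratio consistency check (±30 % of a
reference ratio) exists but is off by default, matching
confirmation-by-detection practice. Blanks must come out negative for
every species.

## Synthetic fixtures

The generator emulates the two data types the workflow consumes.

*Proteomes*: uniform-random sequences over the 20 standard residues, with
marker peptides planted behind a K flank at proline-free junctions so both
cleavage boundaries are intact. Planted peptides must be legal tryptic
products (end in K/R, no internal cleavage site, length within window). A
post-generation rescan re-digests every protein and resamples any
background that accidentally reproduces a planted peptide (exact or
I/L-collapsed), so planted uniqueness labels are exact by construction.

*Peak areas*: multiplicative lognormal noise — areas are positive and
their scatter is relative — with unit-mean factors parameterized by CV
(σ² = ln(1+CV²), μ = −σ²/2): one day factor (inter-day CV, default 3 %)
times one replicate factor (intra-day CV, default 5 %), on a default true
mean of 10⁶ area units/mg, the mid-range of typical storage-protein marker
signals. The precision-recovery test uses 20 days × 10 replicates, sized
so the sampling bands on the estimated RSDs ([4, 6] % intra, [2, 4.5] %
inter) are tight. Calibration series use additive gaussian noise on
area = slope·level, the regime in which R² degradation is assessed.
Everything is reproducible from the fixture seed.

What the fixtures do **not** emulate: chromatographic interference, matrix
suppression, retention-time drift, missing transitions, or correlated
noise between peptides. Passing tests therefore demonstrate correctness of
the computations and decision logic, not instrument-level performance on
real seed extracts.

## Numerical and degenerate-input choices

* m/z comparisons in tests at 1e-4 Da (the 4-dp reporting precision).
* Empty digests are valid results; empty FASTA files, empty sequences,
  and duplicate accessions are hard errors naming the offender.
* Deterministic ordering everywhere (digest by start/length, candidates
  by score with total tie-break, exports in input order) so identical
  inputs give byte-identical outputs.
* Fragment generation requires length ≥ 2; RSD requires n ≥ 2 and a
  non-zero mean; recovery requires a non-zero reference mean.

## Known limitations

* Exact-identity screening cannot flag near-identical homologs that
  differ by one substitution (a BLAST-level concern); it answers only the
  exact-match disqualification question.
* Single-proteome-per-file model; no isoform collapsing beyond identical
  peptides, no annotation-score filtering (requires metadata absent from
  FASTA).
* No retention-time scheduling, spectral-library matching, or absolute
  quantification with labeled standards.
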