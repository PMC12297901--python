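# seedmark

A toolkit for designing and validating targeted LC-MS/MS (MRM) peptide-marker
assays that authenticate seed species — distinguishing, say, flaxseed from
sesame or quinoa from amaranth in flours and food products by the tryptic
peptides their seed storage proteins produce.

It is written for analytical proteomics labs building species-authentication
panels: you supply per-species proteome FASTA files and (once the instrument
has run) peak-area tables from your chromatogram-integration software;
seedmark handles everything in between that is computable at a desk.

## What it does

1. **In silico tryptic digestion** of each species' proteome — cleavage after
   K/R (suppressed before P), configurable missed cleavages, peptide length
   window 5–30 by default.
2. **Monoisotopic mass arithmetic** — peptide neutral mass, precursor m/z at
   any charge, and singly/multiply charged b/y fragment-ion m/z, with fixed
   carbamidomethylation of cysteine (+57.021464 Da) applied by default:

   M = Σ residue masses + H₂O,  m/z = (M + z·1.007276) / z

   b_i = (Σ first i residues + z·H⁺)/z,  y_i = (Σ last i residues + H₂O + z·H⁺)/z

3. **Cross-proteome uniqueness screening** — every tryptic peptide is indexed
   across the combined proteomes of all species; a marker candidate must be
   species-unique. Isoleucine/leucine are isobaric under low-energy CID, so
   I/L-collapsed matching flags isomeric collisions (`il_ambiguous`) that
   exact matching would miss.
4. **Marker ranking and role assignment** — candidates are scored by median
   normalized signal intensity (log10), penalties on oxidation-prone residues
   (Cys, Trp, Met), and evenness of intensity across transitions; per parent
   protein the top candidate becomes the **quantifier** and the next one or
   two become **qualifiers**.
5. **MRM transition design** — 8–10 candidate b/y transitions per peptide in
   the 200–1200 m/z window, trimmed to the 4 most intense, exported as a
   vendor-neutral transition-list CSV.
6. **Validation statistics and authentication** — internal-standard recovery,
   repeatability (intra-day RSD), reproducibility (inter-day RSD of day
   means), calibration linearity (R²), and per-sample species calls
   (positive / inconclusive / negative) from quantifier + qualifier evidence,
   with blank controls expected negative.

A synthetic-fixture module generates toy proteomes with planted
unique/shared/I-L-variant peptides and peak-area tables with prescribed
intra-/inter-day CVs, so the entire pipeline is testable offline with exact
ground truth.

## Worked example

The tryptic peptide LTALEPTNR is produced by homologous 11S globulins of
both amaranth and quinoa — a textbook uniqueness failure. Its transitions:

```python
from seedmark import candidate_transitions, select_top_transitions, round_mz

cands = candidate_transitions("LTALEPTNR")
top = select_top_transitions(cands, {"y7": 100, "y6": 90, "y5": 80, "y4": 70}, n_final=4)
for t in top:
    print(f"{t.peptide}  {round_mz(t.precursor_mz)}++  ->  {t.product.label} {round_mz(t.product.mz)}+  rank {t.rank}")
```

prints

```
LTALEPTNR  507.7826++  ->  y7 800.4261+  rank 1
LTALEPTNR  507.7826++  ->  y6 729.389+  rank 2
LTALEPTNR  507.7826++  ->  y5 616.3049+  rank 3
LTALEPTNR  507.7826++  ->  y4 487.2623+  rank 4
```

i.e. the doubly protonated precursor at m/z 507.7826 and its four
diagnostic singly charged y ions. Screening the same peptide against a
background containing both amaranth and quinoa proteomes returns
`shared{amaranth, quinoa}` and the candidate is disqualified from any
marker role — only peptides unique to one species survive.

The same workflow is available from the shell:

```bash
seedmark screen --species flaxseed=flax.fasta --species sesame=sesame.fasta --out candidates.csv
seedmark transitions --candidates candidates.csv --out transitions.csv
seedmark validate --peak-areas areas.csv --out report.csv
seedmark quantify --peak-areas areas.csv --panel candidates.csv --out calls.csv
```

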