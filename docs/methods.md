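# Methods

This note documents the models, conventions and numerical choices behind
`glycorank`, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the underlying workflow is qualitative.

## 1. Permethylated Bn-glycan mass calculus

Cellular O-glycome reporter/amplification (CORA) profiling feeds cells
peracetylated benzyl-GalNAc; the secreted benzyl glycosides are
permethylated and measured by nanoLC-ESI-MS. All masses derive from
monoisotopic element masses (C 12, H 1.0078250319, N 14.0030740052,
O 15.9949146221, Na 22.98976928); no ion value is hard-coded in the
library.

The neutral mass decomposes as `Σ residue increments + H2O + (Bn − H) +
CH2`. Each increment is the water-free residue mass plus one methyl per
free OH/NH of an in-chain residue (Hex 3, HexNAc 3 — two hydroxyls plus
the acetamido NH, dHex 2, NeuAc 5 — four hydroxyls plus the carboxyl
methyl ester). The closing CH2 is the extra methyl of the single
non-reducing terminus: every additional branch terminus is exactly offset
by the hydroxyl consumed at its branch point, so the formula depends only
on composition, not topology. This reproduces the full ten-ion reference
ladder (368.2–1743.9) to 0.1 Da.

**Adduct.** The profiling literature often reports [M+Na]+ for
permethylated glycans, but the reference ladder is reproduced by the
protonated species, so `proton` is the default and `sodium` is available
behind a flag.

**Rounding.** Comparisons against printed values use round-half-up to
1 decimal (profile ions) or 2 decimals (oxonium ions); internal arithmetic
is full precision.

**Annotation.** Each library species takes the single nearest peak within
a configurable tolerance (default 0.3 Da, matching 1-decimal printed
ions); ties prefer the more intense then the lower-m/z peak. Relative
abundances are normalized over matched species only and always sum to
100 %. Unmatched species are retained with zero abundance and an `absent`
flag rather than dropped, so profiles over the same library are always
comparable row-by-row.

## 2. Glycopeptide annotation and glycosite localization

The production workflow used a commercial search engine with a
probabilistic validator; both are out of scope here. The replacement is a
deliberately simple, fully specified scorer:

- **Digestion.** Trypsin cleaves C-terminal to K/R, chymotrypsin
  C-terminal to F/W/Y/L/M; neither before proline (the chymotrypsin
  specificity is a declared dialect). Up to `max_missed_cleavages`
  (default 2) missed cleavages.
- **Ions.** Singly charged b/y (CID) or b/y/c/z (EThcD): c = b + NH3,
  z• = y − NH3 + H (z-radical convention, plain z behind a flag). Fragment
  matching is singly charged only — a documented simplification; precursor
  charges 2–8 are accepted.
- **Score.** `matched_fraction` = matched / emitted theoretical ions at
  the fragment tolerance (0.1 Da default). Oxonium evidence is any peak
  within fragment tolerance of HexNAc (204.0867) or HexNAc-Hex (366.1395)
  oxocarbenium ions. Confidence is `high` when matched_fraction ≥ 0.6
  (configurable) *and*, for glyco candidates, oxonium evidence is present;
  a glycopeptide match without oxonium evidence is demoted to `medium_low`
  regardless of its ion coverage. These tiers replace q-values; the
  threshold is declared, not inferred.
- **Localization.** All placements of the PSM's glycan multiset over the
  peptide's Ser/Thr are scored by matched *site-determining* c/z ions
  (ions whose m/z differs between at least two placements). The verdict is
  `unique` only when one placement strictly out-scores all others;
  otherwise `ambiguous` with the union of tied sites, in 1-based protein
  coordinates.

Amino-acid residue masses are computed from elemental formulas in-repo
(the usual proteomics helper library is not a dependency) and are
cross-checked against Biopython in the test suite. Search candidates carry
carbamidomethyl as a fixed Cys modification (samples are alkylated before
digestion); Met oxidation is available in the modification table but not
enumerated during candidate generation, to bound the combinatorics.

## 3. Target ranking

- **Curation.** A protein is retained with ≥ 1 high-confidence
  glycopeptide or ≥ 2 distinct medium/low glycopeptide *sequences*
  (spectra of the same peptide count once — the strictest reading
  computable from a PSM table).
- **DE filter.** Linear fold change ≥ 2 and p ≤ 0.05, both
  boundary-inclusive. Whether the source workflow used linear or log2
  ratios is unstated; linear is assumed.
- **Expression bins.** 80–100 % of patients positive → high, 40–79 % →
  moderate, 1–39 % → low, 0 % → negative, not addressed → unknown.
- **Target score.** The published system is qualitative with a stated
  maximum of 15; the point allocation here is this package's declared
  rubric, fully exposed in `ScoreRubric`: healthy-tissue absence 0–5
  (5 × (1 − mean tissue burden), burden weights high 1.0 / moderate 0.6 /
  low 0.3 / negative 0, missing data worst-case), urothelium absence 0–2,
  tumour bin 0–3, plasma membrane 0–2, prognosis 0–1, up-regulation 0–2
  (up in both NMIBC and MIBC scores above MIBC-only), lymphoid/gamete
  penalty −3, clamp to [0, 15]. Unknown annotations score worst case (0)
  rather than excluding the protein; a `require_tumour_data` flag
  reproduces a ranking restricted to proteins with tumour expression data.
  The published example totals (13/13/10/5) are used as calibration
  fixtures with attribute vectors derived under this rubric — they
  exercise its expressiveness, not a recovered weighting.
- **Ordering.** Descending score, ties by tumour bin (high first) then
  protein id: deterministic and permutation-invariant.

## 4. Cohort statistics

- **IHC score** = intensity (0–3) × extension/10 (0–10), range 0–30.
  Intensity 0 iff extension 0 iff location `negative` are enforced
  invariants.
- **Membrane/cytoplasm ratio** per stage counts only antigen-positive
  cases; a zero cytoplasm-only denominator yields an undefined (`None`)
  entry, never infinity.
- **Association tests.** Pearson chi-square from the closed formula
  (df 1, no continuity correction by default); Fisher's exact test is
  auto-selected when any observed cell is < 5. Two-sided Fisher p uses the
  minimum-likelihood rule (scipy's convention), verified in the tests
  against brute-force hypergeometric enumeration.
- **Kaplan–Meier / log-rank.** Product-limit estimator with right
  censoring; group summary is the restricted mean survival time (area
  under the curve to the group's largest observed time — the conventional
  statistical-package "mean survival"; medians are available from the
  curve). The k-sample log-rank statistic sums observed-minus-expected
  events with the hypergeometric covariance over distinct event times;
  p from chi-square with k − 1 df. With zero events the statistic and p
  are `None` rather than a fabricated value.
- **Cox regression.** Newton–Raphson with step-halving on the Efron
  partial likelihood (Breslow behind a flag; identical on tie-free data),
  convergence at relative log-likelihood change < 1e-9 or 50 iterations.
  Constant covariates are excluded from the optimization and reported as
  HR 1, p 1; non-convergence and monotone likelihood (coefficient
  divergence) are flagged on the result object. Estimates and standard
  errors agree with `lifelines` to ≤ 1e-6 in the cross-check tests.

## 5. Synthetic data: what it emulates, what it does not

All generators are pure functions of (config, master seed); each draws
from its own substream (fixed spawn key), so adding a generator never
perturbs another's output, and identical runs are byte-identical.

- **O-glycome spectra**: one peak per planted species at theoretical m/z
  ± uniform jitter (default 0.05 Da, below half the matching tolerance),
  log-normal intensities with sialylated species boosted 4× to mimic the
  ST-dominant bladder-cancer profile, and noise peaks kept 2× tolerance
  away from every library m/z. No isotope patterns, adduct mixtures or
  chromatography.
- **Glycopeptide spectra**: fully tryptic peptides (length 6–30, ≥ 1
  Ser/Thr) from a random 50-protein proteome; each S/T becomes a planted
  site with probability 0.05; one glycan per site (Tn or T, fair coin).
  Spectra hold the complete singly charged b/y/c/z ladder minus
  independent per-ion dropout (default 0.2), the two oxonium diagnostics,
  and guarded noise; precursors are exact at charge 2. Plantings where a
  rival placement's *every* site-determining ion falls within the fragment
  tolerance of a true ion are skipped: such sites are unlocalizable in
  principle (near-isobaric interference), and these spectra exist to test
  the localizer, not fragment-mass degeneracy. A green localization test
  therefore establishes correct hypothesis scoring under dropout — not
  robustness to chimeric spectra, co-eluting glycoforms or calibration
  error, none of which are modeled.
- **Expression/tissues**: 10 % of genes planted up-regulated (fold
  2.5–8, p ≤ 1e-2); the rest deliberately straddle the thresholds (fold
  passes but p fails, or vice versa) so the filter's boundary behaviour is
  exercised. Two planted "ideal targets" receive the score-15 profile.
- **Cohort**: 104 patients (the scale of the original series); stage-wise
  membrane-phenotype probabilities r/(1+r) from the published
  membrane/cytoplasm ratios (0.07/0.38/0.33/0.46/0.63, metastases 0.6);
  exponential survival with baseline hazard ln 2 / 49 months (median
  follow-up of the series) multiplied by exp(ln 3.87) for
  membrane-positive patients; independent exponential censoring (rate
  0.008) capped at 226 months (the series' longest follow-up). Weibull
  survival is available behind a flag. Constant hazards are an analytic
  convenience: recovery tests establish estimator correctness, not
  robustness to non-proportional hazards.

## 6. Known limitations

- No FDR control (target-decoy) and no intact-glycopeptide Y-ion ladders;
  glycan state on a peptide is a multiset over {HexNAc, HexNAc-Hex} with
  at most 3 occupied sites.
- Fragment matching is singly charged; high-charge fragment matching and
  isotope deconvolution are out of scope.
- The target-score weights are declared, not learned; alternative
  weightings are drop-in through `ScoreRubric`.
- The cohort statistics assume proportional hazards and independent
  censoring; competing risks and time-varying covariates are not modeled.
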