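# Methods

## Scope and data model

`micromet` starts from *aligned* untargeted LC-MS data: a feature table whose
rows are features (unique m/z × retention-time entities) with a q-value and
one intensity per sample, plus sample metadata (condition, replicate, blank
flag, culture surface area).  Peak picking, retention-time correction and
alignment are upstream and out of scope.  Intensity 0 encodes "not
detected"; every presence rule keys off that encoding.  Retention time is
seconds everywhere — the grouping window (45 s) and MS/MS window (30 s) are
second-scale while gradients are minute-scale, and a single unit removes a
whole class of bugs.

## Mass calculus

Monoisotopic masses are summed from a package-shipped table of
lightest-stable-isotope element masses (C, H, N, O, F, Na, P, S, Cl, K; ≥ 9
significant decimals; carbon exactly 12), so annotation results do not
depend on any external mass library.  Ion m/z follows

m/z = (n·M + m(additions) − m(losses) + q·mₑ)/|z|,

with q = +1 per negative charge (electron gained) and −1 per positive
charge.  Including the electron mass (0.000549 Da) is the convention that
reproduces published negative-mode 3-decimal m/z values; it can be disabled
(`include_electron=False`) for comparison against tools that omit it.  The
ppm error uses the predicted m/z as denominator; below a 10-ppm gate the
choice is numerically immaterial but must be fixed.  `neutral_mass_from_mz`
inverts the relation exactly (round trip < 1e-9 Da, property-tested).

"FA" adducts are formate from formic acid CH₂O₂ (monoisotopic 46.00548 Da),
the standard ESI− mobile-phase additive convention.  The packaged worked
example prints one adduct label as `[M−2H]−`; at its m/z (137.024 for a
C₁₄H₁₂O₆ neutral) it is only consistent as the doubly charged dianion, so
the extended adduct set spells it `[M-2H]2-` with charge −2.

## Filter cascade

Four order-independent filters (each drops rows, never edits intensities,
hence idempotent and mutually commuting — property-tested):

| filter | rule | default |
|---|---|---|
| q | remove q **>** threshold (`keep-significant`) | 0.05 |
| replicate presence | keep iff detected in ≥ fraction of some condition's non-blank replicates | 0.66 (2/3 passes) |
| blank | remove if detected in ≥ 1 blank | — |
| intensity | remove if max over non-blank samples **<** floor | 5,000 a.u. (60,000 for blood matrix) |

The protocol text this implements reads "removed if q < 0.05" verbatim; that
reading would discard exactly the significant features the downstream
figures analyse, so the default inverts it and the literal reading ships as
the explicit `literal` mode.  Blanks are never counted as a condition
for the replicate rule, and the blank rule is any-blank detection (no
blank-frequency threshold is stated anywhere to copy).

Extraction solvent volume is proportional to culture surface area, anchored
at 30 µl per 3.5-mm-diameter well (9.6211 mm²); the same proportionality
gives 2.449 ml for ten 10-mm cores.  Surface-area intensity normalisation
divides each sample by its area (a.u./mm²) and, when enabled, is applied
before unit-variance scaling.

## Annotation chain

1. **Candidates** — every (feature, compound, adduct) with ppm error
   strictly < 10.  Database entries with identical formulas are first merged
   into composite "A or B" labels (exact mass cannot separate structural
   isomers).
2. **RT grouping** — per compound, single-linkage clustering of candidate
   retention times with a hard span cap at 45 s; a cluster violating the cap
   is split at its largest internal gap until compliant.  Deterministic;
   singleton groups are allowed (several published single-adduct compounds
   exist, so no ≥ 2-adduct requirement is imposed).
3. **Compatibility resolution** — a feature claimed by several compounds
   keeps the compound whose RT group explains the most co-eluting features;
   ties break by lowest group mean error, then compound-name order (logged).
   This operationalises "discard identifications whose proposed adducts are
   incompatible with the spectrum", for which no published algorithm exists.

MS/MS confirmation of a putative identification against a standard requires
retention-time difference < 30 s and every reference fragment matched
within 0.05 m/z (both strict).

The worked-example report prints m/z to 3 decimals; re-annotating those
rounded values can push a genuinely sub-10-ppm match just past the gate
(worst case ≈ 10.4 ppm at m/z 537).  Full-table reproduction therefore
allows the ±0.0005-Da rounding band on top of the gate; the two rows whose
formulas are printed in the report need no such allowance.  One report row
(the emericellin monomer) is numerically inconsistent with its own dimer
partner and is reproduced verbatim but flagged, not reinterpreted.

## Multivariate profiling

Unit-variance scaling divides each feature column by its n−1 standard
deviation; constant columns become all-zero and are flagged rather than
divided by zero.  PCA mean-centers columns and uses the SVD; variance
explained per component is s²ᵢ/Σs².  Sign ambiguity is removed by making the
largest-magnitude entry of each loading column positive.  Group score clouds
are summarised by covariance (data) confidence ellipses with semi-axes
√(χ²₂(0.95)·λᵢ) = √(5.991·λᵢ); whether published "95% confidence" ellipses
are data or standard-error ellipses is ambiguous — data ellipses are
implemented and documented as such.  Degenerate (singular-covariance)
ellipses are returned flagged, not errored.

## Comparison statistics

Presence in a condition reuses the 66%-replicate detection rule.  Zone
classification partitions features into A-only / shared / B-only / neither;
"produced primarily on A" is presence-on-A ∧ absence-on-B (a fold-change
notion of "primarily" is deliberately not implied — nothing quantifies it).
An optional control condition (e.g. matrix alone) can be excluded first.

Kruskal–Wallis uses the tie-corrected H.  Its p-value is computed by
exhaustive enumeration of all regroupings when the pooled sample size is
≤ 10 — at triplicate-scale designs the χ² tail misstates exact p by up to
~0.1 (e.g. {1,2,3} vs {4,5,6}: exact p = 0.100, χ² p = 0.0495), and the
bench statistics tools this mirrors also report exact small-sample p —
falling back to χ² with k−1 df for larger N (`p_method` forces either).
Dunn's post hoc z uses the pooled mid-rank variance with tie term
Σ(t³−t)/(12(N−1)) and comparison-count (Bonferroni) multiplication of the
two-sided normal p.  The two-condition test is the pooled-variance
(Student's, not Welch's) unpaired t.

## Synthetic data generator

The generator emulates what alignment software would export for a microscale
culture study, with full ground truth.  Defaults are the solvent-comparison
design: the curated 19-compound database, 3 conditions × 5 replicates +
3 blanks, standard 3.5-mm wells.

| parameter | meaning | default |
|---|---|---|
| `mass_noise_ppm` | multiplicative m/z noise (TOF-style ppm accuracy), truncated at `mass_noise_max_ppm` = 10 | 2 |
| `rt_jitter_s` | within-compound adduct RT spread (uniform) | 45 |
| `rt_min_s`–`rt_max_s` | anchor range on a ~50-min gradient | 60–2,940 |
| `base_intensity_log_mu/sigma` | log-normal compound abundance | ln 1e5, 1.0 |
| `condition_effect_sigma` | log-normal per-(compound, condition) extraction multiplier | 1.0 |
| `adduct_intensity_log_mu/sigma` | secondary-adduct attenuation | −1.0, 0.5 |
| `replicate_log_sigma` | per-replicate noise | 0.3 |
| `dropout_p` | per-replicate missed detection | 0.10 |
| `extra_adduct_p` | chance of each non-primary adduct per compound | 0.5 |
| `n_contaminants` | blank-borne contaminant features | 5 |

Explicit `condition_multipliers` (with zeros) encode designed
presence/absence for zone studies.  All randomness flows from one seed;
identical configs are byte-identical on disk.  Truncating mass noise at the
gate keeps the noiseless-limit property clean (σ→0 ⇒ perfect recovery) and
means recall degradation near the gate arises through resolution ambiguity,
not gate misses — so recall versus σ is tested as non-increasing, not
strictly decreasing.  Not emulated: isotope envelopes, chimeric peaks,
cross-sample RT drift, batch effects, intensity-dependent mass error.
Passing recovery tests therefore demonstrate the pipeline's logic, not
robustness to all real-data pathologies.

## Problem sizes and determinism

The test suite and analysis drivers use the default design (~70–90 features,
18 samples), 3–10 seeds per stochastic claim, and exhaustive statistical
oracles only at N ≤ 8; everything runs in well under a minute on one core.
Property-based tests run derandomised with fixed profiles.  The pipeline
manifest records a SHA-256 config hash, the seed and per-stage row counts;
identical configs reproduce byte-identical run directories.

## Known limitations

- Exact-mass annotation is putative by construction: isomers share labels,
  and a 10-ppm gate cannot separate isobaric compounds; MS/MS confirmation
  here checks fragment lists, it does not score spectra.
- The compatibility rule is a reasonable operationalisation, not a published
  algorithm; on data where a wrong compound forms the larger co-eluting
  group it will resolve wrongly.
- Real published zone counts and PCA separations derive from ~1,000-feature
  real datasets that are not redistributable; the package validates the
  operations on designed synthetic data instead and makes no claim of
  reproducing those real-data values.
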