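# Methods

This note documents the models, defaults and numerical choices behind
`pistilmet`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Mass arithmetic (`pistilmet.chem`)

Monoisotopic atomic masses are CODATA/NIST values for the most abundant
isotope, shipped as a versioned plain-text table
(`src/pistilmet/data/elements.tsv`) covering C, H, N, O, P, S, Na, K. All
ion m/z values subtract one electron mass (0.000548579909 Da) per positive
charge: at QTOF accuracy (~1 ppm at m/z 550) the electron mass is a 1 ppm
effect and reported 4-decimal m/z values do not reproduce without it.
Internal arithmetic is full double precision; report output rounds half
away from zero at the printed precision (4 dp m/z, 2 dp ppm).

**RDBE** is `1 + Σ nᵢ(vᵢ−2)/2` with valences C=4, H=1, N=3, O=2, P=3, S=2,
Na=K=1. For `[M+H]⁺` compositions the `neutralize` flag removes one
hydrogen first so the value refers to the neutral molecule, matching the
convention of formula-generation reports. The **nitrogen rule** is checked
as parity agreement between the integer nominal mass (mass numbers of the
most abundant isotopes) and the nitrogen count.

**Isotopologue ratios.** The predicted (A+1)/A intensity ratio is the sum
of per-atom heavy/light abundance ratios — exact for independent atoms,
since P(one heavy substitution)/P(none) = Σ nᵢ rᵢ. The per-carbon
contribution is pinned to the 1.08 %/C convention used for carbon counting
(natural ¹³C/¹²C is 1.0816 %); other elements default to their natural
ratios (H 0.0115, N 0.3654, O 0.0381, S 0.7896 %/atom) and are
configurable. Carbon counting inverts a measured ratio as
`estimate = ratio / 1.08` with integer acceptance window
`[⌊estimate⌋−1, ⌊estimate⌋+2]`. The window is deliberately asymmetric:
heteroatoms only ever inflate the measured ratio above the pure-carbon
expectation, so the true carbon count tends to sit at or below
estimate + 1, while measurement error argues for one unit of slack on both
sides. This rule maps 28.60 % → 26.48 → {25…28}.

## Component grouping (`pistilmet.spectra`)

EICs are sums of matching peak intensities per scan under a two-component
tolerance (|Δ| ≤ abs + rel·m/10⁶; default 2 mDa + 3 ppm, a tightened QTOF
isotope-spacing setting and the package-wide default). Grouping is greedy
and deterministic: the most intense unassigned signal seeds a group and
collects every signal whose EIC Pearson correlation with the seed is ≥ the
threshold (default 0.95 — "perfect co-elution" is never exactly 1 in
sampled data). The result is always a partition of the input signals.

Within a group, each member is hypothesised as the protonated molecule and
the hypothesis explaining the most other members via Na/K adduct and
2M+Na/2M+K dimer relations wins; ties resolve to the higher m/z, which is
the only rule that also handles the common fragment-dominated case (a
precursor plus in-source fragments and no adduct relations at all). The
consensus neutral mass is the mean over role-assigned members of the
role-inverted m/z; the max–min spread is reported, and a spread above the
mass tolerance flags a mis-assigned relation. Neutral-loss ladders match
consecutive descending deltas against H₂O (18.01056) and CH₂ (14.01565)
with the relative tolerance evaluated at the upper fragment's m/z, the
scale of the two measurements that form the delta.

This module is a transparent re-implementation of the *logic* of manual
component verification; it is not a vendor-style recursive feature
extractor (no centroiding, no deconvolution of overlapping elution).

## Formula annotation (`pistilmet.annotate`)

Enumeration fixes N, O, P, S, C counts in nested loops and solves the
remaining mass for the hydrogen count, so it is exhaustive over the bounds
by construction (verified against a brute-force oracle in the tests).
Default element bounds are C ≤ 50, H ≤ 100, N ≤ 20, O ≤ 20, P ≤ 4, S ≤ 3 —
generous for metabolites below ~1.5 kDa — with a 10 000-candidate overflow
guard. Filters at enumeration time: nitrogen rule on the neutral form and
RDBE ≥ 0. RDBE 0 is legitimate (fully saturated acyclic molecules), so 0
is not excluded.

Evidence constraints: the largest identified fragment's carbon count is a
lower bound (a fragment cannot out-carbon its precursor) and its
composition minus the transferred proton must embed in the neutral
candidate; the isotope-ratio carbon window applies as above; each H₂O loss
testifies to one oxygen, and one CH₂ step adds one more oxygen by default
because a CH₂ difference between fragments cannot distinguish C-methyl
from O-methyl (configurable via `methyl_oxygen_ambiguity`). Exclusion
reasons form a closed vocabulary (`min-carbon`, `carbon-window`,
`min-oxygen`, `subformula`, `score`) and kept + excluded = initial at every
ledger stage.

The candidate score is an own, documented composite on a 0–100 scale:
`100·exp(−(ppm/3)²/2 − (ΔA1/2)²/2)` with scales of 3 ppm (instrument-level
mass accuracy) and 2 percentage points of isotopologue ratio. It is 100 at
perfect agreement and strictly decreasing in both discrepancies; it is not
a reimplementation of any vendor score, and no score threshold is applied
by default — the score ranks, the constraints exclude. Final selection
ranks kept candidates by (|ppm|, isotope discrepancy, Hill string); the
lexicographic tail makes exact ties deterministic and flagged.

The worked-example precursor is fixed at a measured m/z of 549.3273,
consistent with a +0.7 ppm error on the winning candidate's theoretical
549.3269; two rows of the published candidate table are corrupted as
typeset (one reconstructable as C32H47N4P2 by its RDBE and mass, one not
reconstructable), so tests assert membership of the 16 internally
consistent rows plus the reconstruction rather than a raw candidate count.

## Differential screen (`pistilmet.screen`)

Stage order: intensity floor (max raw abundance ≥ 5×10³ counts) →
internal-standard normalization → frequency filter → monotone filter →
t-test → cross-mode merge. Survivor sets are nested by construction and
the run aborts if nesting is ever violated.

Choices the workflow definition leaves open, and how they were resolved:

* **Missingness.** NaN marks a missing value and is distinct from zero;
  "present" for the frequency filter means non-missing *and* above the raw
  intensity floor. Below-floor values still participate in the t-test —
  they are measurements, just not trustworthy detections.
* **Frequency filter.** A feature qualifies through a genotype when present
  in all 3 replicates of all 4 time points of that genotype; either
  genotype suffices. This keeps genotype-exclusive compounds, which are
  exactly the interesting ones.
* **Monotonicity** is evaluated on replicate means of normalized
  abundances at the ordered time points, strictly (a tie breaks the trend),
  per genotype with either genotype qualifying; the direction per genotype
  is recorded. Strictness plus the t-test keeps the null survivor rate low
  (≈1/6 of exchangeable features pass the monotone filter by chance).
* **t-test.** Default contrast is the final time point (96 h), SC vs SI,
  Student's pooled-variance t on log₁₀ normalized abundances, p < 0.001
  unadjusted, no multiple-testing correction (an optional BH flag exists
  but is off by default to keep the raw-α semantics). Three properties
  drove this default. (i) Log transformation: abundance noise is
  multiplicative, and on the raw scale a 3-vs-3 t statistic is bounded by
  ≈√3/CV regardless of effect size. (ii) Endpoint rather than pooling all
  time points: a compound that diverges progressively has its time trend
  inside the within-group variance under pooling, which caps the
  attainable |t| near 4.6–6 — straddling the p < 0.001 critical value, so
  power would hover near ½ however large the effect. (iii) Pooled variance
  rather than Welch: with triplicates the Welch–Satterthwaite df can drop
  toward 2, where the two-sided 0.001 critical value is 31.6 and the
  nominal level is effectively unattainable; on the log scale the genotype
  variances are comparable by design, which is the regime where the pooled
  test is exact. `pooled` and `per-time` contrasts, Welch, and raw-scale
  testing remain available in `ScreenConfig`.
* **Merging** across ion modes: 10 ppm neutral mass and 0.2 min retention
  time, closest-mass-first for many-to-many ambiguities, profile kept from
  the mode with the higher maximum abundance.

## PCA ranking (`pistilmet.pca`)

PCA is performed on the correlation matrix (compounds standardized), with
compounds as variables and biological samples as observations; squared
cosines are then squared loadings, each compound's cosines sum to 1 over
the full eigensystem, and variance explained sums to 100 %. Factor signs
are oriented so each factor's largest-magnitude loading is positive (the
squared quantities are sign-invariant). Factor assignment is the argmax of
the first *n* squared cosines (ties to the lower factor index, flagged),
reproducing the bold-max reading of a two-factor cosine table. KMO uses
the anti-image partial correlations from the inverse correlation matrix,
with a deterministic pseudo-inverse fallback for singular matrices.

## Synthetic data (`pistilmet.simulate`)

The generator emulates the study conditions: 2 genotypes × 4 time points
(0/3/24/96 h) × 3 replicates per ion mode, ≈4000 positive- and ≈1000
negative-mode null features by default, an internal standard at fixed true
level 10⁵ counts, per-sample injection-scale factors (log-normal, CV 0.10),
replicate noise CV 0.20, and 10 % dropout among nulls. Null base
abundances are 10^N(4.5, 0.6) counts so a realistic fraction sits near the
5×10³ floor. Fifteen planted differential compounds follow two archetypes:
*si-accumulating* (near-absent in SC at ~15 % of the 0 h SI level;
multiplying by a fold of 2–3 per time step in SI only) and *si-decreasing*
(flat in SC; decaying by a per-step fold of 0.35–0.40 in SI). Ten
accumulate and five decrease; five are observable in both ion modes to
exercise merging. Planted 0 h SI levels are kept at least ~2.8× the
intensity floor — a design constraint, since a planted differential that
the workflow's own frequency filter cannot reliably detect would make
"recover the planted set" an incoherent benchmark. Per-step folds of
2–3 (≥ 8-fold over the time course) with CV 0.20 give the endpoint
contrast a deterministic t well above the df = 4 critical value, so
recovery is a design property, not a lucky seed.

Randomness is seeded through `numpy.random.SeedSequence(seed).spawn`, one
child stream each for the positive table, the negative table and the
spectra, so parts can be regenerated independently and the same seed
yields byte-identical CSV output.

**Problem sizes.** The test suite and recovery checks run the identical
pipeline on reduced bundles (300/100 null features for recovery, 100/50
for the 100-seed null-specificity check) — per-feature behaviour does not
depend on how many other null features are present, while the *expected
number* of false discoveries scales linearly with it (each null feature
passes the combined filters with probability ≈ 8×10⁻⁵ at α = 0.001).
"Zero false discoveries" is therefore a statement at the documented
reduced scale; at the full ≈5000-feature default the same pipeline expects
≈0.4 false positives per bundle, which is the honest consequence of an
uncorrected α and would be addressed in practice by the manual-verification
step the screen deliberately leaves to the analyst.

**What the synthetic tests do not show.** The generator draws independent
log-normal features: no correlated biology, no retention-time drift, no
batch structure, no heteroscedastic ionization, no profile-mode peak
shapes, and Gaussian elution with identical widths for all species of a
component. Passing tests demonstrate the pipeline's logic and its designed
operating characteristics under these conditions, not performance on any
real acquisition. Dataset-bound quantities from the motivating study
design (total aligned features, differential counts, explained-variance
percentages, KMO) depend on unavailable raw data and are intentionally not
asserted anywhere; the synthetic defaults only mirror their shape.

## Known limitations

* Positive-mode, singly-charged, even-electron chemistry only; negative
  mode is represented in feature tables but no [M−H]⁻ adduct arithmetic
  beyond neutral-mass bookkeeping is implemented.
* No isotope fine structure; the (A+1) model is first-order and the (A+2)
  channel (S, K) is ignored.
* The co-elution grouper assumes centroided peak lists and resolved
  components; overlapping components at the same retention time merge.
* Candidate enumeration covers CHNOPS; Na/K enter only through adducts.
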