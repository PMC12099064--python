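# Methods

## Problem and scope

Sebaceous tumours (STs) are strongly associated with Lynch syndrome, and
screening them for mismatch-repair (MMR) deficiency is the trigger for
constitutional genetic testing. Two assays measure MMR deficiency:
immunohistochemistry (IHC) of the four MMR proteins (MLH1, PMS2, MSH2,
MSH6), and microsatellite-instability (MSI) analysis, a functional
readout based on insertion–deletion mutations at repetitive loci.
`msipipe` implements the computational half of an amplicon-sequencing MSI
screening analysis: spectrum extraction, a naive-Bayes MSI score with
clinical decision rules, a synthetic-cohort generator, and the exact
statistics used to quantify MSI-versus-IHC concordance. Wet-lab steps,
read alignment of real data, and MMR gene variant interpretation are out
of scope.

## MSI scoring model

Each marker *m* in a panel of 14 microsatellites is summarised by two
features computed from its allele-length spectrum (lengths counted in
repeat units):

- **deletion frequency** `d_m`: the fraction of assigned reads with
  length strictly below a sample-specific reference length;
- **allelic bias** `b_m`: among deletion reads, the proportion carrying
  the single most frequent deleted length (0 when there are no deletion
  reads). Clonal somatic deletions are unimodal; PCR stutter is
  dispersed.

The reference length is the modal observed length when it lies within
±1 unit of the panel reference (tolerating germline length
polymorphism), otherwise the panel reference (so a clonal somatic
deletion cannot redefine the baseline). Modal ties prefer the length
closest to the panel reference, then the longer allele.

The classifier is naive Bayes with independent Beta class-conditionals
per marker, class (MSS, MSI-H) and feature. The sample score is the
natural-log Bayes factor

```
score = prior_log_odds
      + Σ_m [ log f(d_m | MSI-H) − log f(d_m | MSS)
            + log f(b_m | MSI-H) − log f(b_m | MSS) ]
```

Positive scores indicate MSI-high, negative microsatellite-stable.
Markers with zero depth are omitted from the sum (naive Bayes
marginalises over missing evidence). The published description of the
clinical assay fixes the feature basis (deletion frequency and allelic
bias) and the signed-score semantics but not the likelihood family; the
Beta naive-Bayes form used here is this package's own design choice,
matching the additive log-odds behaviour a signed score with a zero
boundary implies.

**Training.** Beta parameters are fitted by the method of moments on
per-sample feature values shrunk into the open interval by
`x → (x·n + 0.5)/(n + 1)` with `n` the class training size; the same
shrinkage (with the stored class `n`) is applied at evaluation time.
When the moment equations have no valid solution (zero or excessive
variance) the fit falls back to the uninformative Beta(1, 1). Densities
are floored at 1e-300 before logs, so no single marker can contribute an
infinite log-ratio; the practical cap is ≈ ±690 per term. Population
(ddof = 0) moments are used. The clinical assay was trained on a
colorectal-cancer cohort that is not distributable; `msipipe` treats the
model as an exchangeable JSON input and trains on synthetic cohorts.

**Decision rules** (defaults mirror the clinical criteria):

- QC: a sample passes when the median per-marker depth is ≥ 100. The
  *lower median* is used for even counts — the conservative choice for a
  pass/fail gate, fixed for reproducibility.
- |score| ≥ band (default 5.0): call by sign.
- |score| < band: a repeat assay is requested. A same-sign repeat
  confirms the call; a conflicting (opposite-sign or exactly zero)
  repeat yields `uncertain` with the reported score set to 0. Without a
  repeat the in-band call is provisional (`needs_repeat` set); a score
  of exactly 0 is `uncertain`.

The ±5 band of the clinical assay lives on that assay's trained score
scale; here the band is a parameter on this package's own natural-log
scale, and all recovery checks use classification semantics rather than
absolute score values. Reproducing the clinical assay's absolute score
medians (e.g. +19.0 / −21.8) is explicitly out of reach without its
training cohort.

## Spectrum extraction

Reads are assigned by exact-substring flank anchoring: the first marker
whose 5′ and 3′ flanks both occur (5′ before 3′) in the read or its
reverse complement claims the read; the repeat length is the number of
complete repeat-unit copies following the 5′ anchor. Partial trailing
units are not counted. This replaces the alignment-based extraction of
the clinical pipeline; it is deterministic and dependency-free, adequate
for synthetic reads, and the scoring layer accepts spectra TSV from any
upstream, so an aligner-based extractor can be swapped in without
touching the classifier. No claim of equivalence with alignment-based
extraction on real, error-containing reads is made.

## Synthetic-data generator

The generator emulates the statistical structure of amplicon MSI data:

| parameter | default | meaning |
|---|---|---|
| `depth_mean` | 2000 | Poisson mean per-marker depth (the assay's nominal ×2000 target) |
| `stutter_rate` | 0.002 /unit | per-unit slippage; a read of template length L deletes ≥1 unit with prob 1−(1−r)^L |
| geometric continuation | 0.5 | given slippage, the deleted size is 1 + Geometric(0.5), capped at the template length |
| `somatic_fraction` | 0.35 | clonal deletion-allele fraction in MSI-H samples (a realistic FFPE tumour fraction) |
| `somatic_del_units` | 3 | size of the clonal deletion |
| `msh6_fraction_multiplier` | 0.35 | attenuation of the somatic fraction in the MSH6-like subclass |
| `marker_dropout_prob` | 0 | per-marker chance of zero depth |

MSS samples have somatic fraction 0 (stutter only); MSH6-like samples
use the MSI-H fraction scaled down, mimicking the attenuated
mononucleotide instability of isolated MSH6 deficiency. Truth records
carry IHC patterns consistent with the class: MSI-H samples draw from
the empirical loss-pattern distribution observed among MMR-deficient
tumours in the reference cohort, MSH6-like samples get isolated MSH6
loss, MSS samples retain all four proteins. Everything is deterministic
given the seed.

The generator deliberately omits base-level sequencing errors in
flanks, insertion stutter, FFPE deamination artefacts and tumour-purity
gradients. Passing recovery checks therefore demonstrates that the
pipeline's logic is correct under the assumed noise model, not that the
classifier would reach the same operating point on real FFPE reads.

## Concordance statistics

The MMR class of a sample derives from its stains with precedence
`uninterpretable → NA`, then `loss → MMRd`, then `equivocal →
equivocal`, else `MMRp` (a clear loss outranks an equivocal stain
elsewhere — MMR function requires all four proteins). Sensitivity is the
MSI-H fraction among conclusive MMRd samples and specificity the MSS
fraction among conclusive MMRp samples; equivocal/NA IHC and uncertain
MSI calls are excluded from those denominators but conserved in the
cross-tabulation.

- **Clopper–Pearson** intervals come from Beta quantiles with the closed
  forms at x = 0 and x = n.
- **Fisher 2×2** uses scipy (probability-≤-observed rule); the odds
  ratio is reported as the conditional MLE of the noncentral
  hypergeometric, with the plain cross-product ratio available
  separately, since the two can differ materially in small tables.
- **Fisher r×c** is computed here by full enumeration of all tables with
  the observed margins (scipy has no exact r×c test), summing
  multivariate-hypergeometric probabilities ≤ the observed probability
  within relative tolerance 1e-7 (guarding float equality). Tables with
  n > 200 are refused outright — no silent asymptotic fallback.
- **Mann–Whitney** uses the exact permutation null when the pooled
  sample is ≤ 12 and tie-free, otherwise the normal approximation with
  tie and continuity corrections. **Kruskal–Wallis** uses the
  chi-squared approximation throughout.
- **ROC AUC** is the Mann–Whitney formulation on midranks, so ties
  contribute exactly 0.5.

## Reference cohort

The package ships the aggregate cross-tabulations of a published
screening study of 107 consecutive sebaceous tumours (staining pattern ×
MSI call; tumour type × IHC class) and expands them into a
deterministic per-sample table. The expansion is synthetic at the sample
level — the within-class linkage of tumour type to staining pattern is
not published — but preserves both published margins exactly, and every
statistic recomputed from it (frequencies, CIs, sensitivity 40/48,
specificity 52/52, loss-pattern fractions, the tumour-type association)
depends only on those margins.

Two documented ambiguities in the published numbers:

- The tumour-type association (p = 4.74 × 10⁻³) is reproduced by the
  3×3 construction (tumour type × {MMRd, equivocal, MMRp}, n = 104, NA
  excluded). The 2×3 MMRd-versus-rest construction gives p ≈ 0.12 and
  cannot be the published test; the 3×3 reading is adopted and flagged
  here rather than silently assumed.
- The published MMRd frequency CI lower bound (37.3%) sits one rounding
  step above the exact Clopper–Pearson value (0.37249 → 37.2%; R's
  `binom.test` agrees). The package reports the computed value.
- The published odds ratio 16.3 for discordance-associated staining is
  not reconstructable from an unambiguous printed table; both OR
  estimators are exposed but no recovery check is tied to that value.

## Problem sizes and runtime

The default end-to-end benchmark simulates 50 MSS / 30 MSI-H / 10
MSH6-like samples at depth 2000 over 14 markers, trains on every second
MSS and MSI-H sample and scores the rest (MSH6-like samples are never
trained on). In-band scores trigger one re-simulated repeat assay. The
benchmark, the reference-cohort statistics and the full oracle suite
(200 exact-test tables, 100 read-emission round trips) together run in a
few seconds on one CPU.

## Known limitations

- Flank anchoring requires exact 12-mer matches; real reads with flank
  sequencing errors would be dropped, biasing depth but not lengths.
- The Beta naive-Bayes likelihood is an assumption, not the clinical
  assay's (unpublished) form; scores are comparable within a trained
  model only.
- Method-of-moments Beta fits on nearly-degenerate features produce very
  concentrated conditionals and hence very large |score|; this is
  harmless for classification but means score magnitudes should not be
  interpreted quantitatively.
- The exact r×c Fisher test is exponential in table size; the n ≤ 200
  budget covers the shipped analyses with a wide margin but is not a
  general-purpose network algorithm.
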