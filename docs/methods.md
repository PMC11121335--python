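# Methods

## Model overview

`ddcm` scores disease–drug pairs by supervised link prediction on similarity
profiles. The modelling assumptions, in order of importance:

1. **Guilt by similarity.** A drug is a plausible therapeutic for a disease
   if it resembles (in target genes/pathways) drugs with known indications,
   and if the disease resembles diseases those drugs treat.
2. **Two-level binary evidence.** Gene-set and pathway-set memberships are
   binary; the two levels carry partially independent signal and are
   combined by an unweighted mean.
3. **Label semantics.** Known associations are positives (label 1);
   non-known pairs are *unlabelled*, treated as negatives (label 0). Scores
   are therefore relative rankings, not calibrated probabilities.
4. **Stability as evidence.** A candidate whose top-50 membership survives
   random deletion of other diseases' training rows is more trustworthy
   than one whose rank depends on a particular training composition.

## Similarity

Binary vectors are compared with the adjusted cosine similarity — the
cosine after centring each vector by its own mean, algebraically the
Pearson correlation of the two vectors and, for binary inputs, the phi
coefficient of the 2×2 membership table. The test suite exploits this
identity as an independent oracle (contingency-table arithmetic vs vector
algebra). Values lie in [−1, 1]; disjoint non-empty sets get *negative*
similarity, which matters downstream (see "Degenerate inputs").

Disease features and drug features live in separate universes built from
the union of observed memberships, ordered lexicographically so every
matrix is bit-reproducible. Cross-kind vectors are never compared.

**Degenerate inputs.** A constant vector (empty or full membership) has
zero centred norm and no defined correlation. Any pair involving one is
assigned similarity 0.0 ("no evidence"), logged; self-pairs are fixed at 1.
For the combined matrix, a pair with exactly one usable level takes that
level's value alone; an entity kind with no pathway data at all degrades to
its gene-level matrix. Nothing ever emits NaN/Inf.

## Hybrid matrix and ε-SVR

Rows are disease–drug pairs, columns the pair's drug similarity to every
drug followed by its disease similarity to every disease. Features are raw
similarities in [−1, 1]; no standardization (the shared ACS scale is the
point of reusing one similarity everywhere).

Training rows are all known pairs plus negatives sampled uniformly without
replacement from non-known combinations (`negative_policy`, default
`matched:1`, i.e. one negative per positive; `all` uses every non-known
pair). The sampler is seeded; row order is deterministic.

The regression is the standard soft-tube linear ε-SVR
(½‖ω‖² + C·Σ slack, ε = 0.1 default). The QP is solved by libsvm's SMO
(scikit-learn `SVR(kernel="linear")`, tol 1e−6), which is deterministic at
fixed inputs. Tests verify the solution against an independent SLSQP solve
of the primal QP (objective agreement ≤ 1e−5 on ≤ 20-row instances) and
against the hand-solvable two-point instance. C is not identifiable from
first principles here; the default is C = 1.0, configurable.

**One global model.** A single model is trained on the full hybrid matrix
and scores every disease. A consequence worth stating plainly: the score of
pair (d, r) decomposes as g(r) + h(d) (drug-block term plus disease-block
term), so the *within-disease ranking of drugs is the same for every
disease*. Disease specificity in the final output comes from the
perturbation stage, whose resampling interacts with each query disease's
training rows differently, and from which drugs survive the stability
cuts. Per-disease models would break the additivity but are a different
method; the global reading is retained.

**De-redundancy.** If a drug ever receives multiple scores for one disease,
the maximum is kept, leaving one row per drug.

## Stability screening

- Per regime j ∈ {1, 2, 5}: M runs (default M = 10; M = 5 in the examples
  and acceptance run to keep a full screen under a minute at desk scale).
  Each run removes j uniformly chosen non-query diseases' rows (positives
  and their sampled negatives) from the fixed training matrix and refits.
  Similarity columns are kept, so the feature layout — and model
  comparability — is preserved across runs.
- Sⱼ = 1 − sample SD (divisor M − 1) of the drug's M binary top-50
  indicators. The alternative 1 − variance reading is available as
  `stability_variant="variance"`; SD is the default because it keeps scores
  in the interpretable upper band.
- A drug absent from *every* run of a regime also gets Sⱼ = 1 (zero
  spread); such drugs are ineligible for that regime's stable set —
  otherwise never-seen drugs would pass the filter.
- "Top 95 %" keeps the top ⌈0.95 n⌉ of the ranked eligible drugs; ties at
  the cut are retained. With fewer than 20 ranked drugs the ceiling means
  nobody is cut — intended behaviour, not a bug.
- Total stability uses M′ = 3M + 1 indicators: all perturbed runs plus the
  unperturbed prediction, whose indicator is DrC membership.
- RNG discipline: one master seed spawns one substream per regime
  (`numpy.random.SeedSequence`), so regimes are independently reproducible
  and two runs at one seed are byte-identical on disk.

A saturation property used in testing: when the number of drugs does not
exceed k, every drug is in every run's top-k, all indicators are 1, and
PtDr = SDrC = DrC for any M — a fixture in which the perturbation stage is
provably inert. (A fixture of mutually feature-disjoint diseases does *not*
freeze the scores: removing training rows changes the fitted weights, and
disjoint binary sets have negative, not zero, ACS.)

## Synthetic benchmark

The generator emulates the structure the method relies on: disease clusters
sharing core gene/pathway pools, therapeutic drugs whose target sets
overlap their disease's genes, and a partially observed association table
(`observed_fraction` of the truth is revealed; the rest is the held-out
recovery target, written to files the dataset manifest never references).

Defaults (chosen once as field-realistic, desk-scale): 20 diseases,
100 drugs, 500 genes, 120 pathways, 4 clusters; 12 genes and 8 pathways
per disease (compact curated-panel scale); 15 targets and 10 pathways per
drug; 3 true therapeutic drugs per disease; within-cluster overlap 0.6;
therapeutic target overlap 0.6; observed fraction 0.7; feature-noise rate
0.02 (probability a planted feature is replaced by a random one). The
compact panels matter: they make the planted drug–drug ACS between
same-disease therapeutics ≈ 0.3–0.4, strong enough for a *linear* model to
transfer (with large panels the pairwise overlap dilutes quadratically and
the planted signal, though present for a nonlinear ranker, is invisible to
the model class).

What the generator does **not** emulate: ontology-structured vocabularies,
multi-indication drugs, drug chemistry, dose, or the long-tailed set-size
distributions of real curation. Passing recovery tests show the pipeline
detects the planted similarity structure; they do not certify performance
on real DrugBank/CTD-scale data.

## Evaluation

Holdout recovery uses the Mann–Whitney AUC (ties half-credit), with two
guards whose necessity was established during design calibration:

- **Global known-drug exclusion.** Every drug with any known association
  has its own similarity column in the model's feature space, so its score
  is inflated by its training label wherever it is queried. Ranking metrics
  therefore exclude all known drugs, not just the query disease's. Held-out
  positives (never observed in training) survive the exclusion by
  construction.
- **Within-disease stratification with dataset-level permutation.** Because
  scores decompose additively, cross-disease score pooling is biased by the
  per-disease offsets; the pooled AUC combines only within-disease
  comparisons (weights n_pos·n_neg). And because all strata of one dataset
  reuse the same global drug ranking, they are dependent: the permutation
  null permutes the drug–score assignment once per dataset, consistently
  across its strata, rather than shuffling labels independently per
  stratum (which would understate the null variance roughly by a factor
  √#strata).

With the default benchmark the pooled held-out AUC is ≈ 0.62–0.65 against
a ±3 SE permutation band of roughly [0.45, 0.56], and the no-signal
generator stays inside the band — numbers the acceptance script recomputes
on every run.

## Known limitations

- The additive global model cannot express disease-specific drug rankings;
  its ceiling on the benchmark (ideal linear weighting of the same
  features) is well below what a max-similarity heuristic achieves (~0.85
  AUC), so the reported AUC reflects the method, not the benchmark's
  difficulty ceiling.
- C, the negative-sampling ratio, and M are not identified by the method's
  description; defaults are documented above and surfaced in configuration.
- With fewer than ~20 eligible drugs the 95 % cuts pass everyone (ceiling
  effect); screening output is only discriminative at realistic drug-list
  sizes.
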