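# Methods

This note documents the models implemented in `thermocomb`, their default
parameters, the synthetic generators the tests run against, and the design
choices made where reasonable alternatives existed.

## Variant algebra

A variant is a set of single-site substitutions with pairwise-distinct
1-based positions, written position-sorted and slash-joined (`L6P/D17V`);
`WT` is the empty set. Numbering refers to the supplied wild-type sequence
exactly as given — no signal-peptide or construct-offset logic. Each token's
expected residue is validated against the sequence and mismatches are
reported as errors rather than resolved by guessing offsets.

Enumeration of the combinatorial space of n candidate singles is a lazy
stream (subsets are yielded, never materialized en masse), ordered by
mutation count and then lexicographically by position tuple, which is the
canonical order for variants of a single protein. The default cap is n = 24
(2^24 ≈ 16.8 M subsets); n = 18 (262,144 variants) enumerates in well under
a second.

## Sequence representation and prediction heads

The predictor consumes a per-residue representation matrix (L × D) mean-pooled
to one D-vector per variant. Three interchangeable backends implement the
representation contract:

* **one-hot** (D = 20) — the default desk-scale surrogate;
* **trainable token embedding** (D configurable, default 64) — a 20 × D table
  learned jointly with the head when `finetune_encoder=True`;
* **precomputed** — variant-keyed L × D matrices from a `.npz` archive, the
  drop-in slot for real protein-language-model embeddings (e.g. L × 1280).

A caveat worth stating plainly: mean pooling of any *context-free* per-token
representation collapses to amino-acid composition. Two candidate mutations
with identical (wild-type, mutant) residue pairs at different positions are
therefore indistinguishable to the surrogate backends. The synthetic
candidate generator gives every site a distinct wild-type residue (n ≤ 18 ≤ 20
letters), which mirrors real candidate panels, where the singles have distinct
identities; positional information beyond composition only enters through the
precomputed backend. Passing surrogate-backend tests consequently
demonstrates that the *pipeline machinery* (training, scoring, selection,
bookkeeping) is correct, not that composition features suffice for real
proteins.

The head is a small MLP: one hidden layer (default width 128), Tanh
activation, dropout (default 0.1), linear scalar output. Training is
mini-batch Adam, implemented directly in numpy (the head is a few thousand
parameters; no autodiff framework is needed):

* regression task — MSE on z-normalized Tm labels (°C), de-normalized at
  prediction time;
* discriminant task — binary cross-entropy on the label
  `relative_activity > threshold` with a strict inequality; the default
  threshold is 60 % of wild type, and the predicted probability is returned
  alongside the ≥ 0.5 flag.

Defaults follow the published fine-tuning recipe: learning rate 1e-5, batch
size 4, at most 200 epochs, early stop when the monitored loss has not
improved for 10 epochs. Early stopping monitors a seeded 10 % validation
split when at least 20 labeled records are available, falling back to the
training loss for smaller datasets (tiny panels would otherwise lose too much
signal to the split). The best-epoch parameters are restored. One seeded
generator drives initialization, the split, shuffling and dropout, so runs
are bit-for-bit reproducible.

The 1e-5 learning rate is appropriate for pretrained-PLM-scale features; the
desk-scale recovery runs in the tests and acceptance script pass an explicit
`learning_rate=0.01` (0.02 for the pure linear head) because one-hot
composition features are small (O(1/L)) and a 200-epoch budget at 1e-5 barely
moves the weights. These rates were fixed as part of the study conditions,
not tuned per test.

Whether both heads should share one encoder state is left open by the
architecture; they are trained independently by default.

## Design loop

One round: fit both heads on all accumulated labels → score every variant in
the space → apply the activity gate as a hard filter *before* ranking →
select a batch → query the measurement oracle → append. Selection is either

* **stratified**: the top `quota` acceptable variants per mutation count over
  a stated order range — the default reading of "top performers among 5–9-
  mutation variants" is an equal quota (5 × 5 = 25), configurable; or
* **flat**: the global top `batch_size` of the acceptable ranking.

Ties on equal predicted score break toward fewer mutations, then the
canonical string, making the ranking a total order. Selected sets are
disjoint across rounds and from all training data. The number of rounds is a
user parameter; as a stopping diagnostic the engine reports the change in
median predicted score of the selected batch between rounds. Shipped oracles:
the synthetic-landscape oracle (truth + seeded noise) and a CSV round-trip
stub that writes a measurement-request table and reads answers back.

## Epistasis

All statistics operate on measured labels only (replicates averaged); missing
intermediate variants make an observation "not evaluable" — they are reported,
never imputed from model predictions.

* Background effect of a mutation set M in background B:
  Δ = y(B ∪ M) − y(B), over every background pair the dataset contains.
* Deviation from additivity of a set S in background B:
  ε = y(B ∪ S) − [y(B) + Σ_m (y(B ∪ {m}) − y(B))].
* A mutation is **sign-epistatic** when some background effect exceeds +δ and
  another falls below −δ.
* A pair is **synergistic** when ε in the wild-type background exceeds +δ.

δ defaults to 0.3 °C, the scale of replicate SDs in typical Tm measurements.
Note the error propagation: a background effect carries √2 × the label noise,
and the pairwise ε carries 2 × the label noise, so at label noise 0.1 °C a
δ of 0.3 °C is 3σ for single labels but only ~1.5σ for ε. Sign-epistasis
calls on pre-screened candidate panels (single effects ≥ 0.5 °C in magnitude)
are then essentially free of false positives, while pair calls at the default
δ retain a per-pair false-positive rate of a few percent; for conservative
synergy screens use δ ≥ 3 × (2 × label SD) or replicate-averaged labels.

## Assay fits

All fitters are deterministic given the data and the documented
initialization rules; convergence failures are flagged, never clipped.
Temperatures are °C at every interface, converted to K only inside
thermodynamic formulas (R = 8.3145 J mol⁻¹ K⁻¹).

* **Boltzmann melt** — y(T) = y_lo + (y_hi − y_lo)/(1 + exp((Tm − T)/a));
  Tm is the inflection, a > 0 the transition width. Initialization: Tm at the
  maximum |dy/dT| (finite differences), a = 2 °C, plateaus from the first and
  last signal deciles. Descending curves (residual activity vs temperature,
  T50^15) fit the same form with the plateau roles reversed. DSF curves often
  decline past the unfolding peak (dye dissociation), so for the `dsf`
  modality only points up to the global signal maximum are fitted
  (configurable). A fit is attempted only when the signal span exceeds 5 ×
  the point-to-point noise estimate.
* **CD unfolding fraction** — fu(T) = (CD_T − CD_min)/(CD_max − CD_min) × 100 %;
  Tm may then be read from the sigmoid fit of fu.
* **DSC two-state** — excess heat capacity
  Cp(T) = ΔH² K / (R T² (1+K)²), K = exp(−(ΔH/R)(1/T − 1/Tm)), plus a linear
  baseline. The van 't Hoff ΔH comes from the peak shape; the calorimetric ΔH
  is reported alongside as the baseline-subtracted trapezoidal peak integral.
  Vendor "two-state scaled" fits are proprietary; this is the closest
  published functional form. Multi-peak thermograms are flagged and the best
  single-peak fit returned with a warning.
* **First-order inactivation** — k is the slope of the least-squares line
  through the origin of ln(Ar/A0) vs t (the t = 0 point is exact by
  construction, so the regression is unweighted and origin-constrained);
  t½ = −ln 2 / k, valid only for k < 0. Non-positive activities are dropped
  with a warning before the log transform. The incubation temperature is
  carried as metadata only.
* **Michaelis–Menten** — nonlinear least squares of v = Vmax·S/(Km + S);
  kcat = Vmax/[E] when an enzyme concentration is supplied. Km beyond 10 ×
  the largest substrate level is flagged as extrapolation.

## Ensemble dynamics

Fluctuation analysis requires prior superposition: every frame is rigid-body
aligned (Kabsch, optimal rotation + translation) in a two-pass scheme — align
to frame 0, recompute the mean structure, realign to the mean. RMSF_i is the
RMS deviation of atom i about its ensemble mean; Rg uses uniform masses by
default (Cα selections make mass weighting negligible) with optional mass
weights. The DCCM is

    C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),

computed on the selection (Cα by default for PDB input); replicate
trajectories are combined by element-wise averaging of per-replicate
correlation matrices, not by pooling frames. Zero-variance atoms produce
flagged (NaN) entries rather than silent zeros. Region summaries report
mean/min/max over the cross-block of two 1-based inclusive residue ranges;
which regions to inspect is user input, not auto-detected. ΔRMSF is
(variant − WT)/WT per residue by default (the plain difference is available),
negative meaning locally stabilized.

Readers: multi-model PDB (via biotite) and a minimal XYZ trajectory parser
(the standard trajectory readers require topology objects; only coordinates
are needed here).

## Synthetic generators

Every generator is a pure function of (spec, seed); regeneration is
bit-identical, and exact truth is available for every variant, so recovery
tests compare against values the tested code path never sees.

**Tm landscape.** Tm(v) = Tm_WT + Σ additive + Σ pairwise + Σ third-order,
plus a sign-epistasis term. The study-like default (`creatinase_like_spec`):
Tm_WT = 59.53 °C; 18 sites with 4 deleterious singles and 4 singles above
+1 °C (the published panel's statistics), the rest mildly beneficial; one
sign-epistatic site (−0.9 °C alone, +2.0 °C once ≥ 3 of its 5 partner sites
are present — deleterious in the wild type, beneficial in multi-mutation
backgrounds); one synergistic pair (+1.5 °C beyond additivity). Measurement
noise SD 0.3 °C on Tm (replicate scale) and 2 % on activity; relative
activity declines 2.5 % per mutation. The structure scales down (the 12-site
variant used for exhaustive-truth campaign tests keeps all planted features).
The initial dataset sampler draws 18/22/21/12 variants of orders 1–4 (73
records, 74 with the optional wild-type row — both conventions appear in
study reporting, so WT inclusion is an explicit flag).

**Additive controls** for false-positive tests draw coefficient magnitudes
uniformly from [0.5, 2.0] with random sign: mutations entering a combination
campaign are pre-screened for a measurable single effect, so near-zero
coefficients are not representative.

**Assay curves** are generated from the exact model each fitter assumes, at
study-scale parameter values by default (e.g. Tm 59.53 °C, ΔH 614.5 kJ/mol,
t½ 1.60 min, Km 10.46 mM for the wild type). Noise is additive (fraction of
amplitude — detector noise) for optical/calorimetric modalities and
multiplicative (constant CV — the standard error structure of coupled
enzymatic activity assays) for inactivation and kinetics series; the
multiplicative model also keeps rates positive and the log-linear decay fit
unbiased. Default noise 2 % where noise is requested.

**Correlated ensembles** sample per-axis displacements from N(0, Σ) about a
Cα-like mean chain, with the same N × N covariance Σ on each axis, so the
analytic displacement-vector correlation is Σ_ij/√(Σ_ii Σ_jj); that matrix is
returned with the ensemble. At 5,000 frames the empirical DCCM matches the
analytic one within 0.05 element-wise.

What the generators deliberately do *not* emulate: structure-based
energetics, sequence-composition realism beyond the wild-type string,
correlated measurement errors between variants, and activity landscapes with
epistasis of their own. Results on synthetic data validate the machinery and
the estimators, not the transferability of surrogate features to real
proteins.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use: 2^18 enumeration (counting
only); a 10-site additive landscape (60 train / 200 held-out, plus 100
training points for linear-head coefficient recovery); a 12-site study-like
landscape (4,096 variants, exhaustive truth) for the two-round batch-25
campaign; a full 18-site campaign for round bookkeeping (74 + 25 = 99
training records in round 2); 50-replicate Monte-Carlo suites per fitter at
2 % noise; 100 additive control landscapes for false-positive counting; and
5,000-frame ensembles of 12 atoms for the DCCM oracle. Label z-normalization
uses the training-set mean/SD (SD floor of 1 for degenerate constant labels).
Dropout is disabled at inference. Boltzmann fits bound Tm within the observed
temperature range ± 5 °C and the width to the observed span; the DSC fit
bounds ΔH to [1, 10^5] kJ/mol.

## Known limitations

* Surrogate backends are composition-level; see the representation caveat.
* The discriminant head calibrates a probability but no uncertainty beyond it.
* DSC fitting assumes a single two-state transition; multi-transition
  deconvolution is out of scope (flagged, not modeled).
* Synergy calls at the default δ are anti-conservative (see the epistasis
  error propagation note).
* No global-epistasis/nonlinearity-removal models or Walsh–Hadamard
  decomposition; these are natural extensions of the landscape machinery.
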