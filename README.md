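# thermocomb

Machine-learning-guided combination of stabilizing point mutations for enzyme
thermostability engineering.

## The problem

Rational design and consensus methods are good at finding *single* point
mutations that raise an enzyme's melting temperature (Tm), but combining many
of them is treacherous: epistatic interactions mean the effect of a mutation
can change magnitude — or sign — depending on which other mutations are
present, and naive stacking frequently inactivates the protein. The
alternative to exhaustive wet-lab screening of a 2^n combinatorial library is
to train a sequence-based predictor on a modest labeled panel and let it rank
the whole library, measuring only small batches per round.

`thermocomb` implements that loop end to end for a creatinase-style campaign
(n = 18 candidate singles, 2^18 = 262,144 combinatorial variants):

1. **Variant algebra** — parse/apply `"L6P/D17V"`-style mutation sets against
   a wild-type FASTA and lazily enumerate the combinatorial space.
2. **Predictors** — a pooled sequence representation (one-hot, trainable
   token embedding, or precomputed protein-language-model matrices) feeding a
   small MLP head (hidden layer, Tanh, dropout), trained with Adam:
   MSE regression for Tm and a binary cross-entropy discriminant for the
   "relative activity > 60 % of wild type" acceptability gate.
3. **Design loop** — score all 2^n variants, hard-filter by predicted
   acceptability, select a batch (stratified top performers among 5–9-mutation
   variants in round 1, flat top 25 in round 2), measure, retrain.
4. **Epistasis analysis** — background-dependent effects
   Δy = y(B ∪ M) − y(B), deviation from additivity
   ε = y(B ∪ S) − [y(B) + Σ_m (y(B ∪ {m}) − y(B))], sign-epistasis and
   synergistic-pair calls, and mutation frequencies across design rounds.
5. **Assay fits** — Boltzmann sigmoid melts (DSF/CD/T50^15),
   two-state van 't Hoff DSC thermograms (Tm, ΔH), first-order thermal
   inactivation (t½ = −ln 2 / k, k·t = ln(Ar/A0)), and Michaelis–Menten
   kinetics (Km, kcat).
6. **Ensemble dynamics** — Kabsch superposition, RMSF, radius of gyration,
   dynamics cross-correlation matrices
   C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with replicate averaging,
   region-block summaries, and variant-vs-WT ΔRMSF maps.
7. **Synthetic data** — seeded generators with exact ground truth for all of
   the above, including a study-like epistatic Tm landscape with a planted
   sign-epistatic site and synergistic pair.

## Worked example

An in-silico two-round campaign against a 12-site study-like landscape
(4,096 variants, exhaustive truth known):

```python
import thermocomb as tc
from thermocomb.synthetic import default_initial_counts

ls = tc.generate_landscape(tc.creatinase_like_spec(n_sites=12))
initial = tc.sample_initial_dataset(ls, counts=default_initial_counts(12), seed=5)
oracle = tc.LandscapeOracle(ls, seed=6)
cfg = tc.HeadConfig(learning_rate=0.01, max_epochs=300, patience=30, seed=0)
policies = [
    tc.SelectionPolicy(batch_size=25, stratify_by_order=True, orders=(5, 6, 7, 8, 9)),
    tc.SelectionPolicy(batch_size=25),
]
rounds = tc.run_campaign(initial, ls.candidates, oracle, 2, cfg,
                         policies=policies, seed=0)
for r in rounds:
    print(f"round {r.round_index}: trained on {r.training_size} records, "
          f"best measured Tm {r.best_measured_tm:.2f} degC")
opt_v, opt_tm = ls.optimum()
print(f"wild-type Tm {ls.spec.wt_tm:.2f} degC; global optimum {opt_tm:.2f} degC ({opt_v})")
```

prints

```
round 1: trained on 68 records, best measured Tm 68.91 degC
round 2: trained on 93 records, best measured Tm 69.69 degC
wild-type Tm 59.53 degC; global optimum 69.63 degC (A3Q/F15V/H18W/I21Y/K24A/L27C/M30D/N33E/P36F)
```

Starting from labels on nothing above quadruple mutants, round 1 (stratified
over 5–9-mutation variants) reaches within 1.1 °C of the global optimum and
round 2 (flat top 25) finds it — a ~10 °C gain over the wild type, with the
planted synergistic pair's frequency among selections rising round over round.

Fitting a melt curve works the same way from arrays or the long-format CSV:

```python
from thermocomb.synthetic import generate_assay_curves
df, _ = generate_assay_curves("dsf", params={"tm": 69.72}, noise=0.02, seed=3)
fit = tc.fit_boltzmann_sigmoid(df["x"], df["y"], modality="dsf")
print(fit.summary())
```

```
Boltzmann melt fit (dsf, n=110)
  Tm        = 69.78 degC
  slope a   = 1.245 degC
  plateaus  = -0.001277 (low T) / 1.009 (high T)
  resid SD  = 0.02082
  converged = True
```

The same functionality is exposed on the command line:

```bash
thermocomb simulate --out-dir data --n-sites 18 --seed 0
thermocomb finetune --labels data/labels.csv --fasta data/wild_type.fasta \
    --task regression --out tm_head.json
thermocomb campaign --n-sites 12 --rounds 2 --seed 0
```

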