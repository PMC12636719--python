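# caremil

Attention-based multiple-instance learning (MIL) for slide-level diagnosis
of hematologic malignancies from bags of per-cell embeddings.

A peripheral-blood-smear slide yields hundreds to thousands of white-blood-
cell images; a frozen single-cell encoder turns each into a feature vector,
and only the slide carries a diagnosis label (acute leukemia, MDS, hairy
cell leukemia, normal). `caremil` implements:

* **CAREMIL** — per-cell transforms whose bag-level summary statistics
  (mean, variance, optional power means) act as *class tokens* in a single
  multi-head self-attention layer over the sequence
  `[K class tokens ; N cell tokens]`; the post-attention class tokens feed
  an MLP classifier. Logits are invariant to cell order; per-cell attention
  scores are equivariant. Formally, with aggregator and parallel networks
  f_a, f_p : R^D → R^H,

      tokens = [mean(f_a(X)), var(f_a(X)), ...]            (K × H)
      out    = SelfAttention([tokens ; f_p(X)])            ((K+N) × H)
      logits = MLP(concat(out[1..K]))

* the **gated-attention MIL** baseline (softmax over
  `w·(tanh(Vh) ⊙ σ(Uh))`, weighted-sum bag vector),
* a **cytometry baseline** (logistic regression on the blood differential),
* training (cross-entropy, Adam, validation-AUROC model selection),
  evaluation (per-task AUROC, sensitivity by circulating-blast bin),
* **explainability**: per-cell attention ranking, top/random/bottom review
  panels, top-fraction cell-type enrichment (per-type 2×2 chi-squared with
  Bonferroni correction, log-odds for rare types), and overlap of
  high-attention cells with known diagnostic cells,
* a **synthetic cohort generator** (cell-type prototype clusters with
  controllable composition-only / morphology-only / combined disease
  signals) and a **synthetic-patient blast-dilution engine** for
  limit-of-detection studies.

The networks run on a small built-in reverse-mode autodiff engine over
numpy; no GPU or deep-learning framework is required. See
[docs/methods.md](docs/methods.md) for the model, statistics, generator
assumptions, and design decisions.

## Worked example

```python
import numpy as np
import caremil as cm

# disease-vs-normal cohort with a morphology-only signal: the blood
# differential is identical in both classes; 5-15% of cells in disease
# slides are a morphologically shifted lymphocyte sub-population
cfg = cm.two_class_config("morphology", n_patients=(25, 25),
                          n_cells_mean=250, D=32, seed=11)
records = cm.generate_cohort(cfg)
split = cm.split_by_patient(records, (0.6, 0.2, 0.2), seed=111,
                            stratify_by_label=True)
task = cm.TaskSpec("al_vs_nl", ("NL", "AL"))

model_cfg = cm.CaremilConfig(D=32, H=32, n_heads=4, n_classes=2, seed=7,
                             aggregator_hidden=(32,), parallel_hidden=(32,),
                             mlp_hidden=(32,))
train_cfg = cm.TrainConfig(epochs=60, learning_rate=3e-3, seed=7,
                           early_stop_patience=15)
model, history = cm.train_model("caremil", split, task, train_cfg,
                                model_config=model_cfg)
print("test AUROC:", cm.evaluate_auroc(model, split.test, task)["macro"])

# count-only comparator on the same cohort
_, cyt = cm.cytometry_baseline(split, task, list(cfg.vocabulary))
print("cytometry AUROC:", cyt["macro"])

# attention enrichment on a correctly classified disease slide
rec = next(r for r in split.test if r.label == "AL")
_, report = cm.forward(model, rec.bag)
table = cm.enrichment_table([(report, rec.bag.cell_types)], 0.10,
                            list(cfg.vocabulary))
print(table.table[["cell_type", "ratio", "significant_bonferroni"]])
```

Output (abridged):

```
test AUROC: 1.0
cytometry AUROC: 0.4
              cell_type     ratio  significant_bonferroni
0  segmented_neutrophil  0.000000                    True
2            lymphocyte  2.659091                    True
...
```

The MIL model separates the classes perfectly while the count-only
baseline is at chance — the differential carries no signal. The top-10%
attention cells of this slide are 2.7× enriched for the planted marker
type (the shifted lymphocyte sub-population) and significantly depleted
of neutrophils: the model is looking at the right cells.

## Command line

```bash
caremil simulate --out cohort --seed 1
caremil split    --manifest cohort/manifest.csv --out splits --stratify --seed 1
caremil train    --arch caremil --task al_vs_nl --manifest cohort/manifest.csv \
                 --split splits/split.json --out run --seed 1
caremil evaluate --checkpoint run/checkpoint.npz --manifest cohort/manifest.csv \
                 --task al_vs_nl --out eval --seed 1
caremil explain  --checkpoint run/checkpoint.npz --manifest cohort/manifest.csv \
                 --fraction 0.10 --out explain --seed 1
caremil lod      --checkpoint run/checkpoint.npz --manifest cohort/manifest.csv \
                 --reps 30 --out lod --seed 1
```

Cohorts are exchanged as a CSV manifest (`slide_id, patient_id, label,
blast_fraction, embedding_file`) plus one CSV matrix per slide
(`dim_0..dim_{D-1}` columns, optional `cell_type` / `cell_ref` columns).
Every command writes a `run.json` with the config snapshot, derived seeds
and input checksums.

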