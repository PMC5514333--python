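# gomultiloc

Multilabel prediction of protein subcellular localization from Gene
Ontology (GO) annotations, aimed at proteins — such as apoptosis
proteins — that reside in more than one compartment at once. Classic
localization predictors assign exactly one compartment per protein;
`gomultiloc` treats localization as a multilabel problem and predicts a
*set* of compartments per protein.

## Method

**Feature encoding.** A query protein P is represented by the GO
annotations of its closest BLAST homolog(s) (homology transfer; the
protein's own annotations are the fallback when its homologs carry no
terms). Given the cohort's *GO subspace* — the ordered set of ω distinct
GO terms observed across all training proteins — P becomes an
occurrence-count vector

    P = (f₁, f₂, …, f_ω)ᵀ,   f_μ = g_μ (count of GO term μ), else 0.

**Label-specific feature selection.** For each of the c compartments
λᵢ, the ±1 label column **Y**ᵢ is correlated with every feature column
**f**_μ by Pearson's r,

    r(f_μ, Yᵢ) = Σₖ (f_{k,μ} − f̄_μ)(y_{k,i} − Ȳᵢ) /
                 √( Σₖ (f_{k,μ} − f̄_μ)² · Σₖ (y_{k,i} − Ȳᵢ)² ),

features are ranked by |r|, and the top-Kᵢ prefix becomes the
*label-specific* feature set for λᵢ (Kᵢ per label, chosen by inner
cross-validation by default).

**Classification.** Binary relevance: one binary classifier (linear SVM
by default) per compartment, trained on the positive set 𝕋⁺(i) of
proteins located in λᵢ against everyone else, each seeing only its own
label-specific features. A query's predicted set Z collects the labels
scoring positive; if none do, the best-scoring label is assigned so
predictions are never empty.

**Evaluation.** Example-based multilabel metrics over m test proteins
with true sets Yᵢ and predicted sets Zᵢ:
mlACC (mean Jaccard |Y∩Z|/|Y∪Z|), mlPRE (|Y∩Z|/|Z|), mlREC (|Y∩Z|/|Y|),
mlF1 (harmonic mean of mlPRE and mlREC) and ACC (exact-match rate),
under leave-one-out (jackknife) cross-validation.

A seeded synthetic generator emulates a GO-like benchmark — sparse
Poisson term counts, a realistic location-count profile, per-compartment
planted signal terms — and writes matching GAF / BLAST-tabular / labels
fixture files, so the whole pipeline is testable without any database
access. See `docs/methods.md` for modelling details and limitations.

## Worked example

```python
from gomultiloc import SyntheticConfig, generate, jackknife
from gomultiloc.model import BinaryRelevanceModel

truth = generate(SyntheticConfig(n=200, c=4, omega=100, s=5, seed=0))
results = BinaryRelevanceModel(truth.dataset).fit()
print(results.summary())
report = jackknife(truth.dataset, selection_mode="global")
print(report.summary())
```

prints

```
Binary-relevance GO localization model
  proteins: 200   GO features (omega): 100   labels: 4
  base learner: SVC   K policy: InnerCVK(fractions=(0.1, 0.2, 0.3, 0.4, 0.5), n_splits=3, fallback_fraction=0.3)

  label                    n_pos     K   max|r|  train_err
  cytoplasm                   81    10    0.786     0.0000
  membrane                    74    40    0.813     0.0000
  secreted                    82    10    0.776     0.0000
  mitochondrion               78    10    0.817     0.0000

Example-based multilabel metrics over m=200 samples
  mlACC              99.46 %
  mlPRE              99.58 %
  mlREC              99.88 %
  mlF1               99.73 %
  mlF1_per_sample    99.66 %
  ACC                98.50 %
```

The fit summary shows, per compartment, how many proteins carry it
(`n_pos`), how many GO features its classifier keeps (`K`, chosen by
inner cross-validation — e.g. 10 of 100 for cytoplasm, which has 5
planted signal terms), and the strongest feature–label correlation
found. The jackknife report then says that 98.5% of the 200 held-out
proteins had their location set predicted *exactly* (ACC), while the
per-protein Jaccard overlap between true and predicted sets averages
99.46% (mlACC). ACC ≤ mlACC ≤ min(mlPRE, mlREC) always holds.

The same pipeline is scriptable from the shell:

```sh
gomultiloc simulate --seed 0 --out-dir sim/ --n 200 --c 4 --omega 100 --s 5
gomultiloc train    --gaf sim/annotations.gaf --blast sim/homologs.blast.tsv \
                    --labels sim/labels.tsv --model model.joblib
gomultiloc evaluate --gaf sim/annotations.gaf --blast sim/homologs.blast.tsv \
                    --labels sim/labels.tsv --out-dir eval/
```

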