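# cwqsar

Descriptor-free QSAR models built directly from SMILES strings, for
modelers who want an endpoint model (for example hERG-blocking potency,
pIC50, or a binary toxic/non-toxic call) without computing any molecular
descriptors.

## The model

A molecule's SMILES string is decomposed into local attributes:

- **Sk** — single tokens, where multi-character units (`Cl`, `Br`, `@@`,
  `%NN` ring closures, bracket atoms `[...]`) count as one token;
- **SSk / SSSk** — adjacent token pairs and triples, canonicalized so the
  reversed string gives the same attributes;
- **FLS** — fragments of local symmetry: windows XYX, XYYX, XYZYX with
  X ≠ Y (and Y ≠ Z);
- **APP** — atom-pair proportions: the discretized count ratio of each
  pair of element tokens present.

Each attribute *k* carries a correlation weight CW(*k*); the optimal
descriptor of a molecule is

    DCW(T, N) = Σ CW(Sk) + Σ CW(SSk) + Σ CW(SSSk) + Σ CW(FLS) + Σ CW(APP)

over its non-blocked attributes (an attribute is blocked when it occurs
fewer than T times in the active training set).  The endpoint model is the
univariate regression

    y = C0 + C1 · DCW(T, N)

used directly for continuous endpoints, or — for 0/1 endpoints — as a
*semi-correlation* classifier calling a molecule active when y ≥ 0.5.

The weights are tuned by a seeded Monte Carlo coordinate search over N
epochs that maximizes one of two target functions on a four-way data split
(active training A, passive training P, calibration C, validation V):

    T1 = RA + RP − |RA − RP|·F1 + (IIC + CII)·F2
    T2 = T1 + CCCP·F3            (F1 = F2 = 0.5, F3 = 0.3)

RA, RP are Pearson correlations on A and P.  The calibration-set criteria
reward correlation *quality*: IIC (index of ideality of correlation)
penalizes asymmetry between the mean absolute errors of over- and
under-predicted molecules; CII (correlation intensity index) and CCCP
(coefficient of conformism of a correlative prediction) are built from the
leave-one-out influence of each molecule on the correlation — molecules
whose removal raises r are *opponents*, those whose removal lowers it are
*supporters*; CII = 1 − Σ(opponent influence), CCCP = 1 − opponent/supporter
influence ratio.  The validation set is never read during training.

Supporting machinery: per-attribute statistical defects across A/P/C
(Eq.-style prevalence dissimilarity) define an applicability domain
(a molecule is in-domain when its summed defect is below twice the
training mean), and a Las Vegas search draws random splits, probes each
with a short optimization, and keeps the split with the best calibration
R².  A synthetic-data module generates grammar-constrained random SMILES
with endpoints linear in token counts plus Gaussian noise, so the whole
pipeline is testable with known ground truth.

## Worked example

```python
from cwqsar import (GeneratorConfig, generate_dataset, random_split,
                    optimize, TargetConfig, extract_attributes,
                    regression_stats)
import numpy as np

df = generate_dataset(GeneratorConfig(n=200, noise_sd=0.3, seed=1))
ids = df["id"].tolist()
labels = random_split(ids, seed=1001).labels_for(ids)
y = df["endpoint"].to_numpy()

state, trace = optimize(df["smiles"].tolist(), y, labels,
                        target=TargetConfig(variant="T2"),
                        epochs=30, seed=1)

bags = [extract_attributes(s) for s in df["smiles"]]
pred = np.array([state.predict(b) for b in bags])
for subset in "APCV":
    idx = [i for i, lab in enumerate(labels) if lab == subset]
    st = regression_stats(y[idx], pred[idx])
    print(f"{subset}: n={st.n} R2={st.r2:.3f} CCC={st.ccc:.3f} "
          f"CII={st.cii:.3f} CCCP={st.cccp:.3f} RMSE={st.rmse:.3f}")
```

prints

```
A: n=50 R2=0.889 CCC=0.940 CII=0.961 CCCP=0.021 RMSE=0.423
P: n=50 R2=0.887 CCC=0.934 CII=0.966 CCCP=0.025 RMSE=0.435
C: n=50 R2=0.928 CCC=0.929 CII=0.976 CCCP=0.060 RMSE=0.632
V: n=50 R2=0.808 CCC=0.874 CII=0.932 CCCP=0.073 RMSE=0.596
```

The calibration set — where the maturing model's criteria were optimized —
fits best; the validation set, never seen in training, measures real
predictive power.  CCCP contrasts the leave-one-out influence of the
molecules that hurt the correlation with that of the molecules carrying
it: values near 1 mean a broad consensus, values near 0 (as here) a
correlation where a few influential molecules matter as much as all the
supporters together.

The same workflow is available from the shell:

```bash
cwqsar synth --n 200 --seed 1 --out data.csv
cwqsar split --data data.csv --seed 2 --out split.csv
cwqsar train --data data.csv --split split.csv --target t2 --epochs 30 \
             --seed 1 --out-model model.json
cwqsar stats --data data.csv --split split.csv --model model.json --out stats.tsv
cwqsar predict --data data.csv --model model.json --split split.csv --out pred.csv
```

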