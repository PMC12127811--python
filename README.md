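# gliotype

Joint prediction of three glioma molecular markers — **IDH** mutation,
**ATRX** mutation and **1p/19q** codeletion — from multi-modal brain MRI
(T1, T1-ce, T2, FLAIR), for researchers in imaging genomics who want a
fully inspectable, CPU-trainable implementation of a dual-path
attention-based genotyping network, complete with a synthetic phantom
generator so every component can be exercised without any external dataset.

Under the WHO CNS5 scheme these three markers jointly determine the glioma
subtype (oligodendroglioma: IDH-mutant + codeleted; astrocytoma:
IDH-mutant + ATRX-mutant; glioblastoma: IDH-wild-type), so a non-invasive
preoperative readout of all three is clinically meaningful.

## The model

Two parallel 3-D convolutional paths — one over all four modalities, one
over T2+FLAIR only (the T2–FLAIR *mismatch sign* is a known IDH-mutation
marker) — exchange features twice: once at the stem, and once mid-network,
where the two 128-channel 16³ maps F3, F4 are concatenated (F5), reduced by
a 1×1×1 conv (F6) and re-injected residually (F7 = F6+F3, F8 = F6+F4).
F7 feeds a 3-D vision transformer (4096 tokens of width 512, 4 layers,
8 heads, softmax(QKᵀ/√d)V); F8 feeds a residual dual-attention tail whose
blocks gate their conv branch per channel, σ(MLP(avg)+MLP(max)), then per
voxel, σ(Conv₇ₓ₇ₓ₇[avg;max]).  Global average+max pooling over three scales
(128/256/512 ch) gives a 1792-dim vector; per-gene FC stacks
1792→1280→512→32→2 end in softmax.  The 1p/19q head additionally receives
max(P_idh) and max(P_atrx) before its final layer, encoding the clinical
rules (IDH-wild-type ⇒ non-codeleted, ATRX-mutant ⇒ non-codeleted) as
learned conditioning.

Training minimizes, per gene, the imbalance-aware LMF loss
`L = α·L_LDAM + β·L_FL` (margin-adjusted cross-entropy with margins
∝ n_j^(−1/4), plus focal loss −α_t(1−p_t)^γ log p_t), combined across genes
by learnable homoscedastic-uncertainty weights:

```
L_mul = L_idh/(3σ²_idh) + L_1p19q/(3σ²_1p19q) + L_atrx/(3σ²_atrx)
        + log(σ_idh σ_1p19q σ_atrx),     σ init = (5, 6, 6)
```

Everything runs on a compact numpy autodiff core shipped with the package
(`gliotype.nn`) — no GPU framework required; a `scale` knob shrinks widths
and input size jointly so the full pipeline trains on one CPU core in
minutes (scale 0.125) or reproduces the full printed architecture
(scale 1.0: 128³ inputs, F3–F8 at 128 ch × 16³, 4096×512 tokens, 1792-dim
pooled features).

## Worked example

Two quick demonstrations: the network memorizes a small labelled phantom
cohort (a capacity/optimizer sanity check), and the LMF loss measurably
mitigates class imbalance against plain cross-entropy.

```python
import numpy as np
from gliotype import GliomaGenotypeClassifier
from gliotype.config import CohortSpec
from gliotype.synthetic import GenotypeTriple, cohort_from_genotypes

genotypes = [GenotypeTriple(*g) for g in
             [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
              (1, 0, 1), (1, 0, 1), (0, 0, 0), (1, 1, 0)]]
spec = CohortSpec(n_subjects=8, volume_shape=(24, 24, 24),
                  lesion_radius_range=(3.0, 4.5), noise_sd=0.0, seed=0)
cohort = cohort_from_genotypes(genotypes, spec)

clf = GliomaGenotypeClassifier(scale=0.125, epochs=30, lr=1e-3,
                               batch_size=8, augment=False, random_state=0)
clf.fit(cohort, validation=cohort)
print(clf.evaluate(cohort).summary().round(3))
sig = clf.uncertainty_.sigmas
print(f"sigma: idh {sig[0]:.3f}, 1p/19q {sig[1]:.3f}, atrx {sig[2]:.3f}")

from gliotype.experiments import imbalance_comparison
runs = [imbalance_comparison(1000 + s) for s in range(10)]
print(f"LMF wins {sum(r['lmf_wins'] for r in runs)}/10 seeds | "
      f"sensitivity at 0.9 specificity: "
      f"LMF {np.mean([r['sens_lmf'] for r in runs]):.3f} vs "
      f"CE {np.mean([r['sens_ce'] for r in runs]):.3f}")
```

prints (one CPU core, ~20 seconds):

```
             acc  auc  sens  spec
idh          1.0  1.0   1.0   1.0
atrx         1.0  1.0   1.0   1.0
codel_1p19q  1.0  1.0   1.0   1.0
sigma: idh 4.852, 1p/19q 5.822, atrx 5.822
LMF wins 10/10 seeds | sensitivity at 0.9 specificity: LMF 0.878 vs CE 0.862
```

Read: the eight noise-free phantoms are classified perfectly on all three
genes (memorization sanity — this is training-set accuracy, by design),
the uncertainty weights have moved from their (5, 6, 6) initialization,
and on the 9:1 imbalanced linear task the LMF-trained model detects more
minority cases than cross-entropy at the same specificity in every seeded
repeat.  `clf.history_` carries per-epoch losses and the σ trajectory;
`clf.predict_proba` returns per-gene mutant/codeleted probabilities.

Generalization to *unseen* phantom subjects at this 1/8 desk scale is
deliberately modest (the 2-channel stems bottleneck contrast features;
small cohorts overfit) — the desk-scale runs validate mechanisms, not
clinical performance; see `docs/methods.md`.

The same workflow is available from the shell:

```bash
gliotype simulate --n 40 --seed 0 --out cohort/ --shape 24,24,24
gliotype train --data cohort/ --scale 0.125 --epochs 70 --seed 0 --out run/
gliotype evaluate --checkpoint run/ --data cohort/
gliotype predict --checkpoint run/ --data cohort/ --out pred.csv
gliotype export-features --checkpoint run/ --data cohort/ --out maps/
```

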