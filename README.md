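# hdlatent

CT-based latent-trait phenotyping of humidifier-disinfectant (HD)
exposed lungs. Inhaled biocides such as PHMG caused lung injury in
exposed populations, yet many exposed subjects present with
normal-appearing CT and normal pulmonary function. This package
implements, end to end, a pipeline that looks for sub-visual structure
in such lungs:

1. **Two-channel images** — paired inspiratory (TLC) / expiratory (RV)
   CT are combined into a rescaled-density channel and a registration
   Jacobian channel J = det(I + ∇u), the EX/IN local volume ratio.
2. **Pattern discovery** — lobule-sized (20 mm) 3D patches are grouped
   into tissue-pattern clusters by a 3D convolutional autoencoder with a
   feature constructor (CAE-FC): the embedding channel with the largest
   positive activation both drives the reconstruction and names the
   patch's cluster.
3. **Latent traits** — sliding-window cluster frequencies per subject
   are reduced by exploratory factor analysis (principal-axis, varimax);
   factors with salient loadings of both signs are *bi-polar*.
4. **Subject phenotypes** — k-means in factor-score space, cohort
   statistics (Welch t / Welch ANOVA + Games–Howell / chi-square),
   quantitative CT metrics (LAA%, Tissue%, PRM-fSAD%, RV/TLC, AWV%),
   and a CART classifier over the discriminating variables.
5. **Airway physiology** — a 1D conducting-airway surrogate: hydraulic
   diameters, Poiseuille resistance, and analytic impaction /
   sedimentation / diffusion deposition of 0.5 µm aerosol over a
   bifurcating tree, driven by a subject-specific half-sine inspiration
   (7 mL/kg tidal volume).

The cohort CT data behind this workflow are not public, so the package
ships a first-class synthetic generator (`hdlatent.synthetic`):
ellipsoidal five-lobe lung phantoms with spatially coherent tissue
patterns of known attenuation and Jacobian, displacement fields whose
Jacobian is exact by construction, planted group-specific pattern
mixtures, and binary airway trees. Every stage is tested against that
ground truth, and the statistics that are derivable from the published
summary tables of the 121-subject HD cohort are reproduced exactly from
those tables (`hdlatent.datasets`).

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from hdlatent.pipeline import run_pipeline

out = run_pipeline("runs/demo", {"seed": 1})
meta = pd.read_csv(out / "metadata.csv")
cl = pd.read_csv(out / "subject_clusters.csv")
m = meta.merge(cl, on="subject_id")
print(pd.crosstab(m.group_id, m.cluster_id))
print("ARI:", adjusted_rand_score(m.group_id, m.cluster_id))
print(pd.read_csv(out / "airway_deposition.csv")[
    ["cluster_id", "subject_id", "total_conducting_df"]])
```

prints (seed 1, default two-group condition — an "exposed-like" group
enriched for deflation-limited and hypo-inflated patterns vs a
mostly-normal control group, 10 subjects each on 64³ grids):

```
cluster_id   0   1
group_id
control      0  10
exposed     10   0
ARI: 1.0
   cluster_id subject_id  total_conducting_df
0           0       S017             0.018494
1           1       S002             0.018712
```

The planted groups are recovered perfectly from the factor scores at
this seed (recovery is exact in roughly 6 of 10 seeds and off by one or
two subjects otherwise — see `docs/methods.md`, known limitations), and
about 1.9% of inhaled 0.5 µm particles deposit in the conducting tree
of each representative subject — small, as expected for half-micron
aerosol, and rising when the airways are narrowed. The run directory
also contains the pattern histograms, factor loadings/scores, QCT
metrics per lobe, per-stage statistics and a manifest with checksums;
rerunning the same config reproduces the checksums bit for bit.

The same pipeline is scriptable from the shell:

```bash
hdlatent run --config config.yaml --out runs/demo --seed 1
hdlatent cohort --out cohort/ --seed 0 --n-per-group 5
hdlatent deposit --tree tree.json --weight 70 --out dep.csv
```

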