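# promact

Infer promoter activity landscapes — H3K4me3 and H3K27ac enrichment at
annotated transcription start sites — from DNA methylation.

ChIP-seq of histone marks is the gold standard for measuring promoter
activity but is infeasible for most patient tumor material, while
bisulfite methylomes (WGBS/RRBS) are routinely available, including for
FFPE archival samples. `promact` learns the nonlinear, spatial mapping
from TSS-proximal methylation patterns to promoter histone-mark
enrichment, so that promoter activity, differential activity, and
alternative promoter usage can be studied in methylation-only cohorts.

## The model

For each promoter (TSS ± 1 kb), per-CpG methylation counts become
clamped log-odds M-values,

    Mval_k = log2((meth_k + 0.5) / (unmeth_k + 0.5)),   |Mval| ≤ log2 65,

coverage-filtered at 5 reads. Two grids of 20 contiguous windows
(250 bp and 2.5 kb wide, spanning TSS ± 2.5 kb and ± 25 kb) summarize
the M-values into three channels per window — mean, variance, and the
window's fraction of the region's total sum of squared deviations
(FSSD) — giving a per-promoter tensor of shape (2, 20, 3), min-max
scaled to [0.1, 1] per sample with missing windows encoded as 0.

The response is the log2 ChIP/input enrichment of the promoter region,

    HM_i = log2((Σ ChIP_i + α) / (Σ Input_i + α)),

with α the sample's 25th percentile of input sums. A small
convolutional network — three conv layers (kernel (1, 3), so the two
window scales never mix), two fully connected layers, LeakyReLU(0.1),
max-norm 3, Adadelta, early stopping — regresses the tensor onto HM_i.
Transfer to a new tumor type freezes the conv layers and retrains only
the fully connected mapping on a single labeled sample.

Downstream, promoters are called active/inactive with a 2-component
Gaussian mixture per sample, groups are compared per promoter with
Wilcoxon rank-sum + Benjamini–Hochberg FDR, and alternative
primary-promoter usage between groups is screened and tested.

A fully synthetic data generator (annotation, methylome with
state-dependent hypomethylation canyons, ChIP/input tracks consistent
with planted enrichment, expression) makes the entire pipeline testable
end to end without external data.

## Worked example

```python
import numpy as np
from promact import (SimConfig, simulate_cohort, PromoterFeaturizer,
                     ConvPromoterRegressor, evaluate_regression, call_activity)

cfg = SimConfig(n_promoters=2000, seed=1)
cohort = simulate_cohort(cfg, 3, shared_fraction=0.5)   # 2 train + 1 test

tensors = [PromoterFeaturizer(s.catalog).fit().transform(s.methylation)
           for s in cohort]
model = ConvPromoterRegressor(random_state=0).fit(
    [t.values for t in tensors[:2]],
    [s.truth["hm_H3K27ac"].to_numpy() for s in cohort[:2]],
)
pred = model.predict(tensors[2].values)
print(evaluate_regression(pred, cohort[2].truth["hm_H3K27ac"].to_numpy()))
calls = call_activity(pred, cohort[2].catalog["transcript_id"].to_numpy())
print(calls["state"].value_counts().to_dict())
```

Output:

```
{'r2': 0.9764522739154875, 'rmse': 0.2647252930657027, 'n': 2000}
{'inactive': 1400, 'active': 600}
```

The model recovers the planted promoter enrichment of the unseen sample
with R² ≈ 0.98 (RMSE ≈ 0.26 log2 units, close to the planted noise
level of 0.3), and the mixture model calls 30% of promoters active,
matching the planted state prior.

The same workflow is available from the shell:

```bash
promact simulate --n-promoters 2000 --n-samples 2 --seed 1 --out sim/
promact catalog  --annotation sim/S0.annotation.gtf --out catalog.bed
promact features --catalog catalog.bed --methylation sim/S0.methylation.tsv --out S0.npz
promact response --catalog catalog.bed --chip sim/S0.H3K27ac.bedGraph \
                 --input sim/S0.input.bedGraph --out S0.hm.tsv
promact train    --features S0.npz --response S0.hm.tsv --out model/
promact predict  --model model/ --features S1.npz --out pred.tsv
promact evaluate --predicted pred.tsv --observed S1.hm.tsv
```

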