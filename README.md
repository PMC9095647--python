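# cyclicproc

Image processing and single-cell analytics for **cyclic immunofluorescence
(CyCIF)** — the multiplexed imaging protocol that labels 40–60 proteins on a
single FFPE tissue section through iterative stain → image → quench rounds.
The package is aimed at imaging core staff and computational biologists who
need a tested, scriptable pipeline from raw per-round TIFF exports to
normalized, batch-corrected single-cell feature tables.

## What it does

- **Registration** — every staining round is aligned to the reference round
  by an affine transform (scaling, rotation, translation) estimated between
  DAPI images via invariant keypoints, descriptor matching and a RANSAC
  consensus fit; the round's transform is applied to all of its channels.
- **Autofluorescence (AF) subtraction** — blank (unstained) acquisitions,
  scaled linearly by exposure time, are subtracted from the AF488/AF555/AF647
  channels. Two algorithms: *baseline* (one blank, ideally collected after
  3–4 quench rounds, near the AF minimum) and *scaled* (linear interpolation
  in round index between early and late blanks, for tissues whose AF drifts).
- **Segmentation** — nuclei from a maximum projection of all rounds' DAPI:
  white top-hat → seed extraction → Prewitt gradient → seeded watershed, with
  class-dependent nuclear size caps (cytokeratin-positive cells may have
  larger nuclei). Whole cells by watershed on the membrane (Ecad) image, or —
  for membrane-negative cells — by expanding each nucleus 5 px (1.6 µm);
  cytoplasm = cell − nucleus.
- **Feature extraction** — per-cell mean intensity per marker per
  compartment, morphology, and a per-marker *selected* intensity from its
  biologically relevant compartment (cytoplasm for CK19, nucleus for Ki67, …).
- **QC metrics** — signal-to-background ratio
  `SBR = (mean FG − mean BG)/mean BG` with a 30 px (10 µm) Euclidean
  exclusion gap around foreground to avoid lateral bleed-through; quantile
  dynamic range (4th / 99.5th percentiles); percent positive; DAPI/Li-threshold
  tissue-retention curves; precision/recall/F1 against manual annotation.
- **Normalization** — transforms (raw, log2, arcsinh) and scikit-learn
  scalers; RESTORE-style background thresholds from mutually exclusive marker
  pairs (exclusivity scored as the minor/major singular-value ratio of the
  standardized pair, cut-offs 0.5/0.2 per core and 0.66/0.5 globally;
  threshold = median over partners of the 99.5th marker percentile among
  partner-positive cells) with the 0.02–1 scaling rule; reverse-compartment
  thresholds; ComBat empirical-Bayes batch adjustment with control-tissue
  parameterization (same / sampled / all training cells); mean-only
  regress-out.
- **Batch evaluation** — kBET rejection rate (chi-squared comparison of
  neighborhood vs global batch composition on an exact k-NN graph; 0 =
  perfect mixing, 1 = no mixing), stratified sampling (600 cells per core per
  batch), Leiden clustering, and Pearson correlation of cluster composition
  between replicate sections.
- **Synthetic fixtures** — generators for multi-round images (nuclei,
  AF fields with per-round dynamics, registration jitter, tissue loss, shot
  noise) and cell tables (lineage-structured exclusive markers, planted batch
  effects) with full ground truth, so the entire pipeline is testable without
  any real data.

Images are single-channel 16-bit grayscale TIFFs with metadata in the
filename: `{slide}_{scene}_R{round}_{marker}_{channel}_{exposure}ms.tif`
(round 0 = pre-staining acquisition; marker `blank` = unstained background).
The template is configurable.

## Worked example

Recover planted exclusive marker pairs, a RESTORE threshold and batch mixing
on a synthetic 3-core × 3-batch table (9 000 cells):

```python
import numpy as np
from cyclicproc import (select_exclusive_pairs, restore_threshold,
                        restore_scale, combat_adjust, stratified_sample,
                        build_knn, kbet_rejection_rate)
from cyclicproc.synthetic_fixtures import SimTableConfig, simulate_cell_table

cfg = SimTableConfig(seed=0)
table, truth = simulate_cell_table(cfg)
markers = list(cfg.markers)

sub = table[table.batch_id == "batch1"]
pairs, _ = select_exclusive_pairs(sub, markers, scope="global")
t = restore_threshold(sub, "CK19", pairs["CK19"])
norm = restore_scale(sub["CK19"].to_numpy(), t, seed=0)

logt = table.copy()
for m in markers:
    logt[m] = np.log2(logt[m] + 1)
sample = stratified_sample(logt, n_per_group=600, seed=0)
raw = kbet_rejection_rate(build_knn(sample[markers].to_numpy(), 50),
                          sample["batch_id"].to_numpy(), seed=0)
adj, _ = combat_adjust(logt, "batch_id", markers)
sample2 = stratified_sample(adj, n_per_group=600, seed=0)
fixed = kbet_rejection_rate(build_knn(sample2[markers].to_numpy(), 50),
                            sample2["batch_id"].to_numpy(), seed=0)
```

This prints (via the obvious `print` statements):

```
exclusive partners found:
  CK19: CD45 (R=0.73), Vim (R=0.72)
  Ecad: CD45 (R=0.74), Vim (R=0.73)
  CD45: CK19 (R=0.73), Ecad (R=0.74)
  Vim: CK19 (R=0.72), Ecad (R=0.73)
CK19 RESTORE threshold: 106.6 (planted background threshold: 108.3)
normalized range: (0.0000, 1.0000); below-threshold max: 0.0200
kBET rejection: raw 0.97 -> ComBat 0.12 (n = 5400 cells)
```

Only the cross-lineage pairs (epithelial CK19/Ecad vs immune-stromal
CD45/Vim) clear the 0.66 exclusivity cut-off; the recovered background
threshold sits within 2% of the planted one; RESTORE scaling maps the
brightest cell to exactly 1 and below-threshold cells into (0, 0.02]; and
ComBat turns near-complete batch separation (kBET 0.97) into good mixing
(0.12).

The image side has a CLI:

```bash
cyclicproc simulate --preset segmentation --seed 1 --out scene/
cyclicproc register --scene scene/ --ref-round 1 --out registered/
cyclicproc afsub    --scene registered/ --algorithm baseline --out corrected/
cyclicproc segment  --scene corrected/ --expand-px 5 --out masks/
cyclicproc run      --out full_run/        # full pipeline on a simulated scene
```

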