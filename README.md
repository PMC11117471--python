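# lungrpn

A tested toolkit for the components of a two-stage pulmonary-nodule detector
on CT images: Hounsfield-unit lung-field preprocessing, anchor-shape priors
fitted by fuzzy c-means (FCM) and k-means clustering, region-proposal
geometry, coordinate-attention blocks, scaled-down patch classifiers with
multi-backbone fusion, and detection metrics with k-fold support.  A
synthetic CT phantom generator with exact ground truth makes every stage
testable end to end without downloading any scan data.

## Who this is for

Medical-image-analysis developers who want the algorithmic pieces of a
faster-R-CNN-style nodule detector as small, independently verified
functions and sklearn-style estimators — for teaching, prototyping, or
benchmarking component changes — rather than as a monolithic training
harness bound to a GPU and an 888-scan benchmark download.

## The core methods

**Lung-field extraction.**  Raw scanner integers are calibrated to
Hounsfield units (HU = raw·slope + intercept), binarized at −400 HU so
air-like voxels (exterior air, lung parenchyma ≈ −850 HU) come out true,
border-connected components are removed, and the remaining air components
are split into a left and a right lung group, closed with a 5-px disk, and
convex-hulled so nodules attached to the lung wall stay inside the mask.
The HU slice is windowed to 8-bit over (−1200, 600) HU, multiplied by the
mask, and bone (> +300 HU) plus its detected edge neighbourhood is blanked.

**Anchor priors by fuzzy c-means.**  Instead of hand-picking anchor scales
and aspect ratios, the (width, height) population of ground-truth boxes is
clustered.  FCM gives each box a graded membership in every cluster

$$u_{ij} = \Bigl[\sum_{k=1}^{c} \bigl(d_{ij}/d_{kj}\bigr)^{2/(m-1)}\Bigr]^{-1},$$

with fuzzifier m = 2 by default; centres are the $u^m$-weighted means, and
the memberships/centres alternate until convergence.  As m → 1⁺ the
assignments become crisp and match k-means.

**Proposal geometry.**  Anchor grids centred at `(i+0.5)·stride`, IoU,
positive/negative/ignore anchor labelling with the argmax rescue rule, the
standard offset parameterisation `(Δcx/w, Δcy/h, log w-ratio, log h-ratio)`,
greedy NMS and top-N selection.

**Attention.**  Squeeze-and-excitation (per-channel gates from global
average pooling) and two coordinate-attention variants: CA-I pools along
each spatial direction separately so the gates retain positional
information; CA-II additionally mixes directional max pooling into each
descriptor (CBAM-style dual pooling).

**Metrics.**  Greedy one-to-one IoU matching reduces detections to
TP/FP/TN/FN, from which accuracy, precision, sensitivity, specificity and
F1 = 2·p·r/(p+r) follow; undefined ratios are flagged, never zeroed.

## Worked example

```python
import numpy as np
from lungrpn import (FCMConfig, fcm_fit, fcm_memberships, f1_from_pr,
                     PhantomSpec, NoduleSpec, make_phantom_slice, preprocess_slice)

# fuzzy memberships: a box at distances 1 and 2 from two centres, m = 2
u = fcm_memberships([(2.0, 5.0)], [(1.0, 5.0), (4.0, 5.0)], m=2.0).u
print(u)                      # [[0.8 0.2]]  — 1/(1 + (1/2)^2) = 0.8

# F1 from a published precision/sensitivity pair
print(round(f1_from_pr(0.9421, 0.9540), 4))   # 0.948

# a phantom slice with one 8 mm nodule, preprocessed
spec = PhantomSpec(image_size=160, spacing=0.7)
lung = spec.left_lung_ellipse
img, boxes = make_phantom_slice(
    spec, [NoduleSpec(center=(lung.cx * 0.7, lung.cy * 0.7), diameter=8.0)])
out, mask = preprocess_slice(img.values, spacing=img.spacing)
b = boxes[0]
print(b.width, mask.values[int(b.y_min):int(b.y_max), int(b.x_min):int(b.x_max)].all())
# 11.0 True   — the 8 mm nodule spans 11 px and sits fully inside the lung mask
```

The command line mirrors the stages:

```bash
lungrpn synth --n-slices 20 --out ds/          # phantom dataset (.mhd + CSV)
lungrpn preprocess --dataset ds/ --out pre/    # PNG masks and masked slices
lungrpn anchors --method fcm --k 5 --boxes boxes.csv --out anchors.json
lungrpn pipeline --n-slices 200 --out run/     # end-to-end demo + report
lungrpn check-tables                           # F1 consistency of published rows
```

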