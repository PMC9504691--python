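# fcamseg

Supervised color-texture segmentation built on **fuzzy color aura
matrices (FCAMs)** — a compact texture descriptor that captures how the
fuzzy colors of neighboring pixels surround each other — with regional
SLIC superpixels and an extreme learning machine (ELM) classifier.

Segmenting an image into regions of homogeneous color texture is a
recurring task in biological and medical image analysis (tissue types
in histology, habitats in remote sensing, material classes in
microscopy). `fcamseg` partitions an RGB image into superpixels,
describes each superpixel by a single small matrix of color
interactions, and classifies the superpixels against user-supplied
training textures.

## The descriptor

For two site sets $S_x, S_{x'}$ of colors $x, x'$ inside a region $P$,
the *aura set* of $S_x$ with respect to $S_{x'}$ is the subset of
$S_{x'}$ lying in the Chebyshev neighborhood ($d = 1$, eight
neighbors) of sites of $S_x$; its cardinal measures how much $x'$
surrounds $x$. Collecting cardinals over all color pairs gives a
texture descriptor, but over the full RGB cube it would be
$256^3 \times 256^3$. The RGB cube is therefore reduced to $C$ *fuzzy
colors* by uniform quantization ($C = C_R\cdot C_G\cdot C_B$, default
$2\times4\times2 = 16$), each with a membership function
$\mu_{\tilde c}(x) \in [0,1]$ (Gaussian by default, calibrated so
$\mu = 0.5$ exactly on the quantization-cell bound). The fuzzy aura
cardinal of fuzzy colors $(c, c')$ over region $P$ is

$$\tilde m_P(c,c') \;=\; \sum_{r \in P} \min\Big(
  \max_{s \in N_r \cap P} \mu_{S_c}(s),\; \mu_{S_{c'}}(r) \Big),$$

and the $C\times C$ matrix of cardinals, normalized to unit mass, is
the FCAM — a $C^2$-length feature per region.

## The pipeline

1. **Regional SLIC.** A first SLIC pass clusters sites on
   $(L, a, b, x, y)$; each superpixel $R$ is summarized by the regional
   feature $f_R = [p_R - p_R\ln p_R] + \frac{1}{|N_R|}\sum_{R'\in N_R}
   [p_{R'} - p_{R'}\ln p_{R'}]$ (area fraction $p_R$, 4-adjacent
   neighbors $N_R$); a second pass clusters $(\hat f_R, a, b, x, y)$,
   which separates textures of equal mean color but different pattern
   scale.
2. **Training.** $T$ prototype patches per class (default 1000, patch
   side chosen so its area is about $N/P$ — 27×27 at 512² and
   $P = 400$) are described by normalized FCAMs and fed to an ELM
   (hidden layer of $100\,K$ logistic units with random weights;
   output weights by minimum-norm least squares).
3. **Segmentation.** One FCAM per superpixel, classified by the ELM;
   every site takes its superpixel's class. Optional refinement
   reassigns superpixels under 0.5% of the image to their largest
   neighbor's class.

Quality metrics are included for both stages: boundary recall,
under-segmentation error, achievable segmentation accuracy and
compactness for partitions; per-class recall/precision/Jaccard and
global/local consistency errors for segmentations.

## Worked example

The synthetic module renders texture mosaics with ground truth, so the
whole pipeline runs without any external dataset:

```python
import numpy as np
from fcamseg import (build_palette, elm_train, mosaic3, patch_halfwidth,
                     sample_prototypes, segment, segmentation_scores)

sample = mosaic3(256, seed=0)            # 3-class mosaic + pure tiles
palette = build_palette((2, 4, 2), "gaussian")
W = patch_halfwidth(256 * 256, 100)      # -> patch side 27
train = {i + 1: tile for i, tile in enumerate(sample.tiles)}
feats, labels = sample_prototypes(train, T=50, W=W, palette=palette, seed=1)
model = elm_train(feats, labels, seed=1)
result = segment(sample.image, model, palette, P=100)
print("pixel accuracy:", np.mean(result.labels == sample.gt))
print(segmentation_scores(result.labels, sample.gt))
```

prints

```
pixel accuracy: 0.9439544677734375
   CO:  94.41 %
   CC:  94.74 %
   CA:  89.57 %
  GCE:   0.1030
  LCE:   0.0735
```

94.4% of sites are recovered; the per-class recall (CO) and precision
(CC) are the pixel-wise scores averaged over the three texture
classes, and the small consistency errors (GCE/LCE) confirm the
prediction is close to a refinement of the ground truth. Errors
concentrate along texture boundaries, where superpixels straddle two
classes.

The same workflow is available from the shell:

```sh
fcamseg synth --preset mosaic3 --size 256 --seed 0 --out fixture/
fcamseg train --classes classes/ --T 50 --P 100 --seed 1 --out model/
fcamseg segment --model model/ --image fixture/image.png --out pred.png --P 100
fcamseg eval --pred pred.png --gt fixture/gt.png
```

(`classes/` holds one training image per class; for user-supplied
datasets such as the Prague texture mosaics, point `--classes` at the
training textures and `segment`/`eval` at each test mosaic and its
ground truth.)

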