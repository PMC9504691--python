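# Methods

This note records the model conventions, parameter choices and
numerical decisions behind `fcamseg`, in the spirit of a methods
appendix: what the code computes, why the defaults are what they are,
and what the synthetic fixtures do and do not demonstrate.

## Fuzzy color palettes

The RGB cube is quantized uniformly: channel $k \in \{R,G,B\}$ is
split into $C_k$ intervals of width $L_k = \lceil 256/C_k \rceil$,
with interval centers $\lfloor((2i+1)L_k - 1)/2\rfloor$, $i = 0..C_k-1$,
clipped to 255 when $C_k$ does not divide 256 (the last interval is
then truncated). Palette colors are the Cartesian product of the
per-channel centers, ordered lexicographically by (R, G, B) center
index with B varying fastest; this ordering is part of the feature
contract since FCAM entries are indexed by it. The default palette is
$2\times4\times2 = 16$ colors — the G channel is favored because it is
the closest proxy for luminance.

Membership functions are evaluated on an **anisotropic scaled
distance**: channel differences are divided by the channel's interval
width $L_k$ before the Euclidean norm,
$d(x,c) = \sqrt{\sum_k ((x_k - c_k)/L_k)^2}$. This is the unique
reading under which the calibration constraint — membership exactly
0.5 at a single-channel offset of $L_k/2$ — holds for unequal $L_k$.
Concretely:

- *crisp*: 1 iff $|x_k - c_k| \le \lfloor L_k/2 \rfloor$ on every
  channel. Adjacent cells overlap only on shared bounds.
- *gaussian*: $\exp(-d^2/2\sigma^2)$ with
  $\sigma = 1/(2\sqrt{2\ln 2})$, i.e. per-channel span
  $\alpha_k = L_k/(2\sqrt{2\ln 2})$. The simpler constant
  $\alpha = \beta/(2\ln 2)$ sometimes quoted for this family does
  *not* satisfy the 0.5-at-bound calibration; the calibrated constant
  is used.
- *triangular*: $\max(1 - d, 0)$; also 0.5 at a bound.
- *fcm*: the fuzzy C-means ratio form with fuzzifier $\zeta = 2$
  (any $\zeta > 1$ accepted), on the same scaled distance; at a color
  equal to a center the ratio degenerates and the standard one-hot
  limit is used. Per-color degrees sum to 1 by construction.

Membership evaluation over an image is memoized per distinct RGB
value, which is value-identical to direct evaluation.

## Aura matrices

Neighborhoods are Chebyshev balls of radius $d$ (default 1: the eight
closest sites), clipped at image borders and — for region-restricted
aura — at the region. A region needs at least two sites, otherwise no
site has an in-region neighbor and the descriptor is undefined
(`DegenerateRegionError`).

The FCAM entry for colors $(c, c')$ over region $P$ is the sum over
$r \in P$ of $\min(M_c(r), \mu_{S_{c'}}(r))$ where
$M_c(r) = \max_{s \in N_r \cap P} \mu_{S_c}(s)$ (0 if $r$ has no
in-region neighbor). The neighbor-max form collapses the literal
sup/min expression with the binary in-region neighborhood function;
`fcam_reference` evaluates the literal expression by exhaustive loops
and the equivalence is asserted to 1e-9 in the tests. The vectorized
path computes one masked maximum filter per palette color over the
region's bounding box ($O(C\,|P|\,(2d+1)^2)$) and an
$O(C^2 |P|)$ min/sum combination.

With crisp memberships on an image whose colors are palette centers,
the FCAM reduces exactly to the crisp aura cardinal matrix; this
fuzzy-to-crisp reduction is the second oracle anchoring the
implementation. Training patches use the same construction with the
patch as the region; border sites simply have fewer in-region
neighbors.

Normalization divides by the total mass; an all-zero matrix raises
`ZeroMassError`, and the segmenter routes such regions (along with
singletons) to the refinement rule instead of the classifier.

## Superpixels

Basic SLIC: centers start on a regular grid of step
$S = \sqrt{N/P}$ (grid dimensions rounded, then shrunk so the seed
count never exceeds $P$); each center competes for sites in its
$2S\times2S$ window under
$D = \sqrt{d_c^2 + m^2 d_s^2 / S^2}$; ten fixed
assignment/update iterations (the count standard for this family of
algorithms; convergence checks buy little). The square root is
applied to $D$ even though some statements of the distance omit it —
it is monotone, so the assignment is identical. Compactness $m = 1$
by default, balancing Lab-scale color against position; $m = 0$
degenerates to pure color clustering.

Connectivity enforcement: 4-connected fragments smaller than $S^2/4$
are absorbed, in raster order, into the adjacent component with the
largest shared border. A component that is not the largest component
of its k-means label is absorbed as well — this second rule guarantees
the partition invariant $P' \le P$, which a size threshold alone
cannot (a label split into two large components would otherwise yield
an extra superpixel). Final labels are renumbered 1..$P'$ in raster
order of first occurrence. All coordinates are 0-based (row, col) in
raster order throughout the package.

The regional feature uses the natural logarithm. In the second SLIC
pass $f_R$ is min–max rescaled to $[0, 100]$ so it is commensurate
with the L channel it replaces (a constant feature map rescales to 0).
The second pass starts from a fresh grid rather than reusing the first
pass's centers — the plainest reading of "apply SLIC again". On a
constant-color image both passes reduce to spatial k-means and the
regional result equals the basic one.

## Classifier and refinement

The ELM hidden layer has $100K$ logistic-sigmoid units for $K$
classes; input weights and biases are drawn uniformly from $[-1, 1]$
(seeded); output weights are the Moore–Penrose minimum-norm
least-squares solution for one-hot targets, computed by `pinv`.
Prediction is the argmax of the output layer with ties broken toward
the lowest class index. The hidden feature matrix of a large random
layer is typically ill-conditioned, so weight values in near-null
directions depend on the SVD cutoff; predictions are unaffected, and
weight-level oracle checks in the tests use a small well-conditioned
hidden layer.

Prototype patches are drawn uniformly with the patch fully inside the
training image (no partial border patches). The patch half-width
derives from the requested superpixel density: the smallest odd side
with $(2W+1)^2 \ge N/P$ — 27 at $N = 512^2$, $P = 400$.

Refinement processes superpixels smaller than 0.5% of the image
smallest-first in a single pass; areas and adjacency are frozen from
the partition, while the class looked up on the chosen (largest
adjacent) neighbor reflects earlier reassignments in the same pass.
Both orderings are deterministic; this one lets a chain of small
superpixels collapse onto their common large neighbor in one pass.

## Synthetic fixtures

The generator produces stripe, checker and correlated-noise textures
composed into mosaics (vertical bands, grids, or Voronoi cells) with
site-aligned ground truth and one pure training tile per class — the
same supervised setting as benchmark texture mosaics, at desk scale.
Deliberate presets:

- `mosaic3` (256² by default): stripes (red/green, 45°), checker
  (blue/yellow), smoothed gray noise — three classes distinguishable
  by both color and structure; the end-to-end accuracy bar of 0.85 is
  checked on it with $T = 50$ prototypes/class and $P = 100$
  superpixels. These problem sizes keep the whole suite under a
  minute while leaving the pipeline's behavior (superpixel leakage at
  boundaries, refinement effects) visible.
- `size_contrast` (128²): two checkerboards with identical colors and
  mean but periods 1 vs 12. Mean color carries no information, so any
  separation must come from pattern scale — exactly the channel the
  regional feature adds. Regional SLIC's boundary recall and ASA are
  verified to be at least basic SLIC's, averaged over five noise
  seeds.
- `fig2_toy`: a 7×7 two-texture stripe image whose aura sets flip
  from nonempty to empty as the superpixel boundary moves across the
  texture transition; the separating column repeats R, G, B from the
  top (a documented choice — no consumer relies on per-site counts in
  that column).

What the fixtures do **not** show: performance on natural textures
(stochastic, multi-scale, uncalibrated illumination), on datasets with
many visually similar classes, or boundary accuracy beyond what
superpixel granularity allows. Passing the synthetic suite
demonstrates correctness of the descriptor and pipeline mechanics, not
benchmark-level accuracy claims.

## Numerical conventions

- Lab conversion is the standard sRGB/D65 one (via scikit-image); its
  matrix constants leave a ~3e-3 residual chroma on the neutral axis,
  which tests tolerate.
- Boundary sites are sites with a 4-neighbor of different label;
  boundary recall uses Chebyshev tolerance 2 by default and is 1 by
  convention when the ground truth has no boundary.
- Compactness uses the isoperimetric quotient with perimeter counted
  as 4-neighbor boundary edges (image border included), area-weighted
  over superpixels.
- CO/CC/CA average per-class recall/precision/Jaccard over the classes
  present in the ground truth; a class never predicted contributes
  zero precision. GCE/LCE follow the standard consistency-error
  construction via the contingency table; both are 0 when one map
  refines the other.
- All randomness flows through explicit `numpy` generators seeded by
  the caller; SLIC is deterministic, so a (image, seeds, config)
  triple reproduces label maps bit-for-bit.

## Known limitations

- The SLIC assignment loop is pure numpy; a 512² image with $P = 400$
  takes seconds, not milliseconds.
- Superpixel-level classification bounds achievable boundary accuracy
  by the pre-segmentation (the ASA of the partition caps the final
  accuracy).
- The supervised setting requires one training texture per class;
  there is no unsupervised or semi-supervised mode.
- Only RGB quantization palettes are supported (no clustering-based
  palettes, no alternative color spaces for the palette itself).
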