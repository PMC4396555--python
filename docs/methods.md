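# Methods

## Problem

A hyperspectral cube carries hundreds of narrow spectral bands over the
same scene.  Adjacent bands are strongly redundant; carrying them all
inflates storage and can even hurt pixel-classification accuracy.  *Band
selection* keeps a small subset of the **original** bands (unlike feature
extraction, which transforms them).  `smiband` implements a dissimilarity
-based selection: estimate how much information every pair of bands
shares, cluster bands in that dissimilarity space, and keep one
representative band per cluster.

## Information metrics

Bands `X`, `Y` are each affinely quantized to `L` gray levels
(`level = floor((v - min)/(max - min) * L)`, clamped to `L-1`; a constant
band maps to level 0).  From the `L x L` joint histogram `cnt(x, y)` over
the `E` corresponding pixels:

- **Mutual information** (bits):

  `MI = (1/E) * sum_xy cnt(x,y) * log2( E*cnt(x,y) / (cnt_x(x)*cnt_y(y)) )`

  which is algebraically the plug-in `H(X) + H(Y) - H(X,Y)` with Shannon
  entropies `H = -sum p log2 p` (empty cells contribute 0; `0*log 0 := 0`).
  The test suite asserts the two routes agree to 1e-9 on random tables.

- **Spatial mutual information (SMI)**: the same sum with every cell
  weighted by `w(x, y) = |x - y| / (L - 1)` — the normalised absolute
  level difference of the co-occurring pixels.  MI is invariant to any
  simultaneous re-ordering of pixels and, via the marginal histograms,
  blind to a *single* band being pixel-shuffled in the sense that the
  shuffled band's own histogram (and hence entropy) is unchanged.  SMI is
  not: a band against itself puts all joint mass on the zero-weight
  diagonal and scores exactly 0, while against a shuffled copy the mass
  scatters off-diagonal and the score is positive (the plug-in estimator's
  positive bias makes each occupied off-diagonal cell contribute a
  positive expected term).  The weight is pluggable (`WeightFunction`);
  an alternative "scalar" reading — mean absolute level difference times
  MI — is available as `metric="smi-scalar"` and labelled as such in
  output metadata, because the prose definition of the weighting admits
  both readings.

### Dissimilarity matrices

- `metric="mi"`: `d(i,j) = 1 - 2*MI/(H_i + H_j)` (one minus normalised
  MI) — bounded in [0, 1], 0 for identical bands.  A zero-entropy band
  shares no information with anything; its pairs are set to `d = 1` with
  a warning.
- `metric="smi"`: raw SMI values affinely rescaled over the whole matrix
  to [0, 1].  Raw SMI can be slightly negative for near-duplicate pairs
  (mass concentrated near the zero-weight diagonal leaves the
  negatively-signed tail terms), so a single affine rescale, rather than
  a per-pair normalisation, keeps the ordering intact and the linkage
  heights comparable.

Defaults: `L = 256` when the data are integer-valued with range < 256
(8-bit sensor output), else `L = 64`; each band is quantized against its
own min/max because bands have heterogeneous dynamic ranges (a global
range is available via `global_range=True`); logs are base 2 throughout —
any other base rescales all pairs uniformly and cannot change the
clustering.

A practical note on binning: with `L = 256` and only a few thousand
pixels the plug-in MI of *independent* bands is strongly positively
biased (the joint histogram is extremely sparse), so normalised MI can
saturate and order band pairs poorly.  SMI is far more robust to
over-binning because its weights, not its log terms, carry the
within-vs-across group contrast.  The examples show exactly this failure
mode for MI on the synthetic benchmark.

## Clustering and representatives

Agglomerative clustering over the dissimilarity matrix: start from B
singletons, repeatedly merge the pair of clusters at minimal linkage
distance (average = mean of all cross-pair dissimilarities — the default,
monotone and the standard compromise; single = min; complete = max).
Determinism is pinned: among tied minimal pairs, the pair whose combined
membership has the lexicographically smallest (min member index, max
member index) merges first.  Average-linkage state is propagated as exact
*sums* of original cross-pair dissimilarities (`S(K, A+B) = S(K,A) +
S(K,B)`), divided by the pair count only at comparison time, so ties on
rational values are detected identically by the incremental algorithm and
by a from-scratch re-scan; the suite checks this equivalence, ties
included, and cross-checks merge heights against
`scipy.cluster.hierarchy` on tie-free matrices.

Cutting the tree at `k` applies only the first `B - k` merges.  Each
cluster is then represented by the member minimising the total
dissimilarity to its fellow members — the band sharing the most
information with the rest of its cluster — using the *same* matrix as the
clustering (internal consistency; no second metric).  Ties go to the
lowest band index.

## Evaluation

Labeled pixels (label 0 = background, always excluded) are split per
class into 55 % training / 45 % testing: `round(n * 0.55)` half-up per
class, guarded so any class with >= 2 pixels keeps at least one pixel on
each side; the draw is uniform under a seed and bit-reproducible.
Features are the selected bands' intensities, z-scored per band with
training statistics only.  The classifier is a one-versus-all soft-margin
SVM with an RBF kernel (`C = 1`, `gamma = 1/(d * Var)`, i.e. sklearn's
"scale"), predicting by maximal decision value with ties to the lowest
class id; any fit/predict classifier can be substituted and is recorded
in the report.  The figure of merit is overall accuracy — correct test
pixels over all test pixels — and `accuracy_vs_k` sweeps it over subset
sizes and selection strategies under identical splits and SVM settings,
reporting per-k means and the mean over the whole k range as the one
summary number.  C and the kernel width are not prescribed by the method
itself; since all strategies share them, the *comparison* between
strategies is fair even where absolute accuracies would differ under
other settings.

## Synthetic scenes

The generator emulates the structure the method assumes of agricultural
scenes: `n_groups` latent signals, each copied into `bands_per_group`
bands with per-band gain `1 +/- gain_jitter` and additive Gaussian noise
(`noise_sigma`, as a fraction of the unit signal range, clipped at
quantization); `n_classes` spatially contiguous label regions ("blocks"
grid or Voronoi cells) with class signatures drawn by rejection until all
pairwise distances exceed `0.15 * sqrt(n_groups)`; a background frame
(10 % of the image) labeled 0; affine quantization to
`quantization_levels` integers (256 = 8-bit).  All randomness flows
through one seeded generator.

Benchmark defaults: 48 x 48 pixels, 5 classes, 6 groups x 5 bands
(B = 30), 5 % noise, 5 % gain jitter — scene sizes at which histograms
are stable, class regions are meaningfully contiguous, and full sweeps
over 100 seeds remain quick.

The `shuffle_confound` variant replaces each group's last band with a
pixel-shuffled copy of the group's first band: a band with a perfectly
genuine histogram but no spatial correspondence with the scene.  Plain MI
treats it as a highly informative (maximally dissimilar) band; SMI scores
it near zero against everything, so it cannot hijack a cluster.

What the generator does **not** emulate: real sensor artefacts
(water-absorption bands, striping, saturated pixels), spectral libraries
of real materials, spatially correlated noise, and mixed pixels at class
boundaries.  Passing the synthetic benchmarks therefore shows the
*mechanism* works — redundancy groups are recovered, spatial weighting
defeats the shuffle confound, selected subsets classify as well as the
full cube — not that specific accuracy numbers transfer to any real
sensor's data.

## Numerical choices and edge cases

- `0 * log 0 := 0` everywhere; MI values in `[-1e-12, 0)` are clamped to 0.
- SMI self-score is exactly 0 (not approximately): the weight matrix has
  an exactly-zero diagonal.
- Constant (zero-entropy) bands: valid input; under `metric="mi"` their
  pairs get `d = 1` with a warning; under `metric="smi"` they behave as
  any other band (self 0, raw scores finite).
- Tie-breaks: merge ties by lexicographic member indices (above);
  representative ties and one-vs-all decision ties by lowest index/class
  id.  No randomness anywhere in selection.
- Dissimilarity matrices must be exactly symmetric and finite; the CSV
  loader re-symmetrises against text round-off.

## Known limitations

- The pairwise loop is O(B^2) joint histograms; fine for a few hundred
  bands, not tuned for thousands.
- Plain-MI selection degrades under over-binning (see above); choose
  `bins` deliberately when using `metric="mi"` on small images.
- The SVM evaluation is a validation harness, not a production
  classifier: no hyperparameter search, no spatial-contextual features.
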