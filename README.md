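# smiband

Band selection for hyperspectral images by **spatial mutual information**
(SMI): estimate how much information every pair of spectral bands shares,
cluster the bands agglomeratively in that dissimilarity space, and keep
one representative band per cluster.  Selections are validated by
supervised pixel classification (one-vs-all RBF-SVM, stratified 55/45
split, background excluded), and a synthetic-cube simulator with known
band-redundancy groups makes every stage testable without downloading any
imagery.

Intended for remote-sensing and biological-imaging practitioners who need
to shrink a cube of hundreds of bands to a handful of informative ones
while keeping the original (untransformed) measurements.

## The method

For quantized bands `X`, `Y` with joint histogram `cnt(x, y)` over `E`
pixels and marginals `cnt_x`, `cnt_y`:

```
MI  = (1/E) Σ_x Σ_y            cnt(x,y) · log2( E·cnt(x,y) / (cnt_x(x)·cnt_y(y)) )
SMI = (1/E) Σ_x Σ_y  w(x,y) ·  cnt(x,y) · log2( E·cnt(x,y) / (cnt_x(x)·cnt_y(y)) )
```

with the default weight `w(x,y) = |x−y|/(L−1)`.  MI is the plug-in
`H(X)+H(Y)−H(X,Y)` and sees only co-occurrence statistics; SMI
additionally weights each joint-histogram cell by the intensity
difference of the co-occurring pixels, so a band scores exactly 0 against
itself but strictly above 0 against a pixel-shuffled copy — it is
sensitive to spatial correspondence where marginal-histogram statistics
are blind.  The B×B dissimilarity matrix (1 − normalised MI, or rescaled
SMI) is clustered bottom-up (average linkage by default); cutting the
tree at `k` and keeping, per cluster, the band with minimal total
dissimilarity to its fellow members yields the selected subset.  See
`docs/methods.md` for assumptions, defaults, and edge cases.

## Worked example

```python
import smiband as sb

# a synthetic scene: 6 redundancy groups x 5 bands, 5 classes, 5% noise
cube, labels, groups = sb.simulate(sb.SynthConfig(seed=0))

subset = sb.select_bands(cube, k=6, metric="smi")
print(subset.indices)                            # (2, 7, 13, 16, 20, 27)
print(sb.group_recovery_score(subset, groups))   # 1.0

report = sb.evaluate_subset(cube, labels, subset, seed=0)
print(round(report.overall_accuracy, 4))         # 1.0
```

The six selected bands fall one-per-redundancy-group (recovery 1.0), and
those six bands alone classify the scene's pixels as well as all thirty.
The narrative scripts in `examples/` walk through each capability;
`examples/04_classification_curve.py` prints the accuracy-vs-k comparison
(on the default benchmark: SMI-selected subsets average 99.95 % overall
accuracy over k = 2..6 versus 97.79 % for random subsets and 81.22 % for
plain-MI selection, whose dissimilarities saturate under fine binning).

The same pipeline runs from the shell on ENVI or `.npz` cubes:

```bash
smiband simulate --out-dir scene/
smiband select   --cube scene/cube.img --k 6 --metric smi --out subset.json
smiband evaluate --cube scene/cube.img --labels scene/labels.csv \
                 --subset subset.json --seeds 0..4 --report report.json
smiband curve    --cube scene/cube.img --labels scene/labels.csv \
                 --k-min 2 --k-max 6 --metrics smi,mi,random --out curve.csv
```

Every JSON artefact records tool version, configuration hash, and input
checksums, and identical runs produce byte-identical outputs.

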