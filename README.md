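# holoenum

Staining-free enumeration of tumor cells flowing through a microfluidic
channel, from in-line digital holograms to a concentration in cells per
mL with a limit of detection.

Circulating tumor cells (CTCs) occur at a few cells per mL of blood.
Immunostaining — the standard way to find them — kills or perturbs the
cells, so label-free counting matters for any downstream use of live
CTCs.  This package implements the computational side of a holographic
flow assay for that problem: cells in a sheathed microchannel (800 µm ×
330 µm cross-section, sample confined to a ~500 µm core) are illuminated
with a 635 nm diode laser; the interference between the scattered and
unscattered waves is recorded at 420 fps, 1 µm/px, on an 800×800 sensor
200 µm below the channel floor.  Numerical reconstruction localizes
every cell in 3D, a shallow CNN classifies each cell's in-focus image,
and a strict decision threshold suppresses the false positives that
would otherwise swamp a rare-cell count.

It is aimed at people building or evaluating holographic cytometry
pipelines: every stage is a plain Python function, and a physics-based
simulator generates hologram stacks with ground-truth tracks so the
whole chain is testable without an instrument.

## The pipeline

1. **Simulate / ingest** (`holoenum.simulate`, `holoenum.io`) — cells as
   weak amplitude disks with organelle-scale internal granularity,
   advected by a product-of-parabolas laminar profile
   u(y,z) = u_max (1−(2y/W−1)²)(1−(2z/H−1)²) scaled so ∬u dA = Q; frames
   are |1 + Σᵢ P_{dᵢ}(tᵢ−1)|² under a vignetted illumination plus sensor
   noise, where P_d is the angular-spectrum propagator over distance
   d = recording distance + cell height.
2. **Clean** (`holoenum.preprocess`) — subtract the pixelwise mean of
   the whole stack (the object-free background) and flat-field to a
   normalized contrast ≈ 1.
3. **Reconstruct** (`holoenum.reconstruct`) — back-propagate the
   zero-mean contrast with the exact angular-spectrum transfer function
   H(f;d) = exp(i 2πn/λ · d · √(1 − (λf/n)²)) to 67 planes spanning the
   channel depth (200–530 µm every 5 µm).
4. **Localize** (`holoenum.localize`) — detect cells on the
   maximum-intensity projection of the scattered intensity |g|², find
   each cell's plane of best focus from the radius-stationary plateau of
   high-passed scattered energy, and cut a 36×36 crop of the image
   intensity |1+g|².
5. **Deduplicate** (`holoenum.dedup`) — a detection in frame i+1 within
   |Δy| ≤ 3 µm and |Δz| ≤ 50 µm of one in frame i is the same cell;
   chains collapse to the first appearance.
6. **Classify** (`holoenum.snet`) — s-Net, a shallow CNN
   (conv8–conv16–conv32, 3×3 kernels, two 2×2 max-pools, 2592-node
   flatten, softmax; 11 186 learnable parameters) trained with Adam
   (10⁻³), minibatch 32, 20 epochs on a stratified 70/30 split.
7. **Gate + enumerate** (`holoenum.gating`) — call a cell a tumor cell
   only when P_tumor > α with α chosen by ROC analysis as the smallest
   threshold reaching the minimum false-positive rate (α = 0.9999999 on
   the default grid); concentration = gated count / imaged volume, and
   the limit of detection over negative-control trials is
   LoD = μ_NC + 2 σ_NC.

`holoenum.pipeline.run_pipeline` chains all stages deterministically and
writes a manifest with per-stage counts and checksums; the `holoenum`
CLI exposes each stage (`simulate`, `preprocess`, `detect`, `dedup`,
`train`, `classify`, `roc`, `enumerate`, `run`).

## Worked example

```python
import holoenum as he

optics = he.OpticalConfig(fov_px=(256, 256), channel_width_um=256,
                          sample_core_width_um=160)
flow = he.FlowConfig(n_frames=200)

crops, labels = he.make_training_crops(1000, optics, seed=1)
model = he.build_snet(seed=0)
he.train(model, crops, labels, epochs=10, seed=0)

test_crops, test_labels = he.make_training_crops(500, optics, seed=2)
p = he.predict_proba(model, test_crops)
cm = he.confusion(p, test_labels, alpha=0.5)
print(f"accuracy {cm.accuracy:.3f}  sensitivity {cm.sensitivity:.3f} "
      f"fpr {cm.fpr:.4f}")
mu, sd, lod = he.limit_of_detection([1, 1, 2])
print(f"negative controls: mu {mu:.2f}  sigma {sd:.2f}  LoD {lod:.2f} cells/mL")
```

prints:

```
accuracy 0.970  sensitivity 0.970 fpr 0.0300
negative controls: mu 1.33  sigma 0.58  LoD 2.49 cells/mL
```

meaning the shallow network separates the two synthetic cell classes
with 97% held-out accuracy while still miscalling 3% of WBCs — which
is exactly why the enumeration stage gates at α ≫ 0.5 — and three
negative-control trials of 1, 1 and 2 counts/mL put the limit of
detection at 2.49 cells per mL.

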