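# morphovae

Landmark-free morphological feature extraction from binary 3-D shape volumes
with a classifier-regularized convolutional variational autoencoder.

A specimen volume is canonically oriented from three anatomical points, split
at the sagittal plane through the tip (the mirrored half doubles the data),
projected to three binary 128×128 silhouettes (x/y/z projections), and
size-normalized by a landmark reference length. The network encodes the
triplet into a 3-D Gaussian latent, decodes it back, and classifies the latent
with a single softmax layer; the objective is
`E_total = (1 − α)(E_Rec + E_Reg) + α·E_C` with `α = 0.1` by default.

The package ships the full evaluation suite: cluster-separation index / 
Davies–Bouldin metrics and an RBF-SVM latent accuracy, a pixel-PCA baseline,
reconstruction re-classification, latent PC-plane generation panels, Score-CAM
saliency maps, projection-direction ablation, and the missing-segment
(crop-rate) reconstruction experiment. A synthetic-shape generator produces
class-labeled mandible-like volumes (ellipsoid body + three process-like
protrusions) so everything is testable without external data.

The neural network is implemented on a small, gradient-checked numpy engine
(`morphovae.nn`) — no deep-learning framework is required.

## CLI pipeline

```bash
morphovae synth --preset separable --classes 3 --n 60 --seed 7 --out data/
morphovae split --manifest data/ --seed 1 --out split.json
morphovae train --data data/ --split split.json --target-length 80 --out run/
morphovae eval  --run run/ --out metrics.json
morphovae panel --run run/ --grid 7x7 --out panel.png
morphovae saliency --run run/ --out maps/
morphovae ablate-directions --run run/ --out ablation.csv
morphovae crop-curve --run run/ --axis vertical --rates 0,0.2,0.4,0.6 --out curve.csv
morphovae preprocess --manifest data/ --out triplets/ --target-length 80
morphovae tune --data data/ --trials 20 --out trials.jsonl
```

Training options (architecture, α, optimizer, learning rate, loss balance)
come from a YAML file mirroring `morphovae.ModelConfig`; see
`morphovae train --config cfg.yaml`.

## Layout

- `morphovae/preprocess.py` — orientation, split/mirror, silhouette
  projection, size-normalized rasterization
- `morphovae/model.py` — the VAE + classifier network and loss breakdown
- `morphovae/training.py` — leakage-safe stratified splits, training loop,
  α selection, budgeted random hyperparameter search
- `morphovae/latent_eval.py` — CSI / Davies–Bouldin / SVM metrics, PCA
  baseline, reconstruction re-classification, latent grid panels
- `morphovae/saliency.py` — Score-CAM and direction ablation
- `morphovae/occlusion.py` — crop-rate reconstruction experiment
- `morphovae/synthetic.py` — labeled synthetic shape generator and fixtures
- `morphovae/nn/` — numpy layers and optimizers
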