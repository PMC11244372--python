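# s5utis

Semantic segmentation of tongue photographs with structured state-space
(S4) sequence kernels extended to 2D inside a convolutional-attention
encoder, decoded through a UNETR-style skip-connection decoder. Ships with
its losses and metrics, a seeded synthetic-data harness that stands in for
private clinical photos, and a CLI covering the whole train/evaluate loop
at desk scale.

Everything runs on CPU: the network is built on a small NumPy reverse-mode
autodiff engine (`s5utis.nn`) whose primitives are finite-difference
checked in the test suite.

## Layout

| Module | Contents |
| --- | --- |
| `s5utis.s4_core` | HiPPO initialization, bilinear discretization, recurrence, 1D kernels, DPLR decomposition, Cauchy kernel path |
| `s5utis.s4_2d` | outer-product 2D kernels, FFT global convolution, trainable `S4Layer2D` |
| `s5utis.encoder` | four-stage convolutional-attention encoder (strides 4/8/16/32, channels 32/64/160/256, depths 3/3/5/2) with the S4-2D layer in the attention block's 1x1-conv slot (`use_s4` ablation switch) |
| `s5utis.decoder` | progressive 2x upsampling with skip fusion and residual blocks; full-resolution two-class head; `ham` decoder config stub |
| `s5utis.losses_metrics` | cross-entropy, boundary loss on signed distance maps, Dice/mIoU/pixel-accuracy from exact confusion counts |
| `s5utis.synthetic_data` | seeded tongue-like scene generator (smooth / tooth-marked / w-tip / twisted shapes, coatings, pigment spots, lip-band distractors), dataset assembly, 8:2 splitting, PNG/JPEG I/O |
| `s5utis.cli` | `s5utis synth\|train\|evaluate\|predict\|kernel-dump` |

## CLI

```bash
# generate a dataset (images/, masks/, manifest.csv)
s5utis synth --n 200 --size 64 --seed 0 --out data/

# train (AdamW, base LR 1e-4, betas 0.9/0.999; all defaults overridable)
s5utis train --data data/ --out runs/exp1 --epochs 20 --batch-size 8 --seed 0

# evaluate a checkpoint (micro-averaged Dice/mIoU/PA + per-image report)
s5utis evaluate --checkpoint runs/exp1/best.npz --data data/ --out report.json

# segment images, writing mask + red-overlay PNGs
s5utis predict --checkpoint runs/exp1/best.npz --out preds/ data/images/00000.png

# debug: dump a 1D kernel as CSV and its 2D outer-product kernel as PNG
s5utis kernel-dump --state-dim 8 --length 64 --out kernels/
```

Ablations: `--no-use-s4` restores the plain 1x1 convolution in the
attention blocks; `--decoder-kind ham` routes to the (unimplemented)
lightweight-decoder stub.

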