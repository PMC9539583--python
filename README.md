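# ivimdnn

Supervised deep-network estimation of intravoxel incoherent motion (IVIM)
parameters from multi-b-value diffusion-weighted (DW) MRI, together with the
multi-SNR numerical-phantom simulator used to train and validate it.

## The problem

IVIM models the DW signal of a voxel as a biexponential mixture of slow
tissue diffusion and fast capillary pseudo-diffusion:

```
S(b) = S0 · [ (1 − f) · e^(−b·D) + f · e^(−b·D*) ]
```

where `D` (mm²/s) is the tissue diffusion coefficient, `D*` (mm²/s) the
pseudo-diffusion coefficient and `f` the perfusion fraction. Voxel-wise
least-squares fitting of this model is ill-conditioned on noisy magnitude
images, and the perfusion parameters `f` and `D*` in particular become
unreliable at low SNR — which is exactly where preclinical and clinical
acquisitions often live.

`ivimdnn` trains one small fully connected network (3 hidden tanh layers,
linear outputs) to map per-voxel DW signals to the (D, f, D\*) triplet. Two
design choices carry the accuracy:

* **standardized targets** — the three parameters differ by orders of
  magnitude, so they are z-scored before entering the MSE loss and the
  inverse transform is applied to the network output; without this, the
  loss is dominated by `f`/`D*` and `D` estimation collapses;
* **one network for the whole SNR range** — training voxels are pooled
  across Rician noise levels from SNR 10 to 100, so the same trained model
  serves images of any quality in that range, with no per-SNR retraining.

Inputs are the signals normalized to b0 (`Sb/Sb0`), augmented with their
natural logarithms (9 b-values → 18 features) and min–max mapped to
[−1, 1] using constants frozen on the training set.

Training data come from a Shepp–Logan-style 64×64 phantom with six
elliptical regions, each carrying a uniformly drawn parameter triplet and
its own b0 level, corrupted by Rician noise whose Gaussian scale is set
voxel-wise (σ = S0/SNR) so a phantom has one well-defined SNR. A segmented
+ full least-squares fitter provides the conventional baseline, and the
evaluation module implements the robust metrics MdAE (relative median
absolute error), MdB (relative median bias), RCV (1.4826·MAD/median within
homogeneous regions) and FR (share of voxels with relative error > 50%),
plus Kruskal–Wallis/Tukey comparison of methods.

## Worked example

Train on a small simulated grid (16 phantoms at each of the seven SNR
levels, half for training) and score the held-out half:

```python
import numpy as np
from ivimdnn import (SimulationGrid, generate_grid, train_on_phantoms,
                     predict, build_report)
from ivimdnn.dnn import NetworkConfig, TrainingConfig

grid = SimulationGrid(phantoms_per_snr=16, master_seed=0)
train_ph, test_ph = [], []
for tag, inst in generate_grid(grid):
    (train_ph if tag == "train" else test_ph).append(inst)

model = train_on_phantoms(
    train_ph,
    network=NetworkConfig(n_inputs=18, hidden_layers=3, hidden_width=32),
    training=TrainingConfig(optimizer="adam", max_iterations=120, seed=0),
    max_voxels=100_000)

records = []
for inst in test_ph:
    d, f, ds = predict(model, inst.noisy, inst.foreground)
    records.append({"method": "dnn", "snr": inst.snr,
                    "est": np.stack([d, f, ds]),
                    "truth": np.stack([inst.truth_D, inst.truth_f,
                                       inst.truth_Dstar]),
                    "roi_labels": inst.roi_labels})
report = build_report(records)
cols = ["parameter", "snr", "MdAE", "MdB", "RCV", "FR"]
print(report[report["snr"].isin([10.0, 100.0])][cols].round(4).to_string(index=False))
```

which prints:

```
parameter    snr   MdAE     MdB    RCV     FR
        D   10.0 0.1250 -0.0032 0.1642 0.0475
        D  100.0 0.0378  0.0209 0.0279 0.0000
    Dstar   10.0 0.3778  0.0544 0.3271 0.4021
    Dstar  100.0 0.2417  0.1056 0.0563 0.2452
        f   10.0 0.2206 -0.0383 0.2977 0.1851
        f  100.0 0.0799 -0.0259 0.0405 0.0905
```

Read: on held-out phantoms the median relative error of `D` is 12.5% at
SNR 10 and under 4% at SNR 100; `D*` is the hardest parameter (38% median
error at SNR 10, 40% of voxels off by more than half); the bias (MdB) of
all parameters stays within a few percent; and within homogeneous regions
the spread of `D` estimates (RCV) drops from 16% to 3% as SNR rises. A
larger training grid (see below) tightens all of these.

The same pipeline is available from the shell:

```sh
ivimdnn simulate --config run.yaml --out sim/
ivimdnn train --data sim/train --config run.yaml --out model.ivimdnn
ivimdnn fit --model model.ivimdnn --dwi vol.nii.gz --bval vol.bval \
            --mask mask.nii.gz --out-prefix maps/vol
ivimdnn fit-lsq --dwi vol.nii.gz --bval vol.bval --out-prefix maps/lsq
ivimdnn evaluate --maps maps/ --truth sim/test --out report.csv
ivimdnn ablate --data sim/ --out ablation/
```

Real acquisitions enter as 4-D NIfTI volumes plus an FSL-style `.bval`
text file; a model trained on one b-value scheme refuses volumes acquired
with another (a different scheme requires retraining).

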