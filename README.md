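# ivdseg

Self-supervised, intensity-based domain adaptation for 3D intervertebral-disc
(IVD) segmentation.

## The problem

Supervised 3D segmentation of IVDs in T2-weighted MRI transfers poorly
between scanners: hardware and protocol differences shift tissue intensity
statistics (noise level, contrast curve, illumination/bias field), and a
U-Net trained on one labeled source domain S degrades on unlabeled target
domains T1, T2 even though the anatomy is unchanged. Annotating every new
domain is expensive; IVD masks are slow to draw.

`ivdseg` implements a dual-task remedy: a 3D encoder–decoder segments discs
from the labeled source while a classification head on the *shared* encoder
solves an intensity pretext task on unlabeled volumes from **all** domains —
predict which distortion c ∈ {identity, Gaussian noise, Gaussian blur,
contrast enhancement} was applied. Labels for the pretext task are generated
automatically, so target domains contribute gradient without annotation.
Training minimises

    L_total = L_seg + L_p

with `L_seg` the soft Dice loss on the source batch and `L_p` cross-entropy
on the pretext batch; both gradients accumulate on the encoder e(·) before a
single Adam step, while the decoder d(·) sees only `L_seg` and each head
i(·) only `L_p`. Model selection keeps the checkpoint with the lowest
validation `L_total` on the source validation split.

Because no MRI datasets ship with the package, a seeded spine-phantom
generator provides domain-shifted benchmark data: stacks of bright
ellipsoidal discs along a curved axis whose *masks are bit-identical across
domains* while noise, gamma and bias field differ — a pure intensity shift,
the regime the method targets. See `docs/methods.md` for the model,
generator and all numerical conventions.

The network engine (3D convolutions, batch norm, pooling, backprop, Adam) is
implemented on numpy/BLAS inside the package (`ivdseg.nn`), so everything
runs on a single CPU core; gradients are verified against finite differences
in the test suite.

## Worked example

```python
from ivdseg.experiment import desk_scale_config, run_experiment

result = run_experiment(desk_scale_config(seed=0))
for row in result.table_rows():
    print(f"{row['model']:12s} {row['domain']:3s} "
          f"DSC {row['dsc_mean']:.3f} ± {row['dsc_std']:.3f}  "
          f"HD {row['hd_mean']:.2f}")
print("held-out pretext accuracy:", result.pretext_acc)
```

This trains the baseline U-Net (source only) and the proposed `t1t2s-int`
model (intensity pretext on S, T1 and T2) on one seed of the phantom
benchmark (32×32×12 volumes, quarter-width network, 24 epochs; ~6 min on
one core) and prints, for seed 0:

```
unet         S   DSC 0.963 ± 0.004  HD 1.00
unet         T1  DSC 0.238 ± 0.014  HD 15.50
unet         T2  DSC 0.469 ± 0.102  HD 11.73
t1t2s-int    S   DSC 0.822 ± 0.035  HD 1.33
t1t2s-int    T1  DSC 0.891 ± 0.011  HD 10.27
t1t2s-int    T2  DSC 0.594 ± 0.118  HD 2.98
held-out pretext accuracy: {'t1t2s-int': 0.9166666666666666}
```

Read: the baseline segments the source domain almost perfectly but collapses
on the brightened target T1 (DSC 0.24) and degrades badly on the noisy,
gamma-compressed T2 (0.47). Adding the intensity pretext on unlabeled
multi-domain volumes recovers both targets (0.89 / 0.59) while keeping
source DSC above 0.8, and the encoder's pretext head identifies the applied
intensity distortion on 92 % of held-out volumes — the domain-adaptation
effect the package exists to demonstrate. DSC is voxel overlap in [0, 1];
HD is the symmetric Hausdorff distance in voxels (boundary worst case).

The same machinery is scriptable: `ivdseg generate / train / evaluate /
predict / experiment --help` cover dataset synthesis to NIfTI, manifest-based
training, per-volume metric CSVs and single-volume inference.

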