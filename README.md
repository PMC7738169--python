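# funcsearchlight

Searchlight multivariate pattern analysis (MVPA) over **functional** voxel
neighborhoods.

Conventional searchlight analysis slides a small anatomical volume — a cube
of side `2r+1` voxels — across the brain and applies the same multivariate
computation at every position. That design can only ever find information
carried by *anatomically contiguous* voxels. `funcsearchlight` implements the
functional searchlight: voxels are first re-embedded into a learned
k-dimensional *functional space*, where a voxel's coordinates are its
loadings on latent components of brain activity, and each searchlight is a
voxel plus its `j` nearest neighbors by cosine distance in that space.
Anatomically distant but functionally similar voxels can then share a
searchlight, so representations that are distributed across the brain become
visible to an otherwise unchanged exhaustive analysis.

## The model

The functional space comes from the shared response model (SRM). For `n`
subjects watching the same stimulus, each subject's voxel × time matrix
`X_i` is factorized as

    X_i = W_i S + E_i,      W_iᵀ W_i = I_k

with a subject-specific orthonormal basis `W_i` (v × k) and one shared
latent timecourse `S` (k × t), fitted by alternating least squares to
minimize `Σ_i ‖X_i − W_i S‖_F²`. Row `v` of `W_i` is voxel `v`'s coordinate
vector in functional space; voxels with all-zero loadings are dropped. For
single-subject designs, PCA loadings play the same role. The dimensionality
`k` is selected by time-segment matching (locating a held-out subject's time
window within the group's shared response).

The package ships the three searchlight kernels used to evaluate the method:

* **RSA** — correlate the searchlight's timepoint × timepoint pattern
  correlation matrix with a model's (e.g., a DNN layer's), excluding pairs
  within a 10-TR buffer of the diagonal to suppress BOLD autocorrelation;
* **embedding decoding** — ridge-regress semantic embedding vectors from
  searchlight activity and score by bin ranking (25 bins, chance 4%);
* **category decoding** — stratified 3-fold linear-SVM classification of
  6-category localizer blocks (chance 1/6).

Chance for analyses without an a-priori baseline is estimated by circularly
misaligning the model features in time (a rolling null); group inference on
the functional-over-anatomical percent improvement uses a subject-level
bootstrap (10,000 resamples, 95% CI).

A simulation module generates multi-subject BOLD data with a planted,
HRF-convolved signal whose spatial dispersion is controlled by the FWHM of a
Gaussian random field — the testbed for the claim that functional
searchlights win precisely when signal is distributed.

## Worked example

```python
import numpy as np
import funcsearchlight as fs

# simulate a 4-subject cohort with a widely distributed planted signal
mask = fs.solid_mask(16, 16, 16)                      # 4,096 voxels
spec = fs.SimulationSpec(mask=mask, n_subjects=4, t=200,
                         fwhm_voxels=0.5, n_signal_voxels=128, seed=0)
bolds, truths, features = fs.simulate_cohort(spec)

# learn the functional space on the first half of the timepoints
train = [(b.data[:, :100] - b.data[:, :100].mean(1, keepdims=True))
         / b.data[:, :100].std(1, keepdims=True) for b in bolds]
model = fs.fit_srm(train, k=40, seed=0)

# functional vs anatomical searchlight RSA on the second half
coords = fs.functional_coordinates(model, subject=0)
func = fs.functional_neighborhoods(coords, j=124)      # matches a radius-2 cube
anat = fs.anatomical_neighborhoods(mask, radius=2)
test = bolds[0].data[:, 100:]
test = (test - test.mean(1, keepdims=True)) / test.std(1, keepdims=True)
for nmap, name in [(func, "functional"), (anat, "anatomical")]:
    mmap = fs.run_rsa_searchlight(test, nmap, features.values[:, 100:],
                                  buffer_trs=10)[0]
    print(name, round(fs.top_percent_summary(mmap, percent=1.0), 3))
```

prints

```
functional 0.152
anatomical 0.087
```

i.e., the mean RSA of the top 1% of functional searchlights (0.152) is about
1.7x that of the top anatomical searchlights (0.087) when the planted signal
is spatially distributed — the anatomical cubes each catch only a few of the
128 signal voxels, while cosine neighborhoods in the learned space
concentrate them. Re-running with `fwhm_voxels=16.0` (localized signal)
erases or reverses the gap.

The same workflows are available from the shell via the `funcsearchlight`
CLI (`simulate`, `fit-space`, `searchlight`, `evaluate`, `tsm`,
`compare-spaces`, `dispersion`); every run writes a JSON manifest with its
config and seed.

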