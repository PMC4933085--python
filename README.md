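# choruscope

Community-level ecoacoustics toolkit: the six classical acoustic
indices computed from field audio, and a spectro-temporal alternative —
sparse dictionary approximation and shift-invariant 2D probabilistic
latent component analysis (SI-PLCA2D) of spectrograms — plus a
synthetic dawn-chorus generator that makes every behaviour testable
without field recordings.

## Who this is for

Soundscape ecologists and bioacousticians who summarise passive
acoustic monitoring data with community-level indices (NDSI, H, ADI,
AEI, ACI, BI) and want to go further: most indices collapse a
recording into the frequency *or* the time domain, so they are blind
to the spectro-temporal call patterns — the interplay of periodic
gestures between species — that actually structure an acoustic
community. Latent component decomposition keeps that structure and
returns interpretable per-voice objects.

## The models

**Acoustic indices.** Shannon entropy H' = -sum p_i ln p_i underlies
the entropy family: acoustic entropy H = sh x th (normalised spectral
entropy of the mean spectrum times normalised temporal entropy of the
Hilbert envelope, 0 for a pure tone, -> 1 for even broadband sound);
ADI (Shannon entropy of band occupancy above a dB threshold); AEI
(Gini coefficient of the same occupancy). NDSI is
(biophony - anthropophony) / (biophony + anthropophony) from band
powers (2-8 kHz vs 0.2-2 kHz by default); ACI accumulates relative
frame-to-frame magnitude changes per frequency band; BI integrates
the min-subtracted in-band mean dB spectrum.

**Latent components.** A normalised spectrogram V (sum = 1) is
decomposed as

    V ≈ Σ_k z_k (W_k ⊛ H_k)

where each kernel W_k is a small time-frequency patch (a recurring
"voice"), each activation H_k is a distribution over (frequency
shift, time) placements, ⊛ is 2D convolution, and z are mixing
weights — all probability distributions, fitted by EM. A sparsity
hyper-parameter alpha < 1 regularises the activations and prunes
components that do not contribute significantly to the
reconstruction, so fitting with K_max = 16 returns an *effective*
component count k — a candidate proxy for how decomposable an
acoustic community is. Plain (non-shift-invariant) PLCA,
V ≈ W·diag(z)·H, is included as the simpler baseline, as are
mini-batch dictionary learning, Gabor field dictionaries, and
Orthogonal Matching Pursuit for patch-wise sparse approximation.

## Worked example

Synthesise a four-species chorus with known ground truth, compute the
indices, and decompose it:

```bash
$ choruscope synth --species 4 --duration 80 --snr 20 --seed 42 \
      --out scene.wav --truth truth.json
wrote scene.wav (80.0 s, S=4, seed=42)

$ choruscope indices scene.wav --out indices.csv
$ cat indices.csv
file,ndsi,adi,aei,sh,th,h,aci,bi
scene.wav,0.6330,2.3025,0.0082,0.8955,0.9670,0.8659,2425.24,40.70
```

(Values above are printed at full precision by the tool; truncated
here for readability.) Reading them: h = sh x th = 0.866 — a busy but
structured scene, well below the ~0.99 of pure noise; NDSI 0.63
because three of the four niches sit in the 2-8 kHz biophony band;
AEI ~0.008 means occupied bands are evenly used; ADI 2.30 is close to
its ln(10) ~ 2.303 ceiling because the noise floor puts some energy
everywhere above the -50 dB threshold.

```bash
$ choruscope decompose scene.wav --method siplca2d --kmax 8 \
      --iters 100 --seed 1 --windows 8 --window-seconds 2 --out-prefix dec
wrote dec_summary.json
```

`dec_summary.json` for this run contains

```
k_effective: 3
z: [0.621, 0.217, 0.162]
kernel entropies: [0.294, 0.281, 0.922]
activation entropies: [0.611, 0.672, 0.417]
```

Three components survived pruning from K_max = 8: the
high-kernel-entropy component (0.922) is the broadband noise floor,
while the two low-entropy kernels (~0.28-0.29) are structured voices;
with a 20 dB floor two of the four synthetic species were absorbed
into neighbouring components — `k` tracks, but undercounts, richness
in noise. Per-component reconstructions are written as
`dec_component*.csv`, the full factors as `dec_model.npz`, and every
command writes its effective configuration to a `*.config.json`
sidecar so any result on disk is reproducible from input + config +
seed.

The same pipeline is available as a library (`choruscope.indices`,
`choruscope.plca`, `choruscope.sparse_dict`, `choruscope.synth`), e.g.
`richness_sweep([1,2,4,8], replicates=10, seed=0)` returns a tidy
DataFrame of index values over choruses of controlled species
richness.

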