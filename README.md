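# septrack

Single-molecule tracking and quantitative cell-biology analysis of bacterial
septal proteins.

Division-site proteins such as the DNA pump FtsK or the condensin SMC are
studied in rod-shaped bacteria (e.g. *Corynebacterium glutamicum*) by
single-particle tracking (SPT): individual fluorophore-labelled molecules are
localized frame by frame, linked into trajectories, and their mobility and
subcellular position are quantified.  `septrack` implements that whole
desk-scale pipeline — from raw image stacks or localization tables to
population-level statistics — together with a synthetic-data generator that
provides ground truth for every stage, so the entire analysis is testable
without microscope data.

## What it computes

**Diffusion populations from jump distances.**  For Brownian motion with
diffusion coefficient *D* and frame interval Δt, the squared frame-to-frame
displacement r² is exponential with mean 4DΔt.  A k-population mixture has
the cumulative distribution

    F(r²) = 1 − Σᵢ fᵢ · exp( −r² / (4 Dᵢ Δt) ),    Σᵢ fᵢ = 1,

which `septrack` fits to the empirical CDF of all pooled squared
displacements (nonlinear least squares, multi-start, simplex constraints).
Components are reported sorted by D — *confined* (divisome/DNA-engaged),
*slow-mobile* (oligomeric/membrane) and *fast-mobile* (free) — with standard
errors, and the model order can be selected automatically.

**Dwell times.**  Durations during which a molecule stays within a small
radius are decomposed into one- or two-component left-truncated exponential
models (τ, or τ₁/τ₂ with percentages) by maximum likelihood.

**Standardized-cell spatial statistics.**  Localizations are projected into
a 3 × 1 µm reference cell (poles at u = ±1.5 µm, membrane at v = ±0.5);
from there the package builds population heatmaps and difference heatmaps
(0.1 µm pixels), demographs (per-cell axial profiles sorted by length),
midcell/polar proportions and the polar ratio (regions spanning 20% of the
cell length), and LOESS trends of any statistic against cell length — the
standard cell-cycle proxy.

**Cell-profile morphometrics.**  From three-channel line profiles (phase /
membrane stain / DNA stain): cell length from the outermost membrane peaks,
septum counts from interior membrane peaks, nucleoid counts from DNA peaks,
and the fraction of a time-lapse cell cycle with septal signal above a
localization threshold.

**Nonparametric inference.**  Kruskal–Wallis with ε² effect size, Dunn's
pairwise post-hoc test (tie-corrected, Holm/Bonferroni/BH adjustment),
Wilcoxon/Mann–Whitney rank-sum, Shapiro–Wilk, and Vargha–Delaney's A.

## Worked example

```python
import numpy as np
from septrack import (
    SimCellConfig, SimMixtureConfig, simulate_cell_population,
    simulate_tracks, simulate_image_stack, detect_spots, link_tracks,
    compute_jump_distances, fit_sqd_mixture,
)

cells = simulate_cell_population(SimCellConfig(n_cells=10, septum_prob=0.7, seed=1))
mix = SimMixtureConfig(k=3, D=(0.017, 0.0509, 0.394), f=(0.4, 0.4, 0.2),
                       dt=0.013, loc_sd=0.0, n_tracks=500, frame_span=300, seed=2)
tracks, truth = simulate_tracks(cells, mix)

stack = simulate_image_stack(tracks, peak_photons=400, seed=3)
locs = detect_spots(stack, diameter=0.5, snr_min=5)
linked = link_tracks(locs, max_link=0.3, min_len=5)

fit = fit_sqd_mixture(compute_jump_distances(linked, dt=0.013), k=3)
print("D (µm²/s):", np.round(fit.D, 4))
print("fractions:", np.round(fit.f, 3))
```

Output from this exact script:

```
D (µm²/s): [0.0185 0.0605 0.3744]
fractions: [0.472 0.294 0.234]
```

The three fitted coefficients recover the simulated confined / slow / fast
populations (0.017, 0.0509, 0.394 µm²/s) after the detected-and-relinked
round trip; at this small size (~3,600 jumps) the confined and slow
fractions trade off against each other — pooling more tracks, or fixing
shared D values via `fit_sqd_mixture(..., fix_D=...)` when comparing
conditions, tightens them (see `docs/methods.md`).

A `septrack` console script exposes the same stages from the shell
(`septrack detect`, `link`, `diffuse`, `dwell`, `spatial`, `profile`,
`septal-fraction`, `dunn`); see `septrack --help`.

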