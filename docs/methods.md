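# Methods

`memfuse` implements distributed electromagnetic source imaging of single
(non-averaged) interictal epileptic spikes, with symmetric EEG–MEG fusion
inside the coherent maximum-entropy-on-the-mean (cMEM) framework, the
classical linear inverses (MNE, dSPM, sLORETA) as references, a simulation
framework for extended spiking sources on synthetic spherical-head geometry,
and the validation metrics used to score reconstructions against ground
truth.  This note records the model, the defaults and their rationale, the
numerical choices, and what the synthetic test bed does and does not show.

## Source model and forward problem

The source space is a triangulated cortical surface with one current dipole
per vertex, oriented along the outward surface normal.  The data model is
linear, `M = G J + E`, with `M` the (q × τ) sensor recording, `G` the
(q × p) lead field, `J` the (p × τ) dipole intensities (nA·m internally,
converted to A·m at the forward projection) and `E` additive noise.

Because the package targets desk-scale, fully synthetic studies, the forward
models are analytic spherical-head solutions rather than boundary-element
models on individual anatomy:

- **EEG**: a dipole inside the innermost shell of three concentric spheres
  (inner skull / outer skull / scalp; default radii 71 / 76.5 / 82 mm,
  conductivities 0.33 / 0.0165 / 0.33 S/m, i.e. brain-to-skull ratio 1:20).
  The potential is expanded in Legendre harmonics; each radial order is
  propagated through the shells by solving the interface continuity
  conditions, with an insulating outer boundary.  The series is truncated at
  60 terms, which is exact to better than 1e-6 (relative) for the dipole
  eccentricities the cortex model can reach; the homogeneous-sphere limit is
  verified against an independently derived closed form (Legendre
  generating functions) to machine precision.  An average reference is
  applied to the lead field, and the same reference must be (and in the
  simulator is) applied to the data.
- **MEG**: the Sarvas closed-form field of a dipole in a spherically
  symmetric conductor, projected on the sensor axes.  Sensors are point
  magnetometers with radial orientation on a helmet sphere (102 mm); axial
  gradiometer geometry is not modelled.  The implementation is verified
  against a Geselowitz surface-integral oracle.

The spherical models keep the physics that fusion exploits — EEG sees radial
and deep sources through the resistive skull, MEG is blind to radial dipoles
and insensitive to the skull — at a fraction of the cost of a BEM.

## Synthetic cortex and sensors

The cortex is an icosphere (default subdivision 4, p = 2562, ≈5 mm vertex
spacing) of base radius 63 mm whose radius is modulated by a smooth
pseudo-random ridge pattern (six oriented sinusoids, relative amplitude
0.08, angular frequency 6).  The folding makes dipole orientation and depth
vary across the surface, which is what gives individual simulations
different SNR and cancellation, but it is far gentler than real sulcal
anatomy: lead-field columns on this surface are more mutually coherent than
on a real cortex, so absolute localization scores here do not transfer to
clinical data — only the relative comparisons (fusion vs monomodal, method
vs method) are meaningful.  EEG electrodes (default 54) are laid
quasi-uniformly on a scalp cap; reduced montages (32, 20) are obtained by
farthest-point subsampling, mimicking the coverage loss of clinical caps.
The MEG array has 272 helmet sensors.

## Spike simulation

- **Patches**: region growing on the mesh graph to neighbourhood order
  `s_e` (default 3, ≈4–8 cm² at the default resolution), uniform amplitude
  9.5 nA·m per dipole.
- **Waveform**: a sum of three Gamma-density components, renormalised to
  unit peak.  The defaults (shape/scale/amplitude/delay:
  12/6 ms/1.0/0 ms, 12/9 ms/−0.30/20 ms, 6/35 ms/0.45/50 ms, at 600 Hz over
  0.4 s) give a dominant ≈50 ms spike, a repolarisation dip and a broad slow
  wave.  The component parameters are exposed; only the qualitative shape
  matters for the analyses here.
- **Background**: synthetic coloured noise (1/f spectrum plus an alpha bump
  at 10 Hz, random smooth channel mixing), standing in for recorded
  spike-free background.  It reproduces the spectral tilt and spatial
  correlation of ongoing activity, not its non-stationarity, artefacts or
  brain-noise topographies; robustness to those is untested here.
- **Scaling**: background amplitude is calibrated once per study to a
  signal-to-background ratio of 1 (0 dB; 3 for propagation studies) for the
  superficial reference configuration, and then held fixed so achieved SNR
  varies with depth, orientation and cancellation.  Two operational choices
  deserve note, since the ratio definition is not uniquely determined by the
  stated conditions:
  - the ratio compares the signal RMS over a ±25 ms window at the spike
    peak against the pooled background standard deviation
    (`ratio_metric="window"`); with this convention the per-spike SNR
    (max |signal| at the peak over pooled baseline std — the clinical
    definition, also implemented) spans roughly 1–12 across the ensemble,
    matching the stated study conditions, whereas peak-based or whole-epoch
    RMS conventions push that range far outside it;
  - the reference configuration is the median over eight patches drawn from
    the most superficial decile of the cortex, so that neither a purely
    radial (MEG-silent) nor a purely tangential patch dictates the
    ensemble's noise level.
- **Propagation**: two patches at graph distance 10 (the mesh-graph
  equivalent of the fixed geodesic separation; on this geometry ≈50 mm),
  same hemisphere, second waveform delayed 15 ms.
- **Conductivity perturbation**: the brain-to-skull ratio can be redrawn
  from a normal distribution (mean 20, sd 3.3) truncated to [15, 25] to
  emulate skull-conductivity mis-modelling; the localization model keeps
  1:20.

## Fusion (three levels)

1. **Normalisation + concatenation.**  Per modality, data and lead field are
   divided by the mean baseline standard deviation over channels (global,
   not channel-wise, SNR transformation; channel-wise made no material
   difference in our checks), then stacked row-wise, EEG block first.  The
   noise covariance is diagonal — the per-channel variance of the scaled
   baseline — and is carried into the solvers; the data are not
   pre-whitened for MEM.
2. **MSP + probabilistic OR.**  Per modality, the multivariate source
   pre-localisation score of each dipole is the squared cosine between its
   unit-normalised scaled gain column and the signal subspace of the scaled
   data (leading left singular vectors).  The subspace dimension keeps
   singular values above the noise bulk edge `(√q + √τ)·σ̄_noise`; an
   energy-fraction rule is available but admits noise directions at the low
   SNR of single spikes.  EEG and MEG maps are combined with a
   probabilistic OR, `a + b − a∘b`.
3. **Parcellation + activation probabilities.**  A data-driven parcellation
   grows parcels breadth-first (up to scale order 4) from the local optima
   of the fused MSP map, re-detecting optima among unassigned vertices until
   the cortex is covered (stray single vertices attach to the nearest
   parcel); ties break to the lowest vertex index.  At the default scale the
   parcel count is of order p/50 (low hundreds on a ~10k-vertex mesh).  Each
   parcel's activation probability α_k is initialised to the median fused
   MSP score over the parcel, clipped to [1e-3, 1−1e-3] so no parcel starts
   exactly shut or exactly Gaussian.

## cMEM solver

The prior factorises over parcels: with probability 1−α_k parcel k is a
Dirac mass at zero current; with probability α_k its currents are Gaussian
N(μ_k, Σ_k) with μ_k = 0 and Σ_k a smoothness covariance
`η·w_k·(W_k W_kᵀ + 1e-4·I)/mean-diag`, where W_k is the within-parcel
diffusion operator (row-normalised (I+A)/2 raised to order 2).  The MEM
estimate maximises the concave dual

    D(λ) = λᵀm − ½λᵀΣ_dλ − Σ_k log[(1−α_k) + α_k exp(μ_kᵀξ_k + ½ξ_kᵀΣ_kξ_k)],

ξ_k = G_kᵀλ, by L-BFGS from λ = 0 (gradient tolerance 1e-8·‖m‖, 500
iterations, log-sum-exp guards), independently per time sample.  At the
optimum, parcel k reports posterior activation ω_k and current
ω_k(μ_k + Σ_kξ_k).

Two scale choices are data-informed and were genuinely open:

- the **global scale η** matches the prior predictive sensor variance
  (Σ_k α_k diag(G_kΣ_kG_kᵀ)) to the data power at the strongest analysed
  sample in excess of the mean noise floor (floored at 1% of the data
  power);
- the **relative parcel weights w_k** default to the squared activation
  probability gated by the parcel-mean energy of a noise-normalised linear
  pre-estimate (sLORETA at the anchor sample):
  `w_k ∝ α_k² · mean(j_pre²)`.  This is in the spirit of the original
  solver's minimum-norm-based covariance initialisation; we found the pure
  pre-estimate weighting brittle exactly when one modality is
  noise-dominated (its λ-selection degrades), while the MSP-evidence gate
  keeps prior variance out of parcels that neither evidence source
  supports.  `uniform`, `alpha`, `mne` and `sloreta` weightings remain
  available.

α is not updated across samples (no temporal model), and Σ_k is built once
per analysis window.

## Linear reference inverses

MNE operates on whitened data/gain (rows divided by the per-channel noise
std): `Ĵ = (G̃ᵀG̃ + λI)⁻¹G̃ᵀM̃`, computed through the q×q dual form.  dSPM
divides each MNE row by its noise std (row norms of the operator, identity
noise after whitening); sLORETA normalises by
`sqrt(diag(W(G̃G̃ᵀ + λI)Wᵀ))` — the regularised model covariance, the form
for which noiseless single-dipole peaks localise exactly.  λ comes from the
L-curve (60-point log grid over [1e-6, 1e3] × trace(G̃G̃ᵀ)/q, three-point
curvature on log-log coordinates, one λ per analysis window), with two
safeguards: light curvature smoothing with endpoint trimming, and a
discrepancy-principle guard that rejects corner candidates whose residual
falls below half the whitened noise floor √(qτ) — without it the
discretised curve occasionally shows a spurious high-curvature wiggle deep
in the under-regularised region and the map collapses to a noise fit.  For
fusion, normalisation, whitening and concatenation precede the inverse.

## Validation metrics

- **AUC** at the spike peak, from the absolute current density: balanced
  detection with the patch's own size of negatives drawn half from the
  nearest non-patch vertices (graph-distance ordered surround) and half
  from the remaining cortex; the two AUCs (tie-corrected Mann–Whitney,
  equivalent to trapezoidal ROC integration) are averaged, over 10 seeded
  draws.  For two-source simulations each source is scored at its own peak
  with the other source's vertices excluded.  An AUC above 0.8 is read as
  good detection.
- **Spatial dispersion (SD, mm)**: energy-weighted RMS of the minimum
  Euclidean distance to the patch; zero iff all energy is inside the patch.
- **Shape error (SE)**: RMS difference of the peak-normalised patch-mean
  absolute time courses of truth and estimate (normalisation applied to
  absolute current; invariant to positive rescaling of either argument).
- **Eccentricity** (mean distance of the patch to the head centre) and the
  **cancellation index** `Ic = 1 − ‖Σ_l g_l‖₂ / Σ_l ‖g_l‖₂` characterise
  each simulation.  On the synthetic sphere the cortex spans ≈58–68 mm, so
  the conventional superficial/mesial/deep cutoffs (80/60 mm) label almost
  everything "mesial"; depth effects here are relative, not absolute.

## Study harness and problem sizes

`run_study` simulates an ensemble on one geometry, calibrates the noise
once, runs every (method × modality) arm and emits a tidy metrics table
plus per-arm medians.  All randomness derives from a single master seed via
stateless per-index seed derivation, so any simulation can be regenerated
in isolation and the full table is bit-reproducible.  The default study —
30 static simulations on the 2562-vertex cortex with 272 MEG + 54 (or 20)
EEG channels, solving cMEM at the spike peak sample with MSP windows of
±25 ms — runs in a few minutes on one CPU; these sizes were chosen as the
smallest at which the ensemble statistics (medians over simulations) are
stable, and are the sizes the acceptance script uses.  The shape-error
metric needs `window_halfwidth > 0` (a multi-sample solve) and is reported
only then.

## Known limitations

- Spherical geometry understates lead-field diversity; absolute AUC/SD
  values are optimistic relative to realistic anatomy for all methods, and
  the EEG montage positions are idealised.
- The background generator is stationary and Gaussian; no artefacts, no
  brain-noise topographies.
- MEG sensors are radial point magnetometers, not axial gradiometers; MEG
  SNR asymmetries specific to gradiometer geometry are not reproduced.
- The MEM dual is solved per sample with a fixed prior; temporal coherence
  of the estimates is emergent, not modelled.
- The L-curve guard assumes whitened inputs; with grossly mis-specified
  noise covariances λ selection degrades gracefully but is untested.
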