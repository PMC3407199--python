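# Methods

This note documents the models implemented in `idpnmr`, the defaults and
why they were chosen, the numerical details of the fits, and what the
synthetic-data generator does and does not emulate.

## Relaxation-rate fitting

Peak-height decays are fitted to the two-parameter model
I(t) = I₀·e^(−Rt) by nonlinear least squares (trust-region reflective,
R constrained ≥ 0, log-linear initial guess).  No offset term is fitted —
properly processed relaxation series decay to the baseline — but an
offset variant exists behind `allow_offset=True` for QC of suspicious
residues.  Replicate measurements enter as independent points.

Experimental intensity errors come from replicated delays: the pooled
standard deviation over all delays with ≥ 2 measurements, divided by the
mean replicate intensity, gives a fractional error applied to every
point of the series.  With only two replicated delays this estimator has
2 degrees of freedom and is itself noisy (≈ ±70% for a single series);
it is unbiased only in aggregate, which the tests check across 100
simulated series.

σ(R) defaults to the covariance estimate of the weighted fit;
`error_method="mc"` switches to Monte Carlo residual resampling (refit
on resampled residuals, default 1000 draws, seeded).  The covariance
path is the default because it is two orders of magnitude cheaper and,
on the ten-delay schedules used here, agrees with the resampling
estimate well within its own uncertainty; the 68%-interval coverage test
(0.68 ± 0.10 over 500 simulations) runs against the default path.
Estimates with σ(R)/R > 0.5 are flagged `unreliable` rather than
dropped, so downstream masks remain explicit.

The heteronuclear NOE is I_sat/I_unsat (saturated over reference), the
convention under which flexible-chain values fall below the ~0.75 rigid
limit and can go negative; `invert_ratio=True` computes the reciprocal
for cross-checking data sets recorded with the other bookkeeping.  No
saturation-transfer or recycle-delay corrections are applied.

Slow proline cis/trans isomerization doubles peaks; the minor-species
fraction is minor/(minor+major) per doubled residue, summarized as mean
± sd across residues.

## Reduced spectral density mapping

The three-frequency reduction assumes J(ω) is flat near ω_H so the three
proton-frequency terms collapse onto 0.87·ω_H:

    σ_NH    = R₁(NOE − 1)·γ_N/γ_H
    J(0.87ω_H) = (4/5)·σ_NH/d²
    J(ω_N)  = [R₁ − (7d²/4)·J(0.87ω_H)] / (3d²/4 + c²)
    J(0)    = [R₂ − (13d²/8)·J(0.87ω_H) − (3d²/8 + c²/2)·J(ω_N)]
              / (d²/2 + 2c²/3)

with d = (μ₀/4π)·ħγ_Hγ_N/r³_NH and c = ω_N·Δσ/√3.  Defaults: r_NH =
1.02 Å, Δσ = 172 ppm, γ_H = 2.6752218744×10⁸, γ_N = −2.71261800×10⁷
rad s⁻¹ T⁻¹ (the signed ¹⁵N ratio makes σ_NH < 0 and J(0.87ω_H) > 0 for
NOE < 1).  The mapping is the exact inverse of the forward rate
equations, which serve as the test oracle.  A single 0.87·ω_H lumping is
used for both R₁ and R₂; chemical exchange is assumed absent, so any
R_ex broadening inflates J(0) — a documented caveat, not a fitted term.
σ(J) is propagated by seeded Monte Carlo (1000 Gaussian draws of the
rate triple).

In the extreme-narrowing regime the mapped values approach (2/5)τ; note
that J(0.87ω_H) carries the factor 1/(1+(0.87ω_H τ)²), which at 600 MHz
and τ = 50 ps is a 2.6% deviation — intrinsic to the model, not an
estimation error.  R₁ and R₂ also remain ~1.6% apart in this limit
because the CSA term weights J(ω_N) differently in the two rates.

## The R₂ cluster model

    R₂(i) = A·Σ_{j=1..N} wⱼ·e^(−|i−j|/λ₀)
            + Σ_c R₂c·e^(−(i−x_c)²/(2Δ²))

The first term models intrinsic segmental motion: residue j's
contribution to residue i decays exponentially with sequence separation,
with persistence length λ₀ (residues).  wⱼ proxies the intrinsic
correlation time: 1 for Gly/Ala and 7 for all other residues in the
size-weighted variant (small residues permit more backbone flexibility),
or uniformly 1.  Each cluster adds a Gaussian of amplitude R₂c (s⁻¹)
centred at x_c with half-width Δ.  The half-width is interpreted as the
Gaussian σ (exponent −(i−x_c)²/2Δ²); the plain decay-length convention
exp(−((i−x_c)/Δ)²) is available via `width_convention="decay"` since
both appear in the literature.

Fitting: weighted nonlinear least squares over (A, λ₀) plus (R₂c, x_c,
Δ) per cluster, with bounds A ≥ 0, λ₀ ∈ (0.1, 20] residues, R₂c ≥ 0,
x_c within [first−2, last+2], Δ ∈ [0.5, N] — chosen for identifiability
on ~20-residue chains.  λ₀ can alternatively be pinned
(`fix_lambda0=`), since published analyses do not always float it.
Cluster centres are multistarted at the local maxima of (data − a
cluster-free prefit baseline), capped at 12 start combinations, with
ties broken on lowest χ².  K defaults to 1; `select_n_clusters` compares
K ∈ {0, 1, 2} by small-sample-corrected AICc.  Parameter uncertainties
come from a bootstrap over residues (unique-resample refits; 50–200
draws are adequate on 20 residues).  On a 20-residue chain A and λ₀ are
partially degenerate (their product sets the baseline level); the
baseline itself, and the cluster parameters, are well determined.

A null/control preset generates cluster-free profiles whose intrinsic
amplitude (A = 0.12, λ₀ = 2) is anchored so the profile tops out near
3.2 s⁻¹ — the behaviour of a coil-like chain without an aromatic
anchor.  On such data the fitted cluster amplitude should be
statistically indistinguishable from zero and the baseline alone should
correlate with the data at r > 0.9; both are exercised as control tests.

## Secondary shifts, CSI, Karplus

Reference shifts are base random-coil values plus neighbour corrections
summed over offsets −2..+2; chain ends use only existing neighbours.
Two base sets ship with the package, both transcribed to working
precision and labelled by provenance: an 8 M urea, pH 2.5 set (the
appropriate reference for urea-denatured samples) and an aqueous 1995
coil set for comparison.  The packaged correction file carries only the
dominant preceding-proline increments (CA −2.0, C′ −0.5, CB +0.1 ppm)
and treats all other corrections as zero; full user-supplied tables are
accepted in the same three/four-column TSV format.  Input shifts are
assumed already referenced to DSS; no re-referencing is attempted.

Because the 8 M urea reference was recorded at pH 2.5 while denatured
samples are often measured near pH 3.5, Asp and Glu (whose ¹³C shifts
titrate in this range) are excluded from Δδ analysis when
`exclude_ph_sensitive` is set; His exclusion is available the same way.

CSI: per-nucleus index +1/0/−1 by thresholded Δδ (defaults ±0.7 ppm CA,
±0.5 ppm C′ and CB), CB sign inverted, majority vote per residue with
ties → coil, and helix/strand runs shorter than 3 residues reset to
coil.  Deviant-residue flagging uses separate thresholds (defaults
0.3 ppm CA/C′, 0.5 ppm CB — common practice for ¹³C secondary shifts;
the exact cutoff used in any given study varies, so the threshold is
configurable and echoed into output metadata).

³J(HN,Hα) couplings are inverted through
J = A·cos²(φ−60°) + B·cos(φ−60°) + C with the HNHA calibration
A = 6.51, B = −1.76, C = 1.60 Hz (configurable).  The quadratic in
cos(φ−60°) is solved exactly, giving up to four φ branches in
(−180°, 180°]; an empty set (J above the curve maximum) is a valid
result.  The chosen branch defaults to the solution nearest φ = −120°,
the sterically dominant region for non-Gly residues.

## Contacts and profiles

Atom classes: HN/H are backbone amide, HA (and Gly HA2/HA3) are alpha,
any other proton is side chain; non-proton names are rejected.  The
class label depends only on the unordered atom-class pair and |j−i|, so
classification is symmetric; contacts are stored with the lower residue
first, and duplicates (same atom pair from different peaks or mixing
times) collapse to one entry with multiplicity.  Side-chain contact
tables around a focus residue include only side-chain-to-side-chain
pairs — backbone contacts live in the connectivity map.

AABUF uses the Rose et al. 1985 average-area-buried scale (packaged),
a uniform sliding window (default 5 — appropriate for a 20-mer;
ProtScale-style weighting) truncated at chain ends, then min–max
normalization to [0, 1].  Constant profiles cannot be normalized and are
returned flagged.  Helix-propensity files from external predictors are
parsed (two-column residue/percent) and validated, never computed.

## Diffusion

Stejskal–Tanner fits use b(g) = (γgδ)²(Δ−δ/3)·s with the rectangular-
pulse exponent by default; s is a configurable shape factor for shaped
gradients.  The recommended route to R_H is an internal reference
compound (R_H = D_ref/D·R_H,ref), which cancels the solvent viscosity —
important because the viscosity of concentrated urea solutions is far
from water's and is deliberately not defaulted.  Stokes–Einstein mode
(R_H = k_BT/6πηD) is provided for when (T, η) are known.

## Synthetic data: what it does and does not emulate

Generators are deterministic functions of (config, seed) and return
(truth, data) pairs.  Defaults emulate the study conditions of a
denatured 20-residue peptide at 600 MHz: ten-delay schedules (10–1200 ms
for R₁, 15.6–469.4 ms for R₂) with duplicates at two delays, 2%
multiplicative intensity noise, 0.1 s⁻¹ additive noise on R₂ profiles,
0.02 ppm shift noise, one cluster (R₂c = 2 s⁻¹, x_c = 8, Δ = 3) on the
size-weighted baseline (A = 0.05, λ₀ = 2), a helix-like shift bump
(+CA/+C′, −CB), a 20% cis-proline fraction with 10% intensity noise,
and 16-point gradient decays with D = 1.5×10⁻¹⁰ m²/s.  Prolines are
masked for HN-detected observables in the paper-like preset.

Not emulated: spin physics of the pulse sequences, lineshapes and peak
overlap, chemical-exchange broadening, baseline distortions, and
assignment errors.  Passing recovery tests therefore demonstrates the
estimators are correct and unbiased under the assumed noise model, not
that real spectra of comparable quality will yield errors this small.

## Problem sizes

Recovery statistics are computed at: 200 series (rate fits), 100 seeds
(cluster recovery, null control, diffusion recovery), 100 random triples
(mapping round trip), 50-draw bootstraps on 20-residue profiles, and
500 simulations for interval coverage.  These sizes put Monte Carlo
error well below every tolerance asserted while keeping a full pipeline
run around a minute.
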