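# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators emulate, and the
known limitations.

## Charge–hydropathy classification

Mean net charge is the absolute per-residue excess of (K, R) over (D, E);
H, C and Y are treated as uncharged at pH 7 and termini are ignored,
matching the convention of the widely used web implementations of the
plot.  Hydropathy uses Kyte–Doolittle values rescaled by (KD + 4.5)/9 to
[0, 1], averaged over fully interior sliding windows (default 5; a
length-N sequence has N−4 windows) and then over windows.  The boundary
⟨R⟩ = 2.785⟨H⟩ − 1.151 separates natively unfolded from ordered proteins;
a point exactly on the line is called *ordered* (the conservative call).
Both boundary coefficients live in `config.py` and can be overridden.
The windowing convention of the original web service is not documented;
interior windows with no padding are this package's choice, and at
window = 1 both statistics are permutation invariant by construction.

## SEC hydrodynamics and compaction states

Calibration regresses K_AV on log₁₀R_S (that is the direction in which
calibration data are plotted) and inverts the fitted line analytically
for unknowns; extrapolation beyond the standards' K_AV range is permitted
with a logged warning.  The native-state scaling law
log₁₀R_S = −0.204 + 0.357·log₁₀MM (MM in Da, R_S in Å) reproduces the
Stokes radii of all six common calibration standards (thyroglobulin
75.1 Å … carbonic anhydrase 24.5 Å) to the printed decimal.  The
non-native laws (molten globule −0.053/0.334, pre-molten globule
−0.210/0.392, GdmCl-unfolded coil −0.723/0.543, natively-unfolded coil
−0.551/0.493, natively-unfolded PMG −0.239/0.403) are transcribed from
the published hydrodynamic compilations; they are externally sourced
constants, shipped in `config.py` and overridable per run.

Classification minimizes |log₁₀R_S − (a + b·log₁₀MM)| over states and
reports both the nearest state and its compaction *family*: the globular
and natively-unfolded PMG branches both read "PMG-like", the two coil
branches read "coil-like".  The family is the scientifically meaningful
call — the sibling branches differ by less than typical measurement
error over much of the mass range — and it makes the call robust to
which sibling happens to win.

Equivalent-sphere volume and density are reported with Table-style
rounding (0.1·10³ Å³, 0.01·10⁻³ kDa/Å³).

## Sedimentation

The module deliberately operates downstream of boundary fitting: raw
scan inversion (c(S) distributions, Lamm-equation solvers) is a project
in itself and is not re-implemented.  Given (s, f/f₀) pairs the full
characterization row follows in closed form by combining the Svedberg
relation with R_S = (f/f₀)·r₀(MM), giving
MM^(2/3) = s·N_A·6πη·(f/f₀)·(3v̄/4πN_A)^(1/3)/(1−v̄ρ).  The frictional
reference is the anhydrous sphere (hydration ignored), which slightly
inflates f/f₀ relative to hydrated conventions; the interpretation bands
(1.05–1.30 globular, 1.75–3.0 IDP-like) are quoted for the same
convention.  Default reference conditions are water at 20 °C
(ρ = 0.99823 g/ml, η = 0.010016 poise) with v̄ = 0.730 ml/g; study-
specific buffer properties enter through `BufferConditions`.

## SAXS

*Guinier.*  ln I is fitted against s² by weighted least squares
(σ_lnI = σ/I) over a window found self-consistently: starting from a
quarter of the curve, the window is re-derived from s·R_g ≤ cutoff until
it stabilizes; two-cycle oscillations settle on the smaller window.  The
default cutoff 1.3 is the field's convention and carries a known
percent-level systematic for globular shapes; accuracy-critical
recoveries on noiseless synthetic curves use 0.5 (sphere) or 0.8
(Gaussian chain), where the approximation is honest — the sphere R_g is
then recovered to < 0.5% and the Debye-chain R_g to < 3%.  The
`first_point` parameter mimics beamstop trimming.

*Kratky.*  s²·I/I(0) is labelled "globular" only if it has an interior
maximum and later falls below 50% of that peak within the measured
range; plateaus and monotone rises are "disordered".  This operational
criterion reproduces the textbook sphere/coil dichotomy; a dimensionless
variant ((sR_g)² I/I₀ vs sR_g) is provided for visualization.

*Indirect Fourier transform.*  I(s) = 4π∫ p(r)·sinc(sr) dr is
discretized by trapezoid quadrature on an r-grid (default 101 points)
with p(0) = p(D_max) = 0 clamped, and solved as a Tikhonov-regularized
weighted least-squares problem with a second-difference penalty.  The
penalty weight α (default 10⁻⁵) is expressed relative to the norm ratio
of the data and penalty blocks, so it is dimensionless and transfers
across intensity scales.  Negative excursions of p(r) are permitted by
the solver; their mass fraction is reported and the moment integrals
(I₀, R_g² = ∫pr²dr / 2∫p dr) use the clipped distribution.  The reduced
χ² uses N − k degrees of freedom with k the number of free grid values;
because regularization reduces the effective parameter count, χ² on
matched-noise data lands slightly below 1 rather than at 1.

*D_max scan.*  Among candidate D_max values the smallest is selected
whose χ² is within 5% of the grid minimum — or already below 1, where
further χ² differences are noise — and whose p(r) is ≥ 99% non-negative
by mass.  This is a proxy for the perceptual criteria of the classical
regularized-IFT programs, which are not replicated.

*Shape ratio.*  R_g/R_S intervals: ≤ 0.80 sphere-like, 0.875–0.987
oblate, 1.36–2.24 prolate, > 2.24 extended; the gaps (0.80–0.875 and
0.987–1.36) report "intermediate".  When both a Guinier and a p(r) R_g
are available the p(r) value is used, being the lower-variance estimate.

## Coarse-grained ensembles and GA selection

Conformers are Cα-only chains with fixed 3.8 Å virtual bonds, bond angle
sampled uniformly in cos θ ∈ [−0.5, 0.9], uniform dihedrals, and
two-tier excluded volume: 1–3 neighbours may approach to 3.3 Å while
sequence-distant residues carry an 8 Å effective diameter that accounts
for side-chain bulk.  Chains are grown with per-step rejection and then
equilibrated with pivot moves (random rigid rotation of the tail about a
random bead, accepted iff the pivot angle stays in the prior's support
and no clash appears) — growth alone over-represents kinetically
accessible conformations and yields near-ideal-chain statistics, whereas
the equilibrated ensemble shows the good-solvent scaling expected of a
coil: mean R_g ∝ N^ν with ν ≈ 0.56–0.59 over N = 50–400.  All geometry
constants are in `config.py`.

Scattering uses the Debye sum with a constant per-bead form factor;
pairwise distances are histogrammed at 0.5 Å by default (exact double
sum available), accurate to ~0.2% over the fitted s-range.  Atomistic
form factors, excluded-volume and hydration-layer terms are out of
scope: all ensemble tests compare against data generated by the same
scattering kernel, so form-factor fidelity would add nothing testable.

The genetic algorithm works on multisets of pool indices (chromosome =
sub-ensemble of fixed size, default 20): fitness is the reduced χ² of
the member-averaged profile with an analytic least-squares intensity
scale; binary-tournament selection, uniform crossover (p = 0.5/gene),
per-gene mutation to a random pool member (p = 0.1), elitism of 1 (the
best χ² is non-increasing by construction).  Defaults (population 50,
100 generations) follow common ensemble-optimization practice; only the
pool size is ever dictated by a study design (10⁴ in the motivating
workflow; tests use 2·10³ to keep runtimes in seconds).

Bimodality of the selected R_g distribution is called by a 2-means split
with Ashman's D > 2 and a 10% minimum mass per component; a unimodal
Gaussian split in half scores D ≈ 1.3, comfortably below threshold.

## CD

Molar residual ellipticity is the per-residue molar form
[θ] = θ_mdeg/(10·l·c·n_res) (deg·cm²·dmol⁻¹); the alternative
mean-residue-weight convention differs only in how the residue count
enters and is a user-side substitution.  Melt cooperativity compares a
straight line with a four-parameter two-state sigmoid by AIC
(n·ln(RSS/n) + 2k): "cooperative" requires the sigmoid to beat the line
by more than 2 AIC units; numerically perfect lines short-circuit the
comparison.  The test is invariant under affine rescaling of the MRE
axis.  Secondary-structure deconvolution is provided only as a
non-negative least-squares hook onto a user-supplied reference basis; no
basis ships with the package.

## Synthetic data: what it does and does not emulate

Generators cover solid spheres, Gaussian (Debye) chains and prolate
ellipsoids with relative-Gaussian or Poisson noise; SEC calibration
tables from a known K_AV line; sequences hitting prescribed composition
statistics (net charge exact by construction, window-1 hydropathy within
0.02); conformer mixtures with named compactness presets (the compact
preset also shrinks the excluded diameter, emulating net intra-chain
attraction of a collapsed sub-state); and linear or sigmoidal melts.
Everything is bit-reproducible under a fixed seed.

These generators validate *recovery*: that the analysis returns known
truth under the stated noise.  They do not emulate inter-particle
interference, radiation damage, buffer-subtraction artifacts, detector
smearing, concentration dependence, or chemically realistic local chain
geometry — so green tests demonstrate correctness of the inference
machinery, not immunity to the systematic errors of real measurements.

## Problem sizes

Default test and acceptance runs use 2,000-conformer pools (chains of
100 residues) for GA recovery, 150 conformers per length for the R_g
scaling check, 200–500-point SAXS grids over s = 0.002–0.213 Å⁻¹, and
200 Monte-Carlo replicates for calibration-bias checks; these sizes give
stable statistics while keeping the whole suite under a minute of CPU.
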