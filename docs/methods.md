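# Methods

This note documents the models, numerical choices and limitations behind
each module, and states precisely what the synthetic-data generator does
and does not emulate.

## Structures, surfaces and interfaces

Structures are held as `biotite` `AtomArray`s wrapped with a provenance
tag. Reading keeps ATOM/HETATM records with occupancy > 0, resolves
alternate locations to the highest-occupancy conformer and drops waters —
all deterministic choices so that downstream geometry is reproducible.

**Canonical frame.** Every quadrature-based quantity (SASA, projected
shadow areas) is computed after re-expressing coordinates in a
molecule-fixed frame: centroid at the origin, axes along the PCA
eigenvectors of the coordinate covariance, signs fixed by the third
moment along each axis, right-handedness enforced. Rigid motion of the
input then changes nothing but floating-point noise, which makes
interface areas and CCS values *exactly* invariant instead of
invariant-up-to-quadrature. Degenerate cases (near-spherical point sets
with ambiguous axes) are harmless because such bodies are quadrature-
isotropic anyway.

**SASA** is Shrake–Rupley (`biotite.structure.sasa`) with the single-atom
van der Waals radius set (C 1.70, N 1.55, O 1.52, S 1.80 Å), probe 1.4 Å,
960 sphere points by default. Exactly coincident atoms are well-defined:
each keeps its boundary points (the area is bounded by the two isolated
spheres), which is the library convention; the contract is determinism,
not a particular split.

**Buried interface area** between domains a and b, per chain, is
`(SASA(a) + SASA(b) − SASA(a∪b)) / 2` with all three terms evaluated in
the *union's* canonical frame so the difference vanishes identically for
non-contacting domains. The mean over chains is reported. The ÷2
(half-buried-SASA, the PISA convention) is an explicit choice: the
alternative 2× convention would double the reported areas.

**Hydrogen bonds** are distance-only on heavy atoms because deposited
models carry no hydrogens: donor = N/O with an attachable proton by
residue chemistry, acceptor = N/O with a lone pair, two tiers (short
< 3.5 Å, long ≤ 4.0 Å). When both atoms could donate, the nitrogen wins;
an O–O tie is broken by lexicographic atom identity, making the census
symmetric in its arguments. Cross-variant matching keys bonds by
(residue, atom) pairs after subtracting the +68 metavinculin tail offset
for residues past the insert.

**Domain partition** (D1 1–252, D2 253–485, D3 486–717, D4 718–835,
hinge 836–895, Vt 896–1066, insert 916–983) follows the deposition's
annotations and lives in an editable YAML, not in code.

## Anchoring spots

A pocket is a cluster of solvent-shell grid points (0.8 Å grid, between
2.6 and 4.2 Å from the nearest atom centre) whose ray-cast buriedness —
the fraction of 32 Fibonacci-fan rays (8 Å reach, 1 Å steps, 2 Å hit
radius) that strike an atom — exceeds 0.55. A point over a convex body
blocks at most about half its rays, so convex fixtures yield nothing.
Cluster depth is the mean excess buriedness scaled to Å, floored so the
lining atoms always fall within `mouth_radius + depth` of the centroid.

Probes are single canonical rotamers built with ideal bond geometry
(side chain from Cβ; Cα retained for Thr/Ile), rigid throughout. The
score is a deliberately lightweight semi-empirical sum:

- **vdW**: united-atom 12-6 Lennard-Jones (Rmin/2: C 1.95, N 1.70,
  O 1.60, S 2.00 Å; ε: 0.12–0.25 kcal/mol, geometric mixing); any
  contact under 2.0 Å scores +∞.
- **Electrostatics**: Coulomb with distance-dependent dielectric
  ε(r) = 4r, multiplied by `(0.5 + 0.5·burial)` so the interaction
  deepens as the probe buries (the dielectric-shielding correction).
  Charges are formal charges smeared over terminal groups (ammonium +1,
  guanidinium +1/3 per atom, carboxylate −0.5 per O, amide ±0.38).
- **Solvation**: atomic-solvation-parameter × buried-area estimate,
  where per-atom burial is the smooth kernel
  `1 − exp(−0.35·Σ exp(−(r/4)²))` over receptor neighbours — an
  analytic stand-in for per-pose SASA that keeps optimisation cheap,
  smooth and rigid-motion invariant. Hydrophobic burial is favourable
  (−0.016 kcal mol⁻¹ Å⁻²), polar mildly unfavourable, charged costly
  (+0.024).

Mapping runs seeded random starts (position jitter σ = 2 Å around the
cavity centroid, uniform orientations) followed by Powell refinement over
the 6 rigid degrees of freedom; the best pose per (cavity, probe) is
kept. **The force field is not parameterised to reproduce published ΔG
magnitudes** — the supported outputs are anchor identities, the strong
flag at the −3 kcal/mol cutoff, and relative counts between interfaces.

## Projection-approximation CCS

CCS is the mean, over seeded uniformly random orientations (quaternion
sampling, default 3000), of the area of the union of atom disks of radius
(vdW + gas radius, default 1.0 Å) projected on the viewing plane,
rasterised at `grid_spacing` (default 1.0 Å; use 0.1 Å for few-atom
analytic checks). The reported sd is the orientation standard error; a
global `scale_factor` (default 1.0) absorbs method differences to other
CCS estimators. PA systematically underestimates large concave shapes
relative to trajectory methods; within this package it is used for
*relative* comparisons along the opening coordinate, where that bias
largely cancels.

Opening models displace the tail domain rigidly; the hinge tether
(default 140 Å, roughly an extended ~60-residue linker) bounds how far
the first tail residue may move from the last head-side residue, and
poses are rejected if they *create* more than `max_clashes` new < 2 Å
contacts (contacts already present in the closed input are its geometry,
not a defect). The separation coordinate is the Cα–Cα distance between
two marker residues (defaults 875/836). In scans, a requested separation
at or below the closed-state distance keeps the closed geometry and is
flagged; matching experimental state CCS values to scan rows is
deliberately one-to-many because distinct geometries share cross
sections.

## IM-MS analysis

Peak picking smooths the trace (σ = 1.5 bins), takes prominence-filtered
local maxima and centroids them over ±3 bins. Charge-ladder inference is
brute force over the charge of the highest-m/z peak; since any integer
multiple of the true charge explains the peaks equally well (harmonic
degeneracy), the smallest charge within twice the best mass-consistency
spread is taken. "Major" states are ≥ 5% of the base peak by default —
the threshold behind the printed 7/11/16 counts — and the envelope centre
is the intensity-weighted mean m/z of all detected peaks.

Calibration is the standard traveling-wave protocol: corrected drift
`t' = t − EDC·√(m/z)/1000` (EDC 1.57), reduced CCS
`Ω' = Ω_lit/(z·√(1/m + 1/m_gas))` with N₂ (28.0134 Da) as drift gas,
least squares on `ln Ω' = ln a + b ln t'`, residuals retained and
analyte conversions flagged when they extrapolate beyond the calibrant
drift range. Proton mass 1.00728 Da. Calibrant identities are not part
of the published record, so the generator ships a fictional but
physically plausible table (masses 40–320 kDa, CCS ~ m^(2/3)); real-data
users supply their own CSV.

Ensemble profiling locates the compact mode from the weighted CCS
histogram and splits at `centroid + 3·sd`. A genuine folded mode is
narrow; if the material around the mode spreads wider than 4% relative,
no compact population exists and the whole ensemble counts as extended
(this handles the degenerate fully-unfolded input).

## CIU state detection

The fingerprint is the per-voltage normalised histogram of calibrated
CCS on a shared axis (default 160 bins, optional sum-preserving Gaussian
smoothing); all-zero rows are flagged, never normalised.

The central model is a **shared-component mixture**: k ≤ 3 Gaussian
components with centroids and widths common to all voltages and
per-voltage weights. Sharing is the scientific statement that the same
three conformers exist throughout the ramp, and it is what stabilises
centroid estimates for states populated only in narrow voltage windows.
Fitting is EM on the binned data weighted by raw counts, with one
deterministic evenly-spread initialisation plus seeded random restarts
(the pooled profile is dominated by the closed state, so naive quantile
initialisation collapses onto it). Model order is chosen by BIC with the
per-voltage weight parameters counted; candidate models whose adjacent
centroids sit closer than two pooled widths are discarded, so unimodal
data yield exactly one state. Components are labelled C, SO, O by
centroid order.

A state is "present" at a voltage when its weight is ≥ 0.10 — the
presence threshold is a configuration value; 0.10 reproduces the printed
onsets on the generator defaults. For each adjacent pair: onset = first
voltage the new state is present, completion = last voltage the old one
is, coexistence = completion − onset, and the transition is *gradual*
when coexistence ≥ 15 V (three grid steps) else *abrupt*. Dwell width is
the presence extent plus one step.

## FA morphometry and decay

Measurements come from `skimage.measure.regionprops`: area = pixel
count × pixel_size², length = `feret_diameter_max` × pixel_size. Note
the Feret convention: skimage measures on the 0.5-level contour of the
pixelated region, so a 10×10-pixel square reports √(10²+9²) ≈ 13.45 px —
between the pixel-centre diagonal (9√2) and the corner diagonal (10√2).
Class thresholds are half-open: small iff area < 1 µm², short iff
length < 2 µm.

Log-normal size fits are exact MLE on log areas with normal-theory CIs
for µ and chi-square CIs for σ; all-equal samples are rejected as
degenerate, n < 20 as underpowered. Bleach correction divides by the
reference channel (smoothed with a 5-frame moving average) rescaled to
its initial value. The decay model `I(t) = p + (1−p)e^(−kt)` includes a
plateau because constitutively active variants hold FAs at a
force-independent level; its initial slope is `100·k·(1−p)` %/min. For a
flat series the (k, p→1) pair is unidentifiable, so the fit falls back
to the zero-rate model whenever the flat fit explains the data within an
AIC-style allowance. CIs come from bootstrap over FAs when per-FA traces
are available, else from the curve covariance; fits with large residuals
or slopes not distinguishable from zero are flagged.

## The synthetic world

The generator emulates, per variant: the charge-state envelope (Gaussian
peaks at (M + z·1.00728)/z, hand-set per-charge weights reproducing
7/11/16 major states and the broad 29+–55+ metavinculin wing, σ = 8 Th,
0.3% baseline noise); CIU occupancies from two sequential logistic gates
(midpoint/sharpness placed so the 10%-presence crossings land on the
observed onsets: 140→180 V gradual for wild type, ~140 V abrupt for
metavinculin, 120 V for both T12 forms, with an early second gate making
the T12-A974K semi-open state short-lived), per-state Gaussian CCS at
the experimentally measured centroids, Poisson ion counts and drift
times through the inverse calibration; a compact + extended ensemble
(40% extended, uniform up to 13,200 Å², mapped to the 19–24 / 25–56
charge split); and FA fields of non-overlapping ellipses on a jittered
grid with log-normal areas, multiplicative per-FA noise (σ = 0.05),
pixel noise, a flat background, plateau-exponential decay and a shared
bleaching channel. Masses are not part of the published record and are
single documented choices (117,000 Da wild type, mutants adjusted by the
substituted side chains, metavinculin +7.4 kDa).

What the generator does **not** emulate: ion heating and gas dynamics
(occupancies are phenomenological logistics, not unfolding
thermodynamics), peak-shape asymmetries and detector saturation, FA
birth/death, translocation and segmentation errors (masks are given, as
segmentation is outside scope), and any pharmacology of the Rho-kinase
inhibitor beyond the decay law itself. A green recovery test therefore
establishes that the analysis inverts the stated observation model at
realistic noise — not that it would survive every instrument artefact.

Determinism: every generator draws from one seeded NumPy `Generator`;
identical parameters and seed give byte-identical outputs, recorded as
SHA-256 digests in a manifest.

## Known limitations

- Anchoring-spot energies use a minimal force field; only identities,
  the strong flag and relative counts are supported claims.
- PA-CCS needs a fine grid (≤ 0.1 Å) for few-atom analytic accuracy; the
  1 Å default is tuned for protein-sized unions.
- Charge-ladder inference assumes one dominant species per spectrum;
  mixtures of masses would need per-envelope segmentation first.
- The mixture fit assumes voltage-independent state centroids; genuine
  centroid drift within a state (intra-state compaction) would be
  absorbed into widths.
- Structure-dependent acceptance checks require user-supplied deposited
  coordinates; nothing is downloaded at run time.
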