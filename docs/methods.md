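# Methods

This note documents the models, numerical choices and limitations of the
`depet` toolkit, module by module.

## Shell-intersection geometry (`depet.geometry`)

The FDQ construction needs the intersection volume of two spherical shells
(thickness δr) whose centers are a distance d apart. We compute it from the
clamped two-ball overlap volume

    L(d, a, b) = 0                        if d ≥ a + b or a ≤ 0 or b ≤ 0
               = (4π/3) min(a, b)³        if d ≤ |a − b|
               = lens formula             otherwise,

with the lens volume of spheres ψ, ω at separation χ

    V = π (ψ+ω−χ)² (χ² + 2χψ − 3ψ² + 2χω − 3ω² + 6ψω) / (12χ),

by inclusion–exclusion over the four bounding spheres:

    V_K∩κ(d, R, r) = L(d,R,r) − L(d,R−δr,r) − L(d,R,r−δr) + L(d,R−δr,r−δr).

This single expression reproduces every named case — disjoint shells, a
shell contained in the other's cavity, outer tangency (single lens), one
inner sphere swallowed (two-term difference), and the generic four-term
case — because the clamps implement exactly the interval dispatch those
cases describe. The lens formula is singular at χ = 0, so separations below
1e−9 Å are treated as concentric analytically (radial-interval overlap).
Boundary conditions written as equalities on the 0.05 Å grid become
half-open interval membership for continuous d.

Every branch is validated against an independent rejection-sampling
Monte-Carlo volume oracle (10⁶ points, agreement within 3 standard errors),
and a conservation identity — summing V_K∩κ over all κ-shells up to r_max
reproduces shell K clipped to the r_max ball — holds to 1e−8 relative.

Angles between fitted distance pairs use the law of cosines on the triangle
(Cys Cα, Trp Cα, Trp Cβ) with the Cα–Cβ bond fixed at 1.54 Å; cosines within
1e−9 of ±1 are clamped (the arccos there is precise only to ~1e−5 degrees,
which the tests reflect). Angles are degrees externally, radians internally.

## Radial densities (`depet.conformer_density`)

Conformer ensembles (multi-model PDB via Biopython, or plain XYZ) are
reduced to the distance between an anchor atom (Cα or Cβ) and the unweighted
centroid of a moiety (xanthene or indole) per frame, then binned at
δr = 0.05 Å with half-open bins ((k−1)δr, kδr]; a distance exactly on an
edge goes to the lower bin, so every sample is counted once. Histograms are
normalised to probability mass. Support is data-driven: bins beyond the last
occupied one carry zero probability, and no fixed maximum radius is imposed.
Cβ-anchored Trp densities reuse the same ensemble with the anchor switched;
nothing is re-simulated. All frames are used as provided (no equilibration
trimming).

## FDQ functions (`depet.fdq`)

The quench curve is the double volume-ratio sum over occupied shell pairs,
implemented exactly in that form (both V∩/V_K and V∩/V_κ factors), on a
distance grid with the same 0.05 Å step as the densities, from 0 to the sum
of the two supports (beyond which the curve is identically zero). Curves of
stereoisomer conjugates are mixed by pointwise averaging.

The empirical parameterisation (≤2 exponentials + ≤6 Gaussians, Gaussian
term A/√(2πσ)·exp(−(d−μ)²/2σ²)) is fit by forward selection: component
counts are tried in order of increasing total, each fit seeded greedily
against the running residual and refined by bounded least squares with
nonnegative amplitudes, stopping when the RMS residual drops below 1e−3 of
the curve maximum. Nonnegativity is imposed because the curve is a
probability; it also guarantees the fitted function never needs clipping.
An all-zero curve yields the zero model. Fluorophores of different
chemistry can be normalised by multiplying a model by the ratio of
Stern–Volmer constants (K_SV / K_SV,reference); the scaling is multiplicative
with an explicit reference.

## Signal preprocessing (`depet.signal_processing`)

* Bleach correction subtracts a single-exponential least-squares fit to a
  no-pulse reference recording.
* ΔF amplitudes are the mean of the last 20% of the pulse minus the
  pre-pulse baseline mean (a documented default; the plateau avoids the
  rising phase).
* ΔF–V is fit by a single Boltzmann ΔF_total/(1 + exp[(zF/RT)(V½ − V)]) +
  ΔF_min (F = 96485.332 C/mol, R = 8.314462 J/mol·K, T = 294 K default);
  a fitted negative z is normalised to the equivalent positive-z
  parameterisation. ΔF > 0 means fluorescence increase upon depolarisation
  (unquenching); the sign convention is carried into the distance fit, where
  c is constrained positive and the sign lives in the FDQ difference.
* Conductance G = I/(V − E_K) excludes points within 0.5 mV of the reversal
  potential (the division is unstable there). The G–V curve is fit by the
  sum of two Boltzmann components from several starts; G_max is the exact
  sum of the two component maxima by construction. Two shallow overlapping
  components are intrinsically correlated: recovery to 10% needs
  well-separated transitions, which the tests use.
* Stern–Volmer: fluorescence normalised by absorbance, F₀/F regressed
  linearly on quencher concentration; the slope is K_SV.

## The inverse problem (`depet.distance_fit`)

`DepetModel` / `DepetResults` follow the model/results pattern: the model
holds the replicate ΔF/G dataset and the FDQ set(s); `fit()` returns a
results object with bootstrap distributions, means, 95% percentile CIs
(2.5–97.5), per-fluorophore fitted ΔF and a `summary()` table.

Bootstrap: each of n_bootstrap sample sets holds, per fluorophore
independently, the mean of a same-size resample (with replacement) of that
fluorophore's replicates. Seeding: each free parameter gets 5 evenly spaced
values spanning its bounds (c log-spaced), and the cartesian product seeds
the optimiser — 125 starts for (d_R, d_A, c), 3125 for the five-parameter
dual fit. Bounds default to 3–28 Å for distances (spanning typical FDQ
supports) and 10³–10⁷ for c. Positivity of c is enforced by optimising
log c.

The per-set optimisation is a bounds-projected Levenberg–Marquardt with
analytic Jacobians, vectorised over the whole seed batch (per-seed damping
and accept/reject, lock-step iterations, SSE-change tolerance 1e−12, at most
120 iterations). Batching over seeds is what makes 12,500+ fits per run
affordable; on noiseless data the optimiser recovers generating parameters
to ~1e−13. Only the least-SSE solution per sample set is kept.

Dual (αα + αβ) fits share c across both equation systems and stack their
residuals. Retained solutions must satisfy |d_αα − d_αβ| ≤ 1.54 Å in the
resting state *and* in the active state — the Trp Cβ sits one C–C bond from
its Cα, so each state's two distances cannot differ by more; this is
enforced per state because that is the only geometrically meaningful
reading. Violating bootstrap solutions are excluded, never projected; the
retained fraction is reported and exhaustion raises.

Orientation: per retained draw, the Cα–WαWβ angle from the law of cosines
(triangle-inequality failures excluded and counted), summarised by mean and
percentile CI, plus planar Cys Cα coordinates with the Trp Cα at the origin
and the Cβ at (0, 1.54).

Determinism: identical (dataset, seed, grid) inputs give bitwise-identical
solution distributions; all randomness flows from one seeded generator per
call, never global state.

## Structure tools (`depet.structure_tools`)

The PPII builder places backbone atoms (N, Cα, C, O) residue by residue from
internal coordinates (NeRF) with standard geometry: bonds N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å; angles N–Cα–C 111.0°, Cα–C–N 116.2°,
C–N–Cα 121.7°; ω = 180°; all residues at φ = −75°, ψ = 150°. The nominal
peptide length is the first-residue (Cys) Cα to last-residue (Trp) Cα
distance; for three prolines this gives 12.50 Å against the 12.4 Å
literature expectation, within the ±0.3 Å agreement one can ask of a
builder whose source used an unstated geometry table. Note that successive
*virtual bonds* (Cα→Cα, 3.804 Å) are exactly constant by screw symmetry,
but the end-to-end chord per added residue oscillates slightly with helical
phase — the helix has ≈3 residues/turn, not exactly 3.

Trilateration solves |x − aᵢ| = rᵢ exactly by the plane–plane–sphere
reduction, returning both mirror branches labelled by the sign along the
anchor-plane normal; target radii are base-point distances plus the
measured distance changes. The bootstrap variant resamples the three delta
distributions per draw, excludes geometrically infeasible draws (raising
beyond 50% infeasible), and summarises clouds by mean displacement along a
configurable axis (the anchor-plane normal by default; pass the structure's
z-axis to report "above/below the membrane plane").

Superposition is Kabsch via SVD with the determinant sign fixed (proper
rotations only); displacement maps superpose on the shared-residue Cα set,
then report per-residue Cα–Cα distances, dropping and logging residues
missing from either structure.

## Synthetic data (`depet.synthetic_fixtures`)

Every experimental input has a generator that is a pure function of
(spec, seed):

* **Conformers** — a freely rotating chain (default bond 1.5 Å, Gaussian
  bend angles 60 ± 15°) with the moiety centroid offset beyond the chain
  end. It reproduces the family behaviour that matters (longer linkers give
  broader, right-shifted reach densities) but none of the force-field
  physics: no excluded volume, no torsional barriers, no solvent. Passing
  tests therefore demonstrate the *pipeline's* correctness, not the realism
  of any particular dye's ensemble.
* **FDQ family** (`example_fdq_family`) — six fixed single-Gaussian models
  with means 8–20 Å and widths 1.8–3.2 Å, peaking near 2×10⁻⁵: magnitudes
  representative of the doubly-volume-normalised contact probabilities the
  pipeline produces, spanning the ~6–25 Å working range of the method.
* **ΔF/G datasets** — the forward model times (1 + cv·N(0,1)) per replicate;
  defaults 10% noise, 5 replicates, matching the recovery benchmarks (truth
  7.0 / 13.5 Å, c = 3×10⁵, within the resting ~6–8 Å and active ~13–14 Å
  regime of the voltage-sensor application and the reported c magnitudes).
* **Sweeps** — Boltzmann fluorescence on a −220…+160 mV / 20 mV protocol
  (20 potentials) plus exponential bleach and Gaussian noise, with a matched
  no-pulse reference.
* **Titrations** — the 0, 2.5, 5, 10, 15, 20, 25, 30 µM series. With
  K_SV ≈ 40 M⁻¹ the ratio F₀/F spans only ~1…1.0012 over this series, so
  noise is parameterised as relative error on the quenching increment
  K_SV·[Q] itself — the quantity the ratioed, baseline-referenced
  measurement actually resolves — rather than on raw fluorescence, where
  even 1% noise would bury the signal tenfold.
* **Peptide peaks** — conjugate/free fluorescence-per-absorbance pairs from
  Q = c·FDQ(d), with multiplicative noise on the conjugate signal.

## Problem sizes

Desk-scale defaults keep full pipelines fast while preserving every
structural feature of the full-size computation: bootstrap criteria run 100
sample sets × 125 seeds (the full-scale routine is 10,000 × 125 =
1,250,000 fits, and the accounting is verified analytically); recovery
benchmarks use 20 independent repetitions; the geometry battery checks ≥50
randomised (d, R, r) triples at 10⁶ Monte-Carlo points each; synthetic
ensembles use 2,000–10,000 frames.

## Known limitations

* The FDQ component-count selection (forward selection at 1e−3 relative
  RMS) is one reasonable rule; externally fitted parameter tables can be
  loaded verbatim through the JSON interface and bypass fitting.
* Static and collisional quenching are treated identically (both are
  contact quenching on steady-state timescales); no quantum-mechanical PET
  rate model is attempted.
* The chain sampler is not an MD substitute in any physical sense (see
  above); real dye ensembles must be imported to build production FDQ
  functions.
* Trilateration assumes exact distances per draw; measurement error enters
  only through the bootstrap deltas, not as a per-sphere tolerance.
* The peptide pipeline analyses the most abundant conjugate species per run
  (largest conjugate absorbance area) and does not model HPLC retention or
  labeling kinetics.
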