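# Methods

## Scope and model system

The package analyses unfolding of the amyloid-β central helix using the
Aβ(13–26) fragment (sequence HHQKLVFFAEDVGS, acetyl/amide capped) and its
helix-stabilising triple replacements V18A/F19A/F20A (`MA`) and
V18L/F19L/F20L (`ML`).  The two histidines can be modelled protonated
(net charge +1 e) or neutral at Nδ (net charge −1 e); protonation enters
only through sidechain partial charges.  Seven residues are classed polar
(H13, H14, Q15, K16, E22, D23, S26) and seven nonpolar (L17, 18, 19, 20,
A21, V24, G25) — a partition that is invariant across variants.

The analysis contract is built around four per-frame observables of the
middle region (residues 15–24):

* **RMSD** over backbone heavy atoms (N, Cα, C, O; 40 atoms), after
  least-squares Kabsch superposition on all heavy atoms of the full
  fragment.  RMSD is mass-unweighted; superposition is likewise
  unweighted.  The reference structure is the ideal built helix
  (φ = −57°, ψ = −47°): no force-field minimiser is in scope, and RMSD is
  reference-relative, so all thresholds are defined against this
  reference.
* **R_g** over all atoms of residues 15–24, mass-weighted (the
  conventional definition; the choice of weighting is a convention, not a
  measurement).
* **αHB count**: the six α-helical backbone hydrogen bonds O(i)→HN(i+4)
  spanning 15–24, numbered 1–6 from the 15→19 pair, each present when the
  acceptor–hydrogen distance is strictly below 2.4 Å.  The criterion is
  distance-only; no angle term and no 3₁₀/π patterns.
* **E_p-p / E_np-np**: summed nonbonded residue–residue interaction
  energies within the polar and nonpolar groups, each pair counted once —
  computed as half the sum of the seven per-residue group energies
  ("divided by two" bookkeeping), which the code asserts equals the
  once-per-pair block sum to 1e-6.

## Structure generation

Conformations are built by sequential internal-coordinate (natural
extension) placement with standard bond lengths and angles, trans peptide
bonds (ω = 180°), amide hydrogens in the peptide plane trans to the
carbonyl oxygen, and L-chirality (N–C–Cα–Cβ improper ≈ −122.7°).
Backbone φ/ψ and the first two sidechain torsions χ₁/χ₂ are free
parameters; remaining sidechain geometry uses fixed extended/planar
templates.  The builder is vectorised over frames, so a whole scripted
trajectory is produced in one pass.  Hydrogens other than amide HN (and
the two C-terminal cap hydrogens) are omitted: no analysis needs them.

## Nonbonded model

Pair energies combine Coulomb and Lennard-Jones 12-6 terms under
atom-based force-shift truncation at r_c = 12 Å: every term is multiplied
by (1 − r/r_c)², which sends the energy *and* its radial derivative
smoothly to zero at the cutoff,

    V(r) = [ C q_i q_j / r + ε_ij ( (R_ij/r)^12 − 2 (R_ij/r)^6 ) ] (1 − r/r_c)²,

with C = 332.0716 kcal·Å·mol⁻¹·e⁻², Lorentz–Berthelot combination
(ε_ij = √(ε_i ε_j), R_ij = R_i/2 + R_j/2).  Atom pairs within three
covalent bonds (1-2, 1-3, 1-4 — including pairs bridging the peptide
bond) are excluded, as is intra-residue interaction; without the bonded
exclusions the covalent-neighbour LJ repulsion between adjacent residues
of the same polarity group (17–18, 22–23, …) would add ~10⁵ kcal/mol of
meaningless constant to the group energies.

The per-atom parameter table is a deliberately simple set shipped with
the package (it is *not* a CHARMM extract, and absolute energies are not
comparable to published force-field values — only arithmetic identities
and qualitative signatures are asserted):

* carbons carry united-atom-like LJ parameters (ε = 0.12 kcal/mol,
  R_min/2 = 2.10 Å) since aliphatic/aromatic hydrogens are implicit;
* each residue template carries its exact formal charge;
* neutral groups (backbone amide dipoles, caps, Gln/Ser/neutral-His
  sidechains) use half-scaled partial charges, emulating aqueous
  dielectric screening of dipole–dipole interactions in the absence of
  explicit solvent.  Ionizable sidechains (His⁺, Lys⁺, Glu⁻, Asp⁻) keep
  integral formal charges, so the net peptide charge is exactly +1/−1 e
  and salt-bridge energetics remain strong.  Without the screening, the
  helical backbone-dipole Coulomb baseline of E_np-np (≈ −150 kcal/mol)
  dwarfs any hydrophobic-cluster signal that rigid-geometry kinematics
  can produce.

## Event detection

Complete unfolding follows three ordered steps: (1) sustained loss of
αHBs, (2) the deepest E_np-np minimum as nonpolar sidechains collapse
into a hydrophobic cluster, (3) a pronounced E_p-p excursion as polar
sidechains (notably the K16 Nζ – D23 Cγ salt bridge) lock in.  The
detector operationalises "changes larger than the high-frequency
fluctuations":

* all four series are smoothed with a centred boxcar of `smooth_ps`
  (default 100 ps);
* **t₁** is the first time the smoothed αHB count drops to ≤ 3 and stays
  there for `sustain_ps` (default 50 ps);
* baseline mean/SD are taken from the pre-t₁ segment of the *smoothed*
  energy series (the same signal searched for minima);
* **t₂** is the first interior local minimum of smoothed E_np-np after t₁
  (horizon 2 ns) that undershoots baseline mean − k·SD (default k = 3);
* **t₃** is the analogous first qualifying E_p-p excursion after t₂
  (horizon 3 ns);
* the verdict is `complete_three_step` exactly when all three steps are
  found in order.  Every threshold is configurable and echoed in reports.

Trajectories are classified from last-2-ns window averages with
precedence C → A → B: C if RMSD ≥ 4.0 Å and αHBs ≤ 0.5 ("≈ 0"), else A if
RMSD < 2.0 Å and αHBs ≥ 2, else B.  This rule (with the 0.5
operationalisation of "≈ 0") uniquely reproduces all 40 reference group
labels, including the two discriminating cases (0.9 αHBs with RMSD < 4
stays B; RMSD 4.72 with 1.9 αHBs stays B).  Column statistics use the
sample SD (n−1): recomputation of the reference RMSD column gives 1.345
(n−1) versus 1.276 (n) against the reported 1.35.  The salt bridge is
called formed below 4.5 Å on Nζ(K16)–Cγ(D23): reported formed/unformed
distances are 3.36 Å and 8.86 Å, and no cutoff is stated, so the midpoint
band edge 4.5 Å (a conventional salt-bridge cutoff) is used.

## Synthetic trajectory generator

The generator is kinematic, not dynamical: scripted torsion schedules
interpolate between fixed way-point conformations (helical, open,
partially unfolded, clustered, polar-bridged, extended) on shortest
angular paths, with per-segment easing so that the energy extrema fall
sharply at the scripted event times; seeded Gaussian jitter then emulates
thermal fluctuation.  Presets:

* `stable` — helical throughout (group A, last-2-ns αHB average ≥ 5);
* `partial_B` — two αHBs break at a sampled time (U(2, 8) ns) and the
  run stays partially unfolded (group B, no step-1 call: the smoothed
  count stays near 4);
* `refold_A` — partial unfolding at U(4, 8) ns, refolded by U(12, 17) ns
  (group A);
* `complete_C` — t₁ ~ U(1, 16) ns, t₂ = t₁ + U(0.05, 0.5),
  t₃ = t₂ + U(0.5, 1.5), then extended for the rest of the 20 ns run
  (group C, complete verdict).  The preset gaps mirror the mechanistic
  bounds (step 2 within 0.5 ns of step 1; step 3 within 1.5 ns of
  step 2).

Defaults — 20 ns duration, 10 ps frame stride (2000 frames, first frame
at t = 10 ps so "the last 2 ns" are exactly the final 200 frames), 0.25 Å
jitter amplitude — are the study conditions the analysis expects.

**Way-point construction.**  The helical state uses rotamers chosen once
to be clash-free yet unpacked (sidechains solvent-extended).  The
clustered and polar-bridged way-points were constructed once by numerical
optimisation in torsion space (L-BFGS over φ/ψ/χ₁/χ₂ with clash and
group-energy constraints): the cluster state minimises E_np-np while
keeping E_p-p at baseline, and the polar state minimises E_p-p (forming
the K16–D23 bridge) while keeping E_np-np near baseline so that the
global E_np-np minimum stays at t₂.  The optimised torsions are frozen
in `helix_unravel/_targets.py`; they are design artifacts of the
generator, not fitted quantities.

**Thermal jitter.**  Jitter is a zero-mean Gaussian displacement field in
Cartesian space with per-atom RMS amplitude 0.25 Å (per-coordinate
σ = 0.25/√3) and spatial correlation (squared-exponential kernel,
correlation length 5 Å) drawn per frame from the clean coordinates.
Correlation is essential: independently jittered atoms would make stiff
short-range contacts (e.g. backbone O(i)···C(i+1) at 2.9 Å, which sits on
the LJ repulsive wall) fluctuate as if free, producing ~8 kcal/mol of
spurious energy noise that no kinematic signal could clear.  The
correlated field emulates collective low-frequency motion: local
geometry is nearly rigid while large-scale fluctuation (RMSD, R_g) is
retained.  The amplitude keeps ideal-helix αHB distances (≈ 2.1 Å) below
the 2.4 Å criterion with high probability, with rare single-bond
flickers.

**Shipped ensembles** mirror the reference study design: the wild type
mixes 4 stable + 3 refolding + 8 partial + 5 complete runs (7 A / 8 B /
5 C over 20 trajectories, protonation alternating), while `MA` and `ML`
have 5 + 2 + 3 (7 A / 3 B over 10, no complete unfolding).  Pooled
αHB-count distributions from these presets put the zero-bond frequency of
the mutants at far below one quarter of the wild type's, since only
complete unfolding produces long zero-bond stretches.

### What the generator does and does not emulate

It reproduces the *statistical signatures* the analysis contract needs —
αHB loss times, energy-minimum locations and depths relative to noise,
class-separating last-2-ns averages, salt-bridge formation — with exact
embedded ground truth.  It does not emulate real solvated dynamics:
no water, no kinetics or free-energy realism, no force-field accuracy,
no genuine barrier crossing; temperature labels are metadata only.
Passing the recovery tests therefore demonstrates correctness of the
*analysis pipeline* (detector, classifier, energy bookkeeping) under
controlled conditions, not fidelity of any physical model of Aβ.

## Numerical choices and degenerate inputs

* Kabsch superposition via SVD with determinant correction (proper
  rotations only); collinear or <3-atom fit selections raise a dedicated
  error.  Batched SVD is used across frames.
* Window averages use half-open windows (from, to] so "the last 2 ns"
  picks exactly the final 200 frames under the frame-time convention.
* Series smoothing pads with edge values; the boxcar width is
  round(smooth_ps/stride) frames, minimum 1.
* The step detector requires at least 5 baseline frames before t₁;
  otherwise steps 2–3 are reported absent (verdict `incomplete`).
* Energies guard r → 0 with a 1e-9 Å floor (only reachable on the masked
  diagonal) and treat r ≥ r_c as exactly zero.
* Torsion interpolation takes the shortest angular path and re-wraps to
  (−180°, 180°].
* Display rounding: 2 decimals for Å and kcal/mol, 1 decimal for αHB
  averages, matching the reference tables; internal computation is never
  rounded.

## Problem sizes

Default test and acceptance runs use the full study conditions: 2000
frames per 20 ns trajectory, 20 seeded complete-unfolding runs plus
stable/partial/refold controls for detector scoring, and the 40-trajectory
ensemble set for the distribution contrast.  These sizes keep the whole
suite comfortably within a desktop-scale run while matching the
trajectory geometry the thresholds were defined for.

## Known limitations

* The builder's rigid standard geometry means absolute energies and
  clash patterns differ from relaxed all-atom structures; only relative
  signatures are meaningful.
* The parameter table is a pedagogical simplification (united-atom
  carbons, screened dipoles); it is not suitable for physical energy
  prediction.
* DCD input is not implemented; multi-model PDB is the trajectory format.
* The detector's thresholds are conventions calibrated to the generator's
  noise model; on real MD output they are starting points to be tuned via
  `StepConfig`.
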