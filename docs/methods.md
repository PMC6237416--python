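# Methods

## The model

`twistslide` simulates active nucleosome repositioning by the two-lobe
ATPase translocase of a chromatin remodeler, reduced to 16 collective
coordinates: the 14 histone–DNA contact indexes `x_j` (one per half-integer
superhelical location, SHL −6.5 … +6.5, measured in base pairs of DNA
displacement relative to the cycle-start register) and the two lobe contact
indexes `y1`, `y2` (each lobe's registration on the DNA). A twist defect at
integer SHL `i` is the derived quantity `d_i = x_{i+0.5} − x_{i−0.5}`; +1
means an extra base pair stored between the flanking contacts, −1 a missing
one. Energies are in units of kT (kT = 1), lengths in base pairs.

The potential energy is a sum of closed-form terms:

* **Histone–DNA contact wells.** Each contact contributes
  `depth_j (1 − cos 2πx_j)/2` plus a *flank* term
  `flank_j S(|x_j − round(x_j)|/0.2)` (S = cubic smoothstep) that saturates
  within 0.2 bp of each register. The flank steepens the well walls the way
  a sharp hydrogen-bond contact does, penalizing partial, distributed DNA
  displacement, without raising the barrier top that a full 1-bp hop must
  cross. Without it, collective "creep waves" (many contacts displaced by
  0.1–0.3 bp) would cut the sliding barrier far below the defect-well
  picture. Contacts are strong at the central SHLs (|SHL| < 3; depth 2.0,
  flank 2.4) and weak on the outer arms (0.5/0.6), so the barrier against
  register change is concentrated where the sliding coordinate is measured
  while defects glide freely along the arms to the entry/exit.
* **Twist defects.** At each integer SHL, a smoothed three-well form with
  minima at `d = −1, 0, +1` of energies `mu_minus`, 0, `mu_plus`, harmonic
  stiffness `k = 15 kT/bp²` around each branch, blended by a log-sum-exp
  with smoothing temperature 0.2 kT so the gradient is continuous. Penalties
  are 5.8 kT at the central SHLs (|SHL| ≤ 2) and 2.8 kT on the outer arms,
  echoing the strong position dependence of defect accommodation in
  nucleosomes. Beyond |d| = 2.5 the outer branch simply continues
  quadratically (the documented clamp).
* **Positioning tilt.** Strong positioning sequences are represented
  phenomenologically by a linear bias `tilt_j x_j` at the two contacts
  flanking the remodeler site (1.45 kT/bp each for the 601-like construct
  started 3 bp off register), not base by base.
* **Lobe grips.** Each lobe sits in a 1-bp-periodic cosine well of depth
  `grip_contacts × eps_lobe_dna` (4.8 × 1.8 kT): the per-contact strength
  is the hydrogen-bond scale, and a lobe engages several DNA contacts at
  once. After hydrolysis the lobe-2 grip is weakened by the factor 0.8 and
  the lobe-1 grip by 0.8 as well (`adp_lobe1_factor`): the opening
  conformational change strains both interfaces, lobe 2 distinctly more
  once its factor compounds with the weaker coupling, which sets the
  direction of opening.
* **Open/closed conformation.** A cosine double well in `u = y1 − y2` with
  minima at `u = 0` (open) and `u = 1` (closed), barrier `closure_barrier`
  = 1.5 kT, a soft flat-bottom confinement of `u` to [−0.25, 1.25], and a
  smoothstep offset placing the closed minimum at
  `closure_offset − eps_lobes` — penalized by ~5 kT in the apo and ADP
  states (coupling 0.17 kT), nearly level with ATP bound (coupling 1.0 kT).
* **ATP lobe-1 strain.** `lobe1_strain (1 − S(y1 − y_anchor))`, a
  saturating destabilization (18.3 kT) of the unadvanced lobe-1 register,
  anchored to the cycle-start registration. This term encodes the
  body-frame asymmetry of closure — the closed native structure has lobe 1,
  not lobe 2, displaced along the DNA — and carries the ATP-binding work
  that loads the ratchet. It is deliberately *not* translation invariant: a
  translation-invariant potential cannot prefer the lobe-1 closure channel,
  because the lobe-2-backward closed state is an exact 1-bp translate of
  the fully slid closed state (a congruence that also caps how much switch
  work an invariant model can inject). The DNA–octamer part of the
  potential is exactly 1-bp periodic; the full potential is invariant under
  a joint shift of all coordinates and the anchor.
* **Site distortion with ATP.** With ATP bound the engaged translocase
  pre-distorts the DNA at its site: the +1 bp penalty at SHL +1 and the
  −1 bp penalty at SHL +2 are reduced by `defect_relief` (5.1 kT), the
  twist stiffness there is halved, and the contact wells at SHL 1.5/2.5
  lose `contact_relief` (2.0 kT) of depth and their flanks. This implements
  the closed-state stabilization of the opposite-type defect pair that
  initiates sliding, and is what reconciles the ~6 kT spontaneous barrier
  with fast ATP-driven sliding.
* **Steric wall.** `wall_height max(0, |ρ| − wall_halfwidth)²` with
  `ρ = (x_1.5 + x_2.5)/2 − (y1 + y2)/2`, height 50 kT, half-width 0.3 bp:
  the remodeler body cannot move far relative to the DNA at its site. In
  the apo state this clamps the nucleosome register; in the slid closed
  state the residual wall strain drives prompt opening after hydrolysis.
* **Electrostatic spring.** `−eps_elec exp(−r1²/2σ²)` with
  `r1 = (x_1.5 + x_2.5)/2 − y1`, depth 6.4 kT, range 0.35 bp: the
  attraction between the lobe-1 basic patch and the distal DNA gyre.
  Closure stretches it (r1 → −1); sliding the site DNA restores it, which
  is the directional drive of the ratchet. The charge-mutant remodeler sets
  it to zero.

## Dynamics and the ATP cycle

Coordinates evolve by overdamped Euler–Maruyama,
`q ← q − ∂E/∂q·D_q·dt + sqrt(2 D_q dt) ξ`, with dt = 5×10⁻⁴ reduced time
units, D = 0.05 bp²/tu for DNA contacts and 1.0 for the lobes (DNA
registration changes require a screw-like motion through many contacts and
are far more damped than single-domain lobe hops). One reduced time unit
stands for 10⁵ steps of the residue-level simulations this model condenses
(a declared convention, not a measured mapping), so the default cycle —
apo 200 tu, ATP 100 tu, ADP 100 tu with instantaneous parameter switches —
mirrors a 2×10⁷/10⁷/10⁷-step protocol. The final switch back to apo changes
interactions only and needs no additional phase. Randomness is
generator-per-trajectory (Philox keyed by the trajectory seed, drawn in
fixed blocks), so ensembles are order-independent and every member is
bit-identical to the same trajectory run alone. An optional numba kernel
accelerates the inner loop; the numpy fallback computes identical
arithmetic.

The cycle operates as a switching ratchet: ATP binding loads the lobe-1
strain; lobe 1 advances (closure, stretching the electrostatic spring); the
pre-distorted site nucleates an opposite-type defect pair (+1 bp at SHL 1,
−1 bp at SHL 2); the missing base pair escapes through the weakly held exit
arm while the spring recaptures the site DNA at the +1 register; hydrolysis
weakens lobe 2 and the wall strain of the slid closed state drives opening
by a forward lobe-2 step. The +1 bp defect left near the dyad outlives the
cycle (its release through the strong central contacts is slow), which is
why trajectories often end in the `o1` label with the register already
advanced.

## Analysis conventions

* **Labels.** `[oc][ABCD]?[012]`: open/closed split at `u = 0.5`; among
  closed frames D (site fully slid, `x_2.5` advance ≥ 0.5) takes precedence
  over C (`x_1.5` advance ≥ 0.5) over B (`y1` advance ≥ 0.8) over A (the
  partial-closure catch-all; the published anchor for the A intermediate is
  a lobe-1 advance of ~0.6). The digit is
  `clamp(round(x_1.5 − x_−1.5), 0, 2)`, the number of +1 bp defects at the
  three central SHLs. Advances are measured against the cycle-start
  registration.
* **Outcomes.** `dna_step`/`lobe_step` are the nearest integers to the
  final `(x_1.5 + x_2.5)/2` and `(y1 + y2)/2`. Closure is the first passage
  of `u` over 0.8. Stepping probabilities carry Wilson 95% intervals.
* **Held-state equilibrium sampling.** Landscape and Markov-state analyses
  hold one chemical-state parameter set fixed. A flat-bottom window
  restraint confines `(x_1.5 + x_2.5)/2` to the analysis window
  [−0.5, 1.5]; inside a flat-bottom restraint the relative Boltzmann
  weights are exact, and it prevents register walk-off in long runs.
  Closed-ensemble protocols additionally keep `u` above 0.7 with a soft
  floor, the in-model version of restricting attention to the closed
  translocase manifold.
* **Free energies.** Boltzmann inversion `F = −ln p̂`, min-shifted; bins
  with fewer than 10 samples are masked, never imputed. Well depths are
  read at the registers (±0.15 bp); the counting error per bin is
  `1/sqrt(n)`.
* **Markov models.** Label states, lag 2.5 tu (a multiple of the snapshot
  stride; the implied-timescale plateau was checked at this lag on the
  shipped ensembles), sliding-window counts that never bridge chemical-state
  switches, detailed balance enforced by count symmetrization
  `(C + Cᵀ)/2` — simple and adequate at desk scale — with the stationary
  distribution given exactly by the symmetrized row sums. Frame labels are
  milestoned (a label must persist 0.3 tu to be accepted) so transitions
  are genuine crossings rather than threshold noise. Mean first-passage
  times solve `(I − T_Q) m = lag·1`. For first-passage sources that are
  rare at equilibrium (cB1), half the replicas start in a source-consistent
  configuration (adaptive seeding). Minimum-energy pathways minimize the
  maximum free energy along 8-connected grid paths (bottleneck Dijkstra),
  with summed free energy and lexicographic order as deterministic
  tie-breaks; masked cells are impassable.

## Sequence mapping

polyApG ("AG" repeated, 147 bp, dyad at the center) is the uniform
reference. SHL n maps to base-pair offset 10n from the dyad (the reduced
model has no helical phase, so the integer convention replaces the
crystallographic ~10.17). A 10-bp element replaces the window centered at
the chosen SHL: poly(dA:dT) ("AA"×5) raises the +1 bp penalty at its SHL by
2.0 kT; a TpA repeat ("TA"×5) softens the twist stiffness (×0.7) and, at
|SHL| = 2, raises the −1 bp penalty by 3.5 kT; a TpA element under the
translocase (SHL +2) also multiplies the lobe-2 grip by `g2 = 0.10` —
the weakened lobe-2 interface that lets lobe 2, rather than lobe 1, make
the closure step in a fraction of cycles. Elements act on the
remodeler-proximal side only; mirrored application is an option, off by
default. The 601-like construct is the polyApG backbone with the
positioning tilt flag.

## Calibration and problem sizes

The residue-level study this model condenses runs ~4×10⁷ MD steps per
trajectory; at desk scale everything here is scaled down and the free
parameters were fixed by a one-time calibration (see
`scripts/calibrate.py`) against the study's probability and free-energy
observables: cycle ensembles of 100 trajectories × 8×10⁵ integrator steps,
held-state equilibrium runs of 32–96 replicas × 500–900 tu, the spontaneous
landscape from 96 × 900 tu. These sizes are the package's defaults; all are
arguments. Within tolerance, the shipped defaults reproduce the nucleosomal
stepping probability (~0.9), the short-hydrolysis closure fraction (~64%),
the spontaneous sliding barrier (~6 kT), the ATP-state landscape drop
(~4.5 kT) and the mutant/601 sliding penalty (~3.4 kT).

## Known limitations

* The calibration trades off coupled observables through shared
  mechanisms. Three couplings resist full resolution at this scale: the
  bare-DNA stepping probability and the nucleosomal one share the ADP
  opening race (the shipped defaults favor the nucleosomal statistic, so
  bare-DNA stepping comes out near 0.7 rather than ~0.45); the
  short-hydrolysis completion fraction sits near 45% rather than ~36%
  because mid-slide states at the hydrolysis switch are still pulled
  forward by the electrostatic spring; and the TpA lobe-2 closure share
  saturates near 15–20% once the closed-state offset needed for ADP
  stability is in place.
* Sliding after closure is drift-limited rather than barrier-limited, so
  label-state mean first-passage times are insensitive to the ±1–2 kT
  intermediate-state shifts produced by the sequence elements; the
  first-passage ratios for the element variants come out near 1 rather
  than the 2.4×/1.3× slowdowns of the residue-level study. A
  barrier-limited variant (weaker site relief, late electrostatic capture,
  faster DNA diffusion) restores the sensitivity but breaks the wall's
  other roles (apo clamp, closure commitment, the opening drive separating
  the nucleosomal from the bare-DNA case).
* The model has no 3-D geometry: no histone tails, no octamer
  deformation, no explicit electrostatics, no helical phase. Contact
  indexes are primitive coordinates, not projections of atomic positions.
* Synthetic fixtures (scripted label paths, known Markov chains, exact
  Boltzmann samplers) exercise the analysis stack with known answers; they
  emulate the statistical structure of trajectories, not their physics, so
  passing fixture tests validates the estimators, not the model.
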