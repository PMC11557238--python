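# Methods

`pulsechem` simulates the chemical stage of water radiolysis under pulsed
electron delivery and asks one question: how does the *time structure* of
the pulse — its duration τ, from 100 fs to 1 µs — change the radiolytic
yields scored per electron and per 100 eV of deposited energy?

## Model overview

A pulse of `n` electrons (default 10, kinetic energy default 10 keV) enters
a 200 × 200 × 400 µm water phantom along z through a 100 µm air gap, with
transverse entry positions drawn from a 5 µm-FWHM Gaussian beam profile and
arrival times drawn from the pulse envelope (top-hat on [0, τ] by default;
Gaussian optional).  The air gap is treated as a chemically inert, lossless
drift.

Three stages are modelled:

1. **Physical / physicochemical (synthetic).**  Full track-structure
   transport is deliberately replaced by a parameterised spur model.  Each
   electron deposits its energy as a straight-line sequence of spurs with
   energies sampled uniformly on 17–100 eV and spacing ε/S(E), where S is
   the collision stopping power of liquid water (bundled log–log table) at
   the current residual energy; transport stops at a 500 eV cutoff, the
   phantom boundary, or an optional spur cap (track-segment mode for high
   energies).  Each spur is populated with chemistry-ready species at
   physicochemical (~1 ps) yields — per 100 eV: e⁻aq 4.8, •OH 5.5, H• 0.62,
   H₂ 0.15, with the H₃O⁺ count set equal to the e⁻aq count so every spur
   is born charge-neutral.  Counts are Poisson; positions are Gaussian
   around the spur centre with σ = 2 nm for heavy species and 5 nm for the
   thermalised electron.  All particles are born one physicochemical offset
   (1 ps) after their track's arrival time.

2. **Chemistry: independent reaction times (IRT).**  Every candidate pair
   with a reaction channel receives a reaction time sampled once by
   inverse transform from the diffusion-controlled pair survival function
   W(t) = (R/r0)·erfc((r0−R)/√(4D′t)); events execute in global time order
   through a priority queue, fire only if both reactants are alive, and
   products sample fresh times against alive neighbours (classic
   non-revisable IRT).  Pairs born at different times — the mechanism by
   which a long pulse staggers its tracks — are handled by blurring the
   earlier particle's position with its free-diffusion propagator to the
   later birth before measuring r0.

3. **Scoring.**  G values are 100 × N(t)/E_dep with N(t) the alive count
   of a species, audited exactly against the event log; per-electron
   yields are N(t)/n.

## The chemical registry

The species set (e⁻aq, •OH, H•, H₂, H₂O₂, H₃O⁺, OH⁻, HO₂•, O₂•⁻, O₂) and
the canonical pure-water reaction list ship as editable TSV files with
room-temperature literature rate and diffusion coefficients (the
Buxton/Elliot compilations used throughout radiation chemistry).  Rate
constants are inverted to effective, fully diffusion-controlled reaction
radii via Smoluchowski, R = k·10⁻³/(4π D′ N_A); partially
diffusion-controlled channels are thereby absorbed into R so the long-time
observed rate is reproduced.  Two conventions are fixed explicitly:

- **Identical reactants (A + A).**  Tabulated constants are read in the
  observed-loss convention (−d[A]/dt = k[A]²); the pair-encounter rate is
  k/2, applied once at radius derivation and asserted by a unit test.
- **Charged pairs.**  Coulomb (Debye) interaction is ignored by default; a
  config flag derives Debye-corrected radii through the Onsager length.
  For attractive pairs whose observed rate lies below the Onsager capture
  limit no contact radius reproduces the rate in the capture model, and the
  neutral radius is kept (with a warning).

Dissolved O₂ is off by default; a configured concentration converts the
bundled O₂ rows into pseudo-first-order scavenging channels.  Superoxide
and hydroperoxyl therefore arise only through minor multi-step channels
(•OH + H₂O₂ → HO₂•, HO₂• + OH⁻ → O₂•⁻) unless O₂ is enabled.

## Scoring end time: the load-bearing convention

The pulse duration has *no* effect on intra-track chemistry (all particles
of one track are born together), and at the studied geometry inter-track
chemistry is negligible: with ≤100 electrons in a 5 µm beam, tracks are
micrometres apart while chemical diffusion lengths by 1 µs are ~100 nm, so
cross-track pair reaction probabilities are of order erfc(7) ≈ 10⁻²⁵.  The
scored τ-dependence therefore comes from *when the clock stops relative to
the envelope*:

- `pulse_end` (default): chemistry and scoring end at τ + 1 ps, i.e. when
  the last track is born.  A track arriving at time a has chemical age
  τ − a, so the scored yield samples the time-dependent radiolytic decay
  G(t) over the ages the envelope produces.  Short pulses score the
  physicochemical yields (G_OH ≈ 5.5); microsecond pulses score partially
  decayed tracks (G_OH ≈ 2.9 averaged over ages).  This reproduces the
  qualitative pulse-duration effect: yields rise monotonically as τ
  shrinks, saturating below the picosecond scale.
- `pulse_plus_window`: chemistry runs to τ + 1 µs, giving every track the
  full chemical stage.  Under this rule the per-electron yield is flat in
  τ (each track's chemistry is complete and independent), which is useful
  as a control but carries no pulse-duration signal.

Both rules are config options; the default is `pulse_end` because it is the
only convention under which the scored yield responds to the pulse
envelope at all at this geometry.

A structural consequence: species *consumed* over time (•OH, e⁻aq, H₃O⁺)
score higher for shorter pulses, while species *produced* over time (H₂O₂,
HO₂•, O₂•⁻) necessarily score higher for longer pulses.  No single scoring
rule can make both directions increase together at this geometry; the
package's tests assert the directions the model actually produces.

## The pulse-duration sweep and its analysis

The default desk-scale sweep uses 10 keV electrons (the pulse-duration
effect is insensitive to electron energy, which only rescales the number
of spurs per track), 10 electrons per pulse, τ ∈ {10⁻¹³ … 10⁻⁶} s one per
decade, and 8 replicates per point with seeds derived deterministically
from a master seed and the grid indices.  A full run takes a couple of
minutes on one core; these sizes were chosen so the entire analysis is
reproducible on a laptop.

The per-electron hydroxyl yield versus τ is fitted with the three-parameter
power law y = aτᵇ + c by weighted least squares.  Because the model is
linear in (a, c) at fixed b, the fit profiles the loss over b (log-spaced
multi-start bracketing plus bounded 1-D refinement), which is exact and
insensitive to the scale difference between a, b and c.  R² is computed
unweighted on the replicate means.  Two degeneracies are flagged rather
than hidden: constant data (b unidentifiable) and the log-linear limit
b → 0⁻, where aτᵇ + c ≈ (a + c) + ab·ln τ and the exponent loses meaning.

Measured behaviour under the default conditions: the yield curve is flat
at the physicochemical yield below ~10 ps (radical pair reaction times in
nanometre-scale spurs are ≥ ~100 ps, and nothing at all reacts below the
1 ps physicochemical offset), then decays smoothly to the partially
decayed microsecond value, a factor ≈ 1.9 overall (100 fs vs 1 µs).  A
power law cannot represent the sub-picosecond plateau, so on this grid the
profiled fit runs into the log-linear degeneracy (flagged, R² ≈ 0.83).
Any diffusion–reaction chemistry produces such a plateau: sub-picosecond
pulse-duration sensitivity would require dynamics faster than radical
encounter times, which do not exist in this stage.  The scale-invariant
summaries (exponent, R², yield ratios) are reported as computed.

Peak power is the analytic n·E·e/τ; a 100 fs pulse carries exactly 10⁷
times the peak power of a 1 µs pulse at equal charge and energy.

## Numerical choices

- **Pair cutoff.**  Candidate pairs are enumerated within
  r_cut = R + 10·√(2D′(t_end − t_start)), capped at 300 nm by default, via
  a k-d tree; the enumeration radius adds 3σ allowances for birth-stagger
  blur in both directions.  Pairs beyond diffusive reach contribute
  negligibly (ultimate probability R/r ≲ 10⁻³ with additionally small
  finite-horizon factors).
- **Product placement** at the diffusion-coefficient-weighted midpoint of
  the reactant positions (weights D_other/(D_a + D_b), i.e. closer to the
  slower diffuser), with birth time equal to the event time.
- **Tie-breaking**: events order by (time, smaller particle id, insertion
  sequence), making event logs bit-reproducible for a fixed seed.
- **Step-by-step oracle.**  The brute-force Brownian validator propagates
  explicit trajectories and reacts pairs on contact, with a Brownian-bridge
  crossing probability exp(−d₀d₁/(D′Δt)) per step to remove the leading
  discretisation bias of an absorbing boundary.  It is guarded to ≤ 50
  particles and to steps satisfying √(2D_max Δt) < R_min/3.
- **Degenerate inputs**: zero-duration pulses are legal (all tracks born
  together); spurs may be empty; particles born at or after the chemistry
  end time simply take no part; species leaving the phantom keep diffusing
  freely (the phantom is ≫ any diffusion length on these time scales).

## What the synthetic stage does and does not emulate

The spur model reproduces the features the chemistry stage cares about:
realistic linear density of energy deposition (via the stopping power),
nanometre radical clustering, charge-neutral spurs, and literature
physicochemical yields.  Its G_OH(t) decay — 5.4 at 3 ps to 2.6 at 1 µs
for 10 keV tracks — matches the standard shape and escape level of
published low-LET yield curves.  It does not emulate δ-ray branching,
elastic-scattering tortuosity, sub-picosecond physicochemical dynamics, or
the correlated sub-nanometre geminate geometry of individual ionisation
events; consequently early (≲ 100 ps) decay is somewhat slower than in
full track-structure codes, and conclusions about sub-picosecond pulse
effects are outside what this model can support.  Passing tests establish
the internal consistency of the chemistry (closed-form pair statistics,
oracle agreement, conservation, reproducibility) and the qualitative
pulse-duration effect — not quantitative agreement with any particular
track-structure engine.

## Known limitations

- The pulse-duration enhancement saturates at the
  physicochemical-to-escape yield ratio (≈ 2 for hydroxyl here), the hard
  ceiling any survival-scored chemistry imposes; claims of larger
  enhancements require mechanisms outside this model.
- Classic IRT is an independent-pair approximation; its error is
  quantified against the step-by-step oracle only on small fixtures.
- Straight tracks overestimate intra-track density at low energies
  (no lateral spreading), slightly deepening late-time recombination.
- The registry is room-temperature, pH-neutral pure water; no temperature
  dependence, pH speciation, or solute chemistry beyond the optional fixed
  O₂ concentration.
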