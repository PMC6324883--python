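# Methods

This note documents the models, numerical choices and limitations behind
`xlinktrap`.

## The ruler model

A bifunctional MTS reagent that has reacted with two engineered cysteines is
assumed to act purely as a tether: it prevents the two SG atoms from
separating beyond the reagent's extended sulfur-to-sulfur span, and (being
flexible, except bMTSp) does not prevent them from approaching.  Spans are
catalog constants stored to 1 Å, exactly as calibrated for the extended
conformers (M1M 7, M3M 9, bMTSp 12, M6M 13, M8M 15, M10M 18 Å); no conformer
chemistry is modelled.  A direct S–S bridge is carried as a ~2 Å
pseudo-linker so recovery-versus-separation trends share one axis.

## Structural geometry

* **Cysteine modelling.**  The side chain beyond CB is replaced by a single
  SG placed from internal coordinates: bond CB–SG 1.81 Å, angle CA–CB–SG
  114°, dihedral N–CA–CB–SG at the modal cysteine rotamer χ₁ = −65°
  (alternate rotamers via parameter).  No repacking or minimisation — the
  measured SG–SG distances are meant to be comparable with distances read
  off deposited coordinates at whole-Å precision.
* **PDB I/O** uses gemmi, restricted to the first model and altlocs ''/'A';
  a validation pass reproduces line-numbered errors for malformed
  fixed-column records that gemmi silently tolerates.  Van der Waals radii:
  C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å (overridable table, default
  1.70 for other elements).
* **SASA** is Shrake–Rupley with a deterministic golden-spiral point set.
  The default 1024 points per atom keeps single-atom areas within 2 % of a
  16384-point reference on dense random clusters; an isolated atom is exact
  (4π(r+probe)²).  Probe radius 1.4 Å.
* **Clash counts** use a KD-tree for candidates but apply the strict
  `d < cutoff` test on exact distances, so the result equals the all-pairs
  count; pairs at exactly the cutoff do not count.
* **Centre-of-mass separation** uses unweighted atom centroids by default
  (mass weighting is a flag); at the ~1 Å scale of dimer separations the two
  are indistinguishable for protein chains.

## Rigid-body accessibility search

The two LBD dimers are rigid bodies.  The frame is built from the dimer
centroids (interface axis = in-plane unit vector joining them) and the
principal axis of the tetramer most orthogonal to it (membrane normal, the
thin direction of the LBD slab).  A pose rotates the mobile dimer about the
two in-plane axes through its centroid — parallel rotation first, then
perpendicular, then in-plane translation; the composition order is a
documented convention, not physics.

The objective is solely the accessible area of the proximal-subunit Cys SG
(subunit A by default; a flag sums both proximal subunits).  Plausibility is
enforced as hard constraints rather than a weighted score: at most 10
inter-dimer atom pairs closer than 2.2 Å, and a dimer separation no more
than 10 Å above the seed separation (the proximity bound is a package
default; only "close proximity" is prescribed by the approach itself).
The search is a seeded local search: each round perturbs the retained seeds
uniformly within the current step sizes (initial 4 Å / 20°), keeps trials
that strictly lower the best objective and satisfy the constraints, halves
the step sizes on rounds without improvement, and stops at 0.1 Å / 0.5°
resolution with no improvement.  Runs are reproducible bit-for-bit under a
fixed seed; multiple independent runs are a loop over seeds.  Retained
arrangements are classified loose (SG–SG < 10 Å) or tight (SG–SG > 20 Å
and SG within 8 Å of the partner helix-K atoms).

## Synthetic electrophysiology

Receptor populations occupy the product of a gating state
(resting/active/desensitized) and a modification flag (free/trapped) — a
six-state linear Markov chain with piecewise-constant generators set by the
solution:

* in agonist: activation `k_act` (default 5000 s⁻¹), desensitization
  `k_des` (180 s⁻¹), resensitization `k_res` (65.2 s⁻¹, placing the
  equilibrium active fraction near 0.27; a constructor sets `k_res` from a
  target steady-state/peak ratio);
* in wash: deactivation `k_deact` (1/1.7 ms) and recovery from
  desensitization `k_rec` (20 s⁻¹);
* CTZ in the solution zeroes `k_des`;
* modification: free → trapped at `k_on · [MTS] · accessibility(state,
  linker)` with `k_on = 1e5 M⁻¹s⁻¹` (near the diffusion-limited thiol
  reaction rate);
* DTT: trapped → free at a per-linker reversal rate — disulfide τ ≈ 3 s,
  M1M τ ≈ 30 s, M3M τ ≈ 10 min, effectively zero from 13 Å up (log-linear
  interpolation for custom spans).

Current is `−amplitude · (occupancy-weighted conductance)`, inward at the
default −40 mV; the open state conducts whenever occupied (so deactivation
tails survive agonist removal), scaled by a kainate efficacy (default 0.46)
when the driving agonist is kainate; trapped receptors conduct
`trap_efficacy(linker)` of a free opening (defaults span-shaped: near zero
for mid-length rulers, 0.25 at 18 Å, 0.85 for the bare disulfide, 1.0 for
the monofunctional control; the 0.4 two-subunit conductance fraction is
available as a constant for configuring partial-block scenarios).
Solution exchange is instantaneous; noise is white Gaussian; run-down is a
linear fraction per minute.

**ODE mode** evaluates the exact matrix-exponential solution per solution
segment via eigendecomposition (chunked over samples; expm stepping as a
fallback for defective generators), so occupancies conserve probability to
machine precision.  **Stochastic mode** steps an N-receptor population with
per-sample multinomial transitions using the single-receptor kernel
`expm(Qᵀ/fs)` — the exact population chain at the sampling resolution — and
converges to the ODE mean at large N.

### The accessibility window model

No state-resolved accessibilities are available, so the default bridge from
linker span to trapping rate is a stand-in: each gating state samples a
Gaussian SG–SG separation (resting 10 ± 3, active 15 ± 3, desensitized
14 ± 5 Å), and accessibility is the probability that the separation lies in
the reactive window [3 Å, span].  This encodes "the linker can only react
when both thiols are within reach" as a rate factor, is monotone in span,
and — combined with span-shaped trap efficacies — produces the parabola-
shaped trapping profiles the analysis stage expects.  It reproduces the
qualitative ordering (longest linker slowest; active state more protected)
but is not calibrated to the absolute per-linker trapping extents, and
passing tests therefore validate the analysis chain, not a quantitative
kinetic model of any receptor.

### What the generator does not emulate

Deep/slow desensitized states (so simulated populations recover within a
second of wash, and the first post-trap pulse is merely reduced rather than
absent), solution-exchange filtering, 1/f noise and seal drift, sublevel
conductances, series-resistance and junction artifacts.

## Analysis conventions

* **Active fraction** = second post-trap response / mean of the four
  pre-trap responses (peak for desensitizing receptors, steady state
  otherwise).  The second pulse is the stated convention because the first
  post-trap response reports desensitization recovery, not trapping; an
  index override exists.
* **Exponential fits** are unweighted nonlinear least squares with
  multi-start initialisation over a log-spaced τ grid; the amplitude-
  weighted τ is Σaᵢτᵢ/Σaᵢ.  A double exponential is preferred only when it
  improves residual RMS by > 20 % — a declared threshold replacing
  per-dataset judgement.
* **Pulse-train modification τ** is fitted against cumulative exposure time
  from the second pulse on: the first pulse starts from a fully recovered
  population, so its gating envelope differs from the remainder of the
  train (the same reason the active fraction skips the first post-trap
  pulse).  From the second pulse the envelope is constant and the fitted τ
  equals 1/(k_on·[MTS]) when accessibility saturates.
* **Recovery envelopes** are monoexponential rises; flat or decreasing
  envelopes are flagged rather than fitted.
* **Parabola fits** minimise Σ((yᵢ−f(xᵢ))/semᵢ)² exactly in the quadratic
  basis (a, b, c), then convert K1 = a, K2 = −b/2a, K0 = c − b²/4a.
  Zero-SEM points inherit the smallest nonzero SEM present.  K2 is
  unconstrained by default; a bounds option pins the vertex to a span range
  (re-fitting K0, K1 with the vertex fixed) for ill-conditioned profiles.
  The disulfide point is excluded from fitted profiles by default (the
  profile axis starts at the 7 Å ruler), as is the monofunctional control.
* **Randomization tests** use |Δmean| (paired: |mean Δ|), enumerate all
  label assignments exactly when there are ≤ 2·10⁵ (then p = count/total,
  seed-independent), and otherwise Monte-Carlo sample with the add-one
  convention p = (count+1)/(iterations+1), which cannot return 0.
  Two-sided by default; sidedness is a flag because the convention is
  otherwise unstated.

## Synthetic data files

`src/xlinktrap/data/synthetic_sourcedata_*.csv` are labelled synthetic
reconstructions of per-linker trapping-profile tables: means placed exactly
on the published parabola summaries (minima (13 Å, 0.30) active,
(11 Å, 0.10) desensitized, (11 Å, 0.30) with Stargazin; curvatures anchored
at the reported flank values).  They exercise the SEM-weighted fit and
round-trip the published minima; they are not raw measurements.

## Problem sizes and determinism

Default traces are sampled at 20 kHz; tests use 2–5 kHz and shortened traps
where only the analysis logic is at stake.  The acceptance computation uses
40 pulses at 50 µM and 240 at 1 µM (covering ≳1.2 fitted time constants of
the slower decay).  Docking tests run on the constructed burial toy
(~150-atom cage) with 512-point SASA; the 1-D grid oracle uses 0.05 Å
resolution.  All stochastic paths take explicit seeds; ODE-mode runs and
exact-enumeration tests are deterministic outright.

## Known limitations

Real deposited structures are needed for the whole-Å calibration distances;
the geometric code paths are exercised on constructed toys whose ground
truth is analytic.  The rigid-body search shares the approach's own
limits — no flexible refinement, accessibility-only objective — and its
trials-per-round/step-schedule defaults are package choices, not a claim
about any original implementation.  The kinetic simulator is a three-state
caricature of AMPA-receptor gating: sufficient for testing estimators that
consume peaks, steady states and decay rates, not for mechanistic
inference.
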