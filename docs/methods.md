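# Methods

`sirasfx` studies a question of experimental phasing economics in serial
femtosecond crystallography (SFX): how many indexed snapshot patterns does
*de novo* phasing need when it can use large isomorphous differences from a
heavy-atom derivative (SIRAS), only those differences (SIR), or only the
weak anomalous differences of the derivative (SAD)?  Every stage of the
pipeline — snapshot simulation, Monte-Carlo merging, substructure search,
probabilistic phasing, density modification, and evaluation — is implemented
here on a synthetic toy crystal whose ground truth is known exactly, so
phase quality can be measured instead of guessed.

## The toy crystal

The default ground truth is an orthorhombic P2(1)2(1)2(1) crystal, cell
30 x 40 x 50 A, diffracting to d_min = 2.5 A, containing 40 "light"
pseudo-atoms and one heavy site per asymmetric unit:

| parameter | value | why |
|---|---|---|
| light f0 | 25 e | a residue-scale blob; see below |
| light/heavy B | 10 A^2 | typical room-temperature order |
| heavy f0 | 80 e | Hg-like |
| heavy occupancy | 0.7 | strong but partial derivatization |
| heavy f'' | 9.75 e | Hg near its L-III edge at 12.6 keV |
| heavy f' | 0 (default) | keeps \|F_H\| equal to the normal heavy scattering; the dispersive term is a config knob |

The light atoms are deliberately *not* carbon-scale.  With 40 atoms at
f0 = 6 e the heavy atom would dominate the structure (rms |F_H|/|F_P| ~ 1.5)
and the Bijvoet ratio would be an order of magnitude larger than in a real
small protein, erasing the phenomenon under study.  At f0 = 25 e each
pseudo-atom stands for several residues' worth of scattering, and the toy
reproduces the signal hierarchy of a ~300-residue protein with one Hg:
rms |F_H|/|F_P| ~ 0.3 (R_iso ~ 0.15-0.25), isomorphous:anomalous signal
ratio f0_H/f'' ~ 8, Bijvoet amplitude ratio of a few per cent.

Scattering factors are constant per atom (no angular falloff beyond the
isotropic B): at 2.5 A on a toy structure the Cromer-Mann s-dependence is
cosmetic, and a constant f0 keeps the P1 brute-force oracle trivial and the
f''/f0 ratio directly controllable.

## The snapshot generator

Each simulated pattern is a random subset of the unique reflections
(Friedel branches counted separately), each observation carrying

* a per-pattern log-normal scale g (sigma_g = 0.4, mean 1) — beam and
  crystal-volume fluctuation;
* an i.i.d. partiality p ~ Uniform[0.1, 1] — the Ewald-offset surrogate;
* Gaussian counting noise, sigma(I) = sqrt(max(I,0) + 25).

The per-observation relative error is therefore ~0.6, dominated by
partiality and scale exactly as in real still-shot data, and merged
intensities converge to <g><p>|F|^2 at the Monte-Carlo rate 1/sqrt(N).
Partiality is a pluggable i.i.d. multiplier, not a geometric Ewald-offset
model, and observed reflections are a random subset rather than an
orientation slice: the analysis treats partiality purely as noise that
averaging defeats, so only the convergence rate and the multiplicity
bookkeeping matter.  An optional low-angle absorber (transmittance T for
d >= d_threshold; defaults match a 300 um Al foil, T = 0.3636 below 3.8 A)
and a weak-pattern fraction exercise the correction and preselection steps.

What the generator does **not** emulate: detector geometry and saturation,
indexing ambiguities, per-pattern unit-cell scatter, non-isomorphism
between native and derivative crystals, and radiation damage.  Passing
tests therefore demonstrate the statistical mechanics of merging and
phasing, not robustness to those experimental pathologies.

## Merging and scaling

Merging is the plain Monte-Carlo estimator: arithmetic mean per unique
reflection/branch after reduction to the asymmetric unit.  No per-pattern
scaling or partiality post-refinement is applied.  The merged sigma is
max(sd/sqrt(n), propagated observation error of the mean): the sample sd
captures partiality and scale noise, but at small multiplicity it is itself
unreliable and must not under-report.

Two scaling steps matter and both proved load-bearing:

1. **Wilson absolute scaling.**  Monte-Carlo merging leaves the data on an
   arbitrary scale (~<g><p>).  Phasing combines the data with an absolute
   heavy-atom model, so each resolution shell is rescaled to the Wilson
   expectation sum (occ f)^2 exp(-B s^2/2) of the known composition —
   the standard composition-based absolute scaling.  Omitting this leaves
   a systematic lack of closure of order (1 - scale)|F_H| that quietly
   ruins the error model.
2. **Model-consistent derivative scaling.**  The relative (native vs
   derivative) Wilson fit equalizes shell-mean amplitudes, which
   under-scales the derivative by its genuine heavy-atom intensity excess
   (~20% here).  Once a substructure model exists, the derivative is
   rescaled per shell so <|F_PH|^2> = <|F_P|^2 + |F_H|^2>.

## Substructure search

Isomorphous ((dF_iso)^2) and anomalous difference Pattersons are
synthesized by expanding indices over the **Laue group** — rotations only;
|F|^2-type coefficients carry no translation phase — and standardized to
sigma units.  Anomalous coefficients default to (dF_ano)^2 =
(|F+| - |F-|)^2.  The intensity-normalized alternative (dI/<I>)^2 is
available but not default: on this generator it equalizes pure-noise
reflections and caps the attainable Harker peak height (~3.4 sigma
regardless of pattern count), whereas (dF_ano)^2 grows from ~2 to ~9 sigma
as multiplicity accumulates — the diagnostic behaviour one wants.

A single site is found by a symmetry-minimum-function scan: candidate
positions over [0, 1/2)^3 (Harker vectors determine a site only modulo the
allowed half-cell origin shifts), scored by the minimum interpolated
Patterson value over all Harker self-vectors and all supplied maps.  The
minimum over maps makes the combination only as strong as its weakest map,
so the pipeline scores against the isomorphous map alone when native data
exist, and the anomalous map only in the anomalous-only (SAD) setting.
A Patterson cannot distinguish a substructure from its enantiomorph; the
search reports both hands.

## Blow-Crick phasing

For each acentric reflection the native phase is scanned on a 5-degree
grid.  With F_H at +h and F_H-bar = conj(F_H(-h)),

    F_PH_calc(+/-)(phi) = |F_P| e^(i phi) + F_H (resp. F_H-bar)

gives an isomorphous residual on the amplitude scale (mean observed minus
mean calculated derivative amplitude) and an anomalous residual on the
**intensity** scale (observed I+ - I- minus calculated).  The intensity
scale was chosen for the anomalous term because merging noise is Gaussian
and honestly characterized there; the sqrt conversion misbehaves exactly
for the weak reflections whose apparent Bijvoet differences are pure noise.
SIR uses the isomorphous factor, SIRAS both, SAD only the anomalous factor
via the classical sine rule Delta_I(phi_T) = 4 |F_T||F_H''| sin(phi_T -
phi_H) (the sign follows the package's exp(+2 pi i h.x) convention).
Centric reflections are evaluated only at their two allowed phases and are
retained in every mode that can use them — dropping them (they have no
Bijvoet mate) measurably cripples density modification.

The Gaussian width per reflection is sqrt(E_shell^2 + sigma_meas^2): a
per-shell RMS lack of closure (model error) plus the propagated
per-reflection measurement error.  E_shell is initialized from RMS
difference amplitudes and refined by two iterations of: phase at the
current width, take the residual at the most probable phase, subtract the
measurement variance, RMS per shell, floor at 5% of the initial value.
Residuals are taken at the probability maximum, not probability-weighted:
the weighted form adds the curvature-times-phase-variance term and
converges to an inflated fixed point, which over-weights whichever term
has the smaller geometric leverage (observed as SIRAS underperforming
SIR).  Separating measurement from model error in this way is what makes
the figure of merit track multiplicity: poorly measured Bijvoet
differences widen only the anomalous factor.

Hand ambiguity: the isomorphous factor is hand-blind, the anomalous factor
is not.  The pipeline therefore phases both substructure hands (SIRAS and
SAD) and keeps the one whose flattened map has the higher protein/solvent
variance contrast; SIR needs a single run.

## Density modification

Cycles of: FOM-weighted map synthesis; solvent mask from the lowest 44%
(configurable) of the locally smoothed density (Gaussian, 2 A radius);
flatten the solvent to its mean; additionally clip the whole map below the
solvent level (a positivity constraint — electron density has a floor);
back-transform; recombine.  Recombination multiplies the *fixed*
experimental phase probability by a von-Mises likelihood centred on the
map phase with a per-reflection Sim-style concentration
kappa = 2 F_obs F_map / <(F_obs - F_map)^2>_shell (capped at 10), so
reflections whose amplitudes the modified map reproduces pull hardest and
the iteration stays anchored to the data rather than compounding its own
feedback.  A divergence guard stops the iteration if the mean FOM drops by
more than 0.2 in one cycle.

The positivity clip is the step that makes density modification genuinely
corrective on this toy (phase error improves in 5/5 seeds versus 2/5 with
flattening alone): the toy's "solvent" is Fourier ripple around point
atoms, which plain flattening reshapes without suppressing.  The default
is 10 cycles; the classical 20 local cycles gain little here because no
chain tracing is interleaved.

## Evaluation

A phased map is compared with the ground-truth F_c map by Pearson
correlation over grid points, maximized over the eight allowed origin
shifts and both hands; the same optimal transform defines the
amplitude-weighted mean absolute phase error.  A trial is a success when
the map correlation exceeds 0.65, the conventional interpretability
threshold for experimentally phased maps.

## Experiments and default sizes

* **Titration** over a 5x5 grid of (native, derivative) pattern counts,
  default axes (25, 50, 100, 200, 300), nested subsampling (the first N
  pattern ids) so larger cells reuse the smaller cells' patterns.  The cap
  at 300 keeps anomalous-only phasing clearly short of the signal it would
  need while both isomorphous modes saturate — the regime in which the
  three modes separate; it also keeps a full three-mode titration under
  a minute.  The boundary statistic is the smallest n_native +
  n_derivative among successful cells.
* **Resolution scan**: phasing repeated with reflections truncated at a
  list of d_min cutoffs.
* **Signal curves**: CC_ano (random-half correlation of Bijvoet
  differences), CC_anoref (correlation of observed Bijvoet differences
  with model-calculated ones — informative long before two noisy halves
  correlate with each other), and the anomalous-Patterson sigma-height at
  the true v = 1/2 Harker vector, per pattern count.

Default problem sizes (40 atoms, <= 400 patterns per crystal form,
~2,000 unique reflections, 36x48x60 grids) were chosen so a full titration
of all three modes completes in about a minute and the entire test suite
in a few minutes on one core.

## Known limitations

* Isomorphism between native and derivative is perfect by construction;
  the non-isomorphism that dominates real SIRAS practice is out of scope.
* The SAD sine-rule parameterization ignores the |F_H|^2 breakdown terms;
  adequate for the qualitative SAD-vs-SIRAS comparison, not for production
  SAD phasing.
* The lack-of-closure model is Gaussian and per-shell; no per-reflection
  model-error heterogeneity (e.g. sigma-A style weighting) is attempted.
* Occupancy/site refinement of the substructure is not performed; the
  heavy-atom model enters with its nominal occupancy and the Patterson
  site position.
* No chain tracing: success is measured by map correlation, not by how
  much of a model an auto-builder could construct.
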