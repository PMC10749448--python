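# Methods

## The model

A monatomic anion X⁻ in water accepts hydrogen bonds through its four
lone pairs, which are carried as explicit geometric sites (in ab initio
data, maximally localized Wannier-function centers; the package never
computes electronic structure — lone pairs are input). The strength of
an individual ion–water contact is summarized by the descriptor

    η = r_LP–H / ( cos(α/2) · cos(β/2) ),

with r_LP–H the lone-pair–hydrogen distance (Å), α the angle at the ion
between the ion→lone-pair and ion→H directions, and β the angle at the
hydrogen between the O–H bond direction and the H→lone-pair direction.
The two secant factors are angular weights: they equal 1 for the ideal
linear hydrogen bond (α = β = 0, where η reduces to the bare
lone-pair–H distance), grow monotonically as the geometry bends, and
diverge as either angle approaches 180°, so η is a length-valued score
in which lower values mean stronger, more linear bonds. This particular
weight was chosen as the simplest smooth form satisfying those
constraints on the full angular range [0°, 180°); any consistent choice
is exercised by the same monotonicity and invariance tests. The
descriptor of an ion–water pair, η_ij, is the minimum over the 4 × 2
(lone pair, hydrogen) combinations — the strongest contact the molecule
offers — with ties broken lexicographically by (lone-pair, hydrogen)
index.

Classification splits waters into three regions:

- **tight**: η_ij < η_cut (no distance condition — a strongly bonded
  water slightly beyond the distance cutoff remains tight);
- **loose**: not tight and r_XO < r_cut;
- **bulk**: everything else.

Both comparisons are strict, with ties assigned to the outer region
(deterministic, measure-zero effect). r_cut is the first minimum of the
X–O g(r) beyond its first maximum; η_cut is placed where the η
distributions of the four closest waters (by ion–O distance, per frame)
and of the 5th–7th closest intersect. Loose waters pointing both
hydrogens more than 90° away from the ion (both O–H · O→ion dot
products negative) are flagged as *misoriented* — second-shell-like
molecules fortuitously inside r_cut — but remain labeled loose.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| g(r) bin width | 0.02 | Å | resolves the sharp tight-shell peak in a 14 Å box |
| P(η) bin width | 0.02 | Å | same resolution for η histograms |
| smoothing window | 5 bins | — | moving average applied before every extremum/intersection search |
| SDF voxel | 0.2 | Å | lone-pair-frame density grid |
| SDF half-extent | 5.0 | Å | covers the first shell with margin |
| transient filter | 0.1 | ps | region changes reversed within this time are fluctuations, not exchanges |
| misorientation angle | 90 | ° | hemisphere criterion at the oxygen |

The curve-extremum conventions (5-bin moving average; minima/maxima tie
to the smallest abscissa; the intersection is the smallest
positive-to-negative crossing of the smoothed difference, linearly
interpolated between bracketing bin centers) are the package's own
numerical choices; peak positions from raw bins differ by at most a bin
or two. `eta_peak` prefers, among smoothed-maximum ties, the bin with
the largest raw density, so an isolated single-bin spike reports its own
center rather than the left edge of the smoothing plateau.

## Exchange events and residence times

Raw label series are first filtered: a change at time t is *committed*
only if the molecule does not re-enter its former region within
(t, t + 0.1 ps]; shorter excursions are erased and scanning resumes
after the return. Committed transitions are then resolved per molecule
into events: a tight departure is T–L–B if the molecule reaches bulk
before re-entering tight (consuming the loose→bulk leg) and T–L
otherwise (a resolved return counts once); direct T↔B transitions are
T–B; loose↔bulk transitions not consumed by a chain are L–B; inbound
chains (B–L–T etc.) mirror the outbound rules into the same undirected
categories. A chain has no time limit — a tight departure stays pending
through an arbitrarily long loose sojourn, since any window would add an
uncited parameter. A trailing unresolved departure counts as the
two-region event of its first leg.

Residence times use the direct method:

    MRT = t_sim · n̄ / N_ex ,   NMRT = MRT / n̄ = t_sim / N_ex ,

with n̄ the time-averaged occupancy from the raw labels and
N_ex^tight = T–L + T–B + T–L–B, N_ex^loose = T–L + L–B + T–L–B. This
reconstruction, applied to published exchange-event tables for Cl⁻ and
I⁻ (10 ps production), reproduces all four printed NMRT values (0.17 /
0.06 and 0.25 / 0.07 ps), which pins down both the algebra and the
disjointness of the categories. Zero events for a shell raise an
undefined-residence-time error (the CLI reports ∞ with a warning).

Because each molecule contributes an O(1) entry/exit boundary term to
N_ex, the direct method is calibrated (MRT → 1/k on two-state Markov
data with escape rate k) only when the sojourn sample is much larger
than the number of molecules; the estimator-recovery test therefore uses
60 ps per seed and sets the transient filter to its minimum (one frame
spacing), since a 0.1 ps filter erases a large fraction of genuine
exponential sojourns at k = 5 ps⁻¹ by construction.

## The synthetic generator

`synthetic_data` emulates the statistical structure the analysis
assumes, with ground-truth labels carried in trajectory metadata (never
read by analysis stages):

- ion at the center of a 14 Å cubic periodic box with 30 waters
  (4 tight + 6 loose + 20 bulk by default), matching the one-ion,
  90-water, 14 Å simulation scale at a desk-sized water count;
- four lone pairs 0.5 Å from the ion along tetrahedral directions,
  rigidly rotated by a slow random walk (1°/frame) — the ion–center
  offset only needs to be much smaller than any ion–water distance,
  since the analysis depends on lone-pair directions;
- tight waters anchored one-per-lone-pair: ion–H distance ~
  N(2.24 Å, 0.1 Å) along the (10°-jittered) lone-pair axis with the
  O–H bond aimed at the lone pair, placing the oxygen near the 3.21 Å
  chloride first-shell distance (iodide preset: 2.61 Å → 3.58 Å);
- loose waters uniform in the outer first-shell region (3.4–4.0 Å for
  chloride-like, 3.7–4.37 Å for iodide-like — loose waters sit at larger
  distances than the tight peak, as the decomposed g(r) shows), with
  random orientation; an optional fraction is drawn misoriented
  (H–O–H bisector pointing away from the ion);
- bulk waters uniform outside the loose shell; all placements enforce a
  2.0 Å minimum O–O separation, which both bounds crowding and
  guarantees that every hydrogen is nearest its own oxygen, so written
  XYZ trajectories re-assemble unambiguously;
- region membership evolves as a continuous-time Markov chain
  discretized at dt = 0.005 ps with rates k_TL = k_LT = 1 ps⁻¹ and
  k_LB = 2.0, k_BL = 0.6 ps⁻¹ (flux-balanced so the loose shell holds
  ~6 waters on average); loose→tight entries require a free lone-pair
  slot. Geometry is resampled for the current region every frame.

What the generator does **not** emulate: water–water forces and
hydrogen-bond networks, vibrational dynamics or any temporal coherence
of positions within a region, polarization, and realistic residence-time
distributions beyond exponential sojourns. Passing tests therefore
demonstrate that the analysis recovers the structure and kinetics it is
designed to detect when they are present, not that ab initio water
behaves this way.

Rigid ideal water (O–H 0.97 Å, H–O–H 104.5°) suffices to exercise every
descriptor. Identical parameters and seed give bit-identical
trajectories.

## Problem sizes and statistical checks

Analyses in the test suite run at 100–2000 frames with 10–30 waters; the
tetrahedral-recovery check uses the full 2000-frame preset, whose
tight-occupancy mode is 4 both in ground truth and after η
classification (tight recall ≈ 1.0 at the intersection cutoff).
Statistical assertions state their expected fluctuations explicitly:
ideal-gas g(r) bins carry 3σ Poisson bands (with ~60 bins, about one
chance excursion beyond 3σ is expected, none beyond 5σ), Monte-Carlo
estimator checks use 3 standard errors over 20 seeds, and the
stationary-occupancy χ² test subsamples far beyond the relaxation time
to decorrelate.

## Known limitations

- Cubic boxes only; one solute ion; water as the only solvent.
- The η functional form is the package's definition (see above); all
  downstream quantities are defined relative to it.
- The SDF reference frame follows lone pairs by maximal-alignment
  tracking; if lone pairs rotated by large angles between saved frames,
  identity tracking could mis-assign (not the case at the default
  frame spacing).
- The direct-method NMRT requires at least one exchange event per
  shell; very short or very stiff trajectories raise rather than
  report a number.
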