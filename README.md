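# lpshells

Lone-pair-based hydration-shell analysis for halide aqua ions.

Radial hydration models describe the solvation of an ion purely through
ion–oxygen distances: every water inside the first minimum of the X–O
g(r) is "first shell". For diffuse anions such as Cl⁻ and I⁻ this hides
real structure — some first-shell waters donate a strong, nearly linear
hydrogen bond to one of the ion's four lone pairs (represented
geometrically by maximally localized Wannier-function centers), while
others merely drift through the first-shell region. `lpshells`
implements an interaction-based decomposition of the first shell built
on the geometric descriptor

```
η = r_LP–H / ( cos(α/2) · cos(β/2) )
```

where `r_LP–H` is the lone-pair–hydrogen distance, α is the angle at the
ion between the ion→lone-pair and ion→H directions, and β the angle at
the hydrogen between the O–H bond direction and the H→lone-pair
direction. η is a length (Å) equal to the bare lone-pair–H distance for
an ideal linear hydrogen bond and growing monotonically as the geometry
bends; it correlates linearly with the ion–water pair interaction
energy, so lower η means a stronger hydrogen bond. Per ion–water pair,
η_ij is the minimum over the 4 × 2 (lone pair, hydrogen) combinations.

A cutoff on η — placed where the η distributions of the four closest
waters and of the 5th–7th closest intersect — splits the conventional
first shell into a **tight** shell (η below the cutoff, tetrahedrally
anchored on the lone pairs, regardless of distance) and a **loose**
shell (the remaining waters inside the distance cutoff). The package
characterizes both subshells structurally and dynamically:

- `core_geometry` — periodic-boundary vector math, `Frame`/`Trajectory`
  containers (cubic box, minimum-image convention throughout);
- `io` — multi-frame XYZ with lone-pair pseudo-atoms (merged or separate
  centers file), two-column curves, Gaussian cube volumetric output;
- `synthetic_data` — a generator of trajectories with known ground truth
  (anchored tight waters, isotropic loose/bulk waters, continuous-time
  Markov region exchange, misoriented-water fraction);
- `rdf` — X–O / X–H g(r), first-minimum cutoffs, coordination numbers;
- `eta` — per-pair geometry, P(η) distributions by distance rank,
  intersection cutoff, peak positions;
- `sdf` — spatial distribution functions in the instantaneous lone-pair
  reference frame (the tetrahedral structure appears as four density
  maxima along the lone-pair directions);
- `shells` — tight/loose/bulk classification, instantaneous
  coordination-number distributions, misoriented-water flags, tight vs
  loose+bulk decomposition of g(r);
- `exchange` — committed exchange events (0.1 ps transient filter),
  event taxonomy (T–L, L–B, T–B, T–L–B), and normalized mean residence
  times via the direct method: `NMRT = MRT / n̄ = t_sim / N_ex`;
- `regression` — linear η → interaction-energy calibration;
- `cli_config` — the `lps` command-line tool and the full pipeline
  (`lps run --config run.toml`).

## Worked example

Analyze a synthetic chloride-like trajectory (30 waters, 14 Å box, 10 ps
at 0.005 ps/frame) end to end:

```python
import numpy as np
import lpshells as lps

params = lps.chloride_preset(n_frames=2000, seed=1)
traj = lps.generate_trajectory(params)

g = lps.compute_rdf(traj, "XO")
r_cut = lps.first_minimum(g, (3.3, 6.0))
print("X-O g(r) first peak:   %.2f A" % g.r_centers[np.argmax(g.g)])
print("first minimum (r_cut): %.2f A" % r_cut)
print("coordination number:   %.1f" % lps.coordination_number(traj, r_cut))

d14 = lps.eta_distribution(traj, "rank14")
d57 = lps.eta_distribution(traj, "rank57")
eta_cut = lps.eta_cutoff_from_intersection(d14, d57)
print("eta peak (rank 1-4):   %.2f A" % lps.eta_peak(d14))
print("eta cutoff:            %.2f A" % eta_cut)

labels = lps.classify(traj, lps.ShellCutoffs(r_cut=r_cut, eta_cut=eta_cut))
cn = lps.cn_distribution(labels, "T")
print("tight CN mode:         %d  (P(4) = %.2f)" % (cn.mode, cn.probability(4)))

grid = lps.accumulate_sdf(traj, species="O", distance_window=(0.0, r_cut))
print("SDF oxygen maxima:     %d" % lps.cluster_count(grid))

summary, _ = lps.exchange_summary(labels)
print("exchange counts:       %s" % summary.counts)
print("NMRT tight / loose:    %.2f / %.2f ps" % (summary.nmrt("T"), summary.nmrt("L")))
```

Output:

```
X-O g(r) first peak:   3.19 A
first minimum (r_cut): 4.05 A
coordination number:   9.4
eta peak (rank 1-4):   1.77 A
eta cutoff:            2.17 A
tight CN mode:         4  (P(4) = 0.58)
SDF oxygen maxima:     4
exchange counts:       {'T-L': 9, 'L-B': 84, 'T-B': 0, 'T-L-B': 42}
NMRT tight / loose:    0.20 / 0.07 ps
```

Reading the numbers: the X–O g(r) peaks at 3.19 Å with a shallow first
minimum near 4.05 Å, and ~9 waters sit inside that conventional shell.
The η distribution of the four nearest waters peaks sharply at 1.77 Å;
cutting at the rank-distribution intersection (2.17 Å) recovers a
dominant 4-fold tight shell — the tetrahedral structure hidden inside
the disordered first shell — confirmed by exactly four oxygen density
maxima in the lone-pair frame. Exchange is dominated by loose↔bulk
events, no tight water ever reaches bulk without passing through the
loose shell (T–B = 0), and tight waters are roughly three times less
mobile than loose ones (NMRT 0.20 vs 0.07 ps).

The same pipeline runs from the shell:

```sh
lps synth --preset chloride --frames 2000 --seed 1 -o traj.xyz
lps run --config run.toml        # writes g(r), P(eta), cubes, labels.tsv,
                                 # exchange.tsv and report.json to a run dir
```

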