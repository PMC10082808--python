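# pedscatter

Analysis of collision avoidance between two-person pedestrian groups
(dyads) and individual pedestrians, using the language of classical
two-body scattering — together with a social-force encounter simulator
that provides ground truth for every stage of the pipeline.

It is aimed at researchers in pedestrian dynamics and crowd modeling who
want to quantify how strongly individuals avoid walking groups, how that
avoidance depends on the group's social relation (couples, friends,
family, colleagues) or interaction intensity, and how often individuals
*intrude* — pass between the two members of a dyad.

## The method

Work in the group-centered frame: positions are translated so the dyad's
geometrical center is at the origin and rotated so the group velocity
points along +x; velocities are shifted by −**v**_g. For each individual
that enters a square observation window of half-width W = 4 m on a roughly
opposing (frontal) heading, two distances are measured:

- **r_b** — the *straight-line distance*: the scattering impact parameter
  of the null hypothesis. If the individual did not react to the group it
  would continue along its relative velocity at window entry t′, passing
  the group center at
  `r_b = |r(t′) × v̄| / |v̄|`,
  with v̄ the relative velocity averaged over the four samples ending at
  entry.
- **r₀** — the *observed minimum distance* (closest approach), found below
  sampling resolution by minimizing the linear interpolant
  `r(t) ≈ r(t_k) + (t − t_k) v(t_k)` on every inter-sample interval.

Distances are scaled by the class-average interpersonal distance d of the
dyads (written r̄), so r̄₀ < 1 means the individual came closer to the
dyad center than its members are to each other — an intrusion. A member
walking exactly at the class separation sits at r̄ = 0.5 from the center.

Any excess of r₀ over r_b is attributed to collision avoidance. For a
conservative central repulsion, energy and angular-momentum conservation
give the value of the interaction potential attained at closest approach;
dropping the constant kinetic-energy scale leaves the dimensionless
**collision-avoidance potential**

    U′(r = r₀) = (r₀² − r_b²) / r₀²,

which can only probe values U′ < 1. The pipeline quantizes r̄_b into
0.5-unit bins, computes per-bin means and standard errors of r̄₀
(with one-way ANOVA across classes per bin), intrusion probabilities
P(r̄₀ < 1) and P(r̄₀ < 0.5) with Pearson's χ² tests, 2D density maps of
the individual's position around the group (absolute, and per-class
relative to the unweighted cross-class mean), and probes U′ per bin,
fitting `k / r^β` and `a·exp(−c·r)` forms by weighted nonlinear least
squares.

The simulator integrates dyad + individual encounters in a straight
corridor under goal attraction, dyad cohesion, and a known central
repulsion `U(r) = k_true / r^β_true` between group center and individual
(suppressed with a per-class intrusion propensity), so every analysis
stage can be checked against ground truth.

## Worked example

Simulate three dyad classes that differ only in repulsion strength
(k_true = 0.2, 0.4, 0.8 with β_true = 2), run the full pipeline, and fit
the avoidance potential per class:

```python
import pedscatter as ps

classes = [
    ps.ClassSpec("weak",   0.7, 0.1, potential_strength=0.2, intrusion_propensity=0.1),
    ps.ClassSpec("medium", 0.7, 0.1, potential_strength=0.4, intrusion_propensity=0.1),
    ps.ClassSpec("strong", 0.7, 0.1, potential_strength=0.8, intrusion_propensity=0.1),
]
scenario = ps.SimScenario(n_encounters=1500,
                          class_mix={c.label: 1.0 for c in classes})
traj, annot, truth = ps.simulate_dataset(scenario, classes, seed=1)

config = ps.RunConfig(rb_correction=False)   # straight corridor: no environment bias
bundle = ps.run_pipeline(config, traj, annot)
```

Output:

```
1165 frontal encounters analyzed
class_label    k_hat  beta_hat
     medium 0.693285  2.428245
     strong 1.117440  2.070031
       weak 0.240956  2.558149
intrusion probability (rbar_b < 1):
medium    0.68
strong    0.28
weak      0.82
```

The fitted strengths reproduce the true ordering (weak < medium <
strong), and the intrusion probability in the near-collision regime falls
monotonically with the true repulsion — the central qualitative result:
the stronger the coupling of the dyad, the more prominently it is
avoided. The recovered exponents scatter around the true β = 2 with a
small upward bias inherent to the probe (the finite window truncates the
potential; see `docs/methods.md`).

A `pedscatter` command exposes the same stages from the shell
(`simulate`, `extract`, `analyze`, `fit`), each taking `--config
config.yaml --out DIR --seed N` and writing CSV tables (binned
statistics, ANOVA and χ² p-values, intrusion probabilities, potential
fits, density-map grids).

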