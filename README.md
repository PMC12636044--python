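# memhairpin

Membrane-binding analysis for an ESCRT-III-type α-helical hairpin:
trajectory-side contact statistics and binding kinetics, and
spectroscopy-side binding-curve fitting, packaged as a library
(`src/memhairpin/`) with numbered analysis drivers (`analysis/`).

ESCRT-III-superfamily proteins such as IM30/Vipp1 remodel membranes via
a conserved α1–α3 helical hairpin that binds negatively charged
(PG-containing) lipid surfaces.  Characterising that binding
computationally needs a small, well-defined toolchain:

* **Contacts** — a protein–membrane contact is a heavy-atom pair within
  0.4 nm (minimum image in the membrane plane).
* **Binding kinetics** — binding is *sustained* contact: ≥5 contacts
  maintained for ≥5 ns; unbinding is <5 contacts for ≥0.5 ns after a
  binding event.  First-binding times across replicas form a cumulative
  binding curve.
* **Occupancy** — per residue, the fraction of frames with ≥1 membrane
  contact, averaged over replicas with 95% BCa bootstrap intervals
  (1000 resamples over replicas).
* **Conformation by state** — backbone essential-dynamics PCA
  (iterative mean-structure fitting, covariance diagonalization),
  Kabsch–Sander α-helix counts, and Shrake–Rupley SASA (0.14 nm probe),
  each split into bound/unbound distributions (Scott-rule KDEs).
* **Affinity** — Laurdan generalized polarization
  GP = (I440 − I490)/(I440 + I490) fitted against protein concentration
  with the Hill model GP = GP₀ + ΔGP·[P]ⁿ/(K_Dⁿ + [P]ⁿ).
* **Coverage** — footprint arithmetic (a 10×2 nm² hairpin over
  0.75 nm²/lipid needs 27 lipids per leaflet, 54 total) and an
  exploratory random-sequential-adsorption simulator.

No trajectories or raw titrations are shipped; the `synth` module
generates structures, binding trajectories, contact series and GP
curves with known ground truth, so every stage is exercised end to end
and checked against independent oracles (brute-force contact counting,
quaternion superposition, reference DSSP, analytic sphere areas,
round-trip Hill fits).  See `docs/methods.md` for models, defaults and
limitations.

## Worked example

Association kinetics across surface-attraction strengths (the PG-content
axis): 20 replicas of a hairpin released 2 nm above a lipid slab, 200 ns
each, classified with the sustained-contact criterion.

```sh
python analysis/02_binding_kinetics.py
```

```
well 0 kT: 0/20 replicas bound, median first-binding time not reached
well 2 kT: 15/20 replicas bound, median first-binding time 159.6 ns
well 5 kT: 20/20 replicas bound, median first-binding time 50.5 ns
```

Without surface attraction (a net-neutral PC surface) the peptide
essentially never establishes sustained contact; increasing attraction
(more PG) makes binding both more likely and faster — the qualitative
signature the pipeline is built to resolve.  Affinity fitting on
synthetic GP titrations with measurement noise:

```sh
python analysis/05_binding_curves.py
```

```
high_affinity: K_D true 1.50 μM → fit 1.69 ± 0.23 μM, n = 1.03
mid_affinity: K_D true 2.00 μM → fit 1.75 ± 0.16 μM, n = 1.39
low_affinity: K_D true 3.30 μM → fit 2.44 ± 0.93 μM, n = 1.26
noise-free round trip: K_D recovered to 2.62e-11 relative error
```

Each fit reports K_D with its asymptotic standard error and the apparent
cooperativity n; noisy single curves recover K_D to roughly the
precision their error bars claim, and noise-free curves round-trip to
numerical accuracy.  The remaining drivers (`01`–`06`) build the
systems, compute occupancy profiles, state-conditioned PCA/helicity/SASA
tables and coverage numbers into `results/`.

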