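# cryptlineage

Tools for analyzing cell-lineage dynamics in intestinal crypts and for
simulating the stochastic stem-cell models that explain how crypts keep
their proliferating-cell number stable.

Renewing epithelia balance proliferation and differentiation by
*population asymmetry*: each cell decides stochastically whether to keep
dividing, and the balance holds only on average. Time-lapse tracking of
organoid crypts shows that this decision is strongly correlated between
sister cells — divisions overwhelmingly produce either two proliferating
or two non-proliferating daughters — and that the number of proliferating
cells per crypt stays nearly constant with *sub-Poissonian* fluctuations
(σ < √N̄). This package implements the full computational chain behind
those observations, for anyone who has (or simulates) single-cell
tracking data of crypt-like tissues:

- **Lineage statistics** (`cryptlineage.lineage`): lineage forests from
  track tables; a proliferative-state classifier (a cell is
  non-proliferating when followed ≥ 30 hr without dividing or found
  beyond 60 µm up the crypt-villus axis); sister/cousin division-pattern
  tallies; the symmetry fraction Φ; and the estimator that inverts the
  division-mode probabilities

  p_pp = (φ + α)/2, p_nn = (φ − α)/2, p_asym = 1 − φ

  to recover the proliferative bias α ∈ [−1, 1] and the division symmetry
  φ ∈ [0, 1] from observed pair outcomes.
- **Crypt geometry** (`cryptlineage.geometry`): "unwrapping" of tracked
  3-D positions into (axis position, angle) coordinates along an
  annotated crypt axis, and link distances δ to the nearest Paneth cell
  on the 5-nearest-neighbour graph (a Paneth neighbour has δ = 0).
- **Population statistics** (`cryptlineage.popstats`): growth-rate fits
  to N(t) = N₀e^{αt/T}; dwell-time-weighted fluctuation measures; the
  bootstrap null for sister symmetry under independent decisions;
  positional division histograms; clone-size distributions over a sliding
  40-hr window with bootstrap errors.
- **Stochastic models** (`cryptlineage.models`): event-driven simulators
  of the *Uniform* model (unbounded pool, division modes as above) and the
  *Compartment* model (a fixed-size niche of S positions with bias α_n > 0
  feeding an unbounded differentiation compartment with α_d < 0, with
  cell rearrangement at rate r), plus niche-size calibration and
  phase-diagram sweeps over (α_n, α_d, φ).
- **Synthetic data** (`cryptlineage.synthetic`): a generator that emits
  track tables with the measured statistical structure (≈30 proliferating
  cells, skew-normal cycle times with mean T = 16.2 hr, sister cycle
  correlation 0.8, α = +0.67 within one cell of a Paneth cell and −0.67
  beyond, φ = 0.98, deaths and tracking losses) together with the ground
  truth, so the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
from cryptlineage import analysis, lineage, models, popstats, synthetic

# a synthetic 60-hr crypt recording (track table + axis annotation + truth)
tracks, axis, truth = synthetic.generate_crypt_tracks(rng=42)

res = analysis.analyze_crypt(tracks, axis)
c = res["sister_counts"]
print(f"sister pairs: {c.n_total} (pp={c.n_pp}, nn={c.n_nn}, pn={c.n_pn})")
print(f"symmetry fraction: {lineage.symmetry_fraction(c):.3f}")
for region, counts in res["patterns_by_delta"].items():
    a, p = lineage.estimate_alpha_phi(counts)
    print(f"{region}: alpha={a:+.2f}, phi={p:.2f}  (n={counts.n_classified})")

null = popstats.bootstrap_symmetry_null(499, 0.79, 100_000, observed_phi=0.97, seed=0)
print(f"independence null: phi = {null.mean_phi:.2f} +/- {null.sd_phi:.2f}, {null.p_label()}")

rng = np.random.default_rng(0)
S = models.calibrate_niche_size(1.0, -1.0, 1.0, N_target=30, r=1/16.2, rng=rng)
sim = models.simulate_compartment(
    models.CompartmentParams(alpha_n=1, alpha_d=-1, phi=1, S=S, r=1/16.2),
    rng=rng, t_max=1e5)
print(f"compartment model: S={S}, <N>={sim.mean:.1f}, sd={sim.sd:.2f}")
```

prints

```
sister pairs: 90 (pp=26, nn=29, pn=0)
symmetry fraction: 1.000
near: alpha=+0.63, phi=1.00  (n=27)
far: alpha=-0.71, phi=1.00  (n=28)
independence null: phi = 0.67 +/- 0.02, p < 1e-05
compartment model: S=21, <N>=29.7, sd=2.86
```

Reading this: on one simulated crypt every classified sister pair had a
concordant outcome (pp or nn, none mixed), far above the 0.67 ± 0.02 a
null of independent per-cell decisions would produce — so pair outcomes
are controlled through the mother, not independently per daughter. The
near/far split recovers the generator's proliferative bias (+0.67 close
to Paneth cells, −0.67 beyond) from the data alone. The calibrated
compartment model holds ⟨N⟩ ≈ 30 proliferating cells with σ ≈ 2.9,
well below the Poisson benchmark √30 ≈ 5.5.

A small CLI fronts the simulators:

```sh
crypt-sim simulate-compartment --alpha-n 1 --alpha-d -1 --phi 1 --seed 0 --out summary.json
crypt-sim sweep --out sweep.csv
```

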