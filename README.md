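# tipshell

Simulator of budding-yeast mating-projection (shmoo) growth as an
axisymmetric, inhomogeneous thin **viscous shell** inflated by turgor
pressure and rebuilt by exo-/endocytosed **Fks1/2 glucan synthases**, with
the cell-wall-integrity pathway modelled as a **mechanical feedback**: the
synthase activation rate senses the local wall expansion rate.

It is written for quantitative cell biologists and biophysicists studying
tip growth who want to ask: *when is wall expansion stable, what sets the
projection radius, and what does the integrity-pathway feedback actually
buy the cell?*

## Model in brief

On the meridian (arclength `s` from the apex, radius `r`, normal angle
`θ`, curvatures `κ_s = ∂θ/∂s`, `κ_φ = sinθ/r`):

```
σ_ss κ_s + σ_φφ κ_φ = P ,         σ_ss κ_φ = P/2            (force balance)
σ_ss = 4μh (ε̇_s + ε̇_φ/2) ,      σ_φφ = 4μh (ε̇_s/2 + ε̇_φ)  (viscous wall)
∂_t(rh) + ∂_s(rhu) = r (m_w k_p / ρ_w) ρ_A                  (wall mass)
∂_t(ρ_I r) = r[k_off ρ_A − k_on ρ_I] + r[k_X ρ_0 − k_D ρ_I]
∂_t(ρ_A r) + ∂_s(ρ_A r u) = r[k_on ρ_I − k_off ρ_A]         (synthases)
k_on = Γ (ε̇_s + ε̇_φ)                                       (feedback)
```

with Gaussian exo/endocytosis profiles `k_X = k_X0 e^{−s²/λ_X²}`,
`k_D = k_D0 e^{−s²/λ_D²}` and viscosity `μ = μ_0 e^{+s²/λ_X²}`.  After
scaling, five dimensionless groups remain; the two control parameters are
the feedback strength `Γ` and `λ_X/λ_m = Pρ_wλ_X/(12μ_0 m_w ρ_0 k_p)`,
the ratio of the exocytosis length to the mechanical length.  Without
feedback (`Γ = 0`, constitutively active synthases) growth is never
steady: the wall either thins to piercing (lysis) or thickens without
bound.  With feedback there is a critical `Γ*` — increasing with
`λ_X/λ_m` — above which the projection grows steadily, with a radius set
by `λ_X` and nearly independent of `Γ`.

See `docs/methods.md` for the numerical scheme (4th-order method of lines
on a tip-co-moving arclength grid, implicit BDF in time) and all defaults.

## Worked example

Simulate one parameter point (scaled units; `gamma` is Γ, `lam_ratio` is
`λ_X/λ_m`):

```toml
# shmoo.toml
[dimensionless]
gamma = 5.0
lam_ratio = 0.2

[numerics]
n_grid = 81
domain_len = 6.0
```

```sh
tipshell simulate --config shmoo.toml --out shmoo-out
# INFO tipshell: outcome: STABLE (t_end=181)
```

`shmoo-out/summary.json` then contains (abridged):

```json
{
  "outcome": "STABLE",
  "final_residual": 0.000297,
  "observables": {
    "R": 1.2303, "H": 2.7010,
    "eps0": 0.04955, "kappa0": 0.9269,
    "rhoA0": 0.4316, "rhoI0": 0.9572,
    "tip_speed": 0.04656
  }
}
```

Reading: the run reached steady tip growth (every scaled field changes by
less than 10⁻³ per unit time).  The projection radius is `R = 1.23 λ_X`
and the distal wall thickness `H = 2.70 H₀` — the radius is set by the
exocytosis scale, the thickness by the feedback balance.  At the apex the
wall expands at `ε̇_s + ε̇_φ ≈ 0.099 k_X0` (both components equal by
axisymmetry), the tip has curvature `0.93/λ_X`, and the apical synthase
density `ρ_A0 + ρ_I0 ≈ 1.39 ρ_0` exceeds the vesicle delivery density —
active synthases are anchored to the wall they extrude, which concentrates
them at the tip.  The tube elongates at `0.047 λ_X k_X0` per unit time.
`shmoo-out/profile.csv` holds the full steady profiles (shape, tensions,
strain rates, velocities, densities).

Other subcommands: `tipshell sweep` (phase diagram over a Γ × λ_X/λ_m
grid), `tipshell critical` (bisect the stability boundary Γ*), and
`tipshell oracle-check` (closed-form sphere/cylinder mechanics checks).
The same operations are available as library functions
(`tipshell.run_to_outcome`, `tipshell.sweep`, `tipshell.critical_gamma`,
`tipshell.radius_scaling_table`).

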