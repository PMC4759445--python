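# ppmap

Stability and Neimark–Sacker bifurcation analysis of the planar
discrete-time predator–prey map

```
x_{n+1} = α x_n (1 − x_n) − x_n y_n
y_{n+1} = (1/β) x_n y_n
```

on the closed first quadrant, where `x` is prey density, `y` predator
density, and `α, β > 0` are the prey growth and predation-efficiency
parameters. The package is aimed at theoretical ecologists and dynamical
systems practitioners who want a tested, reproducible implementation of
the complete local analysis of this map: equilibria and their
lemma-based topological classification, detection of the non-hyperbolic
locus where a complex-conjugate eigenvalue pair sits on the unit circle,
the full normal-form reduction with the first Lyapunov quantity Ω, and
numerical attractor classification (stable focus vs. invariant closed
curve vs. divergence).

## The mathematics in brief

The map has two fixed points: the origin `O(0, 0)` and the coexistence
point `A = (β, α(1−β) − 1)`, which is positive exactly when `β < 1` and
`α > 1/(1−β)`. At `A` the Jacobian has trace `p = 2 − αβ` and
determinant `q = α − 2αβ`, with discriminant
`Δ = p² − 4q = (αβ + 2)² − 4α`. When `Δ < 0` the eigenvalues are a
conjugate pair of modulus `√q`, so `|λ| = 1` exactly on the critical
line

```
α_c(β) = 1/(1 − 2β),   0 < β < 4/9 (Δ < 0 requires β < 4/9).
```

Crossing `α_c` the pair leaves the unit circle with speed
`d|λ|/dα* = (1 − 2β)/2 > 0` (transversality) and `λ^k ≠ 1` for
`k = 1..4` (no strong resonance): the generic Neimark–Sacker scenario,
the discrete-time analogue of the Hopf bifurcation. Translating `A` to
the origin and conjugating the linear part to the rotation–scaling
matrix `[[η, −ζ], [ζ, η]]` with `λ = η + iζ` puts the map in the form
`(X, Y) ↦ (ηX − ζY + F, ζX + ηY + G)` with quadratic `F, G`; the sign of
the first Lyapunov quantity

```
Ω = −Re[(1 − 2λ̄)λ̄²/(1 − λ) · ξ₁₁ξ₂₀] − ½|ξ₁₁|² − |ξ₀₂|² + Re(λ̄ ξ₂₁)
```

decides criticality: Ω < 0 means an attracting invariant closed curve is
born as α crosses α_c (supercritical), Ω > 0 a repelling one
(subcritical). Because the map is quadratic, ξ₂₁ = 0 identically — the
package both derives this and verifies it by exact symbolic
differentiation of the composed transformed map.

## Worked example

At `β = 0.23` the critical value is `α_c = 1/(1 − 0.46) = 1.85185…`.
Classify the equilibria exactly at the critical point:

```
$ ppmap classify --alpha 1.8518518518518519 --beta 0.23 --out-dir out --quiet
O(0,0): saddle
A(0.23,0.425926): non-hyperbolic
normal form: Omega = -0.188004 (supercritical-attracting)
```

The origin is a saddle (it always is once `A` exists), the coexistence
point is non-hyperbolic with `|λ| = 1`, and the normal form report
(written to `out/normal_form.json`) gives η = 0.787037, ζ = 0.616906,
Ω = −0.188004 < 0: the bifurcation is supercritical, so an attracting
invariant closed curve appears just past `α_c`. Simulating there
confirms it:

```
$ ppmap simulate --alpha 1.87 --beta 0.23 --out-dir out2 --quiet
verdict: closed_curve
```

and a bifurcation scan at grid step 0.01 brackets the critical value:

```
$ ppmap scan --beta 0.23 --alpha-lo 1.5 --alpha-hi 2.1 --n-grid 61 --out-dir out3 --quiet
transition bracket: (1.84, 1.86); critical alpha = 1.85185
```

Every run writes its fully resolved configuration
(`resolved_config.yaml`) next to the results, orbits and scans as CSV
with 17-significant-digit floats, and reports as JSON; re-running a
config reproduces the outputs byte for byte. The other subcommands are
`basin` (seeded sampling of initial conditions, reporting the fraction
that converge to `A` — in the stable regime every sampled orbit that
stays in the first quadrant does) and `normal-form` (the full reduction
report on its own).

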