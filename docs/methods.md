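# Methods and numerical conventions

## Model and scope

The object of study is the planar map
`(x, y) ↦ (αx(1−x) − xy, xy/β)` with `α, β > 0`, a discrete-time
predator–prey model with logistic prey growth and a predator whose
reproduction is proportional to encounters. The package performs the
complete *local* analysis at the two fixed points `O(0,0)` and
`A = (β, α(1−β)−1)` plus a numerical global probe. It deliberately does
not attempt: proofs of global asymptotic stability (the basin sampler is
a numerical check, not a proof), flip/period-doubling analysis,
center-manifold reduction for the real-eigenvalue non-hyperbolic case
`α = 1/(1−β)`, rotation numbers, Lyapunov spectra, or chaos detection.

## Sign and convention choices

Three places in the standard derivation of this bifurcation admit
inconsistent sign/typo variants; the package fixes each by requiring the
algebra to be self-consistent, keeps the literal alternative available,
and tests the choice.

**Characteristic polynomial.** We use `λ² − pλ + q = 0` with
`p = 2 − αβ = tr J(A)` and `q = α − 2αβ = det J(A)`. A unit test checks
p and q against the numeric trace and determinant; the opposite sign
convention for p would fail it.

**η convention.** The critical eigenvalue is written `λ = η + iζ` with
`ζ = ½√(4α − (αβ+2)²) > 0`. Only `η = Re λ = (2 − αβ)/2` makes the real
conjugating transform `T = [[a₁₂, 0], [η − a₁₁, −ζ]]` satisfy
`T⁻¹ J(A) T = [[η, −ζ], [ζ, η]]` — the linear part the normal form
assumes. The opposite sign `η = (αβ − 2)/2` appears in some derivations;
it is retained as `convention="paper"` and the report always carries Ω
under both conventions, but the package default is `"jacobian"` because
the transform must actually realize the rotation (verified to 1e−8 at
random critical points).

**Quadratic coefficients of the transformed map.** Writing
`k = η − a₁₁`, symbolic composition of the translation, the Taylor map
and the T-conjugation gives

```
c₁₁ = a₁₂a₁₃ + k a₁₄          c₁₂ = −a₁₄ ζ
c₂₁ = (k/ζ)(a₁₂a₁₃ + k a₁₄ − a₁₂a₂₃)
c₂₂ = a₁₂a₂₃ − k a₁₄
```

These are the package default (`c_convention="derived"`) and are
verified against finite differences of the composed map to 1e−5. A
variant set that circulates with `c₁₂ = −ζ` and an extra `a₁₂` factor
inside `c₂₁` is retained as `c_convention="paper"`; it is *not* the
quadratic part of the transformed map (the finite-difference check
distinguishes them), but is kept so the literal computation can be
reproduced. At `β = 0.23` the sign of Ω — the only decision-relevant
output — is negative under every convention combination (−0.188
jacobian/derived, −12.57 paper-η/derived), so the supercritical verdict
does not depend on the choice; the cross-check against the observed
attracting circle is part of the test suite.

**ξ coefficients and Ω.** The ξ's are assembled from the second partials
of (F, G) exactly as in the classical criterion
(`ξ₁₁ = ½(c₁₁ + i c₂₁)` etc.); the closed forms and the
derivative-based route are cross-checked against each other
property-style. ξ₂₁ combines the eight third-order partials, all of
which vanish because the map is quadratic; the package evaluates them by
exact sympy differentiation of the fully composed transformed map rather
than asserting the structure. In Ω, `λ = η + iζ` (positive imaginary
part) and `‖·‖` is the complex modulus. The verdict "for the
perturbation α* > 0" refers to the side of the critical line on which
the curve exists; the bifurcation parameter α itself is always positive.

## Tolerances and degenerate inputs

- Fixed-point residual of reported equilibria: ≤ 1e−12.
- Algebraic identities (Δ = p²−4q = (αβ+2)²−4α, |λ| = √q when Δ < 0,
  conjugacy of T): 1e−10 … 1e−8.
- Finite-difference verification of closed-form coefficients: central
  differences, h = 1e−6 for first derivatives, h = 1e−4 for second
  (the maps are polynomial, so truncation error vanishes and only
  round-off ~1e−8 remains); agreement required to 1e−5.
- Threshold equalities (non-hyperbolicity, H_A membership): |α −
  threshold| ≤ 1e−9 by default, configurable. Strong-resonance
  exclusion: |λᵏ − 1| > 1e−8 for k = 1..4.
- |Ω| ≤ 1e−10 reports "degenerate": the cubic criterion is then
  inconclusive and the report says so instead of picking a side.
- `β ≥ 1` or `α ≤ 1/(1−β)`: the interior fixed point is reported absent
  (its predator component would be non-positive); an
  `include_nonadmissible` flag returns the algebraic fixed point anyway.
- Δ = 0 falls in the real-eigenvalue branch of the case table.

The lemma-style case table for A is known to disagree with the raw
eigenvalue moduli in part of the real-eigenvalue region (for `β > ½` and
large α, `q < 0` allows a saddle or even a sink where the table says
"source"). `classify_interior` therefore always computes both verdicts
and flags disagreement in the report rather than resolving it silently;
in the complex-pair region `Δ < 0` — the region the bifurcation analysis
lives in — the two always agree (property-tested).

## Attractor classification

`classify_attractor` iterates the map (default 10 000 transient +
10 000 retained steps, escape radius 1e6, default initial condition
`A + (0.05, 0.05)`, recorded in every output) and computes the radial
statistics r_min, r_max, r_mean of the retained window about A, plus a
drift statistic: the difference of mean radius between the first and
second halves of the window, relative to r_mean. Verdicts:

- `fixed_point` — r_max ≤ 1e−6;
- `closed_curve` — r_min ≥ 1e−4, relative annulus width
  (r_max − r_min)/r_mean ≤ 2.0, and drift ≤ 0.02;
- `divergent` — the orbit left the escape disc (the index is reported);
- `undetermined` — everything else.

The width bound is calibrated to this map's geometry: the invariant
curve is an eccentric ellipse-like loop around A (the conjugating
transform is far from orthogonal), and measured widths of genuine
circles near onset are 0.98–1.73 across β ∈ {0.13, 0.23, 0.35}. The
bound therefore only excludes wandering or space-filling behaviour, not
ellipticity. The drift criterion is what keeps the classifier honest
exactly on the critical line, where the linearization is neutral and the
orbit is a slowly contracting spiral: measured drift there is ≈ 0.17
versus < 3e−4 on true circles, so the critical case reports
`undetermined` rather than a spurious circle. Exotic attractors (e.g.
after the curve breaks up at large α) also fall back to `undetermined`
by design; radial statistics make no attempt to recognize them.

`bifurcation_scan` applies the classifier on a uniform α-grid and
reports the transition bracket (last `fixed_point` before the first
`closed_curve`). Near the critical value the linear contraction rate
approaches 1, so grid points within ~one step of α_c may legitimately
come out `undetermined` at the default transient length; the bracket
then spans two grid steps, which still localizes α_c.

`basin_sample` draws seeded-uniform initial conditions in a rectangle
(axis points rejected: the axes are invariant with degenerate dynamics)
and reports both the raw converging fraction and the fraction among
orbits that remain in the first quadrant. The distinction matters: from
much of (0,1)², one step of the map makes the prey density negative
(biologically meaningless), after which the orbit typically escapes. In
the stable regime every positivity-preserving sampled orbit converges to
A — the numerical content of the "globally asymptotically stable"
observation — but this sampling supports, and cannot prove, that claim.

## What the defaults emulate, and limits

The default study conditions mirror the reference simulation setting:
β = 0.23, with α = 1.48 (stable focus), α = α_c = 1.85185… (critical),
and α just above critical (invariant circle); scans use grid step 0.01
over [1.5, 2.1]. The original figures print no initial conditions or
axis ranges, so the qualitative regimes — not pixel coordinates — are
the reproduction target, and the default initial condition is the
package's documented choice. Problem sizes (10 000 + 10 000 iterates,
200-point basins, 61-point scans) were chosen as the smallest that make
the radial statistics stable to well within the decision thresholds;
they are package defaults, not measurement limits, and all are
configurable. Passing tests demonstrate correctness of the analysis for
this map; they say nothing about structurally different predator–prey
functional responses, stochastic variants, or the continuous-time
analogue, all of which are out of scope.
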