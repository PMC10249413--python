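# Methods

## Model

A flat impenetrable wall carries acidic surface groups at areal density
σˢⁱᵗᵉ on a square lattice; the electrolyte is a primitive-model bath of
point-like ions in a uniform dielectric characterized solely by the
Bjerrum length l_B. All internal quantities are reduced: lengths in nm,
densities in nm⁻² / nm⁻³, potentials as x ≡ βeϕ. The surface charge
density is a signed number density, σ = −α σˢⁱᵗᵉ ≤ 0.

Three potentials matter:

- x_ion, the potential on an ion at contact, fixed by the contact-value
  theorem

      Σᵢ ρᵢᵇᵘˡᵏ (e^(−zᵢ x_ion) − 1) = 2π l_B ξ² σ² + βP.

  ξ² ≥ 1 accounts for ion–site correlations (extra contact force over a
  discretely charged wall compared to a smeared one); βP is an external
  osmotic pressure, nonzero only when modelling two walls at finite
  separation. For an electroneutral bath the left side is convex with
  minimum 0 at x_ion = 0, so a positive right side has exactly two
  roots; the counterion-enriched branch (sign(x_ion) = sign(σ)) is
  selected by bracketed Brent iteration. **Consequence:** the left side
  can never be negative, so any βP < −2π l_B ξ² σ² makes the condition
  unsolvable and raises a `NoSolutionError` naming βP — there is no
  "small negative" regime.

- x_site, the potential on a site, related to x_ion by eliminating the
  shared mean-field potential:

      x_site = (x_ion − x_ii − x_ex) + x_cap + x_ss.

- The acid–base equilibrium closes the loop:
  α = 1/(1 + 10^(pKₐ−pH) e^(−x_site)), evaluated through an
  overflow-safe logistic. The hydronium activity is taken as 10^(−pH)
  exactly; pKₐ is intrinsic, and no "apparent pKₐ" is introduced.

## Correction terms

- **Stern capacitor** x_cap = 4π l_B d_is σ (dimensionless form of
  eσ/C_S with C_S = ε₀ε_r/d_is).
- **Excluded volume** x_ex = π l_B d_ii σ: a capacitor-like hole
  correction with effective plate distance d_ii/4. The site–ion
  potential difference then corresponds to the series capacitance
  C_eff = ε₀ε_r/(d_is − d_ii/4); for the default surface C_S = 1.99 and
  C_eff = 2.78 F/m², which explains why mean-field surface-complexation
  fits need a capacitance larger than the geometric Stern value.
- **Site–site correlations** x_ss = +ζ M_sq l_B √(α σˢⁱᵗᵉ): the ionized
  sites at density α σˢⁱᵗᵉ gain the square-lattice Wigner-crystal
  Madelung energy, which favors the ionized state. The Madelung energy
  is used directly as the site potential correction (no thermodynamic
  3/2 derivative factor); ζ is understood to absorb any such prefactor
  together with the lattice-gas entropy of partial occupation. ζ = 0.75
  by default; ζ only mildly affects the curves.
- **Ion–ion correlations**: at weak coupling the one-loop result
  x_ii = −c₀ Ξ/z_s with c₀ = π/8 − 0.3104 ≈ 0.08230; at strong coupling
  the magnitude cannot exceed the Madelung energy of a hexagonal
  crystal of bound counterions at density |σ|/z_s, i.e.
  −M_hex √(Ξ/2π)/z_s. The implementation joins the two with the
  quadratic inverse-sum interpolant

      x_ii = −(1/z_s) [(c₀Ξ)⁻² + (M_hex √(Ξ/2π))⁻²]^(−1/2),

  chosen over the plain (p = 1) harmonic mean because it approaches
  each asymptote quadratically in the asymptote ratio: the loop term is
  essentially unattenuated until the Madelung cap actually comes into
  reach (crossover at Ξ = (M_hex/c₀)²/2π ≈ 90). The p = 1 form damps
  the loop term by ~40% already at Ξ ≈ 50, which visibly suppresses the
  divalent-salt correlation effect; the quadratic form reproduces the
  known magnitudes of that effect while satisfying the same two limits.
  x_ii returns exactly 0 for z_s < 10⁻¹² (the analytic limit at the
  point of zero charge).
- The average contact valency z_s = |Σ zᵢ ρᵢˢ| / Σ ρᵢˢ with
  ρᵢˢ = ρᵢᵇᵘˡᵏ e^(−zᵢ x_ion), and Ξ = 2π l_B² |σ| z_s³ (absolute value
  of σ so that Ξ ≥ 0 for either surface sign). z_s vanishes at the
  point of zero charge and tends to the counterion valency for highly
  charged surfaces, so Ξ regularizes the low-charge regime and matches
  the standard counterion-only coupling parameter at high charge.

Excluded-volume and ion–ion terms are treated as independent; no
image-charge or dielectric-discontinuity corrections are included.

## Madelung constants

`madelung` evaluates the 2D one-component-plasma constants by a
quasi-2D Ewald sum (Gaussian splitting; direct- and reciprocal-shell
sums plus self and background terms), in the convention
u = −M l_B z² √n per charge: M_sq = 1.9501, M_hex = 1.9605 (literature
roundings 1.949/1.961; the two differ by less than 1%, so the exact
lattice choice is not critical). The result is independent of the
splitting parameter, which the tests exploit as a correctness check,
and converges double-exponentially in the shell depth (depth 8 is
converged far below 1e-10; the constants consumed by `potentials` are
frozen literals cross-checked against the live sum in the tests).

## Self-consistent loop

Given pH, the map σ → (x_cap, x_ex) → x_ion → (z_s, Ξ, x_ii) →
x_site → α → σ′ = −α σˢⁱᵗᵉ is iterated with damping
σ_{k+1} = (1−γ)σ_k + γσ′, γ = 0.2, until |σ′ − σ|/σˢⁱᵗᵉ < 10⁻¹²
(max 10⁵ iterations; plain iteration oscillates at strong coupling,
damping restores contraction). Initialization is the ideal-titration
guess σ₀ = −α_HH σˢⁱᵗᵉ; sweeps warm-start from the previous pH. x_ss is
evaluated at the current α = −σ/σˢⁱᵗᵉ inside the loop. On
non-convergence the solver falls back to an independent reformulation:
f(σ) = α_chem(σ) + σ/σˢⁱᵗᵉ is monotone-bracketed on [−σˢⁱᵗᵉ, 0]
(f(0) > 0, f(−σˢⁱᵗᵉ) ≤ 0) and solved by Brent bisection. That
bisection solver is also exposed as `solve_point_bruteforce` and serves
as the oracle in the tests; points that still fail are returned flagged
`converged=False`, never silently.

Level toggles: `use_ex`, `use_ss`, `use_ii` zero their respective
terms. `use_cap` governs the double-layer feedback as a whole — the
mean-field potential together with the Stern term — because the
"simple capacitor" baseline level (a) bundles them and no level of the
theory retains the mean field without the capacitor. All named presets
(a–d) keep it on; switching everything off therefore reduces exactly
to the Henderson–Hasselbalch curve, which the tests assert to 10⁻¹⁰.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| l_B | 0.714 nm | Bjerrum length, water at room temperature |
| σˢⁱᵗᵉ | 4.8 nm⁻² | titratable site density (max charge −769 mC/m²) |
| pKₐ | 7.7 | intrinsic site constant |
| d_is | 0.35 nm | ion–site closest perpendicular separation |
| d_ii | 0.4 nm | ion–ion closest separation |
| ζ | 0.75 | site–site attenuation (0 = off, 1 = perfect lattice) |
| ξ² | 1 | ion–site correlation factor (1 = neglected) |
| T | 298.15 K | used only for SI conversions |
| γ | 0.2 | fixed-point damping |
| tol | 10⁻¹² | convergence on Δσ/σˢⁱᵗᵉ |

The default surface reproduces silica-like titration: microscopic
parameters typical of the simulation and experimental benchmarks in
the charge-regulation literature, and the conditions under which the
package's acceptance numbers (Ξ ≈ 4 and ≈ 50 at pH 9 for 1000 mM 1:1
and 2:1 salt; site–site ≈ 20–25% plateau; ion–ion ≈ 5% for 1:1;
combined ≈ 30% for 1:1 and ≈ 70% for 2:1, with clear synergy) are
computed. Temperature enters only SI reporting: the printed literature
capacitances C_S = 1.93 / C_eff = 2.67 F/m² are internally rounded at
the ~3–4% level relative to the values implied by l_B = 0.714 nm at
298.15 K (1.99 / 2.78), which is why the capacitance checks carry a 5%
band while the series identity C_eff = ε₀ε_r/(d_is − d_ii/4) is exact.

## Configuration schema

TOML (default) or YAML (`.yml`/`.yaml`):

```toml
[surface]   # all optional, defaults above
lB_nm = 0.714
site_density_nm2 = 4.8
pKa = 7.7
d_is_nm = 0.35
d_ii_nm = 0.4
zeta = 0.75
xi2 = 1.0

[salt]
species = [ { z = 2, conc_M = 1.0 }, { z = -1, conc_M = 2.0 } ]

[sweep]
pH_min = 4.0
pH_max = 9.0
pH_step = 0.5

[level]            # either a preset...
preset = "d"       # ...or explicit booleans cap/ex/ss/ii

[solver]           # optional
tol = 1e-12
max_iter = 100000
damping = 0.2

[pressure]         # optional
betaP_nm3 = 0.0
```

Unknown keys are rejected with their section, so typos cannot silently
fall back to defaults.

## What the checks do and do not show

The test-suite validates the theory against closed forms (the Grahame
branch for symmetric salts, the Henderson–Hasselbalch degeneration),
against an independent bisection solver on randomized configurations,
and against the printed reference magnitudes of the correlation
effects. It does not — cannot — validate against real titration data:
no experimental curves ship with the package (the `--overlay` option
exists to compare against user-supplied data). The model itself
neglects ion-specific adsorption, dielectric saturation and images,
multi-pKₐ chemistry, and treats ion–site correlations only through the
user-set scalar ξ²; for trivalent counterions or sub-hydration contact
distances those assumptions degrade. Inter-surface pressure curves
P(h) are out of scope; βP is accepted as an input instead.

## Numerical notes

- Contact solve: bracket expansion by doubling from |x| = 1, Brent
  polish to machine tolerance; residual asserted below 10⁻¹⁰ of the
  problem scale. Exponentials are clamped at 700 to avoid overflow on
  extreme brackets.
- Degenerate inputs: zero-concentration baths raise a no-solution
  error; α is clamped to [0, 1] before the square root in x_ss against
  transient overshoot of the damped iterate; the fully-ionized corner
  of the bisection bracket is handled explicitly.
- Determinism: identical inputs give byte-identical CSV output (12
  significant digits, no timestamps); logs go to stderr only.
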