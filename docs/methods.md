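# Methods

## Two-site CEST model

Magnetization of each spin is a six-vector (Mx, My, Mz) ⊗ (ground G,
excited E) evolving under the Bloch–McConnell generator L: precession at
Ω_state = 2π(δ_state − offset) rad/s, nutation at ω₁ = 2π·B1 about the x
axis, transverse relaxation R₂G/R₂E, longitudinal relaxation R₁ (assumed
equal in both states), and exchange k_GE = k_ex·p_E, k_EG = k_ex·(1 − p_E).
The normalized intensity at each saturation offset is
Mz_G(t_sat)/Mz_G(0), starting from the equilibrium longitudinal populations
(1 − p_E, p_E); the propagator is the matrix exponential, evaluated by a
batched eigendecomposition over all offsets (with a per-matrix `expm`
fallback for defective generators).

Assumptions and consequences:

* **Relaxation toward zero.** Profiles are normalized, so no thermal
  recovery term is carried; the far-off-resonance plateau is exactly
  exp(−R₁·t_sat), and Ĩ ≡ 1 at t_sat = 0.
* **One-bond doublet as a two-component average.** The detected terminal
  carbon is split by ¹J_CC (~35 Hz). The profile is the equal-weight mean
  of two independent two-site systems offset by ±J/2 in *both* states
  (state-independent coupling). This reproduces the observed line
  broadening of the saturation dip without a coupled four-state
  Liouvillian; genuine strong-coupling effects between the doublet
  partners are outside the model.
* **B1 inhomogeneity.** The saturation field is averaged over a normal
  distribution with sd = 5% of nominal (configurable) using Gauss–Hermite
  quadrature; 5 nodes reproduce the first two moments exactly and the
  profile average to well below the noise levels considered here.
* **Units.** All internal frequencies are Hz relative to the carrier;
  ppm ↔ Hz conversion uses the spectrometer frequency stored in the
  schedule and happens only at I/O boundaries.

The saturation duration is a required schedule parameter with no universal
default; the synthetic study uses t_sat = 0.5 s and B1 = 25 Hz, appropriate
for aliphatic ¹³C with R₁ of 0.1–0.3 s⁻¹.

## Global fitting

χ² = Σ (Ĩ_obs − Ĩ_calc)²/σ² is summed over all offsets, field strengths and
spins; k_ex and p_E are shared, each spin contributes (ϖ_G, ϖ_E, R₁, R₂G,
R₂E); ¹J_CC is held fixed at its known value. `share_r2` constrains
R₂G = R₂E for spins whose data cannot determine the excited-state width.
Minimization uses trust-region least squares (via lmfit) with box
constraints: p_E ∈ [0, 0.5), rates ≥ 0.

The χ² surface is multimodal in several directions, which the fit treats
explicitly:

1. **ϖ_E multi-start.** Starting values for the excited-state shift come
   from an 11-point grid over the offset window plus a data-driven guess
   (the deepest secondary feature after masking the main dip); starts are
   screened by initial χ² and the best few refined briefly.
2. **(k_ex, p_E) basin restarts.** Distinct local minima trade k_ex
   against R₂E (including boundary solutions with R₂E pinned at zero).
   A coarse restart grid over k_ex ∈ {30, 100, 300} s⁻¹ ×
   p_E ∈ {0.5, 2, 5}% is run, each node starting from *fresh* data-driven
   per-spin parameters plus the learned ϖ_E — re-using per-spin parameters
   already adapted to a wrong (k_ex, p_E) reliably traps the refit.
3. **Fine shift scans.** χ² is rugged on a 1–3 Hz scale in ϖ_G and ϖ_E:
   points on the steep edges of a saturation dip move by several σ when
   the dip slides one Hz, so gradient steps stall in side minima. After
   polishing, each state shift is stepped over a ±8 Hz window with all
   other parameters re-optimized; any improvement is re-polished and the
   sweep repeats (at most 3 rounds) until stable.

Per-parameter uncertainties come from the covariance matrix at the
optimum. The joint uncertainty of (k_ex, p_E) can be mapped by
`grid_search_uncertainty`, which fixes the pair at each grid node and
re-optimizes everything else; the joint 1σ region is Δχ² ≤ 2.30
(two-parameter), and 1-D profile intervals use Δχ² ≤ 1. The p_E ceiling of
0.4999 keeps the minor state identifiable; a fit whose exchange
contribution is indistinguishable from zero is flagged
`omega_e_unidentifiable`.

## Couplings and rotamers

The cross/diagonal ratio I_c/I_d = tan²(2πJT_J) is inverted on the branch
2πJT_J ∈ [0, π/2); passive couplings cancel in the ratio. Uncertainties
are propagated by redrawing both peak heights from Gaussians of width
equal to the spectral noise (default 1000 draws, seeded); perturbed
negative ratios are truncated at zero, and a cross peak negative beyond
the noise is reported as J consistent with zero and flagged. Peak heights,
not volumes, are the inputs.

Rotamer populations solve δ_obs,a = Σ_r p_r·δ_ref,a,r on the probability
simplex by exact active-set enumeration (7 facets of the 3-simplex) with a
1e-10 relative ridge that selects the minimum-norm solution when the
system is under-determined (e.g. one observed shift); such results carry
an `underdetermined` flag. Karplus coefficients and pure-rotamer reference
shifts are configuration data: the shipped `PLACEHOLDER_KARPLUS` set has a
realistic magnitude (~4 Hz at trans, ~1 Hz at gauche) but is synthetic —
quantitative work must supply literature-calibrated values per residue
type.

## IPAP processing

With IP = L(c−J/2) + L(c+J/2) (half-area components) and
AP = L(c−J/2) − L(c+J/2), the combination
½[(IP + s·AP) shifted by +J/2 + (IP − s·AP) shifted by −J/2] yields a
single line at the doublet centre with the IP area. The low-field
component is shifted up and the high-field component down (the opposite
convention also collapses the doublet; the choice is recorded in the
output metadata). Shifts that are an integer number of grid points use a
circular bin roll (exact, area-conserving); off-grid J/2 falls back to a
Fourier-interpolated shift and is flagged. The scale s defaults to 1.

## Synthetic data

Generators draw all randomness from one `numpy.random.default_rng(seed)`
per call and return a serializable `TruthRecord`; regeneration with the
same seed is bit-identical. The CEST generator adds i.i.d. Gaussian noise
to forward-simulated profiles and sets the σ column to the generating
noise; it emulates offset-sampled steady experiments only — systematic
effects of real data (baseline distortions, correlated FuDA-style
intensity errors, pulse imperfections, partial ²H decoupling) are not
modelled, so passing recovery tests demonstrates correctness of the
estimator under the stated noise model, not robustness to such artefacts.
Schedule presets: 50 offsets over ±600 Hz (valine) and 42 offsets over
±300 Hz (arginine/threonine).

The reference exchange study (`exchange_study_conditions`) uses three
valine-like spins with k_ex = 128 s⁻¹, p_E = 1.15%, R₁ ∈ {0.15, 0.20,
0.24} s⁻¹, R₂G ∈ {4, 6, 8} s⁻¹, R₂E ∈ {6, 8, 10} s⁻¹, ¹J_CC = 35 Hz and
state shifts inside the offset window, at noise sd 0.005 — conditions
under which a single-field experiment recovers both global parameters
within their quoted uncertainties.

## Numerical notes and limitations

* Propagation accuracy is validated against adaptive high-order ODE
  integration (DOP853 at rtol 1e-12) to ≤ 1e-8 relative.
* Monotonicity of the dip minimum in B1 and t_sat holds in the
  incoherent-saturation regime (R₂ above the nutation frequency); with
  slowly relaxing spins and short saturation, transient Rabi oscillations
  can transiently raise the minimum — a property of the physics, not of
  the implementation.
* Unit-area closure of a truncated Lorentzian is limited by its heavy
  tails: the missing mass is ≈ (2/π)·(HWHM/edge), so 1e-3 closure needs an
  axis extending to roughly 600 half-widths.
* Test fits run single-spin problems with the B1-inhomogeneity average
  disabled and trimmed restart grids; the reference study fit runs the
  full pipeline on three spins.
* Only two exchange sites are modelled; anisotropic or cross-correlated
  relaxation, explicit ²H decoupling dynamics and >2-state models are out
  of scope. Model selection (2- vs 3-state) and Bayesian posterior
  sampling are not provided.
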