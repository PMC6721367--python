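# Methods

## Scope and model

`tnirsim` models continuous-wave red/NIR light delivered at the scalp and
the tissue heating it causes, on a simplified layered head. Three coupled
pieces:

1. **Photon transport** in the diffusion (P1) approximation of radiative
   transfer. Valid where scattering dominates absorption (μₛ′ ≫ μₐ), which
   holds for all four tissues at 630–810 nm with the packaged parameters
   (the least diffusive layer, CSF, still has μₛ′/μₐ ≈ 100). Radiance is
   reduced to the isotropic fluence rate φ plus a small flux −D∇φ; the
   time-derivative term is dropped (steady state).
2. **Bioheat transfer** (Pennes): conduction, a blood-perfusion sink
   ρ_b ω_b c_b (T_a − T) that pulls tissue toward arterial temperature, a
   metabolic source, and the optical heat source Q_r = μₐφ. Steady solves by
   default; an implicit-Euler transient integrator is available and shares
   the steady solution as its fixed point.
3. **Chromophore composition**: brain μₐ is the sum of per-chromophore
   contributions. The generic product rules (volume fraction × pure-substance
   μₐ for water; dry-mass fraction × density × specific absorbance for lipid;
   blood volume fraction with an SO₂ split for hemoglobin; mM × per-mM μₐ for
   the CCO redox states) are exposed for user-supplied spectra, while the
   packaged tables carry the already-composed tissue-level contributions,
   which fully determine every downstream computation.

## Phantom

The anatomy is emulated, not segmented: a structured grid labeled
scalp+skull → CSF → gray matter → white matter with depth z from the surface.
Default thicknesses 13 / 7 / 4 mm (white matter fills the remainder) put the
gray-matter interface at 20 mm — a deliberate, configurable assumption; no
canonical thicknesses exist for the source geometry being emulated. Grid
kinds: `slab_1d` (planar source, per-m² normalization), `axisymmetric_2d`
(cylindrical r–z; the default — exact for a source on the axis of a layered
half-space at a fraction of the 3-D cost), `voxel_3d` (used by the Monte
Carlo transport). Default domain: 50 mm radius × 60 mm depth at 0.5 mm
spacing (12 000 cells), chosen so that boundaries are several attenuation
lengths from the source.

What the phantom does **not** capture about real heads: surface curvature,
sulci/gyri (real gray matter is a folded shell, not a plane), anatomical
thickness variation, and any refractive-index mismatch at the surface or
between layers. Conclusions that depend on lateral anatomy or on specular /
diffuse surface reflection are outside what passing tests demonstrate.

## Parameters

All values are packaged as checksummed CSVs in SI units and loaded verbatim;
per-tissue μₐ, μₛ′ at 630/700/810 nm, anisotropy g = 0.89 everywhere,
thermal conductivity / density / metabolic heat, and perfusion parameters
(blood: ρ_b = 1050 kg/m³, c_b = 3600 J/kg·K, T_a = 37 °C).

Documented deviations from the printed tables (all config-overridable):

- **Impossible densities.** CSF 0 kg/m³ and brain 0.08 kg/m³ are physically
  impossible (presumed typos); defaults substitute 1007 and 1040 kg/m³.
  Steady solutions are independent of ρ and c, so this affects transients
  only. A `strict_thermal` mode keeps the printed values (with a warning)
  and refuses transient solves.
- **Missing specific heats**: scalp 3391, skull 1313, CSF 4096, brain
  3630 J/kg·°C (standard literature values).
- **Blood specific heat**: the perfusion table's 3600 J/kg·K is the default;
  the alternative 3664 is selectable.
- **Merged outer layer.** The phantom's single scalp+skull layer uses
  thickness-weighted means (scalp 6 mm / skull 7 mm) of the separate scalp
  and skull entries.
- **Brain perfusion** ω_b = 0.08 1/s is used as tabulated although it is
  ~10× typical literature values; it is what produces the 37.03–37.04 °C
  brain equilibrium (37 + 10437/(1050·0.08·3600) = 37.0345 °C).
- **White-matter water**: the tabulated 1.45 1/m at 810 nm is inconsistent
  with a uniform 0.75 water volume fraction (it implies ≈ 0.66); the printed
  value is stored, the inference is only documented.
- Refractive index is untabulated; n = 1.37 everywhere. Since reflection is
  not modeled, the boundary coefficient is A = 1 and n never enters the
  steady solution.

## Numerics

**Discretization.** Cell-centered finite volumes; harmonic-mean face
conductances; the operator is a symmetric M-matrix, so the discrete maximum
principle holds and fluence/temperature fields are non-negative without
clipping. Direct sparse LU up to 4×10⁵ unknowns, Jacobi-preconditioned CG
above; relative residuals are checked against 1e-8 and a convergence error
is raised otherwise.

**Boundaries.** Photon: partial-current Robin closure on every exterior
face, discretized as an escape conductance A·2D/(h+4D); on the axisymmetric
axis the face area vanishes (natural symmetry). Thermal: series conductance
of convection (h = 4 W/m²·°C, ambient 25 °C) and the half-cell conduction
path at the scalp surface; all other thermal boundaries are insulated
(symmetry / far field).

**Source.** "Irradiance × aperture" defines the injected power (500 mW/cm²
× 1 cm² = 0.5 W default). A point source is regularized as an isotropic
source 1/μₛ′ below the entry point and apportioned linearly between the two
nearest cell planes — without the apportioning, the injection depth snaps to
the grid and deep fluence shifts by ~16% between refinements; with it,
h→h/2 changes are below 2% a couple of transport mean free paths from the
source (at interface kinks, comparisons across the μₐ jump are
interpolation-limited). A disc source distributes the same power over the
aperture footprint with exact ring-overlap weights.

**Fraction convention.** Penetration profiles are normalized to the *entry
cell* (the surface cell above the source). Cells between the surface and the
buried source can therefore exceed 1; below the source the profile is in
(0, 1] and decays monotonically.

**Interface sampling.** "Gray-matter rise at the CSF interface" is read at
the first gray-matter cell center below the interface; interpolating across
the μₐ jump would mix in the CSF-side value.

**Energy accounting.** ∫μₐφ dV plus the summed boundary escape equals the
injected power to machine precision by construction (the FV scheme is
conservative); the acceptance checks assert 1%.

**Transients.** Implicit Euler (unconditionally stable), one LU
factorization reused across steps; the steady solution is an exact fixed
point for any Δt, so long marches converge to it regardless of step size.

## Monte Carlo oracle

Weighted photons on voxel grids: free paths sampled from μ_t = μₐ + μₛ with
μₛ = μₛ′/(1−g); at each collision a μₐ/μ_t weight fraction is deposited and
the direction is redrawn from Henyey–Greenstein (empirical mean cosine
matches g to ±0.005 at 10⁶ samples); Russian roulette below weight 1e-4 with
survival 0.1 (conventional choices); fluence by the track-length estimator.
The kernel is numba-compiled with an explicitly seeded generator — identical
seeds reproduce results bit-for-bit. Launch modes: collimated at the surface
(physical counterpart of the regularized diffusion source) and isotropic at
an interior point (for infinite-medium validation). Escaping weight is
tallied as reflected (z = 0 face) or transmitted; absorbed + reflected +
transmitted = 1 within the roulette tolerance (1e-3).

Agreement: in homogeneous gray matter the diffusion solution matches the
infinite-medium Green's function P e^(−μ_eff r)/(4πDr) within 2% between one
transport mean free path and 10/μ_eff (at 0.2 mm spacing), and matches
shell-averaged Monte Carlo within 10% (measured ≈ 4%) over 1–5 transport
mean free paths at 10⁶ photons. In the layered head the per-layer
median discrepancy is a few per cent in scalp/skull, CSF and gray matter.
Two nuances worth stating plainly: (i) with the tabulated CSF μₛ′ =
250 1/m the CSF layer is *not* a near-void, and its diffusion error is
statistically indistinguishable from gray matter's rather than clearly
larger; (ii) the deep white matter shows the largest discrepancy (~10–25%,
diffusion low), the known far-from-source weakness of the P1 closure.

## Design choices in open territory

- **Attenuation ranking** probes the fluence remaining at the gray-matter
  interface; ties break by tabulated gray-matter μₐ, then name. Because the
  diffusion equation is elliptic, absorption *below* the probe depth
  feeds back on it: chromophore pairs whose gray-matter coefficients are
  within a few per cent can order by their white-matter contributions
  instead (at 810 nm, deoxyhemoglobin — GM 15.48, WM 12.72 1/m — ranks above
  oxidized CCO — GM 16.2, WM 1.1). At 630 and 700 nm the ranking coincides
  with the gray-matter μₐ sort.
- **Rise ordering across wavelengths.** The gray-matter *peak* rise in the
  full coupled run is dominated by heat conducted down from the scalp (which
  absorbs most at 630 nm), not by local absorption; only the volume-mean
  gray-matter rise under gray-matter-restricted heating is proportional to
  the power deposited there (810 > 700 > 630).
- **Baseline for "rise"**: the no-source steady state, not a flat 37 °C —
  convective cooling depresses superficial layers by ~1 °C even without
  light, and subtracting the baseline is the only self-consistent reading.

## Problem sizes

Default runs use the 100×120-cell axisymmetric phantom (seconds per coupled
solve); the Green's-function validation uses a 0.2 mm grid (~7×10⁴ cells);
Monte Carlo checks use 10⁵–10⁶ photons on 0.5–1 mm voxel grids (tens of
seconds, numba-compiled). These sizes were chosen as the point where the
reported quantities are grid-converged (see the refinement tests), not as a
fidelity ceiling; all extents, spacings and photon counts are parameters.

## Known limitations

- The computed **superficial heating for a genuine 0.5 W injection is
  ~5–6 °C at the sub-surface peak** — an order of magnitude above sub-0.25 °C
  figures sometimes quoted for the same nominal dose. The discrepancy is not
  numerical: ~0.33 of the injected power is absorbed, most of it within
  ~5 mm of the source, and Q/(4πKr) alone gives several °C there; Monte
  Carlo confirms the absorbed fraction. Quoted sub-0.25 °C values are only
  reachable if the effectively injected power is tens of times smaller than
  irradiance × 1 cm². Since the Pennes equation is linear in Q_r, all ΔT
  results rescale exactly with source power.
- Gray-matter volume averages depend mildly on domain extents (the heated
  axis column weighs more in smaller domains): 37.026 °C on the default
  phantom, 37.03–37.04 °C across reasonable choices.
- No melanin/lipofuscin skin chromophores, no radiative surface loss, no
  thermoregulatory feedback, no time-resolved optics, no polarization or
  internal refractive mismatch.
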