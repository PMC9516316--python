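# Methods

`nanodef` is a desk-scale Monte-Carlo model of physical dose enhancement by
100 nm gold (Au) and magnetite-core/gold-shell (Fe₃O₄@Au) nanoparticles in
water under keV photon irradiation. This note records the physics model, its
parameters and defaults, the approximations, and the design choices made
where the design was genuinely open.

## Study geometries

* **Single nanoparticle.** A layered sphere at the origin: solid gold
  (r = 50 nm, ρ = 19.32 g/cm³), core-shell (Fe₃O₄ core r = 30 nm,
  ρ = 5.18 g/cm³; gold shell to r = 50 nm), or an all-water null particle
  (WNP) used as the DEF baseline. Dose is scored in concentric water shells
  measured from the particle surface: 1 nm steps on [0, 150] nm, 10 nm on
  (150, 1950] nm, 100 nm on (1950, 9950] nm (410 shells). The scoring world
  is a 20 µm diameter water sphere; the phase-space (step 1) world is a
  200 nm water cube.
* **Cell.** A 10 µm diameter water cell with a concentric 5 µm nucleus,
  inside a 20 µm water sphere. Nanoparticles are placed uniformly at random
  in the cytoplasm (non-overlapping, rejection sampling). Mass concentration
  converts to an integer particle count against the whole-cell sphere volume
  (5.236e-10 mL); with ρ(Au) = 19.32 and ρ(Fe₃O₄) = 5.18 g/cm³ this
  reproduces the published count table exactly (307/615/3074 core-shell and
  259/518/2588 gold at 5/10/50 mg/mL). Magnetic targeting is modelled as a
  concentration multiplier of 1.48 (74 mg/mL for the targeted arm).
* **Beams.** Plane-parallel photon beams along +z starting at the proximal
  surface; beam diameter equals the particle diameter (100 nm) or the cell
  diameter (10 µm), doubled (200 nm / 20 µm) in the magnetic-field study.
  Sources are monoenergetic (50–250 keV) or histogram spectra; the
  brachytherapy arm uses a synthetic Ir-192-like spectrum (below).

## Photon physics (1–900 keV)

Two interaction channels are modelled:

* **Photoelectric absorption.** Per-element mass attenuation tables (H, O,
  Fe, Au) are embedded as packaged CSV data, generated once by
  `scripts/make_physics_tables.py` from hand-curated anchor values consistent
  with the standard compilations (≈10% accuracy); log-log interpolation with
  duplicated nodes preserves the Fe K (7.112 keV), Au L (11.919 keV
  effective) and Au K (80.725 keV) edges. Gold's M subshells are folded into
  a monotone envelope below the L edge, and the three L subshells are merged
  into one effective L level — matching the single-generation relaxation
  model. The absorbing element is sampled by mass-fraction-weighted
  coefficients; the deepest accessible shell is ionized; the photoelectron
  carries E − binding with an isotropic direction (forward peaking is modest
  below 250 keV and cancels in DEF ratios).
* **Compton scattering** per free electron: analytic Klein–Nishina total
  cross section scaled by electron density, sampled by rejection on the
  scattered-energy distribution; the electron direction follows from exact
  momentum balance. The incoherent scattering function is omitted (<5%
  error above ~20 keV). Rayleigh scattering is omitted entirely (no energy
  deposition; negligible angular diffusion at the scored scales).

**Atomic relaxation** is a single-generation cascade with effective shell
energies: a K vacancy fluoresces (K−L photon, the Kα proxy) with probability
ω_K (Au 0.96, Fe 0.34) or emits a KLL Auger electron (K − 2L); the resulting
L vacancies relax one generation further (L−M photon, ω_L(Au) = 0.34, or LMM
Auger, 7.5 keV in gold); remaining binding energy deposits locally. Energy is
conserved exactly per vacancy. With the de-excitation toggle off the whole
binding energy deposits at the interaction site.

## Electron transport

Condensed-history transport with continuous slowing down:

* **Stopping power** is the analytic Bethe collision formula per material
  (Møller close collisions included, density effect neglected below 1 MeV),
  with mean excitation energies I = 75 eV (water), 790 eV (Au) and a
  Bragg-additivity value for Fe₃O₄. It matches the standard liquid-water
  tabulation to <1% above a few keV (22.56 MeV cm²/g at 10 keV). Below its
  validity floor (≈1 keV for gold) the curve is extrapolated as a rising
  power law; transported electrons never reach that region. CSDA ranges are
  the numerical integral of 1/S from 0.1 keV; range and energy lookups are
  mutual inverses on a shared 600-node log grid. Inverting the water range
  at 9.95 µm gives 21.7 keV.
* **Substeps** are bounded by 5% of the residual range, the distance to the
  next region boundary (layer spheres, scoring surface, world), the local
  scoring-shell width, and 5 nm inside nanoparticle layers. Energy loss per
  substep comes from the range tables; deposits are scored at substep
  midpoints. The tracking cutoff is 1 keV (configurable down to 100 eV);
  sub-cutoff energy deposits locally. The first nanometres of the profile
  are therefore lower-fidelity than the rest.
* **Multiple scattering**: one Gaussian polar kick per substep with the
  Highland width in its pure √(x/X₀) form. The thick-step logarithmic
  correction is deliberately dropped: at nanometre substeps it is far
  outside its validity and would make the accumulated angular diffusion
  depend on the substep size.
* **Magnetic deflection**: a uniform field (default perpendicular to the
  beam) rotates the perpendicular velocity component each substep by
  s/r_g with the relativistic gyroradius r_g = p/(qB) (0.772 mm for 50 keV
  electrons at 1 T — four orders of magnitude above the geometry, hence the
  expected null effect). The field does no work, so contained deposits are
  exactly field-independent.
* No bremsstrahlung (radiative yield <1% below 900 keV in these materials)
  and no electron-impact ionization cascades.

## Variance reduction

The natural interaction probability per photon is ~1e-3 (single particle)
to ~5e-4 (cell), so DEF pipelines force exactly one interaction per primary:
the interaction point is sampled from the truncated exponential along the
ray (piecewise by region), and all products carry the weight
1 − exp(−τ_total). For the two-step and one-step single-particle methods the
forcing is restricted to the particle chord: the compared quantity is the
dose produced by the particle's own interactions, and the WNP baseline gets
usable statistics the same way. Forcing is unbiased (tested against analog
sampling) and is off by default at the transport-engine level. Scattered and
fluorescence photons are transported analogue.

## The two methods and their residual difference

* **Two-step**: photons on the particle in the 200 nm box; electrons
  crossing the particle surface outward are recorded once each (first
  crossing — the standard phase-space source convention) and replayed from
  the centre of the 20 µm water sphere with fine shell scoring.
* **One-step**: the same geometry simulated in place, with the layered
  particle present during electron transport.

The integrated DEFs of the two methods agree to better than 0.1%; shell
doses agree within ~6% everywhere beyond 10 nm. The residual shape
difference (one-step a few % high within ~25 nm of the surface and a few %
low at 0.25–1 µm) is real in this model: electrons that return to the
particle meet gold in the one-step and water in the replay — the same
physics-boundary mechanism that produces the large sub-10-nm discrepancy
reported for track-structure toolkits.

## Approximations specific to the cell model

Outside its birth particle an electron sees water only: with ≤0.5% particle
volume fraction even at 74 mg/mL, crossing another particle is a sub-percent
perturbation. The intra-birth-particle leg is transported exactly in the
layered sphere. Scattered/fluorescence photons likewise ignore the particle
ensemble. Region doses are energy over the water mass of cytoplasm or
nucleus (particle-internal deposits are tallied separately and excluded);
the baseline arm is the identical zero-particle cell run with the same seed
stream.

## Synthetic sources

The Ir-192-like spectrum combines the principal gamma lines (206–885 keV
with published relative intensities) broadened into histogram bins with a
low-energy scattered continuum (default 30% of the probability mass, a
gamma-shaped hump below 300 keV) emulating transmission through ~2 cm of
water and the source encapsulation. It is a qualitative stand-in — the
reference spectrum is not tabulated anywhere — so brachytherapy-arm results
characterize the method, not a specific source model. Any user histogram
CSV is accepted. Toy phase spaces (isotropic outward monoenergetic
electrons) support testing the replay stage against an analytic point-source
CSDA kernel (agreement within 10% beyond 100 nm).

## Uncertainties and statistics

All tallies use the history-by-history estimator; DEFs propagate numerator
and denominator errors to first order (arms are independent unless a
baseline explicitly shares the seed stream, in which case the propagation is
conservative). Standard errors follow the 1/√N law (tested). Default
history counts are 1e6 (single particle) and 2e5 (cell), resolving
integrated DEFs to ~1–2%; the test-suite fixtures use a few thousand forced
histories, which keeps the suite in minutes at the cost of 1–5% statistical
resolution, and the acceptance script states its own sizes per quantity.

## Known limitations

* Photoelectric anchors are ~10% accurate; absolute single-particle DEFs
  inherit that scale error, ratios largely cancel it.
* The single-L/effective-M relaxation model coarsens the Auger spectrum;
  only its coarse structure (photopeaks, ≤14 keV Auger band) is meaningful.
* Condensed-history transport with Gaussian kicks is not reliable below
  ~10 nm from a metal surface or below ~1 keV.
* At equal mass concentration the cell-model DEFs of the two particle types
  are statistically tied here: the core-shell's ~7% lower gold content is
  offset by its higher particle count and weaker electron self-absorption.
  Orderings between them are therefore reported with uncertainties, not as
  strict inequalities.
* The single-particle integrated DEF decreases monotonically over
  50–250 keV in this model (the water-baseline denominator rises steeply
  from 50 to 100 keV); the cell-scale finding that 50–100 keV beams enhance
  more than 150–250 keV is reproduced.
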