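"""Physical constants and material data used throughout the package.

Densities of gold and magnetite are the bulk values that, together with a
whole-cell reference volume, reproduce the published nanoparticle counts per
concentration exactly; water is unit density.  Energies are in keV, lengths
in nm unless a function says otherwise.
"""

ELECTRON_REST_KEV = 511.0  # electron rest energy m_e c^2
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23
KEV_TO_JOULE = 1.602176634e-16
SPEED_OF_LIGHT_M_S = 2.99792458e8

# densities, g/cm^3
DENSITY_WATER = 1.00
DENSITY_GOLD = 19.32
DENSITY_MAGNETITE = 5.18

# mass fractions
WATER_COMPOSITION = (("H", 0.1119), ("O", 0.8881))
GOLD_COMPOSITION = (("Au", 1.0),)
# Fe3O4 stoichiometric: 3*55.845 / (3*55.845 + 4*15.999)
MAGNETITE_COMPOSITION = (("Fe", 0.7236), ("O", 0.2764))

ATOMIC_NUMBER = {"H": 1, "O": 8, "Fe": 26, "Au": 79}
ATOMIC_WEIGHT = {"H": 1.008, "O": 15.999, "Fe": 55.845, "Au": 196.967}

# mean excitation energies (eV) for the Bethe collision stopping power
MEAN_EXCITATION_EV = {"H": 19.2, "O": 95.0, "Fe": 286.0, "Au": 790.0}
MEAN_EXCITATION_WATER_EV = 75.0  # standard liquid-water value

# geometry defaults (paper study conditions)
NP_RADIUS_NM = 50.0
CORE_RADIUS_NM = 30.0
CELL_RADIUS_UM = 5.0
NUCLEUS_RADIUS_UM = 2.5
SINGLE_NP_WORLD_RADIUS_UM = 10.0   # 20 um diameter scoring sphere
STEP1_BOX_HALF_NM = 100.0          # 200 nm cube around the nanoparticle
MAGNETIC_UPTAKE_FACTOR = 1.48      # targeted concentration multiplier

ENERGY_GRID_MIN_KEV = 1.0
ENERGY_GRID_MAX_KEV = 900.0
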