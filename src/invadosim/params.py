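"""Physical parameters and the internal unit system.

Internal units are nanometres (length), piconewtons (force) and seconds
(time).  Conversion factors from SI:

======================  ==========================  ====================
quantity                SI unit                     internal unit
======================  ==========================  ====================
stiffness (line)        1 N/m                       1e3 pN/nm
stiffness (area)        1 N/m^2                     1e-6 pN/nm^2
pressure / modulus      1 Pa                        1e-6 pN/nm^2
energy                  1 J                         1e21 pN nm
drag coefficient        1 N s/m                     1e3 pN s/nm
======================  ==========================  ====================

All literature values are converted at definition time below, so the rest
of the package never sees SI.  Dashpot (drag) coefficients are effective
cytoplasmic values chosen so the overdamped explicit integration is stable
at time steps of 1e-3 to 1e-2 s; they are configuration parameters and are
recorded in every run log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

# unit conversion helpers
N_PER_M = 1e3          # -> pN/nm
N_PER_M2 = 1e-6        # -> pN/nm^2
PA = 1e-6              # -> pN/nm^2
UM = 1e3               # -> nm

#: thermal energy at 310 K, pN nm
KBT = 4.28


@dataclass
class MembraneParams:
    """Stiffnesses and couplings of the five cell surfaces.

    The invadopodial membrane (CI) carries line and area elasticity; the
    force-transduction layer (CT) line elasticity only; the actin cortex
    layer (CC) line elasticity with the actin-filament modulus; the two
    nuclear surfaces (PAL, NMS) carry the nuclear line and area terms.
    """

    kappa_line_ci: float = 5.0e-5 * N_PER_M      # pN/nm
    kappa_area_ci: float = 1.0e-4 * N_PER_M2     # pN/nm^2, as printed
    kappa_line_nuc: float = 5.0e-3 * N_PER_M
    kappa_area_nuc: float = 1.0e-4 * N_PER_M2
    kappa_line_ct: float = 8.0e-3 * N_PER_M
    # CC line stiffness is per-edge A_A*E_A/L0 (actin modulus), see build.
    kappa_t: float = 8.0e-3 * N_PER_M            # CI<->CT vertical link
    kappa_c: float = 1.0e-2 * N_PER_M            # CT<->CC (and PAL<->NMS)
    link_rest: float = 50.0                      # nm
    # drags, pN s/nm
    c_pair: float = 0.5
    c_ground: float = 1.0
    c_link: float = 0.5


@dataclass
class ActinParams:
    """Branched actin filament mechanics and lifecycle rates."""

    radius: float = 3.5                           # nm
    youngs: float = 1.8e9 * PA                    # pN/nm^2 (1.8 GPa)
    seg_rest_init: float = 150.0                  # nm
    seg_split: float = 300.0                      # nm, subdivide above
    # pointed-end segments are absorbed into their neighbour below this
    # bound so kappa = A E / L0 stays within ~0.7 N/m (explicit stability)
    seg_merge: float = 100.0
    # kappa = A E / L0 diverges for the transient sub-discretization
    # segments of depolymerizing filaments; the dynamics kernels floor
    # L0 at this value (the initial element length) when forming kappa
    seg_kappa_floor: float = 150.0
    v_growth: float = 20.0                        # nm/s, free barbed end
    v_shrink: float = 10.0                        # nm/s, pointed end
    v0: float = 50.0                              # nm/s, zero-load speed
    f0: float = 20.0                              # pN, force scale of v_g law
    f_ratchet: float = 20.0                       # pN, F_p of the ratchet
    f_ratchet_max: float = 100.0                  # pN, clamp
    kappa_arp: float = 0.01 * N_PER_M             # pN/nm
    lambda_arp: float = 30.0                      # nm
    branch_angle0: float = math.radians(70.0)
    # Branch angular/dihedral moduli (pN nm^2); not printed in the source
    # literature with units usable here, chosen so a 10 degree branch
    # misalignment produces a sub-pN restoring force (soft guidance).
    kappa_br_ang: float = 1.0e4
    kappa_br_dihed: float = 1.0e4
    k_nucleate: float = 50.0                      # 1/s, cell-wide
    k_cap: float = 0.3                            # 1/s
    adhesion_gap: float = 100.0                   # nm, cortex contact
    adhesion_rupture: float = 20.0                # pN
    kappa_adhesion: float = 0.001 * N_PER_M       # barbed<->cortex clutch
    buckle_ratio: float = 0.9                     # severing criterion
    # drags, pN s/nm
    c_pair: float = 2.0
    c_arp: float = 1.0
    c_ground: float = 1.0

    @property
    def area(self) -> float:
        """Cross-section pi r^2, nm^2 (38.48 for r = 3.5)."""
        return math.pi * self.radius**2

    @property
    def bend_modulus(self) -> float:
        """E*I with I = pi r^4 / 4, pN nm^2."""
        return self.youngs * math.pi * self.radius**4 / 4.0


@dataclass
class LinkerParams:
    """Crosslinkers (fascin, filamin, alpha-actinin) and bipolar myosin."""

    kappa: float = 0.01 * N_PER_M                 # pN/nm, all species
    rest: dict = field(default_factory=lambda: {
        "fascin": 40.0, "filamin": 150.0, "alpha_actinin": 50.0,
        "myosin": 300.0})
    turnover: float = 60.0                        # s
    v_sliding0: float = 160.0                     # nm/s
    f_stall: float = 1240.0                       # pN (1.24 nN)
    c_m: float = 4.761
    parallel_max_deg: float = 20.0
    ortho_band_deg: tuple = (70.0, 110.0)
    cone_deg: float = 60.0                        # leading-edge cone
    distance_slack: float = 0.5                   # rest +/- 50 % gate
    p_bind: float = 0.1                           # per eligible pair / 1 s


@dataclass
class AdhesionParams:
    """Integrin-collagen focal complexes with slip-bond kinetics."""

    kappa_lr: float = 1.0                         # pN/nm
    lam: float = 30.0                             # nm, bond rest length
    l_bind: float = 30.0                          # nm, capture radius
    k_on0: float = 1.0                            # 1/(molecule s)
    k_off0: float = 0.05                          # 1/s
    f_intrinsic: float = 200.0                    # pN, kT/x_b
    n_tot: int = 50

    @property
    def x_b(self) -> float:
        return KBT / self.f_intrinsic             # nm


@dataclass
class EcmParams:
    """Discrete collagen fiber network."""

    fiber_diameter: float = 41.0                  # nm
    # Collagen fibril Young's modulus, pN/nm^2.  Calibrated once so the
    # simulated volumetric stretch test of the default network (pore 3 um)
    # reports a bulk modulus of ~2.6 kPa; see scripts/calibrate_ecm.py.
    youngs: float = 269.7
    seg_length: float = 500.0                     # nm discretization
    weld_radius: float = 750.0                    # nm junction capture
    pore_size: float = 3.0 * UM                   # nm
    box: tuple = (45.0 * UM, 30.0 * UM, 20.0 * UM)
    kappa_exclusion: float = 0.01 * N_PER_M       # pN/nm penalty
    degrade_threshold: float = 0.2                # fraction of initial phi6
    c_pair: float = 2.0
    c_ground: float = 1.0

    @property
    def radius(self) -> float:
        return self.fiber_diameter / 2.0

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    @property
    def bend_modulus(self) -> float:
        return self.youngs * math.pi * self.radius**4 / 4.0


@dataclass
class RdParams:
    """Six-species MMP reaction-diffusion system (dimensionless conc.).

    phi1 MMP-2, phi2 TIMP-2, phi3 MT1-MMP, phi4 ternary complex,
    phi5 ligand (collagen molecules), phi6 ECM.  Rate constants are
    normalized magnitudes chosen for explicit stability (k*phi*dt << 1)
    and so that sustained tip secretion degrades phi6 below the fiber
    removal threshold within one protrusive phase.
    """

    h: float = 500.0                              # nm grid spacing
    # MMP-2 diffuses slowly through the dense matrix (binding-retarded);
    # TIMP-2 and free ligand move faster
    d_phi1: float = 0.5e6                         # nm^2/s (0.5 um^2/s)
    d_phi2: float = 2.0e6
    d_phi5: float = 5.0e6
    # The ternary-complex equation as printed carries a +k_on34 phi3 phi4
    # term (autocatalytic); the defaults keep k_on34 phi3 well below
    # k_off4 at the secretion steady state phi3 ~ alpha/k_decay3 so the
    # system stays stable over many phase cycles.
    k_on_12: float = 0.2
    k_on_23: float = 0.5
    k_on_34: float = 0.002
    k_off_4: float = 0.3
    k_decay_1: float = 0.3
    k_decay_3: float = 1.0
    k_decay_5: float = 0.05
    k_deg_6: float = 4.0
    alpha_phi2: float = 1.0                       # tip source rates, 1/s
    alpha_phi3: float = 5.0
    tip_cap_fraction: float = 0.05
    ligand_feedback: bool = False                 # alpha * phi5 if True


@dataclass
class IntegratorParams:
    """Adaptive explicit stepping of the damped equations of motion."""

    dt_init: float = 5.0e-3                       # s
    dt_max: float = 2.0e-2
    dt_min: float = 1.0e-6
    tol: float = 1.0e-4    # error per step relative to length_ref
    length_ref: float = 2000.0                    # nm (cell radius scale)
    control_interval: float = 1.0                 # s (binding, KD-trees)
    grow_factor: float = 1.5


@dataclass
class Params:
    """Bundle of all sub-module parameter groups."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    actin: ActinParams = field(default_factory=ActinParams)
    linker: LinkerParams = field(default_factory=LinkerParams)
    adhesion: AdhesionParams = field(default_factory=AdhesionParams)
    ecm: EcmParams = field(default_factory=EcmParams)
    rd: RdParams = field(default_factory=RdParams)
    integrator: IntegratorParams = field(default_factory=IntegratorParams)

    def to_dict(self) -> dict:
        return asdict(self)
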