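"""Model parameters and unit conventions.

The simulation works in non-dimensional model units in which the preferred
cell cross-sectional area is 1 and the area stiffness is 1.  The anchor to
physical units is the typical cross-sectional area of a cultured MDCK cell,
~100 um^2, so one model length unit corresponds to 10 um.  Adhesion and
cortical strengths map linearly between the two unit systems; the reference
cell-substrate adhesion of 20 N/m corresponds to 0.1 in model units, i.e.
1 model strength unit = 200 N/m for the spring-type strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

#: micrometres per model length unit (area anchor: 100 um^2 <-> 1 unit^2)
UM_PER_LENGTH_UNIT = 10.0
#: N/m per model unit for linear-spring strengths (20 N/m <-> 0.1)
NEWTON_PER_M_PER_STRENGTH_UNIT = 200.0

SPREADING_MODES = ("constant", "linear", "nonlinear")


@dataclass
class ModelParams:
    """All mechanical and integration constants, in non-dimensional units.

    Defaults are the standard non-dimensionalized parameter set for MDCK-like
    cells (preferred area 1, cell-substrate adhesion 0.1 == 20 N/m,
    cell-cell adhesion 0.001 == 0.2 N/m).
    """

    A0: float = 1.0                    # preferred cross-sectional area
    k_A: float = 1.0                   # 2D area stiffness
    k_L: float = 0.0005                # cortical (perimeter) stiffness
    gamma_cc: float = 0.001            # cell-cell adhesion strength
    R_cc: float = 0.05                 # cell-cell repulsion strength
    gamma_cs: float = 0.1              # cell-substrate adhesion strength
    d_cc: float = 0.16                 # cell-cell interaction distance
    d_cs: float = 0.1                  # cell-substrate interaction distance
    l_cc: float = 0.005                # cell-cell adhesion rest length
    l_cs: float = 0.005                # cell-substrate adhesion rest length
    C_s: float = 0.008                 # active spreading strength
    C_G: float = 0.001                 # gravity strength
    beta: float = 1.0                  # viscous drag coefficient
    dt: float = 1.0                    # explicit Euler timestep
    steps_per_hour: float = 750.0      # time calibration (steps per culture hour)
    spreading_mode: str = "constant"   # constant | linear | nonlinear
    gamma_cs_ref: float = 0.1          # reference adhesion gamma_cs,0 for scaling
    spreading_exponent: float = 0.2    # power of the nonlinear scaling
    activation_fraction: float = 0.10  # substrate-contact fraction activating spreading
    feedback_cc_per_bond: float = 0.03  # gamma_cc -> gamma_cc * (1 + 0.03 * N_sub)
    feedback_cs_factor: float = 1.5     # gamma_cs -> 1.5 * gamma_cs on cell-cell contact
    feedback_dcc_factor: float = 1.2    # d_cc -> 1.2 * d_cc on cell-cell contact
    cc_threshold: float = 0.10          # cell-cell connection fraction for Intermediate

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = ("A0", "k_A", "k_L", "gamma_cc", "R_cc", "gamma_cs", "d_cc",
                  "d_cs", "l_cc", "l_cs", "C_s", "C_G", "gamma_cs_ref")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if not self.d_cc > self.l_cc:
            raise ValueError("d_cc must exceed l_cc")
        if not self.d_cs > self.l_cs:
            raise ValueError("d_cs must exceed l_cs")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.spreading_mode not in SPREADING_MODES:
            raise ValueError(
                f"spreading_mode must be one of {SPREADING_MODES}, "
                f"got {self.spreading_mode!r}")

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields overridden."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def length_to_um(x: float) -> float:
    """Convert a model length to micrometres."""
    return x * UM_PER_LENGTH_UNIT


def area_to_um2(a: float) -> float:
    """Convert a model area to square micrometres."""
    return a * UM_PER_LENGTH_UNIT ** 2


def strength_to_N_per_m(g: float) -> float:
    """Convert a spring-type strength (gamma, k_L) to N/m."""
    return g * NEWTON_PER_M_PER_STRENGTH_UNIT


def strength_from_N_per_m(g: float) -> float:
    """Convert a spring-type strength from N/m to model units."""
    return g / NEWTON_PER_M_PER_STRENGTH_UNIT
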