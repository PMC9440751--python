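"""Weight-normalized thrust model for flapping climbing flight.

The core scaling relation expresses the aerodynamic thrust produced over a
wingbeat, normalized by body weight::

    T/mg = 1/2 * rho * U_wing^2 * (S/mg) * C_Talpha * alpha

i.e. thrust grows quadratically with the speed of the beating wing and
linearly with air density, the weight-normalized wing area S/mg (the inverse
of wing loading), the wing angle of attack (radians) and the angle-of-attack-
specific thrust coefficient.  The 1/2 dynamic-pressure factor and the linear
thrust coefficient C_T = C_Talpha * alpha are the conventional blade-element
small-angle forms; C_Talpha defaults to 1 per radian and is configurable.

The climb-angle side of the model is the "helicopter" control hypothesis:
the aerodynamic force is fixed in the body frame, so the animal steers it by
pitching the body, and the climb angle should track body pitch linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats as _stats

__all__ = [
    "MorphologyRecord",
    "ThrustModelParams",
    "weight_normalized_wing_area",
    "thrust_ratio",
    "steady_climb_balance",
    "helicopter_prediction",
]

CM2_TO_M2 = 1e-4
STANDARD_GRAVITY = 9.81  # m s^-2


@dataclass(frozen=True)
class ThrustModelParams:
    """Physical constants of the thrust model.

    rho defaults to 1.17 kg m^-3 (warm air at ~450 m elevation, matching
    lowland tropical field conditions); C_Talpha to 1 per radian since its
    value for butterfly wings is not established.
    """

    rho: float = 1.17  # kg m^-3
    c_t_alpha: float = 1.0  # per rad
    g: float = STANDARD_GRAVITY  # m s^-2

    def __post_init__(self):
        if self.rho <= 0 or self.g <= 0:
            raise ValueError("air density and gravity must be positive")


@dataclass
class MorphologyRecord:
    """Per-individual morphology with derived aerodynamic ratios.

    Input units follow field practice (mass in grams, total wing area of
    both wing pairs in cm^2); derived quantities are SI.
    """

    mass_g: float
    wing_area_cm2: float
    individual: str = ""
    species: str = ""
    microhabitat: str = ""
    g: float = STANDARD_GRAVITY

    def __post_init__(self):
        if self.mass_g <= 0:
            raise ValueError("body mass must be positive")
        if self.wing_area_cm2 <= 0:
            raise ValueError("wing area must be positive")

    @property
    def weight_n(self) -> float:
        """Body weight m*g in newtons."""
        return self.mass_g * 1e-3 * self.g

    @property
    def s_over_mg(self) -> float:
        """Weight-normalized wing area, m^2 N^-1."""
        return self.wing_area_cm2 * CM2_TO_M2 / self.weight_n

    @property
    def wing_loading(self) -> float:
        """Wing loading mg/S in N m^-2 (reciprocal of ``s_over_mg``)."""
        return 1.0 / self.s_over_mg


def weight_normalized_wing_area(
    wing_area_cm2: float, mass_g: float, g: float = STANDARD_GRAVITY
) -> tuple[float, float]:
    """S/mg in m^2 N^-1 and wing loading mg/S in N m^-2.

    Converts the field units (cm^2, g) to SI before taking the ratio.
    """
    if wing_area_cm2 <= 0 or mass_g <= 0 or g <= 0:
        raise ValueError("wing area, mass and g must all be positive")
    s_m2 = wing_area_cm2 * CM2_TO_M2
    weight = mass_g * 1e-3 * g
    s_over_mg = s_m2 / weight
    return s_over_mg, 1.0 / s_over_mg


def thrust_ratio(
    u_wing: float,
    s_over_mg: float,
    alpha_rad: float,
    params: ThrustModelParams = ThrustModelParams(),
) -> float:
    """Weight-normalized thrust T/mg (dimensionless).

    ``alpha_rad`` is the wingbeat angle of attack in radians, in [0, pi/2];
    ``u_wing`` the wingbeat-mean blade-element speed in m/s.
    """
    u_wing = np.asarray(u_wing, dtype=float)
    alpha = np.asarray(alpha_rad, dtype=float)
    s = np.asarray(s_over_mg, dtype=float)
    if np.any(u_wing < 0) or np.any(s < 0):
        raise ValueError("wing speed and S/mg must be non-negative")
    if np.any(alpha < 0) or np.any(alpha > np.pi / 2 + 1e-12):
        raise ValueError("angle of attack must lie in [0, pi/2] radians")
    out = 0.5 * params.rho * u_wing**2 * s * params.c_t_alpha * alpha
    return float(out) if out.ndim == 0 else out


def steady_climb_balance(
    thrust_over_mg: float,
    thrust_angle_deg: float,
    drag_over_mg: float = 0.0,
    tol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Force-balance residuals for constant-speed climbing flight.

    For a climber at constant speed the weight-normalized thrust, tilted
    ``thrust_angle_deg`` above horizontal, must cancel unit weight
    vertically and the weight-normalized drag horizontally.  Returns the
    residual force vector (horizontal, vertical)/mg and whether both
    residuals are within ``tol``.
    """
    if thrust_over_mg < 0:
        raise ValueError("T/mg must be non-negative")
    ang = np.radians(thrust_angle_deg)
    residual = np.array(
        [
            thrust_over_mg * np.cos(ang) - drag_over_mg,
            thrust_over_mg * np.sin(ang) - 1.0,
        ]
    )
    return residual, bool(np.all(np.abs(residual) < tol))


def helicopter_prediction(beta_wingbeat_deg, gamma_climb_deg) -> "_stats.RegressionFit":
    """Test the body-pitch force-vectoring (helicopter) hypothesis.

    Ordinary least-squares fit of climb angle on body pitch (both in
    degrees); under body-fixed force vectoring the two track each other
    linearly.  Delegates to :func:`morphoflight.stats.linear_regression`.
    """
    return _stats.linear_regression(beta_wingbeat_deg, gamma_climb_deg)
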