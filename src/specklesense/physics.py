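"""Closed-form magneto-optic and attenuation relations behind the sensor.

The sensing mechanism rests on the Faraday effect: linearly polarized light
traversing a medium of length ``L`` under a magnetic field ``B`` has its
polarization plane rotated by ``phi = V * B * L``, where ``V`` is the Verdet
constant (magnetic rotatory power) of the medium. Glucose has a large Verdet
constant relative to other plasma constituents, so under an AC magnetic
field the rotation — and hence the speckle decorrelation it induces — is
dominated by, and approximately linear in, the glucose concentration. The
Beer–Lambert law bounds how much light survives the skin/adipose path to the
blood vessel and back.

Units are declared, not enforced: ``V`` in rad·G⁻¹·mm⁻¹, ``B`` in Gauss,
lengths in mm, wavelength in nm. Validation is restricted to finiteness and
sign, since no single unit convention for the Verdet constant is universal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DegenerateGeometryError, InvalidParameterError

__all__ = [
    "MagnetoOpticParams",
    "AttenuationParams",
    "faraday_rotation",
    "faraday_rotation_birefringence",
    "verdet_constant",
    "min_decorrelation_field",
    "beer_lambert",
]


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise InvalidParameterError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class MagnetoOpticParams:
    """Parameters of the Faraday-rotation relations.

    verdet : rotatory power per (field × length) [rad·G⁻¹·mm⁻¹]
    field : magnetic field strength B [Gauss]
    path_length : interaction length L [mm]
    wavelength : optical wavelength λ [nm]
    delta_n : circular birefringence Δn between the two circular
        polarization states [dimensionless]
    alpha : angle between B and the light path [rad]
    beam_radius : illumination beam radius R [mm]
    """

    verdet: float
    field: float
    path_length: float
    wavelength: float
    delta_n: float = 0.0
    alpha: float = 0.0
    beam_radius: float = 1.0

    def __post_init__(self) -> None:
        _require_finite(
            verdet=self.verdet,
            field=self.field,
            path_length=self.path_length,
            wavelength=self.wavelength,
            delta_n=self.delta_n,
            alpha=self.alpha,
            beam_radius=self.beam_radius,
        )
        if self.field < 0:
            raise InvalidParameterError("field must be >= 0")
        if self.path_length <= 0:
            raise InvalidParameterError("path_length must be > 0")
        if self.wavelength <= 0:
            raise InvalidParameterError("wavelength must be > 0")
        if self.beam_radius <= 0:
            raise InvalidParameterError("beam_radius must be > 0")


@dataclass(frozen=True)
class AttenuationParams:
    """Beer–Lambert attenuation parameters.

    molar_attenuation : ε [L·mol⁻¹·mm⁻¹]
    concentration : C [mol·L⁻¹]
    path_length : d [mm], one-way geometric path through the sample
    incident_intensity : I0 [arbitrary units]
    reflection_mode : when True the light traverses the sample twice
        (illumination reflected off the blood vessel), doubling the
        effective optical path.
    """

    molar_attenuation: float
    concentration: float
    path_length: float
    incident_intensity: float = 1.0
    reflection_mode: bool = False

    def __post_init__(self) -> None:
        _require_finite(
            molar_attenuation=self.molar_attenuation,
            concentration=self.concentration,
            path_length=self.path_length,
            incident_intensity=self.incident_intensity,
        )
        if min(self.molar_attenuation, self.concentration, self.path_length) < 0:
            raise InvalidParameterError("attenuation magnitudes must be >= 0")
        if self.incident_intensity <= 0:
            raise InvalidParameterError("incident_intensity must be > 0")


def faraday_rotation(verdet: float, field: float, path_length: float) -> float:
    """Polarization rotation angle phi = V·B·L [rad].

    Exactly multilinear in all three arguments.
    """
    _require_finite(verdet=verdet, field=field, path_length=path_length)
    if path_length <= 0:
        raise InvalidParameterError("path_length must be > 0")
    return verdet * field * path_length


def faraday_rotation_birefringence(
    path_length: float, field: float, delta_n: float, wavelength: float
) -> float:
    """Rotation expressed through circular birefringence: phi = π·L·B·Δn / λ.

    Equivalent to ``faraday_rotation`` when the Verdet constant is supplied
    consistently as V = π·Δn / λ (Δn taken per unit field).
    """
    _require_finite(
        path_length=path_length, field=field, delta_n=delta_n, wavelength=wavelength
    )
    if wavelength <= 0:
        raise InvalidParameterError("wavelength must be > 0")
    return math.pi * path_length * field * delta_n / wavelength


def verdet_constant(
    angle: float, path_length: float, field: float, alpha: float = 0.0
) -> float:
    """Magnetic rotatory power V = phi / (L·B·cos α).

    Inverts ``faraday_rotation`` when the field is parallel to the beam
    (alpha = 0). The geometry degenerates when the field is perpendicular
    to the light path or when field or path length vanish.
    """
    _require_finite(angle=angle, path_length=path_length, field=field, alpha=alpha)
    denom = path_length * field * math.cos(alpha)
    if abs(denom) < 1e-300 or abs(math.cos(alpha)) < 1e-15:
        raise DegenerateGeometryError(
            "verdet_constant undefined: path_length*field*cos(alpha) ~ 0"
        )
    return angle / denom


def min_decorrelation_field(
    path_length: float,
    beam_radius: float,
    angle: float,
    proportionality_k: float = 1.0,
) -> float:
    """Smallest field strength able to decorrelate the observed speckle area.

    The underlying relation is a proportionality, Bmin ∝ π·L / (R·phi);
    ``proportionality_k`` is the explicit calibration constant (default 1,
    since no absolute constant is available for tissue). The bound grows
    with interaction length and shrinks with beam radius and rotation angle.
    """
    _require_finite(
        path_length=path_length,
        beam_radius=beam_radius,
        angle=angle,
        proportionality_k=proportionality_k,
    )
    if proportionality_k <= 0:
        raise InvalidParameterError("proportionality_k must be > 0")
    if beam_radius * angle <= 0:
        raise DegenerateGeometryError(
            "min_decorrelation_field undefined for zero beam radius or angle"
        )
    return proportionality_k * math.pi * path_length / (beam_radius * angle)


def beer_lambert(params: AttenuationParams) -> tuple[float, float]:
    """Absorbance and transmitted intensity for the finger optical path.

    Returns ``(A, I)`` with A = ε·C·d_eff and I = I0·exp(−A), where the
    effective path d_eff is doubled in reflection mode (light crosses the
    skin/adipose layers twice). A ≥ 0 always; I ∈ (0, I0].
    """
    d_eff = 2.0 * params.path_length if params.reflection_mode else params.path_length
    absorbance = params.molar_attenuation * params.concentration * d_eff
    transmitted = params.incident_intensity * math.exp(-absorbance)
    return absorbance, transmitted
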