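"""Closed-form 1D kinematics of ions in a single-stage linear TOF.

The model: an ion of mass ``m`` carrying ``q`` elementary charges sits at the
sample surface (z = 0) until its ejection time ``t_E``, then leaves with an
initial velocity ``v0`` along the TOF axis and is accelerated by the uniform
extraction field ``E`` until it exits the acceleration gap, after which it
drifts field-free to the detector.  With the elapsed acceleration time
``tau = t - t_E`` the propagated distance inside the gap is

    z(tau) = v0 * tau + (q e E / 2 m) * tau**2

which is quadratic in ``tau`` and therefore invertible in closed form.  That
inversion — converting an observed (probe delay, probe position) pair into an
ejection time — is the analysis this module exists for.

All quantities are strict SI (kg, m, s, V/m).  Functions are vectorized over
numpy arrays wherever a per-ion quantity makes sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .constants import ATOMIC_MASS_UNIT, ELEMENTARY_CHARGE

__all__ = [
    "IonSpecies",
    "InstrumentConfig",
    "KinematicState",
    "field_from_voltage",
    "acceleration",
    "propagate_distance",
    "velocity_at",
    "invert_ejection_time",
    "time_of_flight",
    "fragment_arrival",
]


class KinematicsDomainError(ValueError):
    """Raised when inputs leave the physical domain of the closed forms."""


@dataclass(frozen=True)
class IonSpecies:
    """A plume ion: mass, charge multiplicity and display labels.

    Parameters
    ----------
    label:
        Free-text name, e.g. ``"(CHCA)H+"``.
    mass_u:
        Ion mass in unified atomic mass units (monoisotopic by convention).
    charge:
        Charge multiplicity in elementary charges (positive integer).
    nominal_mz:
        Integer m/z used for display; must round-trip ``mass_u / charge``
        within +/- 1.
    """

    label: str
    mass_u: float
    charge: int = 1
    nominal_mz: int | None = None

    def __post_init__(self) -> None:
        if self.mass_u <= 0:
            raise ValueError(f"mass_u must be > 0, got {self.mass_u}")
        if self.charge < 1 or int(self.charge) != self.charge:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")
        if self.nominal_mz is None:
            object.__setattr__(self, "nominal_mz", round(self.mass_u / self.charge))
        if abs(self.nominal_mz - self.mass_u / self.charge) > 1:
            raise ValueError(
                f"nominal_mz {self.nominal_mz} inconsistent with "
                f"mass_u/charge = {self.mass_u / self.charge:.4f}"
            )

    @property
    def mass_kg(self) -> float:
        return self.mass_u * ATOMIC_MASS_UNIT

    @property
    def charge_coulomb(self) -> float:
        return self.charge * ELEMENTARY_CHARGE


@dataclass(frozen=True)
class InstrumentConfig:
    """Single-stage linear TOF geometry and binning.

    ``field`` defaults to ``voltage / gap``; if given explicitly it must agree
    with that ratio to 0.5% (the tolerance of printed voltage/field pairs).
    """

    voltage: float  # accelerating potential, V
    gap: float  # acceleration-region length, m
    drift_length: float = 1.0  # field-free region, m
    bin_width: float = 10e-9  # TOF histogram bin, s
    field: float = dc_field(default=0.0)  # V/m; 0 -> derived from voltage/gap

    def __post_init__(self) -> None:
        if self.voltage <= 0 or self.gap <= 0:
            raise ValueError("voltage and gap must be > 0")
        if self.drift_length < 0:
            raise ValueError("drift_length must be >= 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.field == 0.0:
            object.__setattr__(self, "field", self.voltage / self.gap)
        elif abs(self.field * self.gap - self.voltage) > 0.005 * self.voltage:
            raise ValueError(
                f"field * gap = {self.field * self.gap:.1f} V disagrees with "
                f"voltage {self.voltage:.1f} V by more than 0.5%"
            )


@dataclass(frozen=True)
class KinematicState:
    """Position/velocity/time snapshot of an ion along the TOF axis."""

    position: float  # m from the sample surface
    velocity: float  # m/s
    time: float  # s since the MALDI laser pulse

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.time < 0:
            raise ValueError("time must be >= 0")


def field_from_voltage(voltage: float, gap: float) -> float:
    """Extraction field E = voltage / gap for a single-stage source.

    Raises
    ------
    KinematicsDomainError
        If either input is not strictly positive.
    """
    if voltage <= 0 or gap <= 0:
        raise KinematicsDomainError(
            f"voltage and gap must be > 0 (got voltage={voltage}, gap={gap})"
        )
    return voltage / gap


def acceleration(species: IonSpecies, field: float) -> float:
    """Acceleration q e E / m of *species* in a uniform field, m/s^2."""
    return species.charge_coulomb * field / species.mass_kg


def propagate_distance(t_e, v0, species: IonSpecies, field: float, delta_t):
    """Distance from the surface at probe delay ``delta_t``.

    Ions not yet ejected (``delta_t <= t_e``) report position 0: ejection is a
    step event, positions are never negative.  The result is *not* capped at
    the gap length — callers probing beyond the gap must cap themselves.

    Accepts scalars or numpy arrays for ``t_e``, ``v0`` and ``delta_t``.

    Raises
    ------
    KinematicsDomainError
        If a negative ``v0`` is large enough that the ion would re-enter the
        surface (z < 0) at any evaluated delay.
    """
    t_e = np.asarray(t_e, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise KinematicsDomainError("delta_t must be >= 0")
    a = acceleration(species, field)
    tau = np.maximum(delta_t - t_e, 0.0)
    z = v0 * tau + 0.5 * a * tau * tau
    if np.any(z < 0):
        raise KinematicsDomainError(
            "negative v0 drives the ion back into the surface (z < 0)"
        )
    if z.ndim == 0:
        return float(z)
    return z


def velocity_at(t_e, v0, species: IonSpecies, field: float, delta_t):
    """Velocity at delay ``delta_t`` (v0 for not-yet-ejected ions)."""
    t_e = np.asarray(t_e, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    tau = np.maximum(np.asarray(delta_t, dtype=float) - t_e, 0.0)
    v = v0 + acceleration(species, field) * tau
    if v.ndim == 0:
        return float(v)
    return v


def invert_ejection_time(z, delta_t, v0, species: IonSpecies, field: float):
    """Solve the propagation quadratic for the ejection time.

    Given an observed position ``z > 0`` at delay ``delta_t``, the elapsed
    acceleration time is the positive root of
    ``(a/2) tau^2 + v0 tau - z = 0`` with ``a = q e E / m``:

        tau = (-v0 + sqrt(v0**2 + 2 a z)) / a

    and ``t_E = delta_t - tau``.  Points whose inferred ``t_E`` is negative
    are *unphysical* (the ion could not reach z that early even with t_E = 0);
    they are returned with ``valid = False`` rather than dropped, so that
    downstream diagnostics can count them.

    Returns
    -------
    (t_e, valid):
        Arrays (or scalars) of ejection times and validity flags.
    """
    z = np.asarray(z, dtype=float)
    delta_t = np.asarray(delta_t, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if np.any(z <= 0):
        raise KinematicsDomainError("z must be > 0 to invert")
    if np.any(delta_t <= 0) or field <= 0:
        raise KinematicsDomainError("delta_t and field must be > 0")
    a = acceleration(species, field)
    disc = v0 * v0 + 2.0 * a * z
    # disc >= 2 a z > 0 here, so a positive root always exists.
    tau = (-v0 + np.sqrt(disc)) / a
    t_e = delta_t - tau
    valid = t_e >= 0
    if t_e.ndim == 0:
        return float(t_e), bool(valid)
    return t_e, valid


def _exit_time_and_velocity(v0, a: float, length):
    """Time to traverse *length* under acceleration *a*, and exit velocity."""
    v_exit = np.sqrt(v0 * v0 + 2.0 * a * length)
    tau = (v_exit - v0) / a
    return tau, v_exit


def time_of_flight(t_e, v0, species: IonSpecies, instrument: InstrumentConfig):
    """Arrival time at the detector: ejection + acceleration + drift.

    ``t = t_E + tau_acc + L / v_exit`` where ``tau_acc`` is the positive root
    of ``gap = v0 tau + (a/2) tau^2`` and ``v_exit = sqrt(v0^2 + 2 a gap)``.
    Strictly increasing in mass at fixed (t_E, v0).
    """
    t_e = np.asarray(t_e, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    a = acceleration(species, instrument.field)
    tau_acc, v_exit = _exit_time_and_velocity(v0, a, instrument.gap)
    t = t_e + tau_acc + instrument.drift_length / v_exit
    if t.ndim == 0:
        return float(t)
    return t


def fragment_arrival(
    parent_state: KinematicState,
    parent: IonSpecies,
    fragment: IonSpecies,
    instrument: InstrumentConfig,
):
    """Detector arrival time of a fragment born inside the gap.

    The fragment inherits the parent's velocity at the dissociation point and
    is then accelerated — harder, being lighter — over the remaining gap
    before drifting.  A proper fragment therefore always arrives earlier than
    its intact parent would have.

    Vectorized alternative: pass numpy arrays via
    :func:`fragment_arrival_arrays`.
    """
    if fragment.mass_u >= parent.mass_u:
        raise KinematicsDomainError(
            f"fragment mass {fragment.mass_u} u must be < parent mass "
            f"{parent.mass_u} u"
        )
    if parent_state.position >= instrument.gap:
        raise KinematicsDomainError("parent must dissociate inside the gap")
    return float(
        fragment_arrival_arrays(
            np.asarray(parent_state.position),
            np.asarray(parent_state.velocity),
            np.asarray(parent_state.time),
            fragment,
            instrument,
        )
    )

def fragment_arrival_arrays(position, velocity, time, fragment: IonSpecies,
                            instrument: InstrumentConfig):
    """Array form of :func:`fragment_arrival` (no per-element mass checks)."""
    a = acceleration(fragment, instrument.field)
    remaining = instrument.gap - np.asarray(position, dtype=float)
    tau, v_exit = _exit_time_and_velocity(np.asarray(velocity, dtype=float), a, remaining)
    return np.asarray(time, dtype=float) + tau + instrument.drift_length / v_exit
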