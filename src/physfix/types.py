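"""Domain containers for cyclic-torsion testing of pinned physeal fractures.

Canonical units throughout the package: seconds, newton-metres, degrees,
millimetres.  All unit conversion happens at the I/O boundary.

Sign convention: positive torque = external rotation = positive angle, in a
right-handed frame with +z up the torsion axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

PIN_GROUPS = ("three", "two", "one")
MARKER_LABELS = ("cranial", "lateral", "caudal", "medial")
SEGMENTS = ("epiphysis", "diaphysis", "reference")


@dataclass(frozen=True)
class LoadProtocol:
    """Sinusoidal torsion protocol of the servo-hydraulic test machine.

    Parameters
    ----------
    torque_amplitude : float
        Peak torque, Nm. The machine drives ``T(t) = A sin(2 pi f t)``.
    frequency : float
        Loading frequency, Hz.
    n_cycles : int
        Number of full cycles applied.
    sample_rate : float
        Machine acquisition rate, Hz (angle recorded every sample).
    axial_preload : float
        Constant axial compression, N.  Metadata only: it engages the
        interdigitated physeal surface but does not enter the torsion model.
    """

    torque_amplitude: float = 2.0
    frequency: float = 0.5
    n_cycles: int = 250
    sample_rate: float = 1000.0
    axial_preload: float = 20.0

    def __post_init__(self):
        for name in ("torque_amplitude", "frequency", "sample_rate", "axial_preload"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"LoadProtocol.{name} must be > 0")
        if int(self.n_cycles) != self.n_cycles or self.n_cycles < 1:
            raise ConfigurationError("LoadProtocol.n_cycles must be an integer >= 1")

    @property
    def samples_per_cycle(self) -> int:
        spc = self.sample_rate / self.frequency
        if abs(spc - round(spc)) > 1e-9:
            raise ConfigurationError(
                f"sample_rate/frequency = {spc} is not an integer number of samples per cycle"
            )
        return int(round(spc))

    @property
    def duration(self) -> float:
        return self.n_cycles / self.frequency


@dataclass(frozen=True)
class ConstructParams:
    """Mechanical ground truth of one pinned bone-construct.

    The torque-angle backbone is ``theta(T) = T/k + (toggle/2) tanh(T/Tt)``:
    linear terminal limbs of stiffness ``k`` separated by a near-zero-slope
    toggle band of width ``toggle`` centred on zero load.  ``transition_torque``
    sets how sharply the curve leaves the toggle band.
    """

    stiffness_true: float  # Nm/degree
    toggle_true: float  # degrees
    transition_torque: float = 0.2  # Nm
    angle_noise_sd: float = 0.02  # degrees, additive on the machine angle channel
    pin_group: str = "three"

    def __post_init__(self):
        if self.stiffness_true <= 0:
            raise ConfigurationError("stiffness_true must be > 0")
        if self.toggle_true < 0:
            raise ConfigurationError("toggle_true must be >= 0")
        if self.transition_torque <= 0:
            raise ConfigurationError("transition_torque must be > 0")
        if self.angle_noise_sd < 0:
            raise ConfigurationError("angle_noise_sd must be >= 0")
        if self.pin_group not in PIN_GROUPS:
            raise ConfigurationError(f"pin_group must be one of {PIN_GROUPS}")


@dataclass
class TorsionTrace:
    """One cyclic torsion test: uniform time grid, torque and angle channels."""

    time: np.ndarray  # s
    torque: np.ndarray  # Nm
    angle: np.ndarray  # degrees
    protocol: LoadProtocol

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        n = len(self.time)
        if len(self.torque) != n or len(self.angle) != n:
            raise ConfigurationError("time/torque/angle must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ConfigurationError("time must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ConfigurationError("sample interval must be constant to within 1e-9 s")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class CycleWindow:
    """Half-open sample range [start, end) of one load cycle (1-based index)."""

    cycle_index: int
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ConfigurationError("CycleWindow requires end > start")
        if self.cycle_index < 1:
            raise ConfigurationError("cycle_index is 1-based")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MarkerTrajectory:
    """Time-stamped 3D positions (mm) of one labelled retro-reflective marker."""

    marker_id: str
    label: str
    segment: str
    time: np.ndarray  # s
    position: np.ndarray  # (n, 3) mm

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.label not in MARKER_LABELS:
            raise ConfigurationError(f"unknown marker label {self.label!r}")
        if self.segment not in SEGMENTS:
            raise ConfigurationError(f"unknown segment {self.segment!r}")
        if self.position.ndim != 2 or self.position.shape[1] != 3:
            raise ConfigurationError("position must be (n, 3)")
        if len(self.time) != len(self.position):
            raise ConfigurationError("time and position lengths differ")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ConfigurationError("marker time must be strictly increasing")
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.time))):
            raise ConfigurationError("marker coordinates must be finite")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class TorsionAxis:
    """Torsion axis as a point plus unit direction (machine vertical by default)."""

    point: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ConfigurationError("axis direction must be a unit vector")


@dataclass(frozen=True)
class TerminalFit:
    """OLS line (torque on angle) over an accepted terminal segment.

    slope is the torsional stiffness estimate (Nm/degree); the x-intercept
    (degrees at zero torque) feeds the toggle statistic.
    """

    branch: str  # "external" (+) or "internal" (-)
    n_points: int
    slope: float  # Nm/degree
    intercept: float  # Nm
    r_squared: float
    x_intercept: float  # degrees

    def __post_init__(self):
        if self.branch not in ("external", "internal"):
            raise ConfigurationError("branch must be 'external' or 'internal'")
        if self.n_points < 3:
            raise ConfigurationError("a terminal fit needs >= 3 points")


@dataclass(frozen=True)
class ToggleResult:
    """Interfragmentary free play about zero load, degrees."""

    positive_toggle: float  # x-intercept of the external-rotation terminal line
    negative_toggle: float  # x-intercept of the internal-rotation terminal line
    total_toggle: float  # positive - negative


@dataclass(frozen=True)
class RigGeometry:
    """Marker layout and actuator-bone coupling of the simulated test rig.

    rotation_shares gives, per epiphyseal marker label, the fraction of the
    interfragmentary rotation expressed at that marker (eccentric pin
    placement makes the humeral-head side move more than the greater
    tubercle).  slippage_factor is actuator angle divided by true bone angle:
    friction-grip slippage at the mould makes the machine read high.
    """

    marker_radius: float = 30.0  # mm, marker distance from the torsion axis
    epiphysis_height: float = 40.0  # mm above origin
    diaphysis_height: float = -40.0  # mm
    reference_heights: tuple[float, float] = (80.0, -80.0)  # proximal/distal pot
    rotation_shares: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(MARKER_LABELS, 1.0)
    )
    slippage_factor: float = 2.6
    marker_sample_rate: float = 100.0  # Hz; motion capture runs slower than the machine
    position_noise_sd: float = 0.05  # mm per coordinate

    def __post_init__(self):
        if self.marker_radius <= 0:
            raise ConfigurationError("marker_radius must be > 0")
        if self.slippage_factor < 1:
            raise ConfigurationError("slippage_factor must be >= 1")
        if self.marker_sample_rate <= 0:
            raise ConfigurationError("marker_sample_rate must be > 0")
        if self.position_noise_sd < 0:
            raise ConfigurationError("position_noise_sd must be >= 0")
        unknown = set(self.rotation_shares) - set(MARKER_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown marker label(s) {sorted(unknown)}")
        if any(s < 0 for s in self.rotation_shares.values()):
            raise ConfigurationError("rotation_shares must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Repeated-measures layout: every specimen is tested three -> two -> one pins."""

    n_specimens: int = 12
    group_order: tuple[str, ...] = PIN_GROUPS
    specimen_effect_sd: float = 1.0  # degrees, random intercept shared across a bone's runs
    marker_effect_sd: float = 0.3  # degrees, per-marker intercept reused across runs
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens < 2:
            raise ConfigurationError("a study needs at least 2 specimens")
        if tuple(self.group_order) != PIN_GROUPS:
            raise ConfigurationError(f"group order is fixed as {PIN_GROUPS}")
        if self.specimen_effect_sd < 0 or self.marker_effect_sd < 0:
            raise ConfigurationError("random-effect SDs must be >= 0")
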