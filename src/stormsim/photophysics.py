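"""Fluorophore switching kinetics, photon budgets and photoselection.

Each fluorophore cycles between OFF, ON and BLEACHED states.  Switching is
simulated in continuous time (measured in frame units): OFF -> ON waiting
times are exponential with rate ``on_rate`` scaled by the photoselection
weight of the dipole and by the spectral excitation efficiency of the laser
line; ON durations are exponential with mean ``1/off_rate``; each ON -> OFF
transition bleaches the molecule with probability
``bleach_probability_per_cycle``, so the number of switching cycles is
geometric with mean ``1/bleach_probability``.

Photon budgets per switching event are exponential around the dye's mean
(memoryless emission terminated by stochastic off-switching); a fixed
(deterministic) budget can be selected for testing.  Events that cross frame
boundaries split their photons proportionally to the time spent in each
frame.

Photoselection: the probability of exciting a molecule is proportional to
the squared projection of its absorption dipole on the excitation field
(cos^2 law).  For rapidly rotating dyes the orientation averages out: the
isotropic mean weight (1/3) multiplies the excitation propensity, while the
photon budget of an event is left unscaled — during an ON period a tumbling
dipole samples all orientations and its photon yield is limited by switching
kinetics rather than by instantaneous excitation geometry.  For rigid dyes
both the propensity and the budget carry the cos^2 factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stormsim.patterns import LabeledSet

__all__ = [
    "DyeModel",
    "ExcitationSpec",
    "EmissionEvent",
    "photoselection_weight",
    "simulate_switching",
    "draw_photon_counts",
    "ALEXA647",
    "ALEXA568",
]


@dataclass(frozen=True)
class DyeModel:
    """Photophysical parameters of a dye.

    Rates are per frame.  ``mean_photons_per_event`` is the mean emitted
    photon budget of one switching event at full excitation;
    ``mean_switching_cycles`` is implied by ``1/bleach_probability_per_cycle``.
    """

    name: str = "generic"
    mean_photons_per_event: float = 4000.0
    on_rate: float = 0.002
    off_rate: float = 1.0
    bleach_probability_per_cycle: float = 0.05
    absorption_spectrum_id: str | None = None
    emission_spectrum_id: str | None = None
    photon_budget: str = "exponential"  # exponential | fixed

    def __post_init__(self):
        if min(self.mean_photons_per_event, self.on_rate, self.off_rate) < 0:
            raise ValueError("rates and photon budget must be >= 0")
        if not 0.0 <= self.bleach_probability_per_cycle <= 1.0:
            raise ValueError("bleach_probability_per_cycle must be in [0, 1]")
        if self.photon_budget not in ("exponential", "fixed"):
            raise ValueError("photon_budget must be 'exponential' or 'fixed'")

    @property
    def mean_switching_cycles(self) -> float:
        p = self.bleach_probability_per_cycle
        return np.inf if p == 0 else 1.0 / p


# Default dye presets.  Photon budgets and cycle numbers follow the typical
# dSTORM figures for carbocyanine/rhodamine dyes (thousands of photons per
# event, tens of cycles); switching rates are working defaults.
ALEXA647 = DyeModel(
    name="Alexa647",
    mean_photons_per_event=4000.0,
    bleach_probability_per_cycle=0.05,
    absorption_spectrum_id="alexa647_absorption",
    emission_spectrum_id="alexa647_emission",
)
ALEXA568 = DyeModel(
    name="Alexa568",
    mean_photons_per_event=4000.0,
    bleach_probability_per_cycle=0.05,
    absorption_spectrum_id="alexa568_absorption",
    emission_spectrum_id="alexa568_emission",
)


@dataclass(frozen=True)
class ExcitationSpec:
    """Excitation laser line and polarization state.

    polarization is one of ``circular_xy``, ``linear`` (with
    ``linear_direction`` a unit 2-vector in the xy sample plane) or
    ``longitudinal_z`` (axial field, e.g. highly inclined p-polarized
    illumination).
    """

    laser_wavelength: float = 640.0
    polarization: str = "circular_xy"
    linear_direction: tuple[float, float] = (1.0, 0.0)
    intensity_scale: float = 1.0

    def __post_init__(self):
        if self.laser_wavelength <= 0:
            raise ValueError("laser_wavelength must be > 0")
        if self.polarization not in ("circular_xy", "linear", "longitudinal_z"):
            raise ValueError(f"unknown polarization {self.polarization!r}")
        if self.polarization == "linear":
            e = np.asarray(self.linear_direction, dtype=float)
            if abs(np.linalg.norm(e) - 1.0) > 1e-9:
                raise ValueError("linear_direction must be a unit 2-vector")


@dataclass
class EmissionEvent:
    """One switching event of one fluorophore.

    Frames are 0-based here; the event occupies frames
    ``frame_start..frame_end`` inclusive and ``photons_per_frame`` sums to
    ``photons_total``.  ``position`` is the dye position for this event
    (post-linker; drift is applied downstream per frame).
    """

    fluorophore_id: int
    frame_start: int
    frame_end: int
    photons_total: float
    photons_per_frame: np.ndarray
    position: np.ndarray
    dipole: np.ndarray
    structure_id: int = 0

    def __post_init__(self):
        self.photons_per_frame = np.asarray(self.photons_per_frame, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.dipole = np.asarray(self.dipole, dtype=float)
        if self.frame_start > self.frame_end:
            raise ValueError("frame_start must be <= frame_end")
        if self.photons_total < 0:
            raise ValueError("photons must be >= 0")


def photoselection_weight(dipole, excitation: ExcitationSpec) -> float:
    """Excitation propensity of a fixed dipole, in [0, 1].

    Linear polarization with in-plane field e: (d . e)^2.  Longitudinal
    (axial) field: d_z^2.  Circular in-plane excitation averages the two
    in-plane projections: (d_x^2 + d_y^2) / 2.
    """
    d = np.asarray(dipole, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("dipole must be a unit vector")
    if excitation.polarization == "linear":
        e = np.asarray(excitation.linear_direction, dtype=float)
        return float((d[0] * e[0] + d[1] * e[1]) ** 2)
    if excitation.polarization == "longitudinal_z":
        return float(d[2] ** 2)
    return float((d[0] ** 2 + d[1] ** 2) / 2.0)


def isotropic_average_weight(excitation: ExcitationSpec) -> float:
    """Photoselection weight averaged over uniformly random dipoles (= 1/3)."""
    return 1.0 / 3.0


def draw_photon_counts(event_mean: float, rng_seed, size=None):
    """Draw emitted photon counts for events of a given mean budget.

    The budget is exponential with the given mean (continuous draw, rounded
    to whole photons).  ``rng_seed`` may be an int seed or a Generator.
    """
    if event_mean < 0:
        raise ValueError("event_mean must be >= 0")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if event_mean == 0:
        return np.zeros(size) if size is not None else 0.0
    draws = np.round(rng.exponential(event_mean, size=size))
    return draws if size is not None else float(draws)


def _split_photons(t_on: float, t_off: float, photons: float, n_frames: int):
    """Split an event's photons over frames proportionally to overlap time."""
    f0 = int(np.floor(t_on))
    f1 = min(int(np.floor(t_off - 1e-12)), n_frames - 1)
    f1 = max(f1, f0)
    frames = np.arange(f0, f1 + 1)
    lo = np.maximum(frames.astype(float), t_on)
    hi = np.minimum(frames + 1.0, t_off)
    overlap = np.clip(hi - lo, 0.0, None)
    total = overlap.sum()
    if total <= 0:
        return f0, f0, np.array([photons])
    return f0, f1, photons * overlap / total


def simulate_switching(
    labeled: LabeledSet,
    dye: DyeModel,
    excitation: ExcitationSpec,
    n_frames: int,
    frame_exposure_s: float = 0.1,
    rng_seed=0,
    excitation_efficiency: float = 1.0,
) -> list[EmissionEvent]:
    """Simulate blinking of all fluorophores over an acquisition.

    ``excitation_efficiency`` is the spectral efficiency of the laser line
    for this dye (from the spectral module); it scales both the OFF -> ON
    propensity and the per-event photon budget (the emission rate while ON
    is proportional to the excitation rate, so off-peak excitation produces
    dimmer events).  The photoselection weight additionally scales the
    propensity, and for rigidly fixed dipoles it also scales the photon
    budget (see module docstring).  Events crossing frame boundaries are
    split; events still ON at the end of the acquisition are truncated.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(rng_seed)
    spec = labeled.spec
    free = spec.dipole_mode == "free_rotating"
    events: list[EmissionEvent] = []
    for i in range(len(labeled)):
        dipole = labeled.dipoles[i]
        if free:
            w_rate = isotropic_average_weight(excitation)
            w_budget = 1.0
        else:
            w_rate = photoselection_weight(dipole, excitation)
            w_budget = w_rate
        rate = dye.on_rate * w_rate * excitation_efficiency * excitation.intensity_scale
        if rate <= 0:
            continue
        t = 0.0
        while True:
            t_on = t + rng.exponential(1.0 / rate)
            if t_on >= n_frames:
                break
            duration = rng.exponential(1.0 / dye.off_rate) if dye.off_rate > 0 else float(n_frames)
            t_off = min(t_on + duration, float(n_frames))
            mean = dye.mean_photons_per_event * w_budget * excitation_efficiency
            if dye.photon_budget == "fixed":
                photons = float(np.round(mean))
            else:
                photons = draw_photon_counts(mean, rng)
            if spec.linker_mode == "flexible" and spec.linker_length > 0:
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                pos = labeled.epitope_positions[i] + spec.linker_length * direction
            else:
                pos = labeled.positions[i]
            if photons > 0:
                f0, f1, per_frame = _split_photons(t_on, t_off, photons, n_frames)
                events.append(
                    EmissionEvent(
                        fluorophore_id=i,
                        frame_start=f0,
                        frame_end=f1,
                        photons_total=photons,
                        photons_per_frame=per_frame,
                        position=pos,
                        dipole=dipole,
                        structure_id=int(labeled.structure_id[i]),
                    )
                )
            t = t_off
            if rng.uniform() < dye.bleach_probability_per_cycle:
                break
            if t >= n_frames:
                break
    return events
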