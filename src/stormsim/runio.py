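"""Run configuration, simulation orchestration and file output.

``simulate`` wires the whole pipeline together: ground-truth pattern
generation and labelling, blinking photophysics (with spectral excitation /
detection efficiencies when a filter set and dye spectra are configured),
drift, PSF rendering onto a sub-pixel photon canvas, pixel binning,
structured and uniform background, and the camera noise chain.  The result
is an integer frame stack plus a ground-truth table with one row per
(event, frame).

Reproducibility: a single ``master_seed`` is recorded in the run manifest
and child seeds are derived per sub-system via ``numpy`` seed sequences, so
identical configurations produce byte-identical TIFF and CSV outputs.

Conventions: coordinates in the outputs are sample-space nm with the origin
at the field-of-view corner, x to the right along columns and y down along
rows (image row-column order); frames are 1-based in files, matching TIFF
page order (internally 0-based).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from stormsim.camera import (
    BackgroundSpec,
    CameraConfig,
    apply_camera_noise,
    bin_to_pixels,
    build_structured_background,
    single_molecule_peak,
)
from stormsim.drift import DriftConfig, DriftTrajectory, simulate_drift
from stormsim.optics import OpticalConfig, make_psf_model, render_event
from stormsim.patterns import (
    AxonSegmentSpec,
    LabelingSpec,
    LinePatternSpec,
    VesicleSpec,
    generate_axon_pattern,
    generate_line_pattern,
    generate_vesicle_pattern,
    place_labels,
)
from stormsim.photophysics import DyeModel, ExcitationSpec, simulate_switching
from stormsim.spectral import (
    FilterSet,
    detection_efficiency,
    excitation_efficiency,
    load_dye_spectrum,
)

__all__ = [
    "SpeciesConfig",
    "RunConfig",
    "SimulationResult",
    "simulate",
    "write_ground_truth",
    "write_stack",
    "write_outputs",
    "save_config",
    "load_config",
    "config_hash",
]

GROUND_TRUTH_COLUMNS = [
    "frame",
    "id",
    "x_nm",
    "y_nm",
    "z_nm",
    "x_drifted_nm",
    "y_drifted_nm",
    "photons_detected",
    "dye",
    "channel",
    "dipole_x",
    "dipole_y",
    "dipole_z",
]


@dataclass(frozen=True)
class SpeciesConfig:
    """One labelled structure population: pattern + labelling + dye."""

    name: str
    pattern_kind: str  # axon | line | vesicle
    pattern: dict = field(default_factory=dict)
    labeling: LabelingSpec = field(default_factory=LabelingSpec)
    dye: DyeModel = field(default_factory=DyeModel)

    def __post_init__(self):
        if self.pattern_kind not in ("axon", "line", "vesicle"):
            raise ValueError(f"unknown pattern_kind {self.pattern_kind!r}")


@dataclass(frozen=True)
class RunConfig:
    species: tuple = ()
    excitation: ExcitationSpec = field(default_factory=ExcitationSpec)
    laser_schedule: tuple | None = None  # ((wavelength_nm, n_frames), ...)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    drift: DriftConfig | None = None
    filters: FilterSet | None = None
    use_spectra: bool = False
    n_frames: int = 100
    master_seed: int = 0

    def __post_init__(self):
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        if self.laser_schedule is not None:
            total = sum(n for _, n in self.laser_schedule)
            if total != self.n_frames:
                raise ValueError(
                    "laser_schedule frame counts must sum to n_frames "
                    f"({total} != {self.n_frames})"
                )


@dataclass
class SimulationResult:
    stack: np.ndarray  # (n_frames, rows, cols) uint16
    ground_truth: pd.DataFrame
    manifest: dict
    trajectory: DriftTrajectory | None
    photon_images: np.ndarray | None = None  # pre-camera photon-valued frames


def _generate_pattern(species: SpeciesConfig, seed):
    kind = species.pattern_kind
    if kind == "axon":
        params = dict(species.pattern)
        segments = params.pop("segments", None)
        if segments is None:
            segments = [AxonSegmentSpec(**_tupled(params))]
        else:
            segments = [AxonSegmentSpec(**_tupled(dict(s))) for s in segments]
        return generate_axon_pattern(segments, species.labeling.density, seed)
    if kind == "line":
        spec = LinePatternSpec(**_tupled(dict(species.pattern)))
        return generate_line_pattern(spec, species.labeling.density, seed)
    spec = VesicleSpec(**_tupled(dict(species.pattern)))
    return generate_vesicle_pattern(spec, seed)


def _spectral_factors(species: SpeciesConfig, laser_nm: float, cfg: RunConfig):
    """(excitation, detection) efficiencies for one dye under one laser."""
    if not cfg.use_spectra:
        return 1.0, 1.0
    absorption = load_dye_spectrum(species.dye.absorption_spectrum_id)
    emission = load_dye_spectrum(species.dye.emission_spectrum_id)
    exc = excitation_efficiency(absorption, laser_nm)
    det = detection_efficiency(emission, cfg.filters) if cfg.filters else 1.0
    return exc, det


def simulate(config: RunConfig) -> SimulationResult:
    """Run the full simulation described by ``config``.

    Returns the integer camera stack, the per-(event, frame) ground-truth
    table, a manifest (config hash, seed, version, photon totals) and the
    drift trajectory (None when drift is disabled).
    """
    from stormsim import __version__ as _version

    seeds = np.random.SeedSequence(config.master_seed).spawn(4)
    pattern_seeds = seeds[0].spawn(max(len(config.species), 1))
    switch_seeds = seeds[1].spawn(max(len(config.species) * 8, 1))
    cam_rng = np.random.default_rng(seeds[2])
    drift_seed = seeds[3]

    n_frames = config.n_frames
    rows, cols = config.camera.sensor_size
    over = config.optics.psf_grid_oversampling
    pitch = config.camera.pixel_size / over
    psf_model = make_psf_model(config.optics)

    traj = None
    if config.drift is not None and n_frames > 0:
        dcfg = config.drift
        if dcfg.n_frames != n_frames:
            dcfg = DriftConfig(
                mean_velocity=dcfg.mean_velocity,
                drag_coefficient=dcfg.drag_coefficient,
                random_force_sigma=dcfg.random_force_sigma,
                frame_time=dcfg.frame_time,
                n_frames=n_frames,
            )
        traj = simulate_drift(dcfg, drift_seed)

    schedule = config.laser_schedule
    if schedule is None:
        schedule = ((config.excitation.laser_wavelength, n_frames),)

    # --- photophysics per species and laser block -------------------------
    all_events = []  # (event, detection factor, species index, channel)
    label_map = np.zeros((rows, cols))
    sw = 0
    for si, species in enumerate(config.species):
        epitopes = _generate_pattern(species, pattern_seeds[si])
        labeled = place_labels(
            epitopes, species.labeling, pattern_seeds[si].spawn(1)[0]
        )
        # sum image of all fluorophores, for the structured background
        if len(labeled):
            jj = (labeled.positions[:, 0] / config.camera.pixel_size).astype(int)
            ii = (labeled.positions[:, 1] / config.camera.pixel_size).astype(int)
            ok = (ii >= 0) & (ii < rows) & (jj >= 0) & (jj < cols)
            np.add.at(label_map, (ii[ok], jj[ok]), 1.0)
        frame_offset = 0
        for channel, (laser_nm, block_frames) in enumerate(schedule):
            if block_frames == 0:
                continue
            exc_eff, det_eff = _spectral_factors(species, laser_nm, config)
            excitation = ExcitationSpec(
                laser_wavelength=laser_nm,
                polarization=config.excitation.polarization,
                linear_direction=config.excitation.linear_direction,
                intensity_scale=config.excitation.intensity_scale,
            )
            events = simulate_switching(
                labeled,
                species.dye,
                excitation,
                block_frames,
                rng_seed=switch_seeds[sw],
                excitation_efficiency=exc_eff,
            )
            sw += 1
            for ev in events:
                ev.frame_start += frame_offset
                ev.frame_end += frame_offset
                all_events.append((ev, det_eff, si, channel))
            frame_offset += block_frames

    # --- render frames ----------------------------------------------------
    photon_frames = np.zeros((n_frames, rows, cols))
    canvas = np.zeros((rows * over, cols * over))
    gt_rows = []
    for eid, (ev, det_factor, si, channel) in enumerate(all_events):
        species = config.species[si]
        dipole = None if species.labeling.dipole_mode == "free_rotating" else ev.dipole
        for k, f in enumerate(range(ev.frame_start, ev.frame_end + 1)):
            if f >= n_frames:
                break
            detected = ev.photons_per_frame[k] * det_factor
            if detected <= 0:
                continue
            pos = ev.position.copy()
            if traj is not None:
                dim = traj.offsets.shape[1]
                pos[:dim] += traj.offsets[f]
            canvas[:] = 0.0
            render_event(
                canvas,
                detected,
                pos,
                psf_model,
                config.optics,
                pitch,
                dipole=dipole,
            )
            photon_frames[f] += bin_to_pixels(canvas, config.camera, over)
            gt_rows.append(
                (
                    f + 1,
                    eid,
                    ev.position[0],
                    ev.position[1],
                    ev.position[2],
                    pos[0],
                    pos[1],
                    detected,
                    species.dye.name,
                    channel,
                    ev.dipole[0],
                    ev.dipole[1],
                    ev.dipole[2],
                )
            )

    ground_truth = pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)

    # --- background and camera -------------------------------------------
    bg = config.background
    background_rate = np.full((rows, cols), float(bg.uniform_rate))
    if bg.sfb_strength > 0 and label_map.any():
        ref_photons = (
            config.species[0].dye.mean_photons_per_event if config.species else 4000.0
        )
        peak = single_molecule_peak(psf_model, config.camera, ref_photons, over)
        background_rate = background_rate + build_structured_background(
            label_map, bg.sfb_strength, peak, bg.sfb_defocus, config.camera, psf_model
        )

    stack = np.empty((n_frames, rows, cols), dtype=np.uint16)
    for f in range(n_frames):
        stack[f] = apply_camera_noise(
            photon_frames[f], config.camera, cam_rng, background_rate
        )

    manifest = {
        "stormsim_version": _version,
        "master_seed": int(config.master_seed),
        "config_sha256": config_hash(config),
        "n_frames": int(n_frames),
        "sensor_size": [int(rows), int(cols)],
        "pixel_size_nm": float(config.camera.pixel_size),
        "n_events": int(len(all_events)),
        "total_photons_detected": float(ground_truth["photons_detected"].sum())
        if len(ground_truth)
        else 0.0,
    }
    return SimulationResult(stack, ground_truth, manifest, traj, photon_frames)


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------


def config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["species"] = [asdict(s) for s in config.species]
    return d


def _tupled(d: dict) -> dict:
    return {
        k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
        if isinstance(v, list)
        else v
        for k, v in d.items()
    }


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    species = []
    for s in d.pop("species", []):
        s = dict(s)
        labeling = LabelingSpec(**_tupled(s.pop("labeling", {})))
        dye = DyeModel(**s.pop("dye", {}))
        pattern = _tupled(s.pop("pattern", {}))
        species.append(
            SpeciesConfig(labeling=labeling, dye=dye, pattern=pattern, **s)
        )
    excitation = ExcitationSpec(**_tupled(d.pop("excitation", {})))
    optics = OpticalConfig(**d.pop("optics", {}))
    camera = CameraConfig(**_tupled(d.pop("camera", {})))
    background = BackgroundSpec(**d.pop("background", {}))
    drift = d.pop("drift", None)
    drift = DriftConfig(**_tupled(drift)) if drift else None
    filters = d.pop("filters", None)
    filters = FilterSet(**_tupled(filters)) if filters else None
    sched = d.pop("laser_schedule", None)
    if sched is not None:
        sched = tuple((float(w), int(n)) for w, n in sched)
    return RunConfig(
        species=tuple(species),
        excitation=excitation,
        laser_schedule=sched,
        optics=optics,
        camera=camera,
        background=background,
        drift=drift,
        filters=filters,
        **d,
    )


def _plain(obj):
    """Recursively convert tuples / numpy scalars to YAML/JSON-native types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config_to_dict(config)), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_plain(config_to_dict(config)), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_ground_truth(ground_truth: pd.DataFrame, path) -> None:
    """Write the per-(event, frame) ground-truth table as CSV.

    Frames are 1-based and match TIFF page order; an empty table produces a
    header-only file.
    """
    df = ground_truth.reindex(columns=GROUND_TRUTH_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stack(stack: np.ndarray, path, pixel_size_nm: float) -> None:
    """Write the stack as a 16-bit multi-page TIFF with pixel-size metadata."""
    pixels_per_cm = 1e7 / pixel_size_nm
    tifffile.imwrite(
        path,
        np.asarray(stack, dtype=np.uint16),
        photometric="minisblack",
        resolution=(pixels_per_cm, pixels_per_cm),
        resolutionunit="CENTIMETER",
    )


def write_outputs(result: SimulationResult, outdir, stem: str = "run") -> dict:
    """Write TIFF stack, ground-truth CSV, drift CSV and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": str(outdir / f"{stem}_stack.tif"),
        "ground_truth": str(outdir / f"{stem}_ground_truth.csv"),
        "manifest": str(outdir / f"{stem}_manifest.json"),
    }
    write_stack(result.stack, paths["stack"], result.manifest["pixel_size_nm"])
    write_ground_truth(result.ground_truth, paths["ground_truth"])
    if result.trajectory is not None:
        paths["drift"] = str(outdir / f"{stem}_drift.csv")
        traj = result.trajectory
        cols = {"frame": np.arange(1, traj.n_frames + 1)}
        for ax, name in zip(range(traj.offsets.shape[1]), ("x", "y", "z")):
            cols[f"d{name}_nm"] = traj.offsets[:, ax]
            cols[f"v{name}_nm_s"] = traj.velocities[:, ax]
        pd.DataFrame(cols).to_csv(paths["drift"], index=False, float_format="%.9g")
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return paths
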