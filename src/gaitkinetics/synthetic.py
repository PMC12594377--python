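"""Synthetic multimodal gait simulator with a known linear forward model.

The simulator emulates the structure of a treadmill-gait dataset recorded
with two smartphone cameras, eight body-worn IMUs and per-frame kinetics
targets (knee adduction moment, knee flexion moment and 3-D ground reaction
forces), all at 100 Hz:

* each subject's 3-D joint paths are a truncated Fourier series (gait-cycle
  periodicity, decaying harmonics) around a standing skeleton, with
  subject-level jitter of every coefficient;
* camera 1 views the sagittal plane (anterior-posterior, vertical), camera 2
  the frontal plane (mediolateral, vertical); projections are scaled by the
  subject's height, perturbed with Gaussian measurement noise, then
  re-centered per frame at the mid-point of the two hip projections;
* each IMU reports the true acceleration of its attachment site plus
  gravity, and a synthetic segment angular velocity, both with low noise;
* kinetics are a fixed linear function of the true joint positions and
  velocities plus a term proportional to the true IMU-site accelerations —
  the privileged signal the IMUs observe directly and the cameras can only
  approach by double differencing noisy positions.

Because the forward model is linear and known per subject, training,
knowledge transfer and evaluation can be tested end to end, and ordinary
least squares recovers the coefficients exactly when all noise is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DimensionError, InvalidInputError
from .kinematics import augment

__all__ = [
    "SimConfig",
    "SubjectRecording",
    "Trial",
    "SkeletonGraph",
    "WindowedDataset",
    "generate_dataset",
    "forward_kinetics",
    "window_dataset",
    "pad_step_to_length",
    "trim_padded_step",
    "DEFAULT_JOINTS",
    "DEFAULT_EDGES",
    "IMU_SITES",
    "KINETIC_COMPONENTS",
]

#: canonical 11-joint roster (a tree rooted at the neck)
DEFAULT_JOINTS = (
    "head", "neck", "mid_hip",
    "l_shoulder", "r_shoulder",
    "l_hip", "r_hip",
    "l_knee", "r_knee",
    "l_ankle", "r_ankle",
)

DEFAULT_EDGES = (
    ("head", "neck"),
    ("neck", "l_shoulder"),
    ("neck", "r_shoulder"),
    ("neck", "mid_hip"),
    ("mid_hip", "l_hip"),
    ("mid_hip", "r_hip"),
    ("l_hip", "l_knee"),
    ("r_hip", "r_knee"),
    ("l_knee", "l_ankle"),
    ("r_knee", "r_ankle"),
)

#: attachment joints of the 8 IMUs (trunk, pelvis, both thighs/shanks read
#: at the distal joint, both feet at the ankle)
IMU_SITES = ("neck", "mid_hip", "l_hip", "r_hip", "l_knee", "r_knee",
             "l_ankle", "r_ankle")

#: fixed order of the five kinetics components
KINETIC_COMPONENTS = ("kam", "kfm", "grf_ml", "grf_v", "grf_ap")

_GRAVITY = np.array([0.0, 9.81, 0.0])  # axes: (AP, vertical, ML)

# standing pose for a 1.76 m reference subject, axes (AP, vertical, ML), metres
_BASE_POSE = {
    "head": (0.0, 1.70, 0.0),
    "neck": (0.0, 1.50, 0.0),
    "mid_hip": (0.0, 0.95, 0.0),
    "l_shoulder": (0.0, 1.45, 0.20),
    "r_shoulder": (0.0, 1.45, -0.20),
    "l_hip": (0.0, 0.95, 0.10),
    "r_hip": (0.0, 0.95, -0.10),
    "l_knee": (0.0, 0.50, 0.10),
    "r_knee": (0.0, 0.50, -0.10),
    "l_ankle": (0.0, 0.08, 0.10),
    "r_ankle": (0.0, 0.08, -0.10),
}

# per-joint motion amplitude scale (AP, vertical, ML): legs move most
_MOTION_SCALE = {
    "head": (0.02, 0.02, 0.01),
    "neck": (0.02, 0.02, 0.01),
    "mid_hip": (0.03, 0.03, 0.02),
    "l_shoulder": (0.05, 0.02, 0.02),
    "r_shoulder": (0.05, 0.02, 0.02),
    "l_hip": (0.03, 0.03, 0.02),
    "r_hip": (0.03, 0.03, 0.02),
    "l_knee": (0.15, 0.05, 0.02),
    "r_knee": (0.15, 0.05, 0.02),
    "l_ankle": (0.25, 0.08, 0.03),
    "r_ankle": (0.25, 0.08, 0.03),
}

_REFERENCE_HEIGHT = 1.76


@dataclass
class SimConfig:
    """Parameters of the synthetic gait cohort."""

    n_subjects: int = 17
    trials_per_subject: int = 3
    trial_length: int = 600          # frames
    sampling_rate: float = 100.0     # Hz
    gait_frequency_range: tuple[float, float] = (0.8, 1.2)  # Hz
    n_harmonics: int = 3
    camera_noise_sd: float = 0.005   # height-normalized position units
    imu_noise_sd: float = 0.02       # m/s^2 and rad/s
    kinetics_noise_sd: float = 0.02  # target units
    subject_effect_sd: float = 0.1   # relative coefficient jitter
    freq_detune_sd: float = 0.02     # relative per-channel frequency spread
    seed: int = 0
    window: int = 50                 # ΔT

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ConfigError("counts must be >= 1")
        if self.n_harmonics < 1:
            raise ConfigError("n_harmonics must be >= 1")
        for name in ("camera_noise_sd", "imu_noise_sd", "kinetics_noise_sd",
                     "subject_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.trial_length < self.window:
            raise ConfigError(
                f"trial_length ({self.trial_length}) must be >= window "
                f"({self.window})"
            )
        lo, hi = self.gait_frequency_range
        if not (0 < lo <= hi):
            raise ConfigError("gait_frequency_range must be positive and ordered")


@dataclass
class SkeletonGraph:
    """The 11-node joint graph used by the graph convolution."""

    node_labels: tuple[str, ...] = DEFAULT_JOINTS
    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES
    normalize: bool = True  # self-loops + row normalization

    def __post_init__(self) -> None:
        labels = set(self.node_labels)
        for a, b in self.edges:
            if a not in labels or b not in labels:
                raise ConfigError(f"edge ({a}, {b}) references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def adjacency(self) -> np.ndarray:
        """Adjacency matrix; symmetric binary, optionally with self-loops
        and row normalization (each row then sums to 1)."""
        n = self.n_nodes
        idx = {name: i for i, name in enumerate(self.node_labels)}
        a = np.zeros((n, n))
        for u, v in self.edges:
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
        if self.normalize:
            a = a + np.eye(n)
            a = a / a.sum(axis=1, keepdims=True)
        return a


@dataclass
class Trial:
    """One walking trial of one subject (all arrays time-major)."""

    true_positions: np.ndarray     # [T, 11, 3] metres
    true_velocities: np.ndarray    # [T, 11, 3] m/s
    true_accelerations: np.ndarray  # [T, 8, 3] m/s^2 at the IMU sites
    camera: np.ndarray             # [T, 11, 4] normalized, mid-hip origin
    imu_acc: np.ndarray            # [T, 8, 3]
    imu_gyr: np.ndarray            # [T, 8, 3]
    kinetics: np.ndarray           # [T, 5]
    gait_frequency: float = 0.0


@dataclass
class SubjectRecording:
    """All trials of one subject plus the subject's true forward model."""

    subject_id: str
    height: float
    mass: float
    trials: list[Trial]
    forward_coefficients: dict[str, np.ndarray]


@dataclass
class WindowedDataset:
    """Windowed multimodal samples ready for model training.

    ``jcp``/``jcv``/``jca`` are the three video modalities (44 channels,
    joint-major layout), ``acc``/``gyr`` the IMU modalities (24 channels,
    sensor-major), ``kinetics`` the 5 per-frame targets.  ``meta`` holds
    ``(subject_id, trial_index, start_frame)`` per window so overlapping
    predictions can be averaged back onto frames.
    """

    jcp: np.ndarray
    jcv: np.ndarray
    jca: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    kinetics: np.ndarray
    subject_ids: np.ndarray
    meta: list[tuple[str, int, int]]
    window: int

    def __len__(self) -> int:
        return self.jcp.shape[0]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    def subset(self, subjects) -> "WindowedDataset":
        wanted = set(subjects)
        mask = np.array([s in wanted for s in self.subject_ids])
        return WindowedDataset(
            jcp=self.jcp[mask], jcv=self.jcv[mask], jca=self.jca[mask],
            acc=self.acc[mask], gyr=self.gyr[mask],
            kinetics=self.kinetics[mask],
            subject_ids=self.subject_ids[mask],
            meta=[m for m, keep in zip(self.meta, mask) if keep],
            window=self.window,
        )


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def forward_kinetics(
    true_positions: np.ndarray,
    true_velocities: np.ndarray,
    true_accelerations: np.ndarray,
    coefficients: dict[str, np.ndarray],
) -> np.ndarray:
    """Noise-free kinetics from the linear forward model.

    ``kinetics = P·Wp + V·Wv + A·Wa`` where P, V flatten the [T, 11, 3]
    joint positions/velocities and A flattens the [T, 8, 3] accelerations at
    the IMU sites.  The map is linear and homogeneous: zero input gives zero
    output and doubling every input doubles the output.
    """
    p = np.asarray(true_positions, dtype=float)
    v = np.asarray(true_velocities, dtype=float)
    a = np.asarray(true_accelerations, dtype=float)
    if p.shape[0] != v.shape[0] or p.shape[0] != a.shape[0]:
        raise DimensionError("position, velocity and acceleration lengths differ")
    T = p.shape[0]
    wp, wv, wa = coefficients["Wp"], coefficients["Wv"], coefficients["Wa"]
    pf, vf, af = p.reshape(T, -1), v.reshape(T, -1), a.reshape(T, -1)
    if pf.shape[1] != wp.shape[0] or vf.shape[1] != wv.shape[0] \
            or af.shape[1] != wa.shape[0]:
        raise DimensionError("kinematic feature widths do not match coefficients")
    return pf @ wp + vf @ wv + af @ wa


def _draw_coefficients(rng: np.random.Generator, n_joints: int, n_imu: int
                       ) -> dict[str, np.ndarray]:
    """Population-level forward coefficients.

    Scales are chosen so that on typical simulated gait the position,
    velocity and acceleration terms each contribute order-one variation to
    the targets: joint excursions are ~0.05-0.25 m, velocities ~0.2-1.5 m/s
    and IMU-site accelerations up to ~10 m/s^2.
    """
    k = len(KINETIC_COMPONENTS)
    return {
        "Wp": rng.normal(0.0, 0.5, size=(3 * n_joints, k)),
        "Wv": rng.normal(0.0, 0.3, size=(3 * n_joints, k)),
        "Wa": rng.normal(0.0, 0.05, size=(3 * n_imu, k)),
    }


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _fourier_motion(
    t: np.ndarray,
    freqs: np.ndarray,   # [J, 3] per-channel fundamental frequency, Hz
    amps: np.ndarray,    # [J, 3, H]
    phases: np.ndarray,  # [J, 3, H]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, velocities and accelerations of the Fourier gait model.

    Each joint-axis channel carries its own (slightly detuned) fundamental,
    emulating step-to-step variability; this also keeps the 90 kinematic
    features of the forward model linearly independent over a trial, so the
    forward coefficients are identifiable from noise-free data.
    """
    H = amps.shape[-1]
    harmonics = np.arange(1, H + 1)
    omega = 2.0 * np.pi * freqs[:, :, None] * harmonics  # [J, 3, H]
    arg = omega[None] * t[:, None, None, None] + phases[None]  # [T, J, 3, H]
    pos = (amps[None] * np.sin(arg)).sum(axis=-1)
    vel = (amps[None] * omega[None] * np.cos(arg)).sum(axis=-1)
    acc = (-amps[None] * omega[None] ** 2 * np.sin(arg)).sum(axis=-1)
    return pos, vel, acc


def _project_cameras(
    positions: np.ndarray, height: float, noise_sd: float,
    rng: np.random.Generator, joints: tuple[str, ...],
) -> np.ndarray:
    """Two-camera projection -> noise -> mid-hip centering, height units.

    Returns [T, J, 4] with per-joint layout (cam1 x, cam1 y, cam2 x, cam2 y).
    """
    T, J, _ = positions.shape
    cam = np.empty((T, J, 4))
    cam[..., 0] = positions[..., 0]   # sagittal: anterior-posterior
    cam[..., 1] = positions[..., 1]   # sagittal: vertical
    cam[..., 2] = positions[..., 2]   # frontal: mediolateral
    cam[..., 3] = positions[..., 1]   # frontal: vertical
    cam /= height
    if noise_sd > 0:
        cam += rng.normal(0.0, noise_sd, size=cam.shape)
    li, ri = joints.index("l_hip"), joints.index("r_hip")
    for pair in ((0, 1), (2, 3)):     # per camera
        origin = 0.5 * (cam[:, li, pair] + cam[:, ri, pair])  # [T, 2]
        cam[:, :, pair] -= origin[:, None, :]
    return cam


def generate_dataset(cfg: SimConfig) -> list[SubjectRecording]:
    """Generate a deterministic multimodal cohort from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    joints = DEFAULT_JOINTS
    J, H = len(joints), cfg.n_harmonics
    base_pose = np.array([_BASE_POSE[j] for j in joints])        # [J, 3]
    motion_scale = np.array([_MOTION_SCALE[j] for j in joints])  # [J, 3]

    # population-level gait shape and forward model
    base_amps = (motion_scale[:, :, None]
                 / np.arange(1, H + 1)[None, None, :] ** 2
                 * np.abs(rng.normal(1.0, 0.3, size=(J, 3, H))))
    base_phases = rng.uniform(0.0, 2.0 * np.pi, size=(J, 3, H))
    base_coeffs = _draw_coefficients(rng, J, len(IMU_SITES))
    base_gyro_amp = 0.3 * np.abs(rng.normal(1.0, 0.3,
                                            size=(len(IMU_SITES), 3, H)))
    base_gyro_phase = rng.uniform(0.0, 2.0 * np.pi, size=(len(IMU_SITES), 3, H))

    imu_idx = np.array([joints.index(s) for s in IMU_SITES])
    t = np.arange(cfg.trial_length) / cfg.sampling_rate
    recordings: list[SubjectRecording] = []
    for s in range(cfg.n_subjects):
        height = float(rng.normal(1.76, 0.06))
        mass = float(rng.normal(67.3, 8.3))
        jit = cfg.subject_effect_sd

        def jitter(a: np.ndarray) -> np.ndarray:
            return a * (1.0 + jit * rng.normal(size=a.shape))

        amps = jitter(base_amps) * (height / _REFERENCE_HEIGHT)
        detune = 1.0 + cfg.freq_detune_sd * rng.normal(size=(J, 3))
        phases = base_phases + 0.1 * jit * rng.normal(size=base_phases.shape)
        coeffs = {k: jitter(v) for k, v in base_coeffs.items()}
        gyro_amp = jitter(base_gyro_amp)
        gyro_phase = base_gyro_phase + 0.1 * jit * rng.normal(
            size=base_gyro_phase.shape)

        trials: list[Trial] = []
        for _ in range(cfg.trials_per_subject):
            freq = float(rng.uniform(*cfg.gait_frequency_range))
            trial_phase = float(rng.uniform(0.0, 2.0 * np.pi))
            pos, vel, acc = _fourier_motion(
                t + trial_phase / (2.0 * np.pi * freq), freq * detune,
                amps, phases)
            pos = pos + base_pose[None] * (height / _REFERENCE_HEIGHT)
            acc_sites = acc[:, imu_idx, :]                       # [T, 8, 3]
            camera = _project_cameras(pos, height, cfg.camera_noise_sd,
                                      rng, joints)
            imu_acc = acc_sites + _GRAVITY[None, None, :]
            if cfg.imu_noise_sd > 0:
                imu_acc = imu_acc + rng.normal(
                    0.0, cfg.imu_noise_sd, size=imu_acc.shape)
            # synthetic segment angular velocities (same periodic structure)
            omega = 2.0 * np.pi * freq * np.arange(1, H + 1)
            arg = (omega[None, None, None, :]
                   * (t + trial_phase / (2.0 * np.pi * freq))[:, None, None, None]
                   + gyro_phase[None])
            imu_gyr = (gyro_amp[None] * omega[None, None, None, :]
                       * np.cos(arg)).sum(axis=-1)
            if cfg.imu_noise_sd > 0:
                imu_gyr = imu_gyr + rng.normal(
                    0.0, cfg.imu_noise_sd, size=imu_gyr.shape)
            kin = forward_kinetics(pos, vel, acc_sites, coeffs)
            if cfg.kinetics_noise_sd > 0:
                kin = kin + rng.normal(0.0, cfg.kinetics_noise_sd,
                                       size=kin.shape)
            trials.append(Trial(
                true_positions=pos,
                true_velocities=vel,
                true_accelerations=acc_sites,
                camera=camera,
                imu_acc=imu_acc,
                imu_gyr=imu_gyr,
                kinetics=kin,
                gait_frequency=freq,
            ))
        recordings.append(SubjectRecording(
            subject_id=f"S{s + 1:02d}",
            height=height, mass=mass,
            trials=trials, forward_coefficients=coeffs,
        ))
    return recordings


# ---------------------------------------------------------------------------
# windowing and step padding
# ---------------------------------------------------------------------------

def window_dataset(
    recordings: list[SubjectRecording],
    window: int = 50,
    stride: int | None = None,
    scale_by_rate: bool = False,
    sampling_rate: float = 100.0,
) -> WindowedDataset:
    """Slice trials into half-open windows ``[t, t+window)``.

    The velocity and acceleration modalities are differentiated per whole
    trial *before* windowing, so window edges carry real derivatives (only
    the trial's own first/last frames are zeroed).  Trials shorter than the
    window are skipped with a warning.  ``stride`` defaults to ``window``
    (non-overlapping).
    """
    if stride is None:
        stride = window
    if stride <= 0:
        raise ConfigError("stride must be positive")
    if window < 3:
        raise ConfigError("window must be >= 3 frames")
    jcp_w, jcv_w, jca_w, acc_w, gyr_w, kin_w = [], [], [], [], [], []
    ids: list[str] = []
    meta: list[tuple[str, int, int]] = []
    for rec in recordings:
        for trial_idx, trial in enumerate(rec.trials):
            T = trial.camera.shape[0]
            if T < window:
                warnings.warn(
                    f"trial {trial_idx} of {rec.subject_id} has {T} frames "
                    f"< window {window}; skipped",
                    stacklevel=2,
                )
                continue
            flat = trial.camera.reshape(T, -1)  # [T, 44] joint-major
            aug = augment(flat, sampling_rate, scale_by_rate)
            acc = trial.imu_acc.reshape(T, -1)
            gyr = trial.imu_gyr.reshape(T, -1)
            n_windows = (T - window) // stride + 1
            for w in range(n_windows):
                start = w * stride
                sl = slice(start, start + window)
                jcp_w.append(aug.positions[sl])
                jcv_w.append(aug.velocities[sl])
                jca_w.append(aug.accelerations[sl])
                acc_w.append(acc[sl])
                gyr_w.append(gyr[sl])
                kin_w.append(trial.kinetics[sl])
                ids.append(rec.subject_id)
                meta.append((rec.subject_id, trial_idx, start))
    if not jcp_w:
        shape = lambda f: np.zeros((0, window, f))  # noqa: E731
        return WindowedDataset(shape(44), shape(44), shape(44), shape(24),
                               shape(24), shape(5),
                               np.array([], dtype=object), [], window)
    return WindowedDataset(
        jcp=np.stack(jcp_w), jcv=np.stack(jcv_w), jca=np.stack(jca_w),
        acc=np.stack(acc_w), gyr=np.stack(gyr_w), kinetics=np.stack(kin_w),
        subject_ids=np.array(ids, dtype=object), meta=meta, window=window,
    )


def pad_step_to_length(step: np.ndarray, target_length: int = 152
                       ) -> tuple[np.ndarray, int]:
    """Zero-pad a step to ``target_length`` frames; returns the true length.

    Mirrors the convention of padding shorter steps with trailing zeros to
    the duration of the longest step (152 samples) so they can be stacked.
    """
    step = np.asarray(step)
    T = step.shape[0]
    if T > target_length:
        raise InvalidInputError(
            f"step has {T} frames, longer than target {target_length}"
        )
    if T == target_length:
        return step.copy(), T
    pad_shape = (target_length - T,) + step.shape[1:]
    return np.concatenate([step, np.zeros(pad_shape, dtype=step.dtype)]), T


def trim_padded_step(padded: np.ndarray, true_length: int) -> np.ndarray:
    """Remove the trailing zero padding, recovering the original step."""
    padded = np.asarray(padded)
    if not 0 < true_length <= padded.shape[0]:
        raise InvalidInputError("true_length outside the padded array")
    return padded[:true_length].copy()
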