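"""Synthetic multi-subject, multi-speed gait kinematics with known moments.

Generates periodic joint-angle waveforms for the 18 lower-limb kinematic
channels recorded in pediatric treadmill gait studies (ankle, knee, hip,
pelvis and trunk angles for both sides), organized as time-normalized gait
cycles for a cohort of subjects walking at three speeds. Each channel is a
truncated Fourier series; subjects perturb the shared template in amplitude
and phase, and walking speed scales amplitudes multiplicatively. A known
forward model maps the six sagittal joint angles to joint moments
(stiffness + damping + cross-joint coupling + saturation), so that every
downstream learning stage can be validated against ground truth.

All randomness flows from a single dataset seed through named substreams,
making regeneration bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError

# The 18 kinematic channels, in the conventional alphabetical listing.
CHANNELS: tuple[str, ...] = (
    "Lankleflex",
    "Lanklepron",
    "Lhipabad",
    "Lhipflex",
    "Lhiprot",
    "Lkneeflex",
    "Pelvicobl",
    "Pelvicrot",
    "Pelvictil",
    "Rankleflex",
    "Ranklepron",
    "Rhipabad",
    "Rhipflex",
    "Rhiprot",
    "Rkneeflex",
    "Trunkflex",
    "Trunkrot",
    "Trunktilt",
)

# Fixed joint order used everywhere downstream (cross-joint matrices etc.).
JOINT_ORDER: tuple[str, ...] = ("LKnee", "RKnee", "LAnkle", "RAnkle", "LHip", "RHip")

# Sagittal angle channel feeding each joint's moment, in JOINT_ORDER.
SAGITTAL_ANGLES: tuple[str, ...] = (
    "Lkneeflex",
    "Rkneeflex",
    "Lankleflex",
    "Rankleflex",
    "Lhipflex",
    "Rhipflex",
)

# Moment channel names (flexion/extension moments, N·m/kg), in JOINT_ORDER.
MOMENT_CHANNELS: tuple[str, ...] = (
    "LKneeFlex",
    "RKneeFlex",
    "LAnkleFlex",
    "RAnkleFlex",
    "LHipFlex",
    "RHipFlex",
)

AGE_GROUPS: tuple[str, ...] = ("3-6", "7-8", "9-10", "11-12", ">=13")
# Cohort stratum sizes of the emulated 55-child dataset.
AGE_GROUP_COUNTS: tuple[int, ...] = (11, 10, 15, 11, 8)

SPEEDS: tuple[str, ...] = ("slow", "comfortable", "fast")


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, order-independent random substream derived from one seed.

    String keys are hashed with crc32 so the spawn key is stable across
    processes and sessions.
    """
    ints = tuple(zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=ints))


# ---------------------------------------------------------------------------
# Subject profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    """One subject: age stratum, anthropometrics, and template perturbation.

    `amp_factor` multiplies each channel's oscillatory amplitude and
    `phase_offset` (radians) shifts its fundamental phase; both are drawn
    once per (dataset seed, subject) and are what make cross-subject
    waveforms vary while staying individually consistent.
    """

    subject_id: str
    age_group: str
    body_mass: float  # kg
    leg_length: float  # m
    amp_factor: dict[str, float] = field(default_factory=dict)
    phase_offset: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.body_mass <= 0 or self.leg_length <= 0:
            raise InvalidArgumentError("body_mass and leg_length must be positive")
        if self.age_group not in AGE_GROUPS:
            raise InvalidArgumentError(f"unknown age group {self.age_group!r}")


# Anthropometric centers per age stratum (mass kg, leg length m); values are
# plausible pediatric means spanning the cohort's 3-17 year range.
_GROUP_MASS = (17.0, 26.0, 33.0, 42.0, 52.0)
_GROUP_LEG = (0.55, 0.64, 0.72, 0.79, 0.85)

# Subject-to-subject template variability (dimensionless / radians); the
# emulated cohort was designed for substantial inter-subject variability,
# so individual waveforms differ markedly in amplitude and timing.
_AMP_FACTOR_SD = 0.25
_PHASE_OFFSET_SD = 0.45


def make_subject_profiles(n_subjects: int, seed: int) -> list[SubjectProfile]:
    """Create `n_subjects` profiles with age strata allocated proportionally.

    Strata are assigned by largest-remainder proportional allocation to the
    cohort's (11, 10, 15, 11, 8)/55 weights, then shuffled, so n_subjects=55
    reproduces the cohort composition exactly and every stratum is covered
    whenever n_subjects >= 5.
    """
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    weights = np.asarray(AGE_GROUP_COUNTS, dtype=float)
    weights /= weights.sum()
    quota = weights * n_subjects
    counts = np.floor(quota).astype(int)
    remainder = n_subjects - counts.sum()
    for idx in np.argsort(-(quota - counts), kind="stable")[:remainder]:
        counts[idx] += 1
    groups = np.repeat(np.arange(len(AGE_GROUPS)), counts)
    substream(seed, "strata").shuffle(groups)

    profiles = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        rng = substream(seed, "subjects", i)
        g = int(groups[i])
        mass = float(_GROUP_MASS[g] * np.exp(rng.normal(0.0, 0.12)))
        leg = float(_GROUP_LEG[g] * np.exp(rng.normal(0.0, 0.05)))
        amp = {c: float(np.clip(rng.normal(1.0, _AMP_FACTOR_SD), 0.4, 1.8)) for c in CHANNELS}
        phase = {c: float(rng.normal(0.0, _PHASE_OFFSET_SD)) for c in CHANNELS}
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                age_group=AGE_GROUPS[g],
                body_mass=mass,
                leg_length=leg,
                amp_factor=amp,
                phase_offset=phase,
            )
        )
    return profiles


def neutral_profile(subject_id: str = "S000", age_group: str = "9-10") -> SubjectProfile:
    """A profile with zero perturbation (amplitude factors 1, phase offsets 0)."""
    return SubjectProfile(
        subject_id=subject_id,
        age_group=age_group,
        body_mass=33.0,
        leg_length=0.72,
        amp_factor={c: 1.0 for c in CHANNELS},
        phase_offset={c: 0.0 for c in CHANNELS},
    )


# ---------------------------------------------------------------------------
# Gait waveform template
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitTemplate:
    """Per-channel truncated Fourier series defining the canonical waveforms.

    For channel c, the noise-free waveform over cycle phase u in [0, 1) is

        y_c(u) = mean_c + s(v) * A_c * sum_k amp_{c,k} sin(2 pi k u + phi_{c,k})

    where s(v) is the per-speed amplitude scaling, A_c the subject amplitude
    factor. Right-side channels mirror their left counterpart half a cycle
    out of phase, giving the bilateral anti-phase structure of gait.
    """

    mean: dict[str, float]
    harmonics: dict[str, tuple[tuple[float, float], ...]]  # channel -> ((amp °, phase rad), ...)
    speed_scaling: dict[str, float]

    def __post_init__(self):
        if set(self.mean) != set(CHANNELS) or set(self.harmonics) != set(CHANNELS):
            missing = set(CHANNELS) ^ (set(self.mean) | set(self.harmonics))
            raise SchemaError(f"template channels must match the 18-channel set; mismatch near {sorted(missing)}")
        if any(len(h) < 2 for h in self.harmonics.values()):
            raise InvalidArgumentError("each channel needs K >= 2 harmonics")

    def n_harmonics(self) -> int:
        return max(len(h) for h in self.harmonics.values())

    def evaluate(
        self,
        channel: str,
        u: np.ndarray,
        speed: str = "comfortable",
        amp_factor: float = 1.0,
        phase_offset: float = 0.0,
    ) -> np.ndarray:
        """Evaluate one channel's series on cycle-phase grid u (cycles)."""
        if speed not in self.speed_scaling:
            raise InvalidArgumentError(f"unknown speed {speed!r}; expected one of {sorted(self.speed_scaling)}")
        y = np.full_like(np.asarray(u, dtype=float), self.mean[channel])
        scale = self.speed_scaling[speed] * amp_factor
        for k, (amp, phi) in enumerate(self.harmonics[channel], start=1):
            y = y + scale * amp * np.sin(2.0 * np.pi * k * u + phi + phase_offset)
        return y


# Base amplitudes (degrees) for the left/central channels; harmonics decay
# roughly geometrically, matching the smooth low-frequency shape of gait
# curves. Peak-to-peak ranges: knee ~60 deg, hip ~40 deg, ankle ~20 deg,
# pelvis/trunk a few degrees.
_BASE_WAVEFORMS: dict[str, tuple[float, tuple[float, ...]]] = {
    "ankleflex": (0.0, (10.0, 6.0, 3.0, 1.5)),
    "anklepron": (0.0, (4.0, 2.0, 1.0, 0.5)),
    "hipabad": (0.0, (6.0, 3.0, 1.5, 0.8)),
    "hipflex": (10.0, (20.0, 5.0, 2.0, 1.0)),
    "hiprot": (0.0, (5.0, 2.5, 1.2, 0.6)),
    "kneeflex": (25.0, (30.0, 12.0, 5.0, 2.0)),
    "Pelvicobl": (0.0, (3.0, 1.5, 0.8, 0.4)),
    "Pelvicrot": (0.0, (5.0, 2.0, 1.0, 0.5)),
    "Pelvictil": (12.0, (2.0, 1.0, 0.5, 0.2)),
    "Trunkflex": (5.0, (2.0, 1.0, 0.5, 0.2)),
    "Trunkrot": (0.0, (4.0, 2.0, 1.0, 0.5)),
    "Trunktilt": (2.0, (2.0, 1.0, 0.5, 0.3)),
}

DEFAULT_SPEED_SCALING = {"slow": 0.85, "comfortable": 1.0, "fast": 1.15}


def default_template(speed_scaling: dict[str, float] | None = None) -> GaitTemplate:
    """The package's canonical 18-channel, K=4 gait template.

    Harmonic phases follow a fixed deterministic pattern per channel;
    right-side channels are the left waveform shifted by half a cycle
    (phase shift pi*k on harmonic k).
    """
    mean: dict[str, float] = {}
    harmonics: dict[str, tuple[tuple[float, float], ...]] = {}
    base_names = sorted(_BASE_WAVEFORMS)
    for ch in CHANNELS:
        if ch[0] in "LR" and ch[1:] in _BASE_WAVEFORMS:
            key, side = ch[1:], ch[0]
        else:
            key, side = ch, None
        m, amps = _BASE_WAVEFORMS[key]
        ci = base_names.index(key)
        hs = []
        for k, a in enumerate(amps, start=1):
            phi = 0.9 * ci + 0.5 * k  # fixed, channel- and harmonic-specific
            if side == "R":
                phi += np.pi * k  # half-cycle shift: contralateral limb
            hs.append((a, float(phi % (2 * np.pi))))
        mean[ch] = m
        harmonics[ch] = tuple(hs)
    return GaitTemplate(
        mean=mean,
        harmonics=harmonics,
        speed_scaling=dict(speed_scaling or DEFAULT_SPEED_SCALING),
    )


# ---------------------------------------------------------------------------
# Cycles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitCycle:
    """One time-normalized gait cycle: (18, T) angle array plus metadata."""

    values: np.ndarray  # (n_channels, T), degrees
    channel_names: tuple[str, ...]
    subject_id: str
    speed: str
    cycle_id: str

    def __post_init__(self):
        if tuple(self.channel_names) != CHANNELS:
            raise SchemaError("cycle channels must equal the canonical 18-channel set in order")
        if self.values.shape[0] != len(CHANNELS):
            raise SchemaError(f"expected {len(CHANNELS)} channel rows, got {self.values.shape[0]}")

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[self.channel_names.index(name)]
        except ValueError:
            raise SchemaError(f"cycle is missing channel {name!r}") from None


def synthesize_cycle(
    profile: SubjectProfile,
    template: GaitTemplate,
    speed: str,
    cycle_length: int = 100,
    noise_sd: float = 0.5,
    seed: int = 0,
    cycle_id: str = "c0",
) -> GaitCycle:
    """Generate one cycle: template series x speed scaling x subject
    perturbation, plus i.i.d. Gaussian measurement noise (degrees).

    The phase grid is u = t/T for t = 0..T-1, so the noise-free waveform is
    exactly periodic with period T (sample T would equal sample 0).
    """
    if cycle_length < 8:
        raise InvalidArgumentError("cycle_length must be >= 8")
    if speed not in template.speed_scaling:
        raise InvalidArgumentError(f"unknown speed {speed!r}; expected one of {sorted(template.speed_scaling)}")
    u = np.arange(cycle_length) / cycle_length
    rng = substream(seed, "noise", profile.subject_id, speed, cycle_id)
    rows = []
    for ch in CHANNELS:
        y = template.evaluate(
            ch,
            u,
            speed=speed,
            amp_factor=profile.amp_factor.get(ch, 1.0),
            phase_offset=profile.phase_offset.get(ch, 0.0),
        )
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=cycle_length)
        rows.append(y)
    return GaitCycle(
        values=np.asarray(rows),
        channel_names=CHANNELS,
        subject_id=profile.subject_id,
        speed=speed,
        cycle_id=cycle_id,
    )


# ---------------------------------------------------------------------------
# Angle -> moment forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MomentModelParams:
    """Ground-truth angle->moment mapping for the six sagittal joints.

    moment_j(t) = clip( a_j θ_j(t) + b_j Δθ_j(t) + Σ_{k≠j} c_jk θ_k(t),
                        ±s_j ) + ε,   ε ~ N(0, σ²)

    with θ in degrees, Δ the first central difference per sample, and all
    gains in (N·m/kg) per degree (or per °/sample for damping). Diagonal
    dominance |a_j| > Σ_k |c_jk| makes the same-joint angle the strongest
    predictor of each moment, mirroring real inverse-dynamics structure.
    """

    stiffness: np.ndarray  # (6,)  a_j
    damping: np.ndarray  # (6,)  b_j
    coupling: np.ndarray  # (6,6) c_jk, zero diagonal
    saturation: np.ndarray | None  # (6,) s_j, None = no clipping
    noise_sd: float = 0.0

    def __post_init__(self):
        a = np.asarray(self.stiffness, dtype=float)
        c = np.asarray(self.coupling, dtype=float)
        object.__setattr__(self, "stiffness", a)
        object.__setattr__(self, "damping", np.asarray(self.damping, dtype=float))
        object.__setattr__(self, "coupling", c)
        if self.saturation is not None:
            object.__setattr__(self, "saturation", np.asarray(self.saturation, dtype=float))
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if c.shape != (6, 6) or a.shape != (6,):
            raise SchemaError("stiffness must be (6,), coupling (6,6)")
        if np.any(np.abs(np.diag(c)) > 0):
            raise InvalidArgumentError("coupling diagonal must be zero")
        if np.any(np.abs(a) <= np.abs(c).sum(axis=1)):
            raise InvalidArgumentError("moment model must be diagonally dominant (|a_j| > sum_k |c_jk|)")


def default_moment_params(noise_sd: float = 0.02) -> MomentModelParams:
    """Defaults chosen so all six moments have comparable ~0.7 N·m/kg spread.

    Stiffness gains are inversely proportional to each angle's template
    standard deviation (knee swings ~23 deg, hip ~15 deg, ankle ~9 deg);
    coupling is an order of magnitude weaker than stiffness.
    """
    a = np.array([0.030, 0.030, 0.080, 0.080, 0.048, 0.048])
    # angular velocity contributes a meaningful share of the moment
    # (real inverse-dynamics moments depend on segment accelerations)
    b = np.full(6, 0.10)
    c = np.full((6, 6), 0.0025)
    signs = np.array([(-1.0) ** (j + k) for j in range(6) for k in range(6)]).reshape(6, 6)
    c = c * signs
    np.fill_diagonal(c, 0.0)
    s = np.full(6, 1.6)
    return MomentModelParams(stiffness=a, damping=b, coupling=c, saturation=s, noise_sd=noise_sd)


def linear_moment_params(noise_sd: float = 0.0) -> MomentModelParams:
    """Pure linear variant (no damping, coupling, saturation, noise) used by
    parameter-recovery experiments: moment_j = a_j θ_j exactly."""
    a = np.array([0.030, 0.030, 0.080, 0.080, 0.048, 0.048])
    return MomentModelParams(
        stiffness=a,
        damping=np.zeros(6),
        coupling=np.zeros((6, 6)),
        saturation=None,
        noise_sd=noise_sd,
    )


def forward_moment_model(cycle: GaitCycle, params: MomentModelParams, seed: int = 0) -> np.ndarray:
    """Map one cycle's sagittal angles to the six joint-moment traces.

    Returns a (6, T) array in N·m/kg, rows in JOINT_ORDER, aligned
    sample-for-sample with the cycle.
    """
    theta = np.stack([cycle.channel(ch) for ch in SAGITTAL_ANGLES])  # (6, T)
    # first central difference with one-sided differences at the ends
    dtheta = np.gradient(theta, axis=1)
    m = (
        params.stiffness[:, None] * theta
        + params.damping[:, None] * dtheta
        + params.coupling @ theta
    )
    if params.saturation is not None:
        m = np.clip(m, -params.saturation[:, None], params.saturation[:, None])
    if params.noise_sd > 0:
        rng = substream(seed, "moment-noise", cycle.subject_id, cycle.speed, cycle.cycle_id)
        m = m + rng.normal(0.0, params.noise_sd, size=m.shape)
    return m


# ---------------------------------------------------------------------------
# Dataset assembly and I/O
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDatasetConfig:
    """Everything needed to regenerate a dataset bit-identically."""

    n_subjects: int = 10
    cycles_per_condition: int = 2
    cycle_length: int = 100
    noise_sd: float = 0.5  # degrees, kinematic measurement noise
    moment_noise_sd: float = 0.02  # N·m/kg
    seed: int = 0
    total_cycles: int | None = None  # override: distribute round-robin
    speeds: tuple[str, ...] = SPEEDS
    moment_model: str = "default"  # "default" | "linear"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speeds"] = list(self.speeds)
        return d

    def digest(self) -> str:
        return hashlib.sha1(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def moment_params(self) -> MomentModelParams:
        if self.moment_model == "linear":
            return linear_moment_params(noise_sd=self.moment_noise_sd)
        return default_moment_params(noise_sd=self.moment_noise_sd)


def paper_shape_config(seed: int = 0) -> SyntheticDatasetConfig:
    """Cohort-shaped preset: 55 subjects, 3 speeds, 897 cycles of 100 samples.

    897 is not divisible by 165 subject-speed conditions, so the extra cycles
    are distributed round-robin (the first 72 conditions contribute 6 cycles,
    the rest 5).
    """
    return SyntheticDatasetConfig(n_subjects=55, cycle_length=100, total_cycles=897, seed=seed)


@dataclass
class GaitDataset:
    """Aligned cycles and moment traces plus provenance."""

    cycles: list[GaitCycle]
    moments: list[np.ndarray]  # each (6, T), rows in JOINT_ORDER
    seed: int
    config_digest: str

    def __post_init__(self):
        if len(self.cycles) != len(self.moments):
            raise SchemaError("cycles and moments must align one-to-one")
        for cyc, m in zip(self.cycles, self.moments):
            if m.shape != (len(JOINT_ORDER), cyc.length):
                raise SchemaError("moment trace shape must be (6, cycle length)")

    def __len__(self) -> int:
        return len(self.cycles)


def generate_dataset(config: SyntheticDatasetConfig) -> GaitDataset:
    """Generate the full dataset described by `config`.

    Cycle count is n_subjects x len(speeds) x cycles_per_condition, unless
    `total_cycles` overrides it, in which case cycles are spread round-robin
    over the subject-speed conditions (allowing totals like 897 that do not
    divide evenly).
    """
    profiles = make_subject_profiles(config.n_subjects, config.seed)
    conditions = [(p, s) for p in profiles for s in config.speeds]
    if config.total_cycles is None:
        counts = [config.cycles_per_condition] * len(conditions)
    else:
        base, extra = divmod(config.total_cycles, len(conditions))
        counts = [base + (1 if i < extra else 0) for i in range(len(conditions))]
    params = config.moment_params()
    template = default_template()
    cycles, moments = [], []
    for (profile, speed), n in zip(conditions, counts):
        for j in range(n):
            cid = f"{profile.subject_id}-{speed}-{j}"
            # moments derive from the true (noise-free) kinematics; the
            # recorded angles then carry measurement noise — so labels are
            # clean but inputs are not, as with marker-based capture
            clean = synthesize_cycle(
                profile, template, speed,
                cycle_length=config.cycle_length, noise_sd=0.0,
                seed=config.seed, cycle_id=cid,
            )
            moments.append(forward_moment_model(clean, params, seed=config.seed))
            if config.noise_sd > 0:
                rng = substream(config.seed, "noise", profile.subject_id, speed, cid)
                noisy = clean.values + rng.normal(0.0, config.noise_sd, size=clean.values.shape)
                cycles.append(dataclasses.replace(clean, values=noisy))
            else:
                cycles.append(clean)
    return GaitDataset(cycles=cycles, moments=moments, seed=config.seed, config_digest=config.digest())


def write_dataset(dataset: GaitDataset, out_dir: str | Path) -> Path:
    """Write a dataset as one wide CSV plus a JSON manifest; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for cyc, m in zip(dataset.cycles, dataset.moments):
        df = pd.DataFrame(cyc.values.T, columns=list(cyc.channel_names))
        for j, name in enumerate(MOMENT_CHANNELS):
            df[name] = m[j]
        df.insert(0, "t_index", np.arange(cyc.length))
        df.insert(0, "cycle_id", cyc.cycle_id)
        df.insert(0, "speed", cyc.speed)
        df.insert(0, "subject_id", cyc.subject_id)
        frames.append(df)
    # default float repr round-trips float64 exactly through read_csv
    pd.concat(frames, ignore_index=True).to_csv(out / "cycles.csv", index=False)
    manifest = {
        "seed": dataset.seed,
        "config_digest": dataset.config_digest,
        "n_cycles": len(dataset),
        "units": {"angles": "deg", "moments": "N·m/kg"},
        "channels": list(CHANNELS),
        "moment_channels": list(MOMENT_CHANNELS),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, ensure_ascii=False))
    return out


def read_dataset(in_dir: str | Path) -> GaitDataset:
    """Read a dataset written by `write_dataset` (lossless round trip)."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    if manifest["channels"] != list(CHANNELS):
        raise SchemaError("manifest channel list does not match the canonical 18-channel set")
    df = pd.read_csv(in_dir / "cycles.csv", float_precision="round_trip")
    cycles, moments = [], []
    for (sid, speed, cid), g in df.groupby(["subject_id", "speed", "cycle_id"], sort=False):
        g = g.sort_values("t_index")
        cycles.append(
            GaitCycle(
                values=g[list(CHANNELS)].to_numpy().T,
                channel_names=CHANNELS,
                subject_id=str(sid),
                speed=str(speed),
                cycle_id=str(cid),
            )
        )
        moments.append(g[list(MOMENT_CHANNELS)].to_numpy().T)
    return GaitDataset(
        cycles=cycles,
        moments=moments,
        seed=int(manifest["seed"]),
        config_digest=str(manifest["config_digest"]),
    )
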