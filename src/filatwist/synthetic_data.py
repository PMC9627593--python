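"""Synthetic twist traces, filament lattices and sphere fixtures.

This module emulates the statistical and geometric structure of the
microsecond MD observables the rest of the pipeline consumes, without any
molecular mechanics: piecewise-constant-mean twist traces with (optionally
AR(1)-correlated) Gaussian noise, ideal 4x2 double-protofilament lattices
realizing a prescribed twist schedule by symmetric counter-rotation of
consecutive pairs, and toy sphere sets for SASA tests.

The named presets encode the quasi-stable state narratives of the reference
simulations at 1 ns/frame: an ATP-bound run dwelling at ~10.4deg for almost
1 us, jumping above 12deg for >300 ns and relaxing to ~4.2deg (``atp1``); an
ADP-bound run holding a single ~0.5deg state (``adp1``); an ADP-bound run
stepping 0 -> 5 -> 10deg (``adp2``); and a randomized ensemble preset drawing
segment means from the four-mode landscape {0, 5, 10, 12.5}deg
(``paper-modes``).  The paper-trail for the per-state fluctuation amplitude
is thinner than for the means: presets default to sigma = 1.0deg
(1.2deg for the ensemble preset), chosen so neighbouring modes 2.5deg apart
are statistically distinct yet overlapping in the raw trace, as in the
source histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .geometry import FilamentTrajectory, TwistTrace
from .sasa import ToyStructure

__all__ = [
    "SegmentSchedule",
    "TrajectoryPreset",
    "LatticeSpec",
    "PAPER_MODES_DEG",
    "PRESET_NAMES",
    "gen_twist_trace",
    "gen_filament_trajectory",
    "gen_sphere_set",
    "preset_schedule",
    "get_preset",
    "paper_modes_schedule",
    "paper_modes_ensemble",
    "crystal_standin_trajectory",
]

#: Twist-landscape mode means (degrees) used by the "paper-modes" preset.
PAPER_MODES_DEG = (0.0, 5.0, 10.0, 12.5)


@dataclass
class SegmentSchedule:
    """Piecewise-constant generating schedule for a twist trace.

    ``segments`` is an ordered list of (duration_frames, mean_twist_deg).
    Noise is stationary AR(1) Gaussian parameterized on the *marginal* scale:
    whatever ``ar1_coeff``, the marginal standard deviation is
    ``noise_sigma``.  ``noise_sigma = 0`` gives a noiseless trace.
    """

    segments: list[tuple[int, float]]
    noise_sigma: float = 1.0
    ar1_coeff: float = 0.0
    seed: int = 0
    dt_ns: float = 1.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule has no segments")
        cleaned = []
        for duration, mean in self.segments:
            if int(duration) != duration or duration < 1:
                raise ValueError("segment durations must be integers >= 1")
            cleaned.append((int(duration), float(mean)))
        self.segments = cleaned
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0.0 <= self.ar1_coeff < 1.0):
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")

    @property
    def total_frames(self) -> int:
        return sum(d for d, _ in self.segments)

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment boundaries [0, b1, ..., total_frames]."""
        return np.concatenate([[0], np.cumsum([d for d, _ in self.segments])])


@dataclass(frozen=True)
class TrajectoryPreset:
    """A named schedule with provenance notes."""

    name: str
    schedule: SegmentSchedule
    description: str


@dataclass
class LatticeSpec:
    """Geometry of the ideal 4x2 double-protofilament lattice (nm)."""

    n_pairs: int = 4
    subunit_length: float = 5.0  # axial rise per pair; monomer size ~5 nm
    protofilament_separation: float = 4.0
    marker_offset: float = 1.0  # orientation-marker distance from centroid
    positional_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2 (no twist definable otherwise)")
        for name in ("subunit_length", "protofilament_separation", "marker_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.positional_noise < 0:
            raise ValueError("positional_noise must be non-negative")


def _ar1_noise(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation sigma."""
    if sigma == 0.0:
        return np.zeros(n)
    if rho == 0.0:
        return rng.normal(0.0, sigma, n)
    innov = rng.normal(0.0, sigma * np.sqrt(1.0 - rho * rho), n)
    innov[0] = rng.normal(0.0, sigma)  # start from the stationary marginal
    return lfilter([1.0], [1.0, -rho], innov)


def gen_twist_trace(schedule: SegmentSchedule) -> TwistTrace:
    """Generate a twist trace from a piecewise-constant schedule.

    Within each segment values are the segment mean plus stationary AR(1)
    Gaussian noise; the noise process is continuous across segment
    boundaries (only the mean jumps).  Bit-reproducible for a fixed seed.
    """
    n = schedule.total_frames
    means = np.repeat(
        [m for _, m in schedule.segments], [d for d, _ in schedule.segments]
    )
    rng = np.random.default_rng(schedule.seed)
    noise = _ar1_noise(rng, n, schedule.noise_sigma, schedule.ar1_coeff)
    return TwistTrace(
        time=np.arange(n) * schedule.dt_ns,
        twist=means + noise,
        metadata={
            "source": "synthetic",
            "seed": schedule.seed,
            "noise_sigma": schedule.noise_sigma,
            "ar1_coeff": schedule.ar1_coeff,
            "generating_boundaries": schedule.boundaries.tolist(),
            "generating_means": [m for _, m in schedule.segments],
        },
    )


#: Fixed (duration, mean) tables for the deterministic presets, 1 ns/frame.
_PRESET_TABLES = {
    # ATP-bound run: ~10.4deg for almost 1 us, >12deg for >300 ns, ~4.2deg
    # for the remainder of 2.7 us.
    "atp1": [(950, 10.4), (300, 12.5), (1450, 4.2)],
    # ADP-bound run: a single low-twist state (~0.5deg) over 1 us.
    "adp1": [(1000, 0.5)],
    # Second ADP-bound run: 0deg for 300 ns, ~5deg to 500 ns, then ~10deg.
    "adp2": [(300, 0.0), (200, 5.0), (500, 10.0)],
}

PRESET_NAMES = ("atp1", "adp1", "adp2", "paper-modes")


def preset_schedule(
    name: str,
    seed: int = 0,
    noise_sigma: float | None = None,
    ar1_coeff: float = 0.0,
    **kwargs,
) -> SegmentSchedule:
    """Schedule for a named preset (see module docstring for provenance)."""
    if name in _PRESET_TABLES:
        sigma = 1.0 if noise_sigma is None else noise_sigma
        return SegmentSchedule(
            segments=list(_PRESET_TABLES[name]),
            noise_sigma=sigma,
            ar1_coeff=ar1_coeff,
            seed=seed,
        )
    if name == "paper-modes":
        sigma = 1.2 if noise_sigma is None else noise_sigma
        return paper_modes_schedule(
            seed=seed, noise_sigma=sigma, ar1_coeff=ar1_coeff, **kwargs
        )
    raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")


def get_preset(name: str, seed: int = 0, **kwargs) -> TrajectoryPreset:
    descriptions = {
        "atp1": "ATP-bound double protofilament: three quasi-stable states "
        "(10.4, 12.5, 4.2 deg) over 2.7 us at 1 ns/frame",
        "adp1": "ADP-bound double protofilament: one stable ~0.5 deg state over 1 us",
        "adp2": "ADP-bound replicate: three states stepping 0 -> 5 -> 10 deg over 1 us",
        "paper-modes": "randomized ensemble member with segment means drawn from "
        "the four-mode landscape {0, 5, 10, 12.5} deg",
    }
    return TrajectoryPreset(
        name=name,
        schedule=preset_schedule(name, seed=seed, **kwargs),
        description=descriptions[name],
    )


def paper_modes_schedule(
    seed: int,
    n_frames: int = 2000,
    noise_sigma: float = 1.2,
    ar1_coeff: float = 0.0,
    min_segment: int = 250,
    n_segments_range: tuple[int, int] = (3, 6),
) -> SegmentSchedule:
    """Randomized schedule whose segment means are drawn from the four modes.

    Consecutive segments never repeat a mean; durations are a random
    composition of ``n_frames`` with every segment at least ``min_segment``
    frames, so the change points are resolvable by the detector.
    """
    rng = np.random.default_rng(seed)
    lo, hi = n_segments_range
    hi = min(hi, n_frames // min_segment)
    if hi < lo:
        raise ValueError("n_frames too short for the requested segment count")
    n_seg = int(rng.integers(lo, hi + 1))

    extra = rng.multinomial(n_frames - n_seg * min_segment, np.ones(n_seg) / n_seg)
    durations = (min_segment + extra).tolist()

    means = []
    modes = list(PAPER_MODES_DEG)
    prev = None
    for _ in range(n_seg):
        choices = [m for m in modes if m != prev]
        prev = float(rng.choice(choices))
        means.append(prev)
    return SegmentSchedule(
        segments=list(zip(durations, means)),
        noise_sigma=noise_sigma,
        ar1_coeff=ar1_coeff,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def paper_modes_ensemble(
    n_traces: int = 20,
    n_frames: int = 2000,
    noise_sigma: float = 1.2,
    base_seed: int = 1,
) -> list[TwistTrace]:
    """The documented ensemble: ``n_traces`` independent paper-modes traces."""
    return [
        gen_twist_trace(
            paper_modes_schedule(
                seed=base_seed + i, n_frames=n_frames, noise_sigma=noise_sigma
            )
        )
        for i in range(n_traces)
    ]


def _subunit_points(center: np.ndarray, marker_offset: float) -> np.ndarray:
    """Five reference points: centroid plus four in-plane orientation markers."""
    offsets = np.array(
        [
            [0.0, 0.0, 0.0],
            [marker_offset, 0.0, 0.0],
            [-marker_offset, 0.0, 0.0],
            [0.0, marker_offset, 0.0],
            [0.0, -marker_offset, 0.0],
        ]
    )
    return center[None, :] + offsets


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def gen_filament_trajectory(
    spec: LatticeSpec, twist_schedule: TwistTrace | np.ndarray
) -> FilamentTrajectory:
    """Ideal 4x2 lattice trajectory realizing a prescribed twist schedule.

    For each frame the two protofilaments are built straight along z, and
    consecutive antiparallel pairs are counter-rotated about the filament
    axis symmetrically (pair i rotated by ``(i - (n-1)/2) * theta``) so the
    twist between *every* consecutive pair -- in particular the middle
    doublet -- equals the scheduled angle.  Isotropic Gaussian positional
    noise of amplitude ``positional_noise`` is then added independently to
    every subunit reference point.
    """
    if isinstance(twist_schedule, TwistTrace):
        angles = twist_schedule.twist
        times = twist_schedule.time
    else:
        angles = np.asarray(twist_schedule, dtype=float)
        times = np.arange(angles.size, dtype=float)
    if angles.ndim != 1 or angles.size == 0:
        raise ValueError("twist schedule must be a non-empty 1D angle series")
    if np.any(np.abs(angles) > 180.0):
        raise ValueError("twist schedule contains unphysical angles (>180 deg)")

    n_frames = angles.size
    n = spec.n_pairs
    half_sep = spec.protofilament_separation / 2.0
    coords = np.empty((n_frames, n, 2, 5, 3))
    centers = np.array([[-half_sep, 0.0], [half_sep, 0.0]])  # protofilaments 0, 1

    theta = np.radians(angles)
    for t in range(n_frames):
        for i in range(n):
            R = _rot_z((i - (n - 1) / 2.0) * theta[t])
            z = i * spec.subunit_length
            for s in range(2):
                center = np.array([centers[s, 0], centers[s, 1], 0.0])
                pts = _subunit_points(center, spec.marker_offset)
                pts = pts @ R.T
                pts[:, 2] += z
                coords[t, i, s] = pts

    if spec.positional_noise > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.positional_noise, coords.shape)

    return FilamentTrajectory(
        coords=coords,
        times=times.copy(),
        unit="nm",
        metadata={"source": "synthetic", "lattice": spec.__dict__.copy()},
    )


def crystal_standin_trajectory(
    twist_deg: float = 0.7, positional_noise: float = 0.0, seed: int = 0
) -> FilamentTrajectory:
    """Synthetic stand-in for the crystal-lattice 4x2 filament.

    The deposited crystal structure is not bundled with this package, so
    this is *not* the real structure: it is an ideal lattice constructed at
    the published crystal twist (0.7 deg by default) for testing the
    geometry stage offline.  Any value measured on it reflects the lattice
    construction, not crystallographic coordinates.
    """
    spec = LatticeSpec(positional_noise=positional_noise, seed=seed)
    return gen_filament_trajectory(spec, np.array([twist_deg]))


def gen_sphere_set(
    centers, radii, groups=None
) -> ToyStructure:
    """Sphere-set fixture for the SASA module (angstrom units)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if centers.shape[0] != radii.shape[0]:
        raise ValueError(
            f"got {centers.shape[0]} centers but {radii.shape[0]} radii"
        )
    return ToyStructure(positions=centers, radii=radii, groups=groups)
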