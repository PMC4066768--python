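"""Synthetic ground truth and trajectory generation.

The inference pipeline assumes a stationary multivariate-Gaussian
coordinate process with a prescribed shape vector and a non-local
stiffness matrix.  This module builds such ground-truth models from
sequence-dependent dinucleotide and base-pair parameter tables, draws
Gaussian coordinate trajectories from them, reconstructs base-pair frames
from step coordinates (and extracts them back), and emits the hydrogen-bond
distance fixtures and toy nucleosome templates the rest of the package
consumes.  It is a statistical stand-in for an atomistic simulation
ensemble: the built-in parameter tables are B-DNA-like and illustrative
(twist near 34 deg, rise near 3.3 A, propeller more negative for A.T),
not fitted to any particular force field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .elastic_rod import FrameTrajectory
from .model_core import (
    INTRA_COORDS,
    KB,
    STEP_COORDS,
    ConditioningError,
    CoordinateSchema,
    CoordinateTrajectory,
    DuplexSequence,
    RigidBaseModel,
    reverse_complement,
)
from .threading import TemplateProfile

logger = logging.getLogger("dnamech")

#: The seven 18-bp study duplexes: a C/G-rich control and the same context
#: with symmetric (AnTn) and asymmetric (A2n) A-tracts in the centre.
STUDY_SEQUENCES = {
    "A3T3": "GCCTGGAAATTTCTGTGC",
    "A6": "GCCTGGAAAAAACTGTGC",
    "A4T4": "GCCTGAAAATTTTCGTGC",
    "A8": "GCCTGAAAAAAAACGTGC",
    "A5T5": "GCCGAAAAATTTTTCTGC",
    "A10": "GCCGAAAAAAAAAACTGC",
    "control": "GCCTGGCGCGCGCTGTGC",
}

# Sign flips when a block is read from the complementary strand:
# (tilt, shift) for steps, (buckle, shear) for pairs.
_STEP_FLIP = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, 1.0])
_PAIR_FLIP = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, 1.0])


def _block(mean, diag):
    return np.asarray(mean, dtype=float), np.diag(np.asarray(diag, dtype=float))


# Step table: mean (tilt, roll, twist, shift, slide, rise) in (deg, A) and a
# diagonal 6x6 stiffness in kcal/mol per unit^2, for the 10 unique
# dinucleotides (the other 6 follow by reverse complement).  The AT step is
# made distinctly stiff and the TA step soft, mirroring their reputations.
_BASE_STEP_STIFF = (0.04, 0.02, 0.03, 1.5, 2.0, 5.0)


def _step_stiff(factor):
    return tuple(factor * v for v in _BASE_STEP_STIFF)


DEFAULT_STEP_TABLE = {
    "AA": _block((0.0, 0.5, 35.5, 0.0, -0.2, 3.3), _step_stiff(1.2)),
    "AT": _block((0.0, -1.0, 32.0, 0.0, -0.6, 3.3), _step_stiff(1.5)),
    "TA": _block((0.0, 3.0, 36.0, 0.0, 0.1, 3.4), _step_stiff(0.7)),
    "AC": _block((0.0, 0.5, 33.0, 0.0, -0.3, 3.3), _step_stiff(1.0)),
    "AG": _block((0.0, 2.5, 32.5, 0.0, -0.2, 3.3), _step_stiff(1.0)),
    "CA": _block((0.0, 5.0, 35.0, 0.0, 0.2, 3.4), _step_stiff(0.8)),
    "GA": _block((0.0, 1.5, 37.0, 0.0, -0.1, 3.3), _step_stiff(1.0)),
    "CC": _block((0.0, 2.0, 33.5, 0.0, -0.2, 3.3), _step_stiff(1.1)),
    "CG": _block((0.0, 4.5, 35.5, 0.0, 0.3, 3.4), _step_stiff(0.9)),
    "GC": _block((0.0, 0.5, 38.0, 0.0, 0.2, 3.4), _step_stiff(1.1)),
}

# Pair table: mean (buckle, propeller, opening, shear, stretch, stagger) and
# diagonal stiffness, keyed by the reference-strand base of the pair read as
# a purine (A for A.T, G for G.C).  G.C pairs are stiffer in opening and
# stretch (three hydrogen bonds); A.T pairs carry the negative propeller.
DEFAULT_PAIR_TABLE = {
    "A": _block((0.0, -12.0, 1.0, 0.0, 0.0, 0.1), (0.015, 0.02, 0.06, 3.0, 8.0, 2.0)),
    "G": _block((0.0, -6.0, 0.5, 0.0, 0.0, 0.05), (0.015, 0.025, 0.09, 3.0, 12.0, 2.0)),
}


def step_parameters(step_type: str, table=None):
    """Mean and stiffness block of a dinucleotide step, via reverse complement
    (with tilt/shift sign flips) when the step is not tabulated directly."""
    table = DEFAULT_STEP_TABLE if table is None else table
    if step_type in table:
        return table[step_type]
    rc = reverse_complement(step_type)
    if rc not in table:
        raise KeyError(f"step type {step_type!r} not covered by the table")
    mean, K = table[rc]
    return _STEP_FLIP * mean, (_STEP_FLIP[:, None] * K) * _STEP_FLIP[None, :]


def pair_parameters(base: str, table=None):
    """Mean and stiffness block of a base pair keyed by its reference base."""
    table = DEFAULT_PAIR_TABLE if table is None else table
    if base in table:
        return table[base]
    rc = reverse_complement(base)
    if rc not in table:
        raise KeyError(f"pair type {base!r} not covered by the table")
    mean, K = table[rc]
    return _PAIR_FLIP * mean, (_PAIR_FLIP[:, None] * K) * _PAIR_FLIP[None, :]


@dataclass
class GroundTruthSpec:
    """Recipe for a sequence-dependent ground-truth rigid-base model.

    The long-range kernel couples like coordinates of distinct steps with
    strength decaying exponentially in step separation (decay length in
    bp), emulating the non-local character of base-base interactions.
    """

    sequence: DuplexSequence | str
    step_table: dict | None = None
    pair_table: dict | None = None
    coupling_strength: float = 0.08
    coupling_decay: float = 3.0
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sequence, str):
            self.sequence = DuplexSequence(self.sequence)


def build_ground_truth(spec: GroundTruthSpec) -> RigidBaseModel:
    """Assemble shape vector and non-local stiffness from the parameter tables.

    Intra-pair and step blocks sit on the block diagonal; the coupling
    kernel adds off-diagonal entries between the matching coordinates of
    step pairs, scaled by the geometric mean of their diagonal stiffnesses.
    Positive definiteness is enforced by a uniform diagonal shift if
    needed (logged); an excessive required shift is an error.
    """
    seq = spec.sequence
    schema = CoordinateSchema(seq.n)
    N = schema.N
    w_hat = np.zeros(N)
    K = np.zeros((N, N))
    for i, base in enumerate(seq.sequence, start=1):
        mean, block = pair_parameters(base, spec.pair_table)
        lo = schema.index(INTRA_COORDS[0], i)
        w_hat[lo : lo + 6] = mean
        K[lo : lo + 6, lo : lo + 6] = block
    step_lo = []
    for j, st in enumerate(seq.step_types(), start=1):
        mean, block = step_parameters(st, spec.step_table)
        lo = schema.index(STEP_COORDS[0], j)
        w_hat[lo : lo + 6] = mean
        K[lo : lo + 6, lo : lo + 6] = block
        step_lo.append(lo)

    if spec.coupling_strength != 0.0:
        for a in range(len(step_lo)):
            for b in range(a + 1, len(step_lo)):
                factor = spec.coupling_strength * np.exp(
                    -(b - a) / spec.coupling_decay
                )
                for c in range(6):
                    ia, ib = step_lo[a] + c, step_lo[b] + c
                    coup = factor * np.sqrt(K[ia, ia] * K[ib, ib])
                    K[ia, ib] += coup
                    K[ib, ia] += coup

    eig = np.linalg.eigvalsh(K)
    floor = 1e-6 * eig[-1]
    if eig[0] < floor:
        shift = floor - eig[0]
        if shift > 0.1 * np.mean(np.diag(K)):
            raise ConditioningError(
                f"assembled stiffness needs diagonal shift {shift:.3g}, "
                "beyond the allowed correction"
            )
        logger.info("SPD floor: shifting stiffness diagonal by %.3g", shift)
        K = K + shift * np.eye(N)
    return RigidBaseModel(w_hat, K, spec.temperature, schema)


def sample_trajectory(model: RigidBaseModel, M: int, seed: int) -> CoordinateTrajectory:
    """Draw M iid snapshots from the model's Gaussian ensemble.

    Coordinates are distributed with mean w_hat and covariance
    C = k_B T K^{-1}; draws are reproducible per seed.
    """
    if model.schema is None:
        raise ValueError("sampling requires a model with a coordinate schema")
    rng = np.random.default_rng(seed)
    C = model.covariance
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((M, model.N))
    return CoordinateTrajectory(model.schema, model.w_hat + Z @ L.T)


# ---------------------------------------------------------------------------
# Frame reconstruction from step coordinates (mid-step triad convention)
# ---------------------------------------------------------------------------


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _step_rotations(tilt: float, roll: float, twist: float):
    # Mid-step triad composition: the combined bend of magnitude
    # Gamma = sqrt(tilt^2 + roll^2) with phase phi = atan2(tilt, roll) is
    # applied about the mid-frame, twist split half before / half after.
    gamma = np.hypot(tilt, roll)
    phi = np.arctan2(tilt, roll) if gamma > 0 else 0.0
    a = 0.5 * twist - phi
    b = 0.5 * twist + phi
    R_step = _rot_z(a) @ _rot_y(gamma) @ _rot_z(b)
    R_half = _rot_z(a) @ _rot_y(0.5 * gamma) @ _rot_z(phi)
    return R_step, R_half


def reconstruct_frames(step_coords: np.ndarray) -> FrameTrajectory:
    """Base-pair frames from step coordinates; frame 1 is the identity.

    ``step_coords`` is (M, n-1, 6) or (n-1, 6) in canonical step order
    (tilt, roll, twist, shift, slide, rise; degrees and Angstrom).  Tilt
    and roll rotate about the mid-step frame axes with twist split evenly
    across the step; shift/slide/rise displace along the mid-step axes.
    The exact inverse is :func:`extract_step_coordinates`.
    """
    sc = np.asarray(step_coords, dtype=float)
    if sc.ndim == 2:
        sc = sc[None]
    M, n_steps, six = sc.shape
    if six != 6:
        raise ValueError("step coordinates must have 6 components per step")
    n = n_steps + 1
    origins = np.zeros((M, n, 3))
    axes = np.zeros((M, n, 3, 3))
    axes[:, 0] = np.eye(3)
    for m in range(M):
        for j in range(n_steps):
            tilt, roll, twist = np.radians(sc[m, j, :3])
            disp = sc[m, j, 3:]
            R_step, R_half = _step_rotations(tilt, roll, twist)
            R_mid = axes[m, j] @ R_half
            axes[m, j + 1] = axes[m, j] @ R_step
            origins[m, j + 1] = origins[m, j] + R_mid @ disp
    return FrameTrajectory(origins, axes)


def extract_step_coordinates(frames: FrameTrajectory) -> np.ndarray:
    """Step coordinates from consecutive base-pair frames (inverse composition)."""
    M, n = frames.M, frames.n
    out = np.empty((M, n - 1, 6))
    for m in range(M):
        for j in range(n - 1):
            R = frames.axes[m, j].T @ frames.axes[m, j + 1]
            gamma = np.arccos(np.clip(R[2, 2], -1.0, 1.0))
            if gamma < 1e-12:
                twist = np.arctan2(R[1, 0], R[0, 0])
                phi = 0.0
            else:
                a = np.arctan2(R[1, 2], R[0, 2])
                b = np.arctan2(R[2, 1], -R[2, 0])
                # gauge fix: (b, phi) -> (b - 2 pi, phi - pi) leaves the
                # rotation unchanged; pick the branch with twist in (-pi, pi]
                if a + b > np.pi:
                    b -= 2.0 * np.pi
                elif a + b <= -np.pi:
                    b += 2.0 * np.pi
                twist = a + b
                phi = 0.5 * (b - a)
            tilt = gamma * np.sin(phi)
            roll = gamma * np.cos(phi)
            _, R_half = _step_rotations(tilt, roll, twist)
            R_mid = frames.axes[m, j] @ R_half
            disp = R_mid.T @ (frames.origins[m, j + 1] - frames.origins[m, j])
            out[m, j, :3] = np.degrees([tilt, roll, twist])
            out[m, j, 3:] = disp
    return out


# ---------------------------------------------------------------------------
# Toy nucleosome template and H-bond fixtures
# ---------------------------------------------------------------------------


def make_toy_nucleosome_template(
    L_t: int = 147,
    period: float = 10.0,
    roll_amplitude: float = 6.0,
    roll_mean: float = 0.0,
    twist_mean: float = 34.0,
    slide_mean: float = -0.3,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dyad: int | None = 73,
) -> TemplateProfile:
    """Template with sinusoidal roll of the given period, constant twist/slide.

    Mimics the helically phased roll pattern of nucleosome-wrapped DNA
    without any superhelix geometry.  Optional iid Gaussian noise (seeded)
    can be layered on all three coordinates.
    """
    if L_t < period:
        raise ValueError("template must span at least one period")
    s = np.arange(L_t)
    roll = roll_mean + roll_amplitude * np.sin(2.0 * np.pi * s / period)
    twist = np.full(L_t, float(twist_mean))
    slide = np.full(L_t, float(slide_mean))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        roll = roll + rng.normal(0.0, noise_sd, L_t)
        twist = twist + rng.normal(0.0, noise_sd, L_t)
        slide = slide + rng.normal(0.0, 0.1 * noise_sd, L_t)
    return TemplateProfile(roll, twist, slide, dyad=dyad)


@dataclass
class HBondSeries:
    """Per-snapshot, per-pair maximum Watson-Crick donor-acceptor distance (A)."""

    distances: np.ndarray  # (M, n)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2:
            raise ValueError("distances must be (M, n)")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")


def inject_broken_pairs(
    traj: CoordinateTrajectory,
    fraction: float,
    pairs: list[int],
    seed: int,
    intact_distance: float = 2.9,
    broken_distance: float = 4.5,
) -> tuple[CoordinateTrajectory, HBondSeries]:
    """H-bond distance fixture: break the given pairs in a fraction of snapshots.

    ``pairs`` are 1-based.  Exactly round(fraction * M) snapshots (chosen
    reproducibly per seed) get distances above the 4 A breakage cutoff at
    the listed pairs; everything else sits near the intact distance.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    M = len(traj.values)
    n = traj.schema.n
    dist = np.clip(rng.normal(intact_distance, 0.05, (M, n)), 2.5, 3.6)
    n_broken = int(round(fraction * M))
    if n_broken and pairs:
        snaps = rng.choice(M, size=n_broken, replace=False)
        for p in pairs:
            if not 1 <= p <= n:
                raise IndexError(f"pair {p} outside 1..{n}")
            dist[snaps, p - 1] = broken_distance + np.abs(rng.normal(0.0, 0.2, n_broken))
    return traj, HBondSeries(dist)
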