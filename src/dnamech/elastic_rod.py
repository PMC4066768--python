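"""Anisotropic elastic-rod description of a DNA oligomer.

The whole duplex is reduced to three coordinate frames — two ends and the
middle — each obtained by averaging base-fixed reference frames over a
small window of consecutive base pairs.  The rod state per snapshot is

    u = (rho, tau, omega):  global roll, global tilt, total twist (radians),

where the bend magnitude theta is the angle between the z-axes of the end
frames, the bend direction phi is measured from the mid-oligomer major
groove (phi = 0 toward the major groove, pi toward the minor groove), and
rho = theta cos(phi), tau = theta sin(phi).  Total twist is the sum of
local dinucleotide twists between the end frames with the two boundary
steps half-weighted; the contour length l is the analogous sum of rises.

Fitting the Gaussian fluctuations of u gives the 3x3 stiffness in length
units, K_r = l0 C_u^{-1} (nm), with the deformation energy

    E_r(u) = k_B T / (2 l0) (u - u_hat) . K_r (u - u_hat).

Relaxing twist out of K_r yields the groove/backbone bending constants
a_g, a_b and their harmonic mean a_iso (2/a_iso = 1/a_g + 1/a_b); relaxing
the bend yields the twist stiffness c (all persistence-length-like, nm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model_core import ConditioningError, InsufficientSamplesError

__all__ = [
    "Frame",
    "FrameTrajectory",
    "RodCoordinateSeries",
    "RodModel",
    "BendState",
    "BendingStiffness",
    "mean_frame",
    "antiparallel_flip",
    "global_bend",
    "bend_components",
    "total_twist",
    "contour_length",
    "build_rod_series",
    "fit_rod",
    "bending_stiffness",
    "twist_stiffness",
    "isotropic_bending_stiffness",
]


class AmbiguousAverageError(ValueError):
    """Raised when frame orientations are too spread to average meaningfully."""


@dataclass(frozen=True)
class Frame:
    """An origin (Angstrom) with right-handed orthonormal axes.

    Axes are the columns of ``axes``; by the base-frame convention the
    x-axis points toward the major groove and z along the helix.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValueError("frame axes are left-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


def antiparallel_flip(frame: Frame) -> Frame:
    """Flip a complementary-strand base frame into the reference-strand sense.

    Bases on the two strands are antiparallel, so frames read off the
    complementary strand have their y- and z-axes negated before averaging.
    """
    flipped = frame.axes * np.array([1.0, -1.0, -1.0])
    return Frame(frame.origin, flipped)


# ---------------------------------------------------------------------------
# Frame averaging
# ---------------------------------------------------------------------------


def _mean_rotation_quaternion(mats: np.ndarray) -> np.ndarray:
    # Chordal-mean rotation: principal eigenvector of the summed outer
    # products of unit quaternions (hemisphere-aligned to the first).
    q = Rotation.from_matrix(mats).as_quat().reshape(-1, 4)
    q = np.where((q @ q[0])[:, None] < 0, -q, q)
    A = q.T @ q
    _, vecs = np.linalg.eigh(A)
    return Rotation.from_quat(vecs[:, -1]).as_matrix()


def _mean_rotation_svd(mats: np.ndarray) -> np.ndarray:
    # Oracle path: project the summed rotation matrices back onto SO(3).
    S = mats.sum(axis=0)
    U, _, Vt = np.linalg.svd(S)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def mean_frame(frames: Sequence[Frame], method: str = "quaternion") -> Frame:
    """Average frame: mean origin and the rotation average of the axes.

    ``method`` selects the quaternion eigen-average (default) or the SVD
    projection of the summed rotation matrices; the two agree for any
    reasonably tight cluster.  Orientations spread by 90 degrees or more
    from their average are rejected as ambiguous.
    """
    if len(frames) == 0:
        raise ValueError("cannot average zero frames")
    origin = np.mean([f.origin for f in frames], axis=0)
    mats = np.stack([f.axes for f in frames])
    if method == "quaternion":
        R = _mean_rotation_quaternion(mats)
    elif method == "svd":
        R = _mean_rotation_svd(mats)
    else:
        raise ValueError(f"unknown averaging method {method!r}")
    rel = Rotation.from_matrix(R.T @ mats)
    if np.any(rel.magnitude() >= np.pi / 2):
        raise AmbiguousAverageError(
            "frame orientations spread by >= 90 deg; average is ambiguous"
        )
    return Frame(origin, R)


# ---------------------------------------------------------------------------
# Global bend
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BendState:
    """Bend magnitude/direction and its roll/tilt resolution, radians.

    ``phi_defined`` is False for a straight rod (theta = 0), where the
    bending direction is undefined.
    """

    theta: float
    phi: float
    rho: float
    tau: float
    phi_defined: bool = True


def bend_components(theta: float, phi: float) -> tuple[float, float]:
    """Resolve a bend into global roll and tilt: rho = theta cos phi, tau = theta sin phi."""
    return theta * np.cos(phi), theta * np.sin(phi)


def global_bend(end1: Frame, end2: Frame, middle: Frame) -> BendState:
    """Bend between the end frames, resolved in the mid-oligomer groove frame.

    theta is the angle between the end z-axes.  phi is the direction of the
    z-axis deflection (z2 - z1) projected on the middle frame's x-y plane,
    increasing from +x (major groove, phi = 0) toward +y; phi = pi is the
    minor groove.
    """
    z1, z2 = end1.z, end2.z
    theta = float(np.arctan2(np.linalg.norm(np.cross(z1, z2)), np.dot(z1, z2)))
    d = middle.axes.T @ (z2 - z1)
    if theta < 1e-10 or np.hypot(d[0], d[1]) < 1e-14:
        return BendState(theta, 0.0, 0.0, 0.0, phi_defined=False)
    phi = float(np.arctan2(d[1], d[0]))
    rho, tau = bend_components(theta, phi)
    return BendState(theta, phi, float(rho), float(tau))


# ---------------------------------------------------------------------------
# Total twist and contour length
# ---------------------------------------------------------------------------


def _end_half_weights(n_steps: int) -> np.ndarray:
    if n_steps < 2:
        raise ValueError("window must cover at least 2 steps")
    w = np.ones(n_steps)
    w[0] = w[-1] = 0.5
    return w


def total_twist(step_twists: np.ndarray, window: tuple[int, int] | None = None) -> np.ndarray | float:
    """Sum of local twists between the end frames, boundary steps half-weighted.

    ``step_twists`` is a step vector or an (M, steps) array; ``window`` is a
    0-based half-open step slice.  Units follow the input (degrees from
    3DNA-style coordinates).
    """
    t = np.asarray(step_twists, dtype=float)
    if window is not None:
        t = t[..., window[0] : window[1]]
    w = _end_half_weights(t.shape[-1])
    out = t @ w
    return float(out) if np.ndim(out) == 0 else out


def contour_length(step_rises: np.ndarray, window: tuple[int, int] | None = None) -> np.ndarray | float:
    """Sum of local rises (Angstrom in, nm out), boundary steps half-weighted."""
    r = np.asarray(step_rises, dtype=float)
    if window is not None:
        r = r[..., window[0] : window[1]]
    w = _end_half_weights(r.shape[-1])
    out = (r @ w) / 10.0
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Rod coordinate series and fitting
# ---------------------------------------------------------------------------


@dataclass
class RodCoordinateSeries:
    """Per-snapshot global coordinates: rho, tau, omega (rad) and length (nm)."""

    rho: np.ndarray
    tau: np.ndarray
    omega: np.ndarray
    length: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        M = self.rho.size
        if not (self.tau.size == self.omega.size == self.length.size == M):
            raise ValueError("rod coordinate series must have equal lengths")
        if np.any(self.length <= 0):
            raise ValueError("contour lengths must be positive")

    @property
    def M(self) -> int:
        return self.rho.size

    @property
    def theta(self) -> np.ndarray:
        return np.hypot(self.rho, self.tau)

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.rho, self.tau, self.omega])


@dataclass
class FrameTrajectory:
    """Base-pair frames per snapshot: origins (M, n, 3) A, axes (M, n, 3, 3)."""

    origins: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.origins.ndim != 3 or self.origins.shape[2] != 3:
            raise ValueError("origins must be (M, n, 3)")
        if self.axes.shape != self.origins.shape + (3,):
            raise ValueError("axes must be (M, n, 3, 3)")

    @property
    def M(self) -> int:
        return self.origins.shape[0]

    @property
    def n(self) -> int:
        return self.origins.shape[1]

    def frame(self, snapshot: int, pair: int) -> Frame:
        """Frame of 1-based ``pair`` at 0-based ``snapshot``."""
        return Frame(self.origins[snapshot, pair - 1], self.axes[snapshot, pair - 1])


def build_rod_series(
    frames: FrameTrajectory,
    step_twists: np.ndarray,
    step_rises: np.ndarray,
    window_pairs: tuple[int, int] | None = None,
    frames_per_location: int = 2,
) -> RodCoordinateSeries:
    """Reduce a frame trajectory to per-snapshot rod coordinates.

    ``window_pairs`` is the 1-based inclusive pair range analysed (default:
    the whole duplex).  End and middle frames are averages over
    ``frames_per_location`` consecutive base-pair frames at the window
    start, centre and end.  Twists and rises are summed over the steps the
    window spans, boundary steps half-weighted.
    """
    p0, p1 = window_pairs if window_pairs is not None else (1, frames.n)
    if not (1 <= p0 < p1 <= frames.n):
        raise ValueError(f"invalid pair window ({p0}, {p1}) for n={frames.n}")
    k = frames_per_location
    if p1 - p0 + 1 < 2 * k:
        raise ValueError("pair window too short for the frame-averaging windows")
    mid_lo = (p0 + p1 - k + 1) // 2
    twists = np.asarray(step_twists, dtype=float)
    rises = np.asarray(step_rises, dtype=float)

    omega = np.radians(total_twist(twists, window=(p0 - 1, p1 - 1)))
    length = contour_length(rises, window=(p0 - 1, p1 - 1))
    rho = np.empty(frames.M)
    tau = np.empty(frames.M)
    for m in range(frames.M):
        f_end1 = mean_frame([frames.frame(m, p) for p in range(p0, p0 + k)])
        f_end2 = mean_frame([frames.frame(m, p) for p in range(p1 - k + 1, p1 + 1)])
        f_mid = mean_frame([frames.frame(m, p) for p in range(mid_lo, mid_lo + k)])
        bend = global_bend(f_end1, f_end2, f_mid)
        rho[m] = bend.rho
        tau[m] = bend.tau
    return RodCoordinateSeries(rho, tau, np.atleast_1d(omega), np.atleast_1d(length))


@dataclass
class RodModel:
    """Equilibrium rod coordinates and stiffness in length units.

    ``u_hat`` = (rho, tau, omega) means in radians; ``K_r`` is the 3x3
    stiffness in nm (persistence-length analogue); ``l0`` the equilibrium
    contour length in nm.
    """

    u_hat: np.ndarray
    K_r: np.ndarray
    l0: float

    def __post_init__(self) -> None:
        self.u_hat = np.asarray(self.u_hat, dtype=float).reshape(3)
        self.K_r = np.asarray(self.K_r, dtype=float).reshape(3, 3)
        if not np.allclose(self.K_r, self.K_r.T, rtol=1e-8, atol=1e-12):
            raise ValueError("rod stiffness must be symmetric")
        if np.any(np.linalg.eigvalsh(self.K_r) <= 0):
            raise ConditioningError("rod stiffness must be positive definite")
        if self.l0 <= 0:
            raise ValueError("equilibrium length must be positive")

    def energy_kbt(self, u: np.ndarray) -> float:
        """Rod deformation energy in units of k_B T."""
        d = np.asarray(u, dtype=float).reshape(3) - self.u_hat
        return float(d @ self.K_r @ d / (2.0 * self.l0))

    def to_dict(self) -> dict:
        a_g, a_b, a_iso, coupling = bending_stiffness(self)
        return {
            "u_hat_deg": np.degrees(self.u_hat).tolist(),
            "K_r_nm": self.K_r.tolist(),
            "l0_nm": self.l0,
            "a_g_nm": a_g,
            "a_b_nm": a_b,
            "a_iso_nm": a_iso,
            "bend_coupling_nm": coupling,
            "c_twist_nm": twist_stiffness(self),
        }


def fit_rod(series: RodCoordinateSeries, min_snapshots: int = 100) -> RodModel:
    """Infer the rod model from Gaussian fluctuations of u = (rho, tau, omega).

    u_hat are the sample means, l0 the mean contour length, and
    K_r = l0 C_u^{-1} with C_u the (ML) covariance of u in rad^2.
    """
    if series.M < min_snapshots:
        raise InsufficientSamplesError(
            f"rod fit needs at least {min_snapshots} snapshots, got {series.M}"
        )
    U = series.as_matrix()
    u_hat = U.mean(axis=0)
    C = np.atleast_2d(np.cov(U, rowvar=False, ddof=0))
    eig = np.linalg.eigvalsh(C)
    if eig[0] <= 1e-12 * eig[-1]:
        raise ConditioningError(
            f"rod coordinate covariance is singular (eigenvalue {eig[0]:.3e})"
        )
    l0 = float(series.length.mean())
    K_r = l0 * np.linalg.inv(C)
    return RodModel(u_hat, 0.5 * (K_r + K_r.T), l0)


# ---------------------------------------------------------------------------
# Stiffness decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BendingStiffness:
    """Groove/backbone bending constants, their harmonic mean and coupling (nm)."""

    a_g: float
    a_b: float
    a_iso: float
    coupling: float

    def __iter__(self):
        return iter((self.a_g, self.a_b, self.a_iso, self.coupling))


def isotropic_bending_stiffness(a_g: float, a_b: float) -> float:
    """Effective isotropic bending constant: 2/a_iso = 1/a_g + 1/a_b."""
    if a_g <= 0 or a_b <= 0:
        raise ValueError("bending constants must be positive")
    return 2.0 / (1.0 / a_g + 1.0 / a_b)


def bending_stiffness(rod: RodModel) -> BendingStiffness:
    """Pure-bending stiffness with total twist free to relax.

    Relaxing omega out of K_r (Schur complement) leaves an effective 2x2
    stiffness over (rho, tau); its diagonal entries are the constants for
    bending toward the grooves (a_g) and toward the backbone (a_b), and
    a_iso is their harmonic mean.  The off-diagonal coupling is reported
    for the smallness check (an order of magnitude below the diagonal for
    real duplexes); bending in any direction costs between a_g and a_b.
    """
    K = rod.K_r
    Kb = K[:2, :2] - np.outer(K[:2, 2], K[2, :2]) / K[2, 2]
    a_g, a_b = float(Kb[0, 0]), float(Kb[1, 1])
    return BendingStiffness(a_g, a_b, isotropic_bending_stiffness(a_g, a_b), float(Kb[0, 1]))


def directional_bending_stiffness(rod: RodModel, phi: float) -> float:
    """Stiffness for pure bending along direction ``phi`` (rad), twist relaxed.

    With e = (cos phi, sin phi) and K_bend the twist-relaxed 2x2 stiffness,
    the constant is e . K_bend e; when the groove/backbone coupling is
    negligible this interpolates a_g cos^2(phi) + a_b sin^2(phi) and lies
    between a_g and a_b.
    """
    K = rod.K_r
    Kb = K[:2, :2] - np.outer(K[:2, 2], K[2, :2]) / K[2, 2]
    e = np.array([np.cos(phi), np.sin(phi)])
    return float(e @ Kb @ e)


def twist_stiffness(rod: RodModel) -> float:
    """Pure-twist stiffness with bending unconstrained (nm).

    The 1x1 relaxation of K_r onto omega; equivalently l0 / Var(omega).
    """
    K = rod.K_r
    c = K[2, 2] - K[2, :2] @ np.linalg.solve(K[:2, :2], K[:2, 2])
    if c <= 0:
        raise ConditioningError("relaxed twist stiffness is not positive")
    return float(c)
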