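"""Non-local interacting-rigid-base model of DNA mechanics.

A duplex of ``n`` base pairs is described by ``N = 12n - 6`` rigid-base
coordinates: six intra-basepair coordinates per pair (buckle, propeller,
opening, shear, stretch, stagger) and six step coordinates per dinucleotide
step (tilt, roll, twist, shift, slide, rise), following the 3DNA sign and
unit conventions (angles in degrees, displacements in Angstrom).

The deformation energy is harmonic but non-local: every coordinate may
couple to every other coordinate,

    E(w) = 1/2 (w - w_hat) . K (w - w_hat),

so the oligomer in a thermal bath at temperature T has Gaussian coordinate
fluctuations and the model parameters follow from the first two moments of
the simulated (or synthetic) ensemble,

    w_hat = <w>,        K = k_B T C^{-1},

with C the full N x N coordinate covariance matrix.  Marginal (partially
relaxed) models, single-coordinate force constants, conformational entropy
and coordinate non-dimensionalization are all derived from (w_hat, K) here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Constants and conventions
# ---------------------------------------------------------------------------

#: Boltzmann constant, kcal mol^-1 K^-1.  All energies are kcal/mol.
KB = 0.0019872041

#: Default bath temperature (simulation temperature), K.
DEFAULT_TEMPERATURE = 300.0

#: Default coordinate scales for non-dimensionalization: 1 A for distances
#: and 360/34 degrees (one helical turn over the canonical B-DNA repeat,
#: ~10.6 deg) for angles.
DEFAULT_LENGTH_SCALE = 1.0
DEFAULT_ANGLE_SCALE = 360.0 / 34.0

#: Intra-basepair coordinate names, canonical order.
INTRA_COORDS = ("buckle", "propeller", "opening", "shear", "stretch", "stagger")

#: Base-pair step coordinate names, canonical order.
STEP_COORDS = ("tilt", "roll", "twist", "shift", "slide", "rise")

#: Coordinates measured in degrees; the rest are in Angstrom.
ANGLE_COORDS = frozenset({"buckle", "propeller", "opening", "tilt", "roll", "twist"})

#: Coordinates whose sign flips when the duplex is read from the
#: complementary strand (3DNA convention).
STRAND_FLIP_COORDS = frozenset({"buckle", "shear", "tilt", "shift"})

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a reference-strand sequence."""
    return "".join(_COMPLEMENT[b] for b in reversed(sequence.upper()))


class InsufficientSamplesError(ValueError):
    """Raised when a trajectory has too few snapshots for an estimate."""


class ConditioningError(ValueError):
    """Raised when a covariance matrix is singular or not positive definite."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexSequence:
    """Reference strand (5'->3') of a Watson-Crick paired duplex."""

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 2:
            raise ValueError("duplex needs at least 2 base pairs")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def is_palindromic(self) -> bool:
        return self.sequence == reverse_complement(self.sequence)

    def step_types(self) -> list[str]:
        """Dinucleotide identity of each of the n-1 steps."""
        return [self.sequence[i : i + 2] for i in range(self.n - 1)]


@dataclass(frozen=True)
class CoordinateSchema:
    """Canonical layout of the N = 12n - 6 rigid-base coordinates.

    The ordering is: the six intra-basepair coordinates of pairs 1..n,
    then the six step coordinates of steps 1..n-1 (1-based indices in all
    coordinate labels; a step ``j`` joins pairs ``j`` and ``j+1``).
    """

    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("schema requires n >= 2 base pairs")

    @property
    def N(self) -> int:
        return 12 * self.n - 6

    @property
    def n_steps(self) -> int:
        return self.n - 1

    def labels(self) -> list[str]:
        out = [f"{c}_{i}" for i in range(1, self.n + 1) for c in INTRA_COORDS]
        out += [f"{c}_{j}" for j in range(1, self.n) for c in STEP_COORDS]
        return out

    def coordinate_names(self) -> list[str]:
        """Bare coordinate name (no index) for each of the N slots."""
        out = [c for _ in range(self.n) for c in INTRA_COORDS]
        out += [c for _ in range(self.n - 1) for c in STEP_COORDS]
        return out

    def units(self) -> list[str]:
        return ["deg" if c in ANGLE_COORDS else "angstrom" for c in self.coordinate_names()]

    def index(self, name: str, position: int) -> int:
        """Flat 0-based index of coordinate ``name`` at 1-based ``position``."""
        if name in INTRA_COORDS:
            if not 1 <= position <= self.n:
                raise IndexError(f"pair index {position} outside 1..{self.n}")
            return (position - 1) * 6 + INTRA_COORDS.index(name)
        if name in STEP_COORDS:
            if not 1 <= position <= self.n - 1:
                raise IndexError(f"step index {position} outside 1..{self.n - 1}")
            return 6 * self.n + (position - 1) * 6 + STEP_COORDS.index(name)
        raise KeyError(f"unknown coordinate name {name!r}")

    def step_subset(self, names: Sequence[str], steps: Sequence[int]) -> np.ndarray:
        """Flat indices of the given step coordinates at the given steps.

        Ordered step-major: all requested names of step ``steps[0]`` first.
        """
        return np.array(
            [self.index(nm, s) for s in steps for nm in names], dtype=int
        )

    def scale_vector(
        self,
        length_scale: float = DEFAULT_LENGTH_SCALE,
        angle_scale: float = DEFAULT_ANGLE_SCALE,
    ) -> np.ndarray:
        """Per-coordinate divisor used for non-dimensionalization."""
        return np.array(
            [angle_scale if u == "deg" else length_scale for u in self.units()]
        )

    def reverse_complement_transform(self) -> tuple[np.ndarray, np.ndarray]:
        """Permutation and signs mapping coordinates onto the complementary strand.

        Returns ``(perm, signs)`` such that reading the duplex 5'->3' on the
        other strand sends a coordinate vector ``w`` to
        ``signs * w[perm]``: pair i maps to pair n+1-i, step j to step n-j,
        and buckle, shear, tilt and shift change sign.
        """
        perm = np.empty(self.N, dtype=int)
        signs = np.ones(self.N)
        k = 0
        for i in range(1, self.n + 1):
            for c in INTRA_COORDS:
                perm[k] = self.index(c, self.n + 1 - i)
                if c in STRAND_FLIP_COORDS:
                    signs[k] = -1.0
                k += 1
        for j in range(1, self.n):
            for c in STEP_COORDS:
                perm[k] = self.index(c, self.n - j)
                if c in STRAND_FLIP_COORDS:
                    signs[k] = -1.0
                k += 1
        return perm, signs


@dataclass
class CoordinateTrajectory:
    """Time series of rigid-base coordinate vectors, native units."""

    schema: CoordinateSchema
    values: np.ndarray  # (M, N)
    snapshot_times: np.ndarray | None = None
    included_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.schema.N:
            raise ValueError(
                f"values must be (M, {self.schema.N}), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory contains non-finite entries")
        if self.included_mask is None:
            self.included_mask = np.ones(len(self.values), dtype=bool)
        else:
            self.included_mask = np.asarray(self.included_mask, dtype=bool)
            if self.included_mask.shape != (len(self.values),):
                raise ValueError("included_mask must have one entry per snapshot")

    @property
    def M(self) -> int:
        """Number of snapshots currently included."""
        return int(self.included_mask.sum())

    @property
    def included_values(self) -> np.ndarray:
        return self.values[self.included_mask]

    def select(self, snapshot_mask: np.ndarray) -> "CoordinateTrajectory":
        """New trajectory keeping only snapshots where ``snapshot_mask`` is True."""
        mask = np.asarray(snapshot_mask, dtype=bool)
        times = None if self.snapshot_times is None else self.snapshot_times[mask]
        return CoordinateTrajectory(
            self.schema, self.values[mask], times, self.included_mask[mask]
        )

    def halves(self) -> tuple["CoordinateTrajectory", "CoordinateTrajectory"]:
        M = len(self.values)
        if M < 4:
            raise InsufficientSamplesError("need at least 4 snapshots to split")
        h = M // 2
        idx = np.arange(M)
        return self.select(idx < h), self.select(idx >= h)


def trim_ends(traj: CoordinateTrajectory, pairs: int = 1) -> CoordinateTrajectory:
    """Drop the terminal ``pairs`` base pairs at each end and their flanking steps.

    End pairs fray in simulation and are excluded from all estimation by
    default; the trimmed trajectory has a valid schema for n - 2*pairs pairs.
    """
    n = traj.schema.n
    if pairs < 0 or n - 2 * pairs < 2:
        raise ValueError(f"cannot trim {pairs} pairs from an {n}-bp duplex")
    if pairs == 0:
        return traj
    sch = traj.schema
    keep = [sch.index(c, i) for i in range(pairs + 1, n - pairs + 1) for c in INTRA_COORDS]
    keep += [sch.index(c, j) for j in range(pairs + 1, n - pairs) for c in STEP_COORDS]
    new_schema = CoordinateSchema(n - 2 * pairs)
    return CoordinateTrajectory(
        new_schema, traj.values[:, keep], traj.snapshot_times, traj.included_mask
    )


@dataclass
class RigidBaseModel:
    """Shape vector and non-local stiffness of a harmonic rigid-base model.

    ``K`` carries kcal/mol per (native unit)^2; ``scaling`` records the
    (length, angle) divisors if the coordinates have been
    non-dimensionalized, else ``None``.
    """

    w_hat: np.ndarray
    K: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    schema: CoordinateSchema | None = None
    scaling: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.w_hat = np.atleast_1d(np.asarray(self.w_hat, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        N = self.w_hat.size
        if self.K.shape != (N, N):
            raise ValueError(f"K must be ({N}, {N}), got {self.K.shape}")
        if not np.allclose(self.K, self.K.T, rtol=1e-8, atol=1e-12):
            raise ValueError("stiffness matrix must be symmetric")
        if not np.all(np.isfinite(self.w_hat)):
            raise ValueError("w_hat must be finite")
        if self.schema is not None and self.schema.N != N:
            raise ValueError("schema size does not match w_hat")

    @property
    def N(self) -> int:
        return self.w_hat.size

    @property
    def covariance(self) -> np.ndarray:
        """Equilibrium coordinate covariance C = k_B T K^{-1}."""
        C = KB * self.temperature * np.linalg.inv(self.K)
        return 0.5 * (C + C.T)

    def to_dict(self) -> dict:
        d = {
            "w_hat": self.w_hat.tolist(),
            "K": self.K.tolist(),
            "temperature": self.temperature,
            "n": None if self.schema is None else self.schema.n,
            "scaling": None if self.scaling is None else list(self.scaling),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RigidBaseModel":
        schema = None if d.get("n") is None else CoordinateSchema(d["n"])
        scaling = d.get("scaling")
        return cls(
            np.asarray(d["w_hat"], dtype=float),
            np.asarray(d["K"], dtype=float),
            float(d["temperature"]),
            schema,
            None if scaling is None else (float(scaling[0]), float(scaling[1])),
        )


@dataclass
class MarginalModel:
    """Partially relaxed model: effective quadratic energy on a coordinate subset.

    ``K_tilde`` is the Schur complement of the full stiffness onto the kept
    coordinates (equivalently k_B T times the inverse covariance submatrix).
    """

    subset: np.ndarray
    w_hat: np.ndarray
    K_tilde: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.subset = np.asarray(self.subset, dtype=int)
        self.w_hat = np.atleast_1d(np.asarray(self.w_hat, dtype=float))
        self.K_tilde = np.atleast_2d(np.asarray(self.K_tilde, dtype=float))

    def deformation_energy(self, w_A: np.ndarray) -> float:
        d = np.atleast_1d(np.asarray(w_A, dtype=float)) - self.w_hat
        if d.shape != self.w_hat.shape:
            raise ValueError("coordinate vector does not match subset size")
        return float(0.5 * d @ self.K_tilde @ d)


@dataclass
class ErrorEstimate:
    """Statistic on the full trajectory plus its half-trajectory error bar."""

    value: np.ndarray | float
    half_error: np.ndarray | float


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _check_spd(C: np.ndarray, what: str = "covariance") -> None:
    eig = np.linalg.eigvalsh(C)
    if eig[0] <= 1e-10 * max(eig[-1], 0.0) or eig[-1] <= 0:
        raise ConditioningError(
            f"{what} is singular or not positive definite: "
            f"smallest eigenvalue {eig[0]:.3e} vs largest {eig[-1]:.3e}"
        )


def sample_covariance(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Coordinate covariance; maximum-likelihood normalization by default.

    The fluctuation relation K = k_B T C^{-1} equates ensemble moments, so
    the ML estimator (divide by M) is used; pass ``ddof=1`` for the
    unbiased variant.
    """
    C = np.cov(values, rowvar=False, ddof=ddof)
    return np.atleast_2d(C)


def estimate_model(
    traj: CoordinateTrajectory,
    temperature: float = DEFAULT_TEMPERATURE,
    ddof: int = 0,
) -> RigidBaseModel:
    """Infer (w_hat, K) from coordinate fluctuations: w_hat = <w>, K = k_B T C^{-1}."""
    vals = traj.included_values
    M, N = vals.shape
    if M <= N:
        raise InsufficientSamplesError(
            f"need more snapshots than coordinates: M={M} <= N={N}"
        )
    w_hat = vals.mean(axis=0)
    C = sample_covariance(vals, ddof=ddof)
    _check_spd(C)
    K = KB * temperature * np.linalg.inv(C)
    K = 0.5 * (K + K.T)
    return RigidBaseModel(w_hat, K, temperature, traj.schema)


def deformation_energy(model: RigidBaseModel, w: np.ndarray) -> float:
    """Harmonic deformation energy E = 1/2 (w - w_hat) . K (w - w_hat), kcal/mol."""
    d = np.atleast_1d(np.asarray(w, dtype=float)) - model.w_hat
    if d.shape != model.w_hat.shape:
        raise ValueError(
            f"coordinate vector has {np.size(w)} entries, model expects {model.N}"
        )
    return float(0.5 * d @ model.K @ d)


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------


def conformational_entropy(
    model_or_covariance: RigidBaseModel | np.ndarray,
) -> tuple[float, float]:
    """Gaussian conformational entropy S_c and entropy per coordinate s_c.

    S_c = 1/2 k_B ln[(2 pi e)^N det C], evaluated through the
    log-determinant so large N cannot overflow the determinant.  Returned in
    kcal mol^-1 K^-1.  For cross-model comparisons the coordinates should be
    non-dimensionalized first; with a single length scale and a single angle
    scale, differences of s_c are scale-invariant.
    """
    if isinstance(model_or_covariance, RigidBaseModel):
        C = model_or_covariance.covariance
    else:
        C = np.atleast_2d(np.asarray(model_or_covariance, dtype=float))
    _check_spd(C)
    N = C.shape[0]
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise ConditioningError("covariance has non-positive determinant")
    S_c = 0.5 * KB * (N * np.log(2.0 * np.pi * np.e) + logdet)
    return S_c, S_c / N


# ---------------------------------------------------------------------------
# Marginalization (partial relaxation)
# ---------------------------------------------------------------------------


def relax(model: RigidBaseModel, subset_A: Sequence[int]) -> MarginalModel:
    """Effective stiffness of a coordinate subset with the rest relaxed.

    Minimizing the full quadratic energy over the unconstrained coordinates
    yields the Schur complement K_AA - K_AB K_BB^{-1} K_BA; identically,
    k_B T times the inverse of the covariance submatrix C_AA.  Both routes
    are computed and must agree.
    """
    idx = np.asarray(subset_A, dtype=int)
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    if idx.min() < 0 or idx.max() >= model.N:
        raise IndexError("subset indices outside schema")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("subset contains repeated indices")

    comp = np.setdiff1d(np.arange(model.N), idx)
    K = model.K
    if comp.size == 0:
        K_t = K[np.ix_(idx, idx)]
    else:
        K_AA = K[np.ix_(idx, idx)]
        K_AB = K[np.ix_(idx, comp)]
        K_BB = K[np.ix_(comp, comp)]
        K_t = K_AA - K_AB @ np.linalg.solve(K_BB, K_AB.T)
    K_t = 0.5 * (K_t + K_t.T)

    C_AA = model.covariance[np.ix_(idx, idx)]
    _check_spd(C_AA, "covariance submatrix")
    K_cov = KB * model.temperature * np.linalg.inv(C_AA)
    if not np.allclose(K_t, K_cov, rtol=1e-6, atol=1e-9 * np.abs(K_t).max()):
        raise ConditioningError(
            "Schur-complement and covariance-submatrix stiffnesses disagree; "
            "the model is too ill-conditioned to marginalize"
        )
    return MarginalModel(idx, model.w_hat[idx], K_t, model.temperature)


def force_constant(model: RigidBaseModel, coordinate: int) -> float:
    """Force constant for distorting one coordinate with all others relaxed.

    K_a = k_B T / Var(w_a) — the 1x1 marginal stiffness.
    """
    if not 0 <= coordinate < model.N:
        raise IndexError(f"coordinate {coordinate} outside 0..{model.N - 1}")
    var = model.covariance[coordinate, coordinate]
    if var <= 0:
        raise ConditioningError(f"coordinate {coordinate} has non-positive variance")
    return KB * model.temperature / var


# ---------------------------------------------------------------------------
# Non-dimensionalization
# ---------------------------------------------------------------------------


def nondimensionalize(
    model: RigidBaseModel,
    length_scale: float = DEFAULT_LENGTH_SCALE,
    angle_scale: float = DEFAULT_ANGLE_SCALE,
) -> RigidBaseModel:
    """Divide every coordinate by its scale (1 A, 360/34 deg by default).

    The stiffness transforms contragradiently (K' = S K S for the diagonal
    scale matrix S), so deformation energies of corresponding displacements
    are unchanged.  Applying twice is rejected.
    """
    if model.scaling is not None:
        raise ValueError("model is already non-dimensionalized")
    if model.schema is None:
        raise ValueError("non-dimensionalization needs a coordinate schema")
    if length_scale <= 0 or angle_scale <= 0:
        raise ValueError("scales must be positive")
    s = model.schema.scale_vector(length_scale, angle_scale)
    return RigidBaseModel(
        model.w_hat / s,
        model.K * np.outer(s, s),
        model.temperature,
        model.schema,
        (length_scale, angle_scale),
    )


def redimensionalize(model: RigidBaseModel) -> RigidBaseModel:
    """Undo :func:`nondimensionalize`, restoring native units."""
    if model.scaling is None:
        raise ValueError("model is not non-dimensionalized")
    s = model.schema.scale_vector(*model.scaling)
    return RigidBaseModel(
        model.w_hat * s,
        model.K / np.outer(s, s),
        model.temperature,
        model.schema,
        None,
    )


# ---------------------------------------------------------------------------
# Half-trajectory error bars
# ---------------------------------------------------------------------------


def half_trajectory_error(
    statistic: Callable[[CoordinateTrajectory], np.ndarray | float],
    traj: CoordinateTrajectory,
) -> ErrorEstimate:
    """Error bar as the mean absolute deviation of half-trajectory estimates.

    The statistic is evaluated on the full trajectory and on each half; the
    reported error is the mean of |full - half| over the two halves,
    component-wise for vector statistics.
    """
    value = statistic(traj)
    first, second = traj.halves()
    parts = []
    for name, half in (("first", first), ("second", second)):
        try:
            parts.append(statistic(half))
        except Exception as exc:  # propagate with context
            raise type(exc)(f"statistic failed on {name} half: {exc}") from exc
    v = np.asarray(value, dtype=float)
    err = 0.5 * (np.abs(v - np.asarray(parts[0])) + np.abs(v - np.asarray(parts[1])))
    if np.ndim(value) == 0:
        return ErrorEstimate(float(value), float(err))
    return ErrorEstimate(v, err)
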