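"""Nucleosome-style threading of a duplex through a template geometry.

A template profile prescribes roll, twist and slide per step — the three
step coordinates that are strongly conserved across nucleosome structures.
A window of the duplex is constrained to the template values at some
offset while every other rigid-base coordinate relaxes to its optimum; the
resulting quadratic energy comes from the partially relaxed model (the
Schur complement of the full non-local stiffness onto the constrained
coordinates).  Shifting the window by 1 bp along the template and
repeating yields the deformation-energy profile; its minima mark the
rotational positionings the sequence prefers, and the energies are upper
bounds since no binding-partner adaptation is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import MarginalModel, RigidBaseModel, relax

#: Constrained step coordinates, in the order they are packed per step.
CONSTRAINED_COORDS = ("roll", "twist", "slide")


@dataclass
class TemplateProfile:
    """Per-step roll (deg), twist (deg) and slide (A) of a template geometry."""

    roll: np.ndarray
    twist: np.ndarray
    slide: np.ndarray
    dyad: int | None = None

    def __post_init__(self) -> None:
        self.roll = np.asarray(self.roll, dtype=float)
        self.twist = np.asarray(self.twist, dtype=float)
        self.slide = np.asarray(self.slide, dtype=float)
        if not (self.roll.shape == self.twist.shape == self.slide.shape):
            raise ValueError("roll, twist and slide must have equal lengths")
        if self.roll.ndim != 1 or self.roll.size < 1:
            raise ValueError("template must be a non-empty 1-D step profile")
        for name in ("roll", "twist", "slide"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"template {name} contains non-finite values")

    @property
    def n_steps(self) -> int:
        return self.roll.size

    def slice_vector(self, offset: int, n_steps: int) -> np.ndarray:
        """(roll, twist, slide) of steps offset..offset+n_steps-1, step-major."""
        sl = slice(offset, offset + n_steps)
        return np.column_stack([self.roll[sl], self.twist[sl], self.slide[sl]]).ravel()


@dataclass
class ThreadingProfile:
    """Deformation energy (kcal/mol) of a window at each 1-bp template offset."""

    offsets: np.ndarray
    energies: np.ndarray
    window_steps: tuple[int, int]
    description: str = ""

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.offsets.shape != self.energies.shape:
            raise ValueError("offsets and energies must align")

    @property
    def mean_energy(self) -> float:
        return float(self.energies.mean())


def thread(
    model: RigidBaseModel,
    template: TemplateProfile,
    window_steps: tuple[int, int] | None = None,
) -> ThreadingProfile:
    """Slide a duplex window along the template, recording relaxed energies.

    ``window_steps`` is the 1-based inclusive step range of the duplex that
    is constrained (default: all steps).  At offset k the window's roll,
    twist and slide are pinned to template steps k..k+L_w-1 and the energy
    E(k) = 1/2 (t_k - w_hat_A) . K~ (t_k - w_hat_A) is evaluated with the
    marginal stiffness K~ of the constrained coordinates.  Offsets run over
    the half-open admissible range [0, L_t - L_w], no wrap-around.
    """
    if model.schema is None:
        raise ValueError("threading requires a model with a coordinate schema")
    n_steps_model = model.schema.n_steps
    if window_steps is None:
        window_steps = (1, n_steps_model)
    s0, s1 = window_steps
    if not (1 <= s0 <= s1 <= n_steps_model):
        raise ValueError(f"invalid step window ({s0}, {s1}) for {n_steps_model} steps")
    L_w = s1 - s0 + 1
    if template.n_steps < L_w:
        raise ValueError(
            f"template has {template.n_steps} steps, window needs {L_w}"
        )
    subset = model.schema.step_subset(CONSTRAINED_COORDS, range(s0, s1 + 1))
    marginal = relax(model, subset)
    offsets = np.arange(template.n_steps - L_w + 1)
    energies = np.array(
        [marginal.deformation_energy(template.slice_vector(k, L_w)) for k in offsets]
    )
    return ThreadingProfile(
        offsets,
        energies,
        window_steps,
        description=f"steps {s0}-{s1} threaded over {template.n_steps}-step template",
    )


# ---------------------------------------------------------------------------
# Profile summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileSummary:
    """Mean/min energies, local minima and dominant offset periodicity."""

    mean: float
    min_energy: float
    argmin: int
    minima_offsets: tuple[int, ...]
    spacing: float | None
    spacing_defined: bool


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or x.size < window:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def _dominant_spacing(x: np.ndarray) -> float | None:
    # First local maximum of the (biased) autocorrelation at lag >= 1.
    x = x - x.mean()
    if np.allclose(x, 0.0, atol=1e-12):
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    for lag in range(1, ac.size - 1):
        if ac[lag] >= ac[lag - 1] and ac[lag] > ac[lag + 1] and ac[lag] > 0:
            # parabolic refinement around the discrete peak
            y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            return float(lag + delta)
    return None


def profile_summary(profile: ThreadingProfile, smooth_window: int = 3) -> ProfileSummary:
    """Summarize a threading profile.

    Local minima are located after a moving-average smoothing (window 3 by
    default) to suppress single-offset noise; the dominant spacing between
    preferred positions is the first autocorrelation peak of the
    mean-removed profile.  A flat profile has no defined spacing.
    """
    if profile.energies.size == 0:
        raise ValueError("profile is empty")
    e = profile.energies
    es = _smooth(e, smooth_window)
    minima = [
        int(profile.offsets[i])
        for i in range(1, es.size - 1)
        if es[i] <= es[i - 1] and es[i] < es[i + 1]
    ]
    spacing = _dominant_spacing(es)
    return ProfileSummary(
        mean=float(e.mean()),
        min_energy=float(e.min()),
        argmin=int(profile.offsets[int(np.argmin(e))]),
        minima_offsets=tuple(minima),
        spacing=spacing,
        spacing_defined=spacing is not None,
    )
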