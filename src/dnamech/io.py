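"""File dialects, snapshot filtering and configuration.

All on-disk formats are plain delimited text or JSON:

* coordinate trajectories — tab-separated, one row per snapshot, header
  naming each coordinate ``<name>_<index>`` in canonical order (1-based
  pair/step indices), ``#`` comment lines carrying units;
* base-pair frame trajectories — one row per (snapshot, pair) with the
  origin and the row-major 3x3 axes matrix;
* threading templates — columns step, roll, twist, slide;
* H-bond distance series — one row per snapshot, one column per pair;
* model archives and rod reports — JSON, lossless round-trip.

Snapshot filtering removes snapshots with a broken interior base pair
(Watson-Crick donor-acceptor distance above 4 A); terminal pairs fray
routinely and are ignored by the filter.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .elastic_rod import FrameTrajectory, RodModel
from .model_core import (
    CoordinateSchema,
    CoordinateTrajectory,
    MarginalModel,
    RigidBaseModel,
)
from .synthetic import HBondSeries
from .threading import TemplateProfile, ThreadingProfile

logger = logging.getLogger("dnamech")


class FileFormatError(ValueError):
    """Raised when an input file does not conform to its dialect."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FileFormatError(f"{path}: file is empty") from exc
    if df.empty:
        raise FileFormatError(f"{path}: no data rows")
    return df


def _to_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any():
        col = out.columns[out.isna().any()][0]
        row = int(out.index[out[col].isna()][0])
        bad = df.loc[row, col]
        raise FileFormatError(
            f"{path}: non-numeric value {bad!r} at data row {row + 1}, column {col!r}"
        )
    # convert from the raw strings so parsing is correctly rounded
    return df.astype(float)


# ---------------------------------------------------------------------------
# Coordinate trajectories
# ---------------------------------------------------------------------------


def write_trajectory(traj: CoordinateTrajectory, path: str | Path) -> None:
    path = Path(path)
    labels = traj.schema.labels()
    with open(path, "w") as fh:
        fh.write("# rigid-base coordinate trajectory\n")
        fh.write(f"# n = {traj.schema.n} base pairs, N = {traj.schema.N} coordinates\n")
        fh.write("# units: angles deg, distances angstrom\n")
        cols = labels if traj.snapshot_times is None else ["time"] + labels
        fh.write("\t".join(cols) + "\n")
        vals = traj.values
        if traj.snapshot_times is not None:
            vals = np.column_stack([traj.snapshot_times, vals])
        np.savetxt(fh, vals, fmt="%.17g", delimiter="\t")


def read_trajectory(
    path: str | Path, schema: CoordinateSchema | None = None
) -> CoordinateTrajectory:
    """Read a coordinate trajectory, reordering columns to canonical order.

    The header may list the coordinates in any order (and may include a
    leading ``time`` column); if ``schema`` is given the columns must match
    it exactly as a set.
    """
    path = Path(path)
    df = _read_table(path)
    times = None
    if "time" in df.columns:
        times = pd.to_numeric(df.pop("time"), errors="coerce").to_numpy()
    cols = list(df.columns)
    N = len(cols)
    if (N + 6) % 12 != 0:
        raise FileFormatError(
            f"{path}: {N} coordinate columns do not form a 12n-6 schema"
        )
    n = (N + 6) // 12
    inferred = CoordinateSchema(n)
    if schema is not None and schema.n != n:
        raise FileFormatError(
            f"{path}: file has n={n} base pairs, expected n={schema.n}"
        )
    canonical = inferred.labels()
    if set(cols) != set(canonical):
        missing = sorted(set(canonical) - set(cols))[:4]
        raise FileFormatError(f"{path}: header mismatch; e.g. missing {missing}")
    df = _to_numeric(df, path)[canonical]
    return CoordinateTrajectory(inferred, df.to_numpy(), snapshot_times=times)


# ---------------------------------------------------------------------------
# Frame trajectories
# ---------------------------------------------------------------------------

_FRAME_COLS = ["snapshot", "pair", "ox", "oy", "oz"] + [
    f"a{r}{c}" for r in (1, 2, 3) for c in (1, 2, 3)
]


def write_frames(frames: FrameTrajectory, path: str | Path) -> None:
    path = Path(path)
    M, n = frames.M, frames.n
    snap = np.repeat(np.arange(M), n)
    pair = np.tile(np.arange(1, n + 1), M)
    origins = frames.origins.reshape(M * n, 3)
    axes = frames.axes.reshape(M * n, 9)
    with open(path, "w") as fh:
        fh.write("# base-pair frame trajectory: origin (angstrom), axes row-major\n")
        fh.write("\t".join(_FRAME_COLS) + "\n")
        np.savetxt(
            fh,
            np.column_stack([snap, pair, origins, axes]),
            fmt=["%d", "%d"] + ["%.17g"] * 12,
            delimiter="\t",
        )


def read_frames(path: str | Path) -> FrameTrajectory:
    path = Path(path)
    df = _to_numeric(_read_table(path), path)
    if list(df.columns) != _FRAME_COLS:
        raise FileFormatError(f"{path}: expected columns {_FRAME_COLS}")
    snaps = df["snapshot"].astype(int).to_numpy()
    pairs = df["pair"].astype(int).to_numpy()
    M = snaps.max() + 1
    n = pairs.max()
    if len(df) != M * n:
        raise FileFormatError(f"{path}: expected {M * n} rows, found {len(df)}")
    order = np.lexsort((pairs, snaps))
    origins = df[["ox", "oy", "oz"]].to_numpy()[order].reshape(M, n, 3)
    axes = df[[c for c in _FRAME_COLS[5:]]].to_numpy()[order].reshape(M, n, 3, 3)
    return FrameTrajectory(origins, axes)


# ---------------------------------------------------------------------------
# Templates, H-bond series, profiles
# ---------------------------------------------------------------------------


def write_template(template: TemplateProfile, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# threading template: roll/twist deg, slide angstrom\n")
        if template.dyad is not None:
            fh.write(f"# dyad = {template.dyad}\n")
        fh.write("step\troll\ttwist\tslide\n")
        for s in range(template.n_steps):
            fh.write(
                f"{s + 1}\t{template.roll[s]:.17g}\t{template.twist[s]:.17g}"
                f"\t{template.slide[s]:.17g}\n"
            )


def read_template(path: str | Path) -> TemplateProfile:
    path = Path(path)
    dyad = None
    for line in open(path):
        if line.startswith("#") and "dyad" in line:
            dyad = int(line.split("=")[1])
    df = _to_numeric(_read_table(path), path)
    for col in ("step", "roll", "twist", "slide"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column {col!r}")
    df = df.sort_values("step")
    return TemplateProfile(
        df["roll"].to_numpy(), df["twist"].to_numpy(), df["slide"].to_numpy(), dyad=dyad
    )


def write_hbonds(hbonds: HBondSeries, path: str | Path) -> None:
    path = Path(path)
    n = hbonds.distances.shape[1]
    with open(path, "w") as fh:
        fh.write("# max Watson-Crick donor-acceptor distance per pair, angstrom\n")
        fh.write("\t".join(f"pair_{i}" for i in range(1, n + 1)) + "\n")
        np.savetxt(fh, hbonds.distances, fmt="%.6g", delimiter="\t")


def read_hbonds(path: str | Path) -> HBondSeries:
    path = Path(path)
    df = _to_numeric(_read_table(path), path)
    return HBondSeries(df.to_numpy())


def write_profile(profile: ThreadingProfile, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# threading profile: {profile.description}\n")
        fh.write("offset\tenergy_kcal_mol\n")
        for k, e in zip(profile.offsets, profile.energies):
            fh.write(f"{k}\t{e:.17g}\n")


# ---------------------------------------------------------------------------
# Model archives
# ---------------------------------------------------------------------------


def save_model(model: RigidBaseModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path: str | Path) -> RigidBaseModel:
    return RigidBaseModel.from_dict(json.loads(Path(path).read_text()))


def save_marginal(marginal: MarginalModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "subset": marginal.subset.tolist(),
                "w_hat": marginal.w_hat.tolist(),
                "K_tilde": marginal.K_tilde.tolist(),
                "temperature": marginal.temperature,
            },
            indent=1,
        )
    )


def save_rod_report(rod: RodModel, path: str | Path, extra: dict | None = None) -> None:
    d = rod.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=1))


def export_matrix(matrix: np.ndarray, path: str | Path, labels: list[str] | None = None) -> None:
    """Delimited-text export of a covariance or stiffness matrix."""
    path = Path(path)
    with open(path, "w") as fh:
        if labels is not None:
            fh.write("\t".join(labels) + "\n")
        np.savetxt(fh, np.atleast_2d(matrix), fmt="%.17g", delimiter="\t")


# ---------------------------------------------------------------------------
# Snapshot filtering
# ---------------------------------------------------------------------------


def filter_snapshots(
    traj: CoordinateTrajectory,
    hbonds: HBondSeries,
    cutoff: float = 4.0,
    ignore_terminal: bool = True,
) -> CoordinateTrajectory:
    """Drop snapshots in which any interior base pair is broken.

    A pair is broken when its maximum Watson-Crick donor-acceptor distance
    exceeds ``cutoff`` (4 A by default).  Terminal pairs break routinely
    through end fraying and are ignored unless ``ignore_terminal`` is
    False.  The removed fraction is logged.
    """
    dist = hbonds.distances
    if dist.shape != (len(traj.values), traj.schema.n):
        raise ValueError(
            f"H-bond series shape {dist.shape} does not match trajectory "
            f"({len(traj.values)} snapshots, {traj.schema.n} pairs)"
        )
    considered = dist[:, 1:-1] if ignore_terminal else dist
    keep = ~(considered > cutoff).any(axis=1)
    removed = int((~keep).sum())
    logger.info(
        "H-bond filter: removed %d of %d snapshots (%.2f%%)",
        removed,
        len(keep),
        100.0 * removed / len(keep),
    )
    return traj.select(keep)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict:
    """Flat ``key = value`` configuration; '#' starts a comment.

    Values are parsed as int, then float, then kept as strings.  Keys use
    underscores and mirror CLI flags.
    """
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FileFormatError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key.replace("-", "_")] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key.replace("-", "_")] = val
    return out
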