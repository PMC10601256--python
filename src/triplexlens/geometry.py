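"""Least-squares superposition (Kabsch), RMSD series, convergence windows."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from triplexlens.errors import DegeneracyError, ValidationError
from triplexlens.topology import Topology
from triplexlens.trajio import Trajectory

logger = logging.getLogger(__name__)


def superpose(
    reference: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense; the rotation is proper (det = +1).  Raises
    :class:`DegeneracyError` for fewer than 3 points or (near-)collinear
    selections, where the rotation is not uniquely determined.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape:
        raise ValidationError(
            f"coordinate shapes differ: {ref.shape} vs {mob.shape}"
        )
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise DegeneracyError("superposition needs at least 3 points in 3D")

    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    # collinearity check on both point sets
    for label, pts in (("reference", ref_c), ("mobile", mob_c)):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[0] == 0.0 or s[1] / s[0] < 1e-8:
            raise DegeneracyError(
                f"{label} selection is degenerate (collinear or coincident)"
            )

    h = mob_c.T @ ref_c
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    fitted = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD without superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("coordinate shapes differ")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    trajectory: Trajectory,
    topology: Topology,
    selection: str = "all",
    fit: bool = True,
) -> pd.DataFrame:
    """Per-frame RMSD vs the first frame on a named selection.

    ``selection`` ∈ {"rna", "duplex", "all"}.  With ``fit=True`` each frame
    is first superposed on the reference over the same selection.
    """
    idx = topology.select(selection=selection)
    ref = trajectory.coords[0, idx]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f, idx]
        if fit:
            _, _, values[f] = superpose(ref, frame)
        else:
            values[f] = raw_rmsd(ref, frame)
    return pd.DataFrame(
        {"time_ns": trajectory.times, "rmsd": values, "selection": selection}
    )


def converged_window(trajectory: Trajectory, tail: float = 400.0) -> np.ndarray:
    """Frame indices of the trailing ``tail`` ns of the trajectory.

    Selects frames with time strictly greater than ``t_end - tail``.  If the
    tail covers the whole span, all frames are returned with a warning.
    """
    if tail <= 0:
        raise ValidationError("tail must be > 0 ns")
    if trajectory.n_frames == 0:
        raise ValidationError("empty trajectory")
    t_end = float(trajectory.times[-1])
    span = t_end - float(trajectory.times[0])
    if tail >= span:
        logger.warning(
            "tail %.6g ns >= trajectory span %.6g ns — using all frames",
            tail,
            span,
        )
        return np.arange(trajectory.n_frames)
    return np.flatnonzero(trajectory.times > t_end - tail)


__all__ = ["superpose", "raw_rmsd", "rmsd_series", "converged_window"]
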