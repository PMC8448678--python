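"""Least-squares rigid-body superposition (Kabsch) and RMSD time series.

The Kabsch fit minimises the weighted RMSD between two coordinate sets over
proper rotations and translations; reflections are excluded by the usual
determinant correction.  A batched variant fits many frames to one reference
in a single vectorised pass (numpy's batched 3x3 SVD), which is what the
concatenation step uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SuperpositionError(ValueError):
    """Raised for degenerate point sets or mismatched inputs."""


@dataclass
class RigidTransform:
    """Proper rotation + translation; ``apply`` maps mobile coords onto the reference frame."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class RmsdSeries:
    """Per-frame RMSD (nm), optionally aggregated over several subunits."""

    times: np.ndarray  # (F,) ps
    values: np.ndarray  # (S, F) nm, one row per subunit
    selection: str = ""
    reference: str = ""

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        return self.values.std(axis=0)


def _weights(n: int, weights) -> np.ndarray:
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,):
        raise SuperpositionError(f"weights shape {w.shape} != ({n},)")
    if np.any(w < 0) or w.sum() <= 0:
        raise SuperpositionError("weights must be non-negative with positive sum")
    return w


def rmsd(a: np.ndarray, b: np.ndarray, weights=None) -> float:
    """Weighted root-mean-square deviation between two coordinate sets (nm)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise SuperpositionError("coordinate shapes differ")
    w = _weights(a.shape[0], weights)
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * d2) / w.sum()))


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal rigid fit of ``mobile`` onto ``reference``.

    Returns ``(RigidTransform, fitted_coordinates)``.  Requires at least 3
    non-collinear atoms; collinear or degenerate point sets are rejected.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise SuperpositionError("mobile and reference atom counts differ")
    n = mobile.shape[0]
    if n < 3:
        raise SuperpositionError("need >= 3 atoms for a rigid fit")
    w = _weights(n, weights)
    wn = w / w.sum()
    cm = wn @ mobile
    cr = wn @ reference
    H = (mobile - cm).T @ ((reference - cr) * wn[:, None])
    U, s, Vt = np.linalg.svd(H)
    # rank < 2 => points (near-)collinear, rotation under-determined
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise SuperpositionError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    tf = RigidTransform(rotation=R, translation=t)
    return tf, tf.apply(mobile)


def kabsch_fit_many(frames: np.ndarray, reference: np.ndarray, weights=None) -> np.ndarray:
    """Fit every frame of ``frames`` (F, A, 3) onto ``reference`` (A, 3); returns fitted frames.

    Vectorised over frames via batched SVD; agrees with :func:`kabsch_fit`
    frame by frame.
    """
    frames = np.asarray(frames, float)
    reference = np.asarray(reference, float)
    F, n, _ = frames.shape
    w = _weights(n, weights)
    wn = w / w.sum()
    cm = np.einsum("a,fax->fx", wn, frames)
    cr = wn @ reference
    X = frames - cm[:, None, :]
    Y = (reference - cr) * wn[:, None]
    H = np.einsum("fax,ay->fxy", X, Y)
    U, s, Vt = np.linalg.svd(H)
    if np.any(s[:, 1] <= 1e-12 * np.maximum(s[:, 0], 1e-300)):
        raise SuperpositionError("degenerate (collinear) point set in at least one frame")
    d = np.sign(np.linalg.det(np.einsum("fxy,fyz->fxz", np.transpose(Vt, (0, 2, 1)), np.transpose(U, (0, 2, 1)))))
    D = np.zeros((F, 3, 3))
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("fxy,fyz,fzw->fxw", np.transpose(Vt, (0, 2, 1)), D, np.transpose(U, (0, 2, 1)))
    return np.einsum("fax,fyx->fay", X, R) + cr


def rmsd_series(
    trajectories,
    reference: np.ndarray,
    *,
    times: np.ndarray | None = None,
    fit: bool = True,
    weights=None,
    selection: str = "",
    reference_label: str = "frame 0",
) -> RmsdSeries:
    """Per-frame RMSD against a reference, for one or several subunits.

    ``trajectories`` is a single (F, A, 3) array or a list of such arrays with
    identical shapes (one per subunit); with several subunits the series
    carries the per-frame mean and standard deviation across them.
    """
    if isinstance(trajectories, np.ndarray) and trajectories.ndim == 3:
        trajectories = [trajectories]
    reference = np.asarray(reference, float)
    rows = []
    for frames in trajectories:
        frames = np.asarray(frames, float)
        if frames.shape[1:] != reference.shape:
            raise SuperpositionError("selection/reference atom-count mismatch")
        fitted = kabsch_fit_many(frames, reference, weights) if fit else frames
        w = _weights(reference.shape[0], weights)
        d2 = np.sum((fitted - reference) ** 2, axis=2)
        rows.append(np.sqrt((d2 * w).sum(axis=1) / w.sum()))
    values = np.stack(rows)
    if times is None:
        times = np.arange(values.shape[1], dtype=float)
    return RmsdSeries(
        times=np.asarray(times, float),
        values=values,
        selection=selection,
        reference=reference_label,
    )
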