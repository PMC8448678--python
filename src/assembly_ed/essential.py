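"""Essential dynamics of concatenated subunit trajectories.

The central idea: instead of one long trajectory of a single heterodimer,
superpose the trajectories of *all* equivalent heterodimers of an assembly
onto a common reference and pool them into one ensemble before covariance
analysis.  The pooled ensemble samples the subunit's configuration space far
more broadly than any single subunit's trajectory of the same aggregate
length, so the principal modes (eigenvectors of the coordinate covariance)
converge with the number of concatenated subunits -- which this module also
quantifies (overlap matrices, RMSIP, convergence curves).

Conventions: population covariance (divide by N), mass-weighting off by
default, eigenvector sign fixed by making the largest-magnitude component
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .superpose import kabsch_fit_many
from .topology import AssemblyTopology
from .trajectory import SubunitTrajectory


class EssentialDynamicsError(ValueError):
    pass


# -- containers ------------------------------------------------------------------------


@dataclass
class ConcatenatedEnsemble:
    """Pooled, superposed subunit frames: (N_total, 3M) rows + row provenance."""

    rows: np.ndarray  # (N, 3M) nm
    labels: pd.DataFrame  # per-row: system, dimer_id, position_class, frame, time
    reference: np.ndarray  # (M, 3) structure all rows were fitted to
    selection: str = ""

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.rows.mean(axis=0)

    def subset(self, **criteria) -> "ConcatenatedEnsemble":
        """Rows whose labels match all given column=value criteria."""
        mask = np.ones(self.n_rows, dtype=bool)
        for col, val in criteria.items():
            values = self.labels[col].to_numpy()
            mask &= np.isin(values, val) if isinstance(val, (list, tuple, set)) else values == val
        return ConcatenatedEnsemble(
            rows=self.rows[mask],
            labels=self.labels[mask].reset_index(drop=True),
            reference=self.reference,
            selection=self.selection,
        )


@dataclass
class ModeSet:
    """Mean structure + orthonormal eigenvectors + descending eigenvalues (nm^2)."""

    mean: np.ndarray  # (3M,)
    eigenvectors: np.ndarray  # (k, 3M)
    eigenvalues: np.ndarray  # (k,), descending
    n_frames: int
    selection: str = ""

    def validate(self, tol: float = 1e-8) -> None:
        lam = self.eigenvalues
        if np.any(lam < -tol * max(lam.max(initial=0.0), 1.0)):
            raise EssentialDynamicsError("negative eigenvalues")
        if np.any(np.diff(lam) > tol * max(lam.max(initial=0.0), 1.0)):
            raise EssentialDynamicsError("eigenvalues not in descending order")
        G = self.eigenvectors @ self.eigenvectors.T
        if np.max(np.abs(G - np.eye(G.shape[0]))) > tol:
            raise EssentialDynamicsError("eigenvectors not orthonormal")

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class ScreeData:
    """Eigenvalue spectrum with per-mode fraction and accumulated dynamics.

    ``accumulated[i]`` is the ratio between the sum of all modes up to mode
    i+1 and the sum of all modes.
    """

    mode_index: np.ndarray  # 1..k
    eigenvalue: np.ndarray
    fraction: np.ndarray
    accumulated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": self.mode_index,
                "eigenvalue_nm2": self.eigenvalue,
                "fraction": self.fraction,
                "accumulated": self.accumulated,
            }
        )


@dataclass
class ProjectionSeries:
    """Centered scalar projections (nm) of ensemble rows onto selected modes."""

    values: np.ndarray  # (N, k)
    labels: pd.DataFrame
    mode_indices: np.ndarray  # 1-based

    def subset(self, **criteria) -> "ProjectionSeries":
        mask = np.ones(self.values.shape[0], dtype=bool)
        for col, val in criteria.items():
            values = self.labels[col].to_numpy()
            mask &= np.isin(values, val) if isinstance(val, (list, tuple, set)) else values == val
        return ProjectionSeries(
            values=self.values[mask],
            labels=self.labels[mask].reset_index(drop=True),
            mode_indices=self.mode_indices,
        )


@dataclass
class ProjectionHistogram:
    """2D population histogram of two projections, as log10 counts.

    Empty bins are NaN in ``log10_counts`` (distinct from log10(1) = 0).
    """

    counts: np.ndarray
    log10_counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


@dataclass
class OverlapMatrix:
    """|inner products| between two mode sets' eigenvectors, plus RMSIP."""

    values: np.ndarray  # (k, k), entries in [0, 1]
    rmsip: float
    label_a: str = ""
    label_b: str = ""


@dataclass
class ConvergenceCurve:
    """Mode-overlap between disjoint subunit subsets vs subset size N."""

    N: np.ndarray
    overlaps: np.ndarray  # (len(N), replicates) first-mode |inner product|
    rmsips: np.ndarray  # (len(N), replicates)
    replicates: int
    seed: int

    @property
    def mean_overlap(self) -> np.ndarray:
        return self.overlaps.mean(axis=1)

    @property
    def se_overlap(self) -> np.ndarray:
        return self.overlaps.std(axis=1, ddof=1) / np.sqrt(self.replicates)

    @property
    def mean_rmsip(self) -> np.ndarray:
        return self.rmsips.mean(axis=1)


# -- operations ------------------------------------------------------------------------


def concatenate(
    subunits: list[SubunitTrajectory],
    reference: np.ndarray,
    topology: AssemblyTopology | None = None,
    system: str = "",
    weights=None,
    reference_mode: str = "mean",
) -> ConcatenatedEnsemble:
    """Superpose and pool subunit trajectories into one ensemble.

    Every subunit frame is Kabsch-fitted onto ``reference``; with
    ``reference_mode="mean"`` (default) a second pass refits all frames onto
    the mean structure of the first pass, which removes the bias of an
    arbitrary reference choice from the covariance.  ``reference_mode="fixed"``
    keeps the single-pass fit.
    """
    if not subunits:
        raise EssentialDynamicsError("no subunits to concatenate")
    sig = subunits[0].ordering_signature
    n_atoms = subunits[0].n_atoms
    for s in subunits:
        if s.ordering_signature != sig or s.n_atoms != n_atoms:
            raise EssentialDynamicsError(
                f"subunit {s.dimer_id}: atom ordering signature mismatch, cannot concatenate"
            )
    reference = np.asarray(reference, float)
    if reference.shape != (n_atoms, 3):
        raise EssentialDynamicsError("reference atom count does not match subunits")

    fitted = [kabsch_fit_many(s.coordinates, reference, weights) for s in subunits]
    if reference_mode == "mean":
        mean_struct = np.concatenate(fitted).mean(axis=0)
        fitted = [kabsch_fit_many(s.coordinates, mean_struct, weights) for s in subunits]
        reference = mean_struct
    elif reference_mode != "fixed":
        raise EssentialDynamicsError(f"unknown reference_mode {reference_mode!r}")

    rows = np.concatenate([f.reshape(f.shape[0], -1) for f in fitted])
    label_frames = []
    for s in subunits:
        cls = topology.position_class(s.dimer_id) if topology is not None else "body"
        label_frames.append(
            pd.DataFrame(
                {
                    "system": system,
                    "dimer_id": s.dimer_id,
                    "position_class": cls,
                    "frame": np.arange(s.n_frames),
                    "time": s.times,
                }
            )
        )
    labels = pd.concat(label_frames, ignore_index=True)
    return ConcatenatedEnsemble(
        rows=rows, labels=labels, reference=reference, selection=subunits[0].selection
    )


def _as_rows(ensemble) -> np.ndarray:
    if isinstance(ensemble, ConcatenatedEnsemble):
        return ensemble.rows
    return np.asarray(ensemble, float)


def covariance_modes(ensemble, mass_weighted: bool = False, masses=None) -> ModeSet:
    """Eigendecomposition of the (population) covariance of ensemble rows.

    With ``mass_weighted=True`` the coordinates are scaled by sqrt(mass)
    before the covariance is formed (modes then live in mass-weighted
    coordinates); ``masses`` gives one mass per atom.
    """
    X = _as_rows(ensemble)
    if X.ndim != 2 or X.shape[0] < 2:
        raise EssentialDynamicsError("need >= 2 rows for a covariance")
    N, D = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    if mass_weighted:
        if masses is None:
            raise EssentialDynamicsError("mass_weighted=True requires per-atom masses")
        w = np.repeat(np.sqrt(np.asarray(masses, float)), 3)
        if w.shape != (D,):
            raise EssentialDynamicsError("masses length does not match coordinates")
        Xc = Xc * w
    C = (Xc.T @ Xc) / N
    lam, V = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    V = V[:, order].T  # rows are eigenvectors
    # deterministic sign: largest-|component| positive
    idx = np.argmax(np.abs(V), axis=1)
    signs = np.sign(V[np.arange(V.shape[0]), idx])
    signs[signs == 0] = 1.0
    V = V * signs[:, None]
    modes = ModeSet(
        mean=mean,
        eigenvectors=V,
        eigenvalues=lam,
        n_frames=N,
        selection=getattr(ensemble, "selection", ""),
    )
    modes.validate()
    return modes


def scree(modes: ModeSet) -> ScreeData:
    """Per-mode eigenvalue fraction and accumulated dynamics."""
    lam = modes.eigenvalues
    total = lam.sum()
    if total <= 0:
        raise EssentialDynamicsError("zero-variance spectrum has no scree fractions")
    frac = lam / total
    return ScreeData(
        mode_index=np.arange(1, lam.size + 1),
        eigenvalue=lam.copy(),
        fraction=frac,
        accumulated=np.cumsum(frac),
    )


def cattell_kink(scree_data, eps: float = 1e-9) -> list[int]:
    """Kink indices of a scree plot (essential-subspace boundary candidates).

    A kink at mode i means the spectrum drops sharply *after* mode i: the
    forward second difference of log-eigenvalues
    ``d_i = ln lam_i - 2 ln lam_{i+1} + ln lam_{i+2}`` is positive.  Kinks are
    returned ranked by d_i (largest first); the first entry is the
    essential-subspace boundary.  A smooth geometric spectrum has constant
    log-differences, hence no kink.  Accepts a :class:`ScreeData`,
    :class:`ModeSet` or plain eigenvalue array.
    """
    if isinstance(scree_data, ScreeData):
        lam = scree_data.eigenvalue
    elif isinstance(scree_data, ModeSet):
        lam = scree_data.eigenvalues
    else:
        lam = np.asarray(scree_data, float)
    lam = lam[lam > lam.max(initial=0.0) * 1e-14]
    if lam.size < 3:
        raise EssentialDynamicsError("need >= 3 positive eigenvalues for the kink criterion")
    f = np.log(lam)
    d = f[:-2] - 2.0 * f[1:-1] + f[2:]  # d[i] belongs to mode i+1 (1-based)
    kinks = [(float(d[i]), i + 1) for i in range(d.size) if d[i] > eps]
    kinks.sort(key=lambda t: -t[0])
    return [idx for _, idx in kinks]


def project(ensemble: ConcatenatedEnsemble, modes: ModeSet, k: int = 3) -> ProjectionSeries:
    """Centered projections (row - mean) . eigenvector, in nm, for the first k modes."""
    X = _as_rows(ensemble)
    if X.shape[1] != modes.eigenvectors.shape[1]:
        raise EssentialDynamicsError("ensemble/mode dimensionality mismatch")
    k = min(k, modes.eigenvectors.shape[0])
    values = (X - modes.mean) @ modes.eigenvectors[:k].T
    labels = (
        ensemble.labels
        if isinstance(ensemble, ConcatenatedEnsemble)
        else pd.DataFrame(index=range(X.shape[0]))
    )
    return ProjectionSeries(values=values, labels=labels, mode_indices=np.arange(1, k + 1))


def projection_histogram(px: np.ndarray, py: np.ndarray, bins: int = 100, limits=None) -> ProjectionHistogram:
    """2D log10-population histogram of two projection series.

    Bin edges are symmetric about zero and span at least +-4 sigma of each
    axis, widened when necessary so every sample is counted (total counts
    always equal the number of rows).
    """
    px = np.asarray(px, float).ravel()
    py = np.asarray(py, float).ravel()
    if px.size != py.size:
        raise EssentialDynamicsError("projection series must have equal row counts")
    if limits is None:
        lim_x = max(4.0 * px.std(), np.abs(px).max(initial=0.0) * (1 + 1e-9), 1e-12)
        lim_y = max(4.0 * py.std(), np.abs(py).max(initial=0.0) * (1 + 1e-9), 1e-12)
    else:
        lim_x = lim_y = float(limits)
    x_edges = np.linspace(-lim_x, lim_x, bins + 1)
    y_edges = np.linspace(-lim_y, lim_y, bins + 1)
    counts, _, _ = np.histogram2d(px, py, bins=[x_edges, y_edges])
    with np.errstate(divide="ignore"):
        log10 = np.where(counts > 0, np.log10(np.maximum(counts, 1e-300)), np.nan)
    return ProjectionHistogram(
        counts=counts.astype(int), log10_counts=log10, x_edges=x_edges, y_edges=y_edges
    )


def overlap_matrix(a: ModeSet, b: ModeSet, k: int | None = None, label_a: str = "", label_b: str = "") -> OverlapMatrix:
    """Absolute inner products between two mode sets + RMSIP over the k x k block."""
    if a.eigenvectors.shape[1] != b.eigenvectors.shape[1]:
        raise EssentialDynamicsError("mode sets have different dimensionality")
    if k is None:
        k = min(a.eigenvectors.shape[0], b.eigenvectors.shape[0])
    values = np.abs(a.eigenvectors[:k] @ b.eigenvectors[:k].T)
    rmsip = float(np.sqrt((values**2).sum() / k))
    return OverlapMatrix(values=values, rmsip=rmsip, label_a=label_a, label_b=label_b)


def convergence_curve(
    subunit_rows: list[np.ndarray],
    N_list,
    replicates: int = 20,
    seed: int = 0,
    k: int = 3,
) -> ConvergenceCurve:
    """Mode-overlap between disjoint random subunit subsets of growing size.

    ``subunit_rows`` holds one (frames, 3M) array per subunit, already
    superposed to a common reference.  For every N in ``N_list`` and
    replicate, two disjoint subsets of N subunits are drawn, a mode set is
    built from each pooled subset, and the first-mode |inner product| and
    RMSIP over the first k modes are recorded.
    """
    N_list = sorted(int(n) for n in N_list)
    n_sub = len(subunit_rows)
    if 2 * max(N_list) > n_sub:
        raise EssentialDynamicsError(
            f"N={max(N_list)} too large for disjoint subsets of {n_sub} subunits"
        )
    if min(N_list) < 1:
        raise EssentialDynamicsError("subset sizes must be >= 1")
    rng = np.random.default_rng(seed)
    overlaps = np.empty((len(N_list), replicates))
    rmsips = np.empty((len(N_list), replicates))
    for i, N in enumerate(N_list):
        for r in range(replicates):
            perm = rng.permutation(n_sub)
            rows_a = np.concatenate([subunit_rows[j] for j in perm[:N]])
            rows_b = np.concatenate([subunit_rows[j] for j in perm[N : 2 * N]])
            ma = covariance_modes(rows_a)
            mb = covariance_modes(rows_b)
            om = overlap_matrix(ma, mb, k=k)
            overlaps[i, r] = om.values[0, 0]
            rmsips[i, r] = om.rmsip
    return ConvergenceCurve(
        N=np.array(N_list), overlaps=overlaps, rmsips=rmsips, replicates=replicates, seed=seed
    )


def block_average(series: np.ndarray, block_size: int) -> np.ndarray:
    """Average non-overlapping consecutive blocks; a trailing partial block is averaged as-is.

    Works on 1D series and on 2D arrays (blocks along axis 0).
    """
    if block_size < 1:
        raise EssentialDynamicsError("block_size must be >= 1")
    x = np.asarray(series, float)
    n = x.shape[0]
    starts = np.arange(0, n, block_size)
    sums = np.add.reduceat(x, starts, axis=0)
    counts = np.diff(np.append(starts, n)).astype(float)
    if x.ndim == 1:
        return sums / counts
    return sums / counts[:, None]
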