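"""Ensemble dynamics: cross-correlation maps and essential-dynamics PCA.

Works on coordinate ensembles (frames x residues x 3, one point per residue
— conventionally the Calpha position). The dynamic cross-correlation map
(DCCM) between residues i and j is

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

with dr the displacement from the time-averaged position: +1 means the two
residues move in the same direction, -1 in opposite directions. Essential
dynamics diagonalises the covariance of the flattened coordinates, ranking
collective motions by their variance contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "TrajectoryEnsemble",
    "CorrelationMap",
    "PCAResult",
    "CouplingScore",
    "superpose",
    "compute_dccm",
    "site_coupling",
    "trajectory_pca",
]


@dataclass
class TrajectoryEnsemble:
    """Coordinate ensemble with residue labels and optional named sites.

    ``residue_sets`` maps a site name (e.g. ``"site1"``) to 0-based residue
    indices; ``ground_truth`` optionally records the generating covariance
    spec of a synthetic ensemble.
    """

    coords: np.ndarray  # (n_frames, n_residues, 3), Angstrom
    labels: Optional[list[str]] = None
    residue_sets: dict[str, list[int]] = field(default_factory=dict)
    superposed: bool = False
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_residues, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.labels is None:
            self.labels = [f"R{i+1}" for i in range(self.n_residues)]
        if len(self.labels) != self.n_residues:
            raise ValueError("one label per residue required")
        for name, idx in self.residue_sets.items():
            idx = np.asarray(idx, int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_residues):
                raise ValueError(f"residue set {name!r} indexes outside the ensemble")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def mean_structure(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def _kabsch_align(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of one frame onto the reference."""
    cm_mob = mobile.mean(axis=0)
    cm_ref = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cm_ref, mobile - cm_mob)
    return rot.apply(mobile - cm_mob) + cm_ref


def superpose(ens: TrajectoryEnsemble, reference_frame: int = 0) -> TrajectoryEnsemble:
    """Rigid-body superpose every frame onto a reference frame.

    The optimal rotation is the SVD-based (Kabsch) least-squares solution
    over all residues. Collinear reference coordinates leave the rotation
    about the line undetermined and raise an error.
    """
    if not 0 <= reference_frame < ens.n_frames:
        raise IndexError("reference frame out of range")
    ref = ens.coords[reference_frame]
    centered = ref - ref.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise ValueError("degenerate (collinear) reference coordinates")
    with warnings.catch_warnings():
        # align_vectors warns for near-exact alignments; harmless here
        warnings.simplefilter("ignore", UserWarning)
        aligned = np.stack([_kabsch_align(f, ref) for f in ens.coords])
    return TrajectoryEnsemble(
        coords=aligned,
        labels=list(ens.labels),
        residue_sets=dict(ens.residue_sets),
        superposed=True,
        ground_truth=ens.ground_truth,
    )


@dataclass
class CorrelationMap:
    """Symmetric residue-pair displacement-correlation matrix in [-1, 1].

    Rows/columns of residues with zero displacement variance are NaN
    (undefined) except for the unit diagonal.
    """

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite.T], atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("diagonal must be exactly 1")
        if np.any(np.abs(m[finite]) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        self.matrix = m

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CorrelationMap":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.columns))

    def plot(self, ax=None, residue_offset: int = 0):
        """Heat map with the conventional coloring: blue -1, green 0, red +1.

        ``residue_offset`` shifts the axis numbering (e.g. to display
        construct residue numbers rather than array indices).
        """
        import matplotlib.pyplot as plt
        from matplotlib.colors import LinearSegmentedColormap

        if ax is None:
            _, ax = plt.subplots()
        cmap = LinearSegmentedColormap.from_list("dccm", ["blue", "green", "red"])
        n = self.n_residues
        extent = (
            residue_offset + 0.5,
            residue_offset + n + 0.5,
            residue_offset + 0.5,
            residue_offset + n + 0.5,
        )
        im = ax.imshow(
            self.matrix, cmap=cmap, vmin=-1, vmax=1, origin="lower", extent=extent
        )
        ax.set_xlabel("residue")
        ax.set_ylabel("residue")
        plt.colorbar(im, ax=ax, label="C$_{ij}$")
        return ax


def compute_dccm(ens: TrajectoryEnsemble) -> CorrelationMap:
    """Dynamic cross-correlation map of residue displacements.

    Requires a superposed ensemble with at least 10 frames. Residues with
    zero displacement variance get NaN rows/columns (with a warning); the
    diagonal stays 1.
    """
    if not ens.superposed:
        raise ValueError("ensemble must be superposed before computing the DCCM")
    if ens.n_frames < 10:
        raise ValueError("DCCM needs at least 10 frames")
    dev = ens.coords - ens.coords.mean(axis=0, keepdims=True)
    # cov_ij = <dr_i . dr_j>, averaged over frames
    cov = np.einsum("fia,fja->ij", dev, dev) / ens.n_frames
    var = np.diag(cov).copy()
    zero = var <= 1e-300
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} residue(s) with zero displacement variance; "
            "their correlations are undefined (NaN)",
            stacklevel=2,
        )
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    c = cov / denom
    c[zero, :] = np.nan
    c[:, zero] = np.nan
    np.fill_diagonal(c, 1.0)
    return CorrelationMap(c, list(ens.labels))


@dataclass(frozen=True)
class CouplingScore:
    """Summary of inter-site coupling over an A x B rectangle of the map."""

    mean_correlation: float
    mean_abs_correlation: float
    fraction_strong: float
    threshold: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "mean_correlation": self.mean_correlation,
            "mean_abs_correlation": self.mean_abs_correlation,
            "fraction_strong": self.fraction_strong,
            "threshold": self.threshold,
            "n_pairs": self.n_pairs,
        }


def site_coupling(
    cmap: CorrelationMap,
    set_a: Sequence[int],
    set_b: Sequence[int],
    threshold: float = 0.5,
) -> CouplingScore:
    """Quantify correlated motion between two disjoint residue sets.

    Reports the mean signed correlation, the mean absolute correlation and
    the fraction of pairs with |C_ij| >= ``threshold`` over all A x B pairs.
    """
    a = np.asarray(set_a, int)
    b = np.asarray(set_b, int)
    if a.size == 0 or b.size == 0:
        raise ValueError("residue sets must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("residue sets must be disjoint")
    block = cmap.matrix[np.ix_(a, b)]
    vals = block[np.isfinite(block)]
    if vals.size == 0:
        raise ValueError("all pair correlations undefined")
    return CouplingScore(
        mean_correlation=float(vals.mean()),
        mean_abs_correlation=float(np.abs(vals).mean()),
        fraction_strong=float(np.mean(np.abs(vals) >= threshold)),
        threshold=threshold,
        n_pairs=int(vals.size),
    )


@dataclass
class PCAResult:
    """Essential-dynamics decomposition of the coordinate covariance."""

    eigenvalues_A2: np.ndarray  # descending, length k
    modes: np.ndarray  # (k, 3*n_residues), orthonormal rows
    projections: np.ndarray  # (n_frames, k)
    explained_fraction: np.ndarray
    total_variance_A2: float

    def to_dict(self) -> dict:
        return {
            "eigenvalues_A2": self.eigenvalues_A2.tolist(),
            "explained_fraction": self.explained_fraction.tolist(),
            "total_variance_A2": self.total_variance_A2,
        }


def trajectory_pca(ens: TrajectoryEnsemble, k: int = 3) -> PCAResult:
    """Principal modes of the mean-centered flattened coordinates.

    Eigenvalues are displacement variances (Angstrom^2, population
    normalisation 1/n_frames, matching the DCCM); projections are the
    centered frames dotted with each mode and therefore have zero mean.
    """
    if not ens.superposed:
        raise ValueError("ensemble must be superposed before PCA")
    if ens.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    dim = 3 * ens.n_residues
    if not 1 <= k <= dim:
        raise ValueError(f"k must be in [1, {dim}]")
    X = ens.coords.reshape(ens.n_frames, dim)
    X = X - X.mean(axis=0, keepdims=True)
    # SVD of the centered data avoids forming the (possibly large) covariance
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / ens.n_frames
    total = float(np.sum(X**2) / ens.n_frames)
    return PCAResult(
        eigenvalues_A2=eig[:k],
        modes=Vt[:k],
        projections=X @ Vt[:k].T,
        explained_fraction=eig[:k] / total if total > 0 else np.zeros(k),
        total_variance_A2=total,
    )
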