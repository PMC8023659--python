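"""Configurational landscapes of the Mg2+–triphosphate tail.

The six-atom tail representation (Palpha, O3alpha, Pbeta, O3beta, Pgamma,
Mg2+) captures the metal–phosphate coordination geometry while averaging
over the rest of the nucleotide.  This module superposes tail frames
(Kabsch least-squares fit, iterated mean reference), performs a coordinate
PCA on the flattened 18-dimensional vectors, estimates density maps with
cluster labels on the 2D eigenvector projection, and converts (reweighted)
sample densities into free-energy surfaces, including the reprojection
onto the alpha–beta–gamma phosphate angle.

Units: coordinates are handled internally in Å; eigenvector projections
are reported in nm (matching the conventional axis labelling of such
maps); angles in degrees; free energies in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

from .structure_mining import LigandComplex

__all__ = [
    "TAIL_ATOM_ORDER",
    "TailFrame",
    "PCAModel",
    "Axis",
    "FreeEnergySurface",
    "DensityClusterMap",
    "ExtractionError",
    "extract_tail_frame",
    "superpose",
    "fit_pca",
    "project",
    "estimate_density_clusters",
    "build_fes",
    "marginalize_fes",
    "phosphate_angle",
    "reproject_angle_fes",
    "select_diverse_subset",
    "KT_300K",
]

#: Boltzmann constant times 300 K, in kcal/mol.
KT_300K = 0.0019872041 * 300.0  # 0.59616

#: Fixed atom order of the tail representation.
TAIL_ATOM_ORDER = ("PA", "O3A", "PB", "O3B", "PG", "MG")

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


class ExtractionError(ValueError):
    """Raised when a complex lacks one of the six tail atoms."""


@dataclass
class TailFrame:
    """Coordinates of the six tail atoms plus all phosphate oxygens (Å)."""

    six_atom_coords: np.ndarray  # (6, 3)
    all_phosphate_oxygens: dict[str, np.ndarray] = field(default_factory=dict)
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.six_atom_coords = np.asarray(self.six_atom_coords, dtype=float)
        if self.six_atom_coords.shape != (6, 3):
            raise ValueError("six_atom_coords must be a 6x3 matrix")
        if not np.all(np.isfinite(self.six_atom_coords)):
            raise ValueError("non-finite tail coordinates")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")

    def atom(self, name: str) -> np.ndarray:
        return self.six_atom_coords[TAIL_ATOM_ORDER.index(name)]

    @property
    def flat(self) -> np.ndarray:
        return self.six_atom_coords.reshape(-1)

    def mg_pa_distance(self) -> float:
        return float(np.linalg.norm(self.atom("MG") - self.atom("PA")))


@dataclass
class PCAModel:
    """Coordinate PCA of flattened 18-vectors (uniform weights, no masses)."""

    mean_coords: np.ndarray        # (18,)
    eigenvectors: np.ndarray       # (18, m), orthonormal columns
    eigenvalues: np.ndarray        # (m,), Å^2, nonincreasing

    def __post_init__(self) -> None:
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10):
            raise ValueError("eigenvector columns must be orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")


@dataclass
class Axis:
    name: str
    edges: np.ndarray
    units: str

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class FreeEnergySurface:
    """Binned free-energy map, min-shifted to zero over finite bins."""

    axes: list[Axis]
    free_energy: np.ndarray
    bin_weight: np.ndarray
    inaccessible_mask: np.ndarray
    kT: float
    cap: float = 18.0


@dataclass
class DensityClusterMap:
    axes: list[Axis]
    density: np.ndarray
    cluster_labels: np.ndarray     # 0 = background
    cluster_names: dict[int, str]


# ---------------------------------------------------------------------------
# Frame extraction and superposition
# ---------------------------------------------------------------------------

def extract_tail_frame(cx: LigandComplex) -> TailFrame:
    """Pull the six tail atoms (and the oxygen map) out of a complex."""
    coords = np.empty((6, 3))
    for i, name in enumerate(TAIL_ATOM_ORDER):
        if name == "MG":
            coords[i] = cx.mg.position
            continue
        try:
            coords[i] = cx.atom(name).position
        except KeyError:
            raise ExtractionError(f"{cx.source_id}: missing tail atom {name}"
                                  ) from None
    oxygens = {
        a.atom_name: a.position.copy()
        for a in cx.atp_atoms
        if a.atom_name in {"O1A", "O2A", "O3A", "O1B", "O2B", "O3B",
                           "O1G", "O2G", "O3G", "O5'"}
    }
    return TailFrame(coords, oxygens)


def _kabsch_transform(mobile: np.ndarray, reference: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid fit of mobile onto reference: returns (R, t_mob, t_ref)."""
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    return rot.as_matrix(), mob_c, ref_c


def _apply_fit(frame: TailFrame, R: np.ndarray, mob_c: np.ndarray,
               ref_c: np.ndarray) -> TailFrame:
    new_coords = (frame.six_atom_coords - mob_c) @ R.T + ref_c
    new_oxy = {k: (v - mob_c) @ R.T + ref_c
               for k, v in frame.all_phosphate_oxygens.items()}
    return TailFrame(new_coords, new_oxy, frame.weight)


def superpose(frames: Sequence[TailFrame],
              reference: TailFrame | str = "iterative-mean",
              max_iter: int = 50, rmsd_tol: float = 1e-6
              ) -> list[TailFrame]:
    """Least-squares rigid-body fit of each frame onto a common reference.

    With ``reference="iterative-mean"``, frames are first fitted onto the
    first frame, then repeatedly onto the mean structure until the mean
    changes by less than ``rmsd_tol`` Å RMSD.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    for f in frames:
        _check_nondegenerate(f.six_atom_coords)

    def fit_all(ref_coords: np.ndarray) -> list[TailFrame]:
        out = []
        for f in frames:
            R, mc, rc = _kabsch_transform(f.six_atom_coords, ref_coords)
            out.append(_apply_fit(f, R, mc, rc))
        return out

    if isinstance(reference, TailFrame):
        return fit_all(reference.six_atom_coords)

    if reference != "iterative-mean":
        raise ValueError(f"unknown reference {reference!r}")
    ref = frames[0].six_atom_coords
    fitted = fit_all(ref)
    for _ in range(max_iter):
        mean = np.mean([f.six_atom_coords for f in fitted], axis=0)
        _check_nondegenerate(mean)
        change = np.sqrt(np.mean((mean - ref) ** 2))
        fitted = fit_all(mean)
        ref = mean
        if change < rmsd_tol:
            break
    return fitted


def _check_nondegenerate(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9:
        raise ValueError("degenerate (collinear) reference structure")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(frames: Sequence[TailFrame],
            c2c3_labels: Sequence[str] | None = None) -> PCAModel:
    """Eigendecompose the sample covariance of flattened tail coordinates.

    Frames must already be superposed.  When ``c2c3_labels`` are supplied,
    eigenvector signs are fixed so the mean C3 projection on EV2 is
    negative and the mean C2 projection on EV1 is positive (the
    conventional map orientation); otherwise each eigenvector's
    largest-magnitude component is made positive.
    """
    if len(frames) < 2:
        raise ValueError("PCA needs at least two frames")
    X = np.array([f.flat for f in frames])
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if c2c3_labels is not None:
        labels = np.asarray(c2c3_labels)
        proj = (X - mean) @ evecs
        if np.any(labels == "C3") and proj[labels == "C3", 1].mean() > 0:
            evecs[:, 1] *= -1
        if np.any(labels == "C2") and proj[labels == "C2", 0].mean() < 0:
            evecs[:, 0] *= -1
    else:
        for j in range(evecs.shape[1]):
            i = np.argmax(np.abs(evecs[:, j]))
            if evecs[i, j] < 0:
                evecs[:, j] *= -1
    return PCAModel(mean_coords=mean, eigenvectors=evecs, eigenvalues=evals)


def project(model: PCAModel, frames: Sequence[TailFrame],
            n_components: int = 2) -> np.ndarray:
    """Project frames onto the leading eigenvectors; output in nm."""
    X = np.array([f.flat for f in frames])
    if X.shape[1] != model.mean_coords.shape[0]:
        raise ValueError("frame dimensionality does not match the model")
    proj_angstrom = (X - model.mean_coords) @ model.eigenvectors[:, :n_components]
    return proj_angstrom / 10.0  # Å -> nm


# ---------------------------------------------------------------------------
# Density maps and clusters
# ---------------------------------------------------------------------------

def estimate_density_clusters(
    projections: np.ndarray,
    weights: np.ndarray | None = None,
    bandwidth: str | float = "silverman",
    level: float = 0.2,
    grid_size: int = 100,
    pad_fraction: float = 0.05,
) -> DensityClusterMap:
    """Gaussian KDE on a regular grid with connected-component clusters.

    Clusters are the connected components of the region where the density
    exceeds ``level`` times its maximum, labelled I, II, ... in order of
    decreasing total mass.
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("projections must be an (n, 2) array")
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 points for a density estimate")
    if np.allclose(pts.std(axis=0), 0):
        raise ValueError("all points identical: zero-bandwidth density")
    kde = gaussian_kde(pts.T, bw_method=bandwidth, weights=weights)
    axes = [_padded_axis(pts[:, i], grid_size, pad_fraction,
                         name=f"EV{i + 1}", units="nm") for i in range(2)]
    gx, gy = np.meshgrid(axes[0].centers, axes[1].centers, indexing="ij")
    density = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    cell = np.diff(axes[0].edges)[0] * np.diff(axes[1].edges)[0]
    density = density / (density.sum() * cell)
    labels, n_found = ndimage.label(density >= level * density.max())
    masses = ndimage.sum_labels(density, labels, index=np.arange(1, n_found + 1))
    order = np.argsort(masses)[::-1]
    relabel = np.zeros(n_found + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        relabel[old + 1] = new
    labels = relabel[labels]
    names = {i + 1: _ROMAN[i] if i < len(_ROMAN) else str(i + 1)
             for i in range(n_found)}
    return DensityClusterMap(axes=axes, density=density,
                             cluster_labels=labels, cluster_names=names)


def _padded_axis(values: np.ndarray, n_bins: int, pad: float,
                 name: str, units: str) -> Axis:
    lo, hi = float(np.min(values)), float(np.max(values))
    span = hi - lo
    if span == 0:
        span = max(abs(lo), 1.0)
    lo -= pad * span
    hi += pad * span
    return Axis(name=name, edges=np.linspace(lo, hi, n_bins + 1), units=units)


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

def build_fes(
    projections: np.ndarray,
    weights: np.ndarray | None = None,
    axes: Sequence[Axis] | None = None,
    kT: float = KT_300K,
    cap: float = 18.0,
    n_bins: int = 100,
) -> FreeEnergySurface:
    """F(bin) = −kT ln(sum of weights in bin), min-shifted to zero.

    Accepts 1D samples (shape (n,)) or 2D samples (shape (n, 2)).  Empty
    bins and bins above ``cap`` kcal/mol are flagged inaccessible.
    """
    pts = np.asarray(projections, dtype=float)
    one_d = pts.ndim == 1
    if one_d:
        pts = pts[:, None]
    n, dim = pts.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("total weight must be positive")
    if axes is None:
        axes = [_padded_axis(pts[:, i], n_bins, 0.05, name=f"axis{i}",
                             units="") for i in range(dim)]
    edges = [ax.edges for ax in axes]
    hist, _ = np.histogramdd(pts, bins=edges, weights=weights)
    with np.errstate(divide="ignore"):
        F = -kT * np.log(hist)
    finite = np.isfinite(F)
    F[finite] -= F[finite].min()
    mask = (hist == 0) | (F > cap)
    return FreeEnergySurface(axes=list(axes), free_energy=F, bin_weight=hist,
                             inaccessible_mask=mask, kT=kT, cap=cap)


def marginalize_fes(fes: FreeEnergySurface, keep_axis: int) -> FreeEnergySurface:
    """Marginalize a 2D surface onto one axis by summing bin weights."""
    if fes.free_energy.ndim != 2:
        raise ValueError("marginalize_fes expects a 2D surface")
    sum_axis = 1 - keep_axis
    w = fes.bin_weight.sum(axis=sum_axis)
    with np.errstate(divide="ignore"):
        F = -fes.kT * np.log(w)
    finite = np.isfinite(F)
    F[finite] -= F[finite].min()
    mask = (w == 0) | (F > fes.cap)
    return FreeEnergySurface(axes=[fes.axes[keep_axis]], free_energy=F,
                             bin_weight=w, inaccessible_mask=mask,
                             kT=fes.kT, cap=fes.cap)


def phosphate_angle(frame: TailFrame) -> float:
    """Interior alpha–beta–gamma phosphate angle at Pbeta, in degrees."""
    pa, pb, pg = frame.atom("PA"), frame.atom("PB"), frame.atom("PG")
    v1, v2 = pa - pb, pg - pb
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("coincident phosphorus atoms")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def reproject_angle_fes(
    frames: Sequence[TailFrame],
    weights: np.ndarray | None,
    ev2_projections: np.ndarray,
    kT: float = KT_300K,
    cap: float = 18.0,
    n_bins: int = 100,
    axes: Sequence[Axis] | None = None,
) -> FreeEnergySurface:
    """2D free-energy surface over (phosphate angle [deg], EV2 [nm])."""
    angles = np.array([phosphate_angle(f) for f in frames])
    pts = np.column_stack([angles, np.asarray(ev2_projections)])
    if axes is None:
        axes = [
            _padded_axis(pts[:, 0], n_bins, 0.05, name="angle", units="deg"),
            _padded_axis(pts[:, 1], n_bins, 0.05, name="EV2", units="nm"),
        ]
    return build_fes(pts, weights, axes=axes, kT=kT, cap=cap)


# ---------------------------------------------------------------------------
# Diverse subset selection
# ---------------------------------------------------------------------------

def select_diverse_subset(projections: np.ndarray, k: int) -> list[int]:
    """Pick k points maximizing the sum of mutual Euclidean distances.

    Greedy construction followed by pairwise-exchange refinement; exact
    maximization is NP-hard, but the exchange step recovers the optimum on
    small instances.  Deterministic for a given input order.
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if k > n:
        raise ValueError(f"cannot select {k} of {n} points")
    if k == n:
        return list(range(n))
    if k <= 0:
        return []
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    # greedy: seed with the globally farthest pair, then add best marginal gain
    i, j = np.unravel_index(np.argmax(D), D.shape)
    chosen = [min(i, j)] if k == 1 else [int(min(i, j)), int(max(i, j))]
    chosen = chosen[:k]
    while len(chosen) < k:
        gains = D[:, chosen].sum(axis=1)
        gains[chosen] = -np.inf
        chosen.append(int(np.argmax(gains)))
    # pairwise exchange until no single swap improves the objective
    improved = True
    while improved:
        improved = False
        inside = set(chosen)
        for pos in range(k):
            current = chosen[pos]
            others = [c for c in chosen if c != current]
            base = D[current, others].sum()
            contrib = D[:, others].sum(axis=1)
            contrib[list(inside)] = -np.inf
            best = int(np.argmax(contrib))
            if contrib[best] > base + 1e-12:
                inside.discard(current)
                inside.add(best)
                chosen[pos] = best
                improved = True
    return sorted(chosen)
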