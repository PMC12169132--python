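"""Essential dynamics: covariance PCA and two-state subspace comparison.

The positional covariance of the superposed Cα coordinates is
diagonalised; eigenvectors sorted by decreasing eigenvalue are the
principal components (collective motion modes).  Designated components —
typically PC1 when it is dominated by a disordered tail — can be excluded:
they stay in the object but are skipped by the variance accounting,
subspace comparison and projection defaults.  Component numbering is
1-based and always refers to the pre-exclusion rank, so "PC2" keeps its
identity after PC1 is excluded.

Two-state similarity is reported three ways, all standard:

* the full dot-product matrix ``D_ij = |v_i^A · v_j^B|`` over the first
  ``m`` retained modes,
* RMSIP = sqrt(mean of D²) with the derived subspace-overlap percentage
  RMSIP² × 100,
* the Hess covariance overlap, which additionally weights by eigenvalue.

Per-mode maximum dot products are reported averaged over A-modes, over
B-modes, and over both, since conventions differ between studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .ensemble import Ensemble
from .geometry import iterative_mean_align

__all__ = [
    "EssentialSubspace",
    "OverlapReport",
    "ModevectorField",
    "compute_subspace",
    "components_for_variance",
    "compare_subspaces",
    "project_density",
    "modevectors",
]


@dataclass
class EssentialSubspace:
    selection: np.ndarray          # atom indices the PCA was computed over
    mean: np.ndarray               # (3n,) mean conformation of the selection
    eigenvalues: np.ndarray        # descending, Å²
    eigenvectors: np.ndarray       # (3n, K) orthonormal columns
    variance_fractions: np.ndarray
    excluded: tuple = ()           # 1-based component ranks excluded downstream
    state: str = ""

    def retained(self) -> np.ndarray:
        """1-based component ranks that remain after exclusion, in order."""
        return np.array([k for k in range(1, len(self.eigenvalues) + 1)
                         if k not in self.excluded], dtype=int)

    def component_vector(self, rank: int) -> np.ndarray:
        return self.eigenvectors[:, rank - 1]

    def component_eigenvalue(self, rank: int) -> float:
        return float(self.eigenvalues[rank - 1])


@dataclass
class OverlapReport:
    m: int
    dot_matrix: np.ndarray
    rmsip: float
    subspace_overlap_pct: float
    hess_overlap: float
    max_dot_per_a: np.ndarray
    max_dot_per_b: np.ndarray
    mean_max_dot_a: float
    mean_max_dot_b: float
    mean_max_dot_both: float
    best_pairs: list  # (rank_a, rank_b, dot) sorted by dot descending


@dataclass
class ModevectorField:
    component: int
    vectors: np.ndarray     # (n_atoms_sel, 3) displacement between extremes
    magnitudes: np.ndarray  # per selected atom
    extreme_plus: np.ndarray
    extreme_minus: np.ndarray


def compute_subspace(ensemble: Ensemble, selection=None, exclude=(),
                     superpose: bool = True) -> EssentialSubspace:
    """Diagonalise the positional covariance of the selected coordinates.

    Frames are aligned to their iterative mean over the selection (two
    passes) unless ``superpose=False``; the covariance is unweighted, as
    is conventional for Cα essential dynamics.
    """
    if ensemble.n_frames < 2:
        raise ValueError("covariance analysis needs at least 2 frames")
    top = ensemble.topology
    if selection is None:
        selection = top.calpha_indices()
    selection = np.asarray(selection, dtype=np.intp)
    dim = 3 * selection.size
    if ensemble.n_frames <= dim:
        warnings.warn(
            f"only {ensemble.n_frames} frames for a {dim}-dimensional covariance; "
            "the spectrum is rank-deficient", stacklevel=2)
    if superpose:
        aligned, _ = iterative_mean_align(ensemble.coords, selection)
    else:
        aligned = ensemble.coords
    X = aligned[:, selection, :].reshape(ensemble.n_frames, dim)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (ensemble.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return EssentialSubspace(
        selection=selection, mean=mean, eigenvalues=evals, eigenvectors=evecs,
        variance_fractions=fractions, excluded=tuple(int(k) for k in exclude),
        state=ensemble.state,
    )


def components_for_variance(subspace: EssentialSubspace, fraction: float = 0.95) -> int:
    """Smallest number of retained components whose cumulative variance
    (renormalised over the retained set) reaches ``fraction``, boundary
    inclusive."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    ranks = subspace.retained()
    vals = subspace.eigenvalues[ranks - 1]
    total = vals.sum()
    if total == 0:
        return 0
    cum = np.cumsum(vals) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def compare_subspaces(sub_a: EssentialSubspace, sub_b: EssentialSubspace,
                      m: int = 10) -> OverlapReport:
    """Dot-product matrix, RMSIP and covariance overlap of the first ``m``
    retained modes of each subspace."""
    if sub_a.eigenvectors.shape[0] != sub_b.eigenvectors.shape[0]:
        raise ValueError("subspaces have different coordinate dimensions")
    ranks_a = sub_a.retained()[:m]
    ranks_b = sub_b.retained()[:m]
    if len(ranks_a) < m or len(ranks_b) < m:
        raise ValueError(f"fewer than m={m} retained modes available")
    Va = sub_a.eigenvectors[:, ranks_a - 1]
    Vb = sub_b.eigenvectors[:, ranks_b - 1]
    D = np.abs(Va.T @ Vb)
    rmsip = float(np.sqrt(np.sum(D ** 2) / m))
    la = sub_a.eigenvalues[ranks_a - 1]
    lb = sub_b.eigenvalues[ranks_b - 1]
    # Hess (2002) covariance overlap on the truncated spectra.
    cross = np.sum(np.sqrt(np.outer(la, lb)) * D ** 2)
    denom = la.sum() + lb.sum()
    hess = float(1.0 - np.sqrt(max(denom - 2.0 * cross, 0.0) / denom)) if denom > 0 else 0.0
    max_a = D.max(axis=1)
    max_b = D.max(axis=0)
    pairs = [(int(ranks_a[i]), int(ranks_b[j]), float(D[i, j]))
             for i in range(m) for j in [int(np.argmax(D[i]))]]
    pairs.sort(key=lambda t: -t[2])
    return OverlapReport(
        m=int(m), dot_matrix=D, rmsip=rmsip,
        subspace_overlap_pct=100.0 * rmsip ** 2, hess_overlap=hess,
        max_dot_per_a=max_a, max_dot_per_b=max_b,
        mean_max_dot_a=float(max_a.mean()), mean_max_dot_b=float(max_b.mean()),
        mean_max_dot_both=float(np.concatenate([max_a, max_b]).mean()),
        best_pairs=pairs,
    )


def project_density(ensemble: Ensemble, subspace: EssentialSubspace,
                    components=(2, 3), grid_size: int = 100,
                    allow_excluded: bool = False):
    """Project frames onto two components and estimate a normalised KDE map.

    Returns ``(projections, (xgrid, ygrid, density))`` where the density is
    renormalised so that ``density.sum() * cell_area == 1`` on its grid.
    Scott's rule sets the kernel bandwidth; the grid spans the data ± 3
    bandwidths.
    """
    for c in components:
        if c in subspace.excluded and not allow_excluded:
            raise ValueError(f"component {c} is excluded; pass allow_excluded=True")
    sel = subspace.selection
    X = ensemble.coords[:, sel, :].reshape(ensemble.n_frames, -1)
    V = np.stack([subspace.component_vector(c) for c in components], axis=1)
    proj = (X - subspace.mean) @ V
    kde = gaussian_kde(proj.T, bw_method="scott")
    bw = kde.factor * proj.std(axis=0, ddof=1)
    lo = proj.min(axis=0) - 3 * bw
    hi = proj.max(axis=0) + 3 * bw
    xg = np.linspace(lo[0], hi[0], grid_size)
    yg = np.linspace(lo[1], hi[1], grid_size)
    XX, YY = np.meshgrid(xg, yg, indexing="ij")
    Z = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(grid_size, grid_size)
    cell = (xg[1] - xg[0]) * (yg[1] - yg[0])
    Z = Z / (Z.sum() * cell)
    return proj, (xg, yg, Z)


def modevectors(subspace: EssentialSubspace, component: int,
                scale: float = 2.0) -> ModevectorField:
    """Displacement field between the two extreme conformations along a
    component: extremes are mean ± scale·sqrt(λ)·v, so the field equals
    2·scale·sqrt(λ)·v exactly."""
    if scale < 0:
        raise ValueError("scale must be non-negative")
    lam = subspace.component_eigenvalue(component)
    v = subspace.component_vector(component)
    if lam == 0 and scale > 0:
        warnings.warn(f"component {component} has zero eigenvalue; field is zero",
                      stacklevel=2)
    amp = scale * np.sqrt(lam)
    plus = subspace.mean + amp * v
    minus = subspace.mean - amp * v
    field = (plus - minus).reshape(-1, 3)
    return ModevectorField(
        component=int(component), vectors=field,
        magnitudes=np.linalg.norm(field, axis=1),
        extreme_plus=plus.reshape(-1, 3), extreme_minus=minus.reshape(-1, 3),
    )
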