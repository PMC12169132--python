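"""Rigid-body superposition and scalar structure metrics.

Everything here works on plain ``(N, 3)`` / ``(F, N, 3)`` Å arrays so the
functions are equally usable on read-in or synthetic ensembles.  RMSD,
RMSF and the downstream essential-dynamics analysis default to the Cα
selection — the standard choice for residue-level comparative work — with
the selection always overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import Ensemble

__all__ = [
    "DegenerateGeometryError",
    "RigidTransform",
    "kabsch_superpose",
    "superpose_frames",
    "rmsd_series",
    "rmsf_profile",
    "iterative_mean_align",
    "gyration_series",
    "differential_profile",
    "DifferentialFlags",
    "distance_series",
    "DistanceSeries",
    "dihedral",
    "rotamer_bin",
    "sidechain_conformation_series",
    "SidechainConformationSeries",
    "FluctuationProfile",
]


class DegenerateGeometryError(ValueError):
    """Fewer than three selected atoms, or a collinear selection."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation; ``apply`` maps mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_selection(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateGeometryError("selected atoms are collinear")


def kabsch_superpose(mobile, reference, selection=None):
    """Least-squares rigid superposition (Kabsch, via quaternion SVD).

    Returns ``(RigidTransform, rmsd)`` where the transform maps the full
    mobile frame onto the reference and the RMSD is evaluated over the
    selection after the fit.  The rotation is always proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = slice(None) if selection is None else np.asarray(selection, dtype=np.intp)
    mob, ref = mobile[sel], reference[sel]
    _check_selection(mob)
    _check_selection(ref)
    mob_mean, ref_mean = mob.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_mean, mob - mob_mean)
    R = rot.as_matrix()
    t = ref_mean - mob_mean @ R.T
    transform = RigidTransform(rotation=R, translation=t)
    moved = transform.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return transform, rmsd


def superpose_frames(coords, reference, selection=None):
    """Superpose every frame of ``(F, N, 3)`` onto a reference frame."""
    out = np.empty_like(coords)
    rmsds = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        transform, rmsds[f] = kabsch_superpose(coords[f], reference, selection)
        out[f] = transform.apply(coords[f])
    return out, rmsds


def iterative_mean_align(coords, selection=None, passes: int = 2):
    """Align frames to their evolving mean (default two passes).

    This removes the arbitrary dependence on which frame is used as the
    fitting reference and is the conventional preprocessing step for RMSF
    and covariance analysis.
    """
    aligned = np.array(coords, dtype=float, copy=True)
    mean = aligned.mean(axis=0)
    for _ in range(max(passes, 1)):
        aligned, _ = superpose_frames(aligned, mean, selection)
        mean = aligned.mean(axis=0)
    return aligned, mean


@dataclass
class FluctuationProfile:
    """Per-residue RMSF with its residue numbering and state label."""

    resids: np.ndarray
    rmsf: np.ndarray
    state: str = ""


@dataclass
class DifferentialFlags:
    resids: np.ndarray
    delta: np.ndarray
    threshold: float
    flagged: np.ndarray  # residue ids with |delta| >= threshold


@dataclass
class DistanceSeries:
    pair: tuple
    values: np.ndarray
    mean: float
    sd: float
    reference_length: float = None
    pct_deviation: float = None


@dataclass
class SidechainConformationSeries:
    resid: int
    rmsd: np.ndarray
    chi: np.ndarray       # (F, n_chi) degrees in (-180, 180]
    rotamers: np.ndarray  # (F, n_chi) bin labels


def rmsd_series(ensemble: Ensemble, reference, selection=None):
    """Per-frame superposed RMSD against a reference conformation.

    Returns ``(values, mean, sd)``; window/stride restriction is expected
    to have been applied on the ensemble beforehand (``Ensemble.window``).
    """
    _, values = superpose_frames(ensemble.coords, np.asarray(reference, float), selection)
    return values, float(values.mean()), float(values.std(ddof=0))


def rmsf_profile(ensemble: Ensemble, selection=None) -> FluctuationProfile:
    """Cα root-mean-square fluctuation about the ensemble mean.

    RMSF_i = sqrt(<|r_i − <r_i>|²>) per residue, after two passes of
    alignment to the evolving mean over the same selection.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    top = ensemble.topology
    if selection is None:
        selection = top.calpha_indices()
    selection = np.asarray(selection, dtype=np.intp)
    aligned, mean = iterative_mean_align(ensemble.coords, selection)
    disp = aligned[:, selection, :] - mean[selection]
    rmsf = np.sqrt(np.mean(np.sum(disp ** 2, axis=2), axis=0))
    return FluctuationProfile(
        resids=top.resids[selection].astype(int), rmsf=rmsf, state=ensemble.state
    )


def gyration_series(ensemble: Ensemble, selection=None, mass_weighted: bool = True):
    """Radius of gyration per frame: Rg = sqrt(Σ m_i |r_i − r_com|² / Σ m_i)."""
    top = ensemble.topology
    sel = slice(None) if selection is None else np.asarray(selection, dtype=np.intp)
    masses = top.masses[sel] if mass_weighted else np.ones(len(top.masses[sel]))
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass is zero")
    xyz = ensemble.coords[:, sel, :]
    com = (xyz * masses[None, :, None]).sum(axis=1) / total
    d2 = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt((d2 * masses[None, :]).sum(axis=1) / total)
    return rg, float(rg.mean()), float(rg.std(ddof=0))


def differential_profile(profile_a: FluctuationProfile, profile_b: FluctuationProfile,
                         threshold: float) -> DifferentialFlags:
    """Per-residue Δ = A − B with boundary-inclusive |Δ| ≥ threshold flags.

    By convention the first argument is the deoxygenated-like state so that
    positive Δ means "more flexible without cargo".
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.array_equal(profile_a.resids, profile_b.resids):
        raise ValueError("profiles cover different residue sets")
    delta = profile_a.rmsf - profile_b.rmsf
    flagged = profile_a.resids[np.abs(delta) >= threshold]
    return DifferentialFlags(
        resids=profile_a.resids.copy(), delta=delta, threshold=float(threshold),
        flagged=flagged,
    )


def distance_series(ensemble: Ensemble, pairs, reference_lengths=None):
    """Euclidean per-frame distances for atom-index pairs, with mean/SD.

    If reference lengths are supplied (e.g. QM-optimised bond lengths) the
    percentage deviation of the mean is reported alongside.
    """
    out = []
    reference_lengths = reference_lengths or [None] * len(pairs)
    for (i, j), ref in zip(pairs, reference_lengths):
        if i == j:
            raise ValueError(f"distance pair ({i}, {j}) repeats one atom")
        d = np.linalg.norm(ensemble.coords[:, i, :] - ensemble.coords[:, j, :], axis=1)
        mean = float(d.mean())
        pct = None if ref is None else 100.0 * (mean - ref) / ref
        out.append(DistanceSeries(
            pair=(int(i), int(j)), values=d, mean=mean, sd=float(d.std(ddof=0)),
            reference_length=ref, pct_deviation=pct,
        ))
    return out


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (−180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def rotamer_bin(chi: float) -> str:
    """120° sector binning centred at +60° / 180° / −60°."""
    c = ((chi + 180.0) % 360.0) - 180.0
    if 0.0 <= c < 120.0:
        return "gauche+"
    if -120.0 <= c < 0.0:
        return "gauche-"
    return "trans"


def sidechain_conformation_series(ensemble: Ensemble, resid: int,
                                  chain: str = None,
                                  atom_names=None) -> SidechainConformationSeries:
    """Side-chain heavy-atom RMSD vs frame 1 plus χ dihedrals and rotamers.

    Each frame is first superposed on frame 1 using the Cα atoms of the
    residue and its two sequence neighbours on either side, so the series
    reports genuine side-chain motion rather than backbone drift.  χ_k is
    computed over consecutive quadruples of the pseudo side-chain chain
    (previous-residue Cα, Cα, then the side-chain atoms in order), which
    reduces to the conventional definition for these reduced topologies.
    """
    top = ensemble.topology
    res_mask = top.resids == resid
    if chain is not None:
        res_mask &= top.chains == chain
    side_mask = res_mask & (top.names != "CA")
    if atom_names is not None:
        side_mask &= np.isin(top.names, list(atom_names))
    side = np.flatnonzero(side_mask)
    if side.size == 0:
        raise ValueError(f"residue {resid} has no side-chain atoms")
    ca_self = np.flatnonzero(res_mask & (top.names == "CA"))
    bb_mask = (np.abs(top.resids - resid) <= 2) & (top.names == "CA")
    if chain is not None:
        bb_mask &= top.chains == chain
    backbone = np.flatnonzero(bb_mask)

    prev_mask = (top.resids == resid - 1) & (top.names == "CA")
    if chain is not None:
        prev_mask &= top.chains == chain
    prev_ca = np.flatnonzero(prev_mask)
    chain_atoms = np.concatenate([prev_ca[:1], ca_self[:1], side])
    n_chi = max(len(chain_atoms) - 3, 0)

    F = ensemble.n_frames
    ref = ensemble.coords[0]
    rmsds = np.empty(F)
    chis = np.full((F, n_chi), np.nan)
    rots = np.empty((F, n_chi), dtype=object)
    for f in range(F):
        if backbone.size >= 3:
            transform, _ = kabsch_superpose(ensemble.coords[f], ref, backbone)
            frame = transform.apply(ensemble.coords[f])
        else:
            frame = ensemble.coords[f]
        rmsds[f] = np.sqrt(np.mean(np.sum((frame[side] - ref[side]) ** 2, axis=1)))
        for k in range(n_chi):
            quad = chain_atoms[k:k + 4]
            chis[f, k] = dihedral(*frame[quad])
            rots[f, k] = rotamer_bin(chis[f, k])
    return SidechainConformationSeries(resid=int(resid), rmsd=rmsds, chi=chis, rotamers=rots)
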