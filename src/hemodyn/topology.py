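"""Atom/residue bookkeeping and the selection mini-language.

A :class:`Topology` is an ordered table of atoms with residue assignments,
van der Waals radii, masses and optional chemistry annotations (hydrogen-bond
donors/acceptors, formal charges, aromatic rings).  All other modules consume
topologies plus coordinate arrays; nothing downstream re-parses files.

Internal atom indices are 0-based; residue numbers follow the PDB convention
and are 1-based at every I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "EmptySelectionWarning",
    "SelectionError",
    "select_atoms",
    "vdw_radius_for",
    "mass_for",
]

# Bondi (1964) van der Waals radii, Å.  Unknown elements fall back to 1.7 Å
# (carbon-like), which is the conventional choice for coarse models.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "CU": 1.40, "ZN": 1.39, "FE": 1.40, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CU": 63.546, "ZN": 65.38, "FE": 55.845, "SE": 78.971,
    "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}
DEFAULT_MASS = 12.011


def vdw_radius_for(element: str) -> float:
    return BONDI_RADII.get(element.upper(), DEFAULT_RADIUS)


def mass_for(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


class EmptySelectionWarning(UserWarning):
    """Raised (as a warning) whenever a selection matches no atoms."""


class SelectionError(ValueError):
    """Malformed selection expression."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology (convenience row view)."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str
    segment: str
    vdw_radius: float
    mass: float


@dataclass
class Topology:
    """Ordered atom table for a (usually single-chain) structure.

    Arrays are aligned: entry ``i`` of each array describes atom ``i``.
    ``charges`` holds formal charges (−1/0/+1), ``donor_flags`` /
    ``acceptor_flags`` mark hydrogen-bond capable heavy atoms, and ``rings``
    lists aromatic rings as index tuples — these annotations drive typed
    contact detection and are optional for purely geometric analyses.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    vdw_radii: np.ndarray
    masses: np.ndarray
    charges: np.ndarray = field(default=None)
    donor_flags: np.ndarray = field(default=None)
    acceptor_flags: np.ndarray = field(default=None)
    rings: list = field(default_factory=list)
    named_selections: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.names)
        for attr in ("elements", "resids", "resnames", "chains", "vdw_radii", "masses"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology array {attr!r} has wrong length")
        if self.charges is None:
            self.charges = np.zeros(n, dtype=np.int8)
        if self.donor_flags is None:
            self.donor_flags = np.zeros(n, dtype=bool)
        if self.acceptor_flags is None:
            self.acceptor_flags = np.zeros(n, dtype=bool)
        if np.any(self.vdw_radii <= 0):
            raise ValueError("all van der Waals radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=i + 1,
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_index=int(self.resids[i]),
            residue_name=str(self.resnames[i]),
            chain=str(self.chains[i]),
            segment=str(self.chains[i]),
            vdw_radius=float(self.vdw_radii[i]),
            mass=float(self.masses[i]),
        )

    def residue_table(self):
        """(resid, resname, chain, atom index array) per residue, in order."""
        out = []
        keys = list(zip(self.chains.tolist(), self.resids.tolist()))
        seen = {}
        for i, key in enumerate(keys):
            if key not in seen:
                seen[key] = len(out)
                out.append((int(self.resids[i]), str(self.resnames[i]), str(self.chains[i]), [i]))
            else:
                out[seen[key]][3].append(i)
        return [(r, n, c, np.asarray(ix, dtype=np.intp)) for r, n, c, ix in out]

    def calpha_indices(self) -> np.ndarray:
        return np.flatnonzero(self.names == "CA")

    def select(self, expression: str) -> np.ndarray:
        return select_atoms(self, expression)


def _primitive_mask(topology: Topology, tokens: list[str]) -> np.ndarray:
    """Evaluate one selection primitive given as a token list."""
    key = tokens[0].lower()
    if key in topology.named_selections and len(tokens) == 1:
        mask = np.zeros(topology.n_atoms, dtype=bool)
        mask[np.asarray(topology.named_selections[key], dtype=np.intp)] = True
        return mask
    if key == "all":
        return np.ones(topology.n_atoms, dtype=bool)
    if key == "calpha":
        return topology.names == "CA"
    if key == "sidechain":
        return topology.names != "CA"
    if key == "resid":
        if len(tokens) != 2:
            raise SelectionError(f"'resid' needs one argument: {' '.join(tokens)}")
        mask = np.zeros(topology.n_atoms, dtype=bool)
        for part in tokens[1].split(","):
            if ":" in part:
                lo, hi = part.split(":")
                mask |= (topology.resids >= int(lo)) & (topology.resids <= int(hi))
            else:
                mask |= topology.resids == int(part)
        return mask
    if key in ("chain", "segment"):
        if len(tokens) != 2:
            raise SelectionError(f"'{key}' needs one argument")
        vals = tokens[1].split(",")
        return np.isin(topology.chains, vals)
    if key == "name":
        if len(tokens) != 2:
            raise SelectionError("'name' needs one argument")
        return np.isin(topology.names, tokens[1].split(","))
    raise SelectionError(f"unknown selection primitive {tokens[0]!r}")


def select_atoms(topology: Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning topology-ordered indices.

    Grammar (no parentheses): primitives joined by ``and`` / ``or`` with
    ``and`` binding tighter; a primitive may be prefixed by ``not``.
    Primitives: ``all``, ``calpha``, ``sidechain``, ``resid A[:B][,C:D...]``,
    ``chain X[,Y]``, ``segment X``, ``name N1[,N2]``, or the name of a stored
    named selection.  An empty result emits :class:`EmptySelectionWarning`.
    """
    if not expression or not expression.strip():
        raise SelectionError("empty selection expression")
    or_masks = []
    for or_part in expression.split(" or "):
        and_mask = np.ones(topology.n_atoms, dtype=bool)
        for and_part in or_part.split(" and "):
            tokens = and_part.split()
            if not tokens:
                raise SelectionError(f"dangling operator in {expression!r}")
            negate = False
            if tokens[0].lower() == "not":
                negate = True
                tokens = tokens[1:]
                if not tokens:
                    raise SelectionError("'not' needs an operand")
            mask = _primitive_mask(topology, tokens)
            and_mask &= ~mask if negate else mask
        or_masks.append(and_mask)
    final = np.logical_or.reduce(or_masks)
    indices = np.flatnonzero(final)
    if indices.size == 0:
        warnings.warn(
            f"selection {expression!r} matched no atoms", EmptySelectionWarning,
            stacklevel=2,
        )
    return indices
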