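"""Multi-model PDB reading/writing.

Ensembles travel as standard multi-model PDB files (one MODEL/ENDMDL pair
per frame) with an optional JSON sidecar (``<file>.json``) carrying the
state label, replicate index and frame labels.  Parsing and formatting are
delegated to :mod:`biotite.structure.io.pdb`; this module adds topology
conversion, radius/mass assignment and the error diagnostics the rest of
the package relies on.

Coordinates are Å throughout and survive a round trip at the PDB's
3-decimal precision.  Atom serials above 99999 are written using biotite's
hybrid-36 convention; the synthetic systems here never reach that regime.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as _pdb

from .ensemble import Ensemble
from .topology import Topology, mass_for, vdw_radius_for

__all__ = ["PDBFormatError", "read_pdb_models", "write_pdb_models"]


class PDBFormatError(ValueError):
    """Unparseable or internally inconsistent PDB input."""


def _model_atom_counts(path: Path) -> list[int]:
    counts, current, in_model, any_model = [], 0, False, False
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, any_model, current = True, True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
            if not any_model:
                in_model = True
    if not any_model:
        counts = [current] if current else []
    return counts


def read_pdb_models(path) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Every MODEL becomes one frame; the atom order of model 1 defines the
    topology and must be identical across models.  A JSON sidecar next to
    the file, if present, supplies state/replicate/frame labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = _pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        counts = _model_atom_counts(path)
        if len(set(counts)) > 1:
            bad = next(i + 1 for i, c in enumerate(counts) if c != counts[0])
            raise PDBFormatError(
                f"{path.name}: model {bad} has {counts[bad - 1]} atoms, "
                f"model 1 has {counts[0]}"
            ) from exc
        raise PDBFormatError(f"{path.name}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])

    elements = np.array([e if e else "C" for e in stack.element], dtype=object)
    topology = Topology(
        names=np.array(stack.atom_name, dtype=object),
        elements=elements,
        resids=np.array(stack.res_id, dtype=np.int64),
        resnames=np.array(stack.res_name, dtype=object),
        chains=np.array(stack.chain_id, dtype=object),
        vdw_radii=np.array([vdw_radius_for(e) for e in elements], dtype=float),
        masses=np.array([mass_for(e) for e in elements], dtype=float),
    )

    state, replicate, frame_labels = "", 0, None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        state = meta.get("state", "")
        replicate = int(meta.get("replicate", 0))
        if "frame_labels" in meta:
            frame_labels = np.asarray(meta["frame_labels"], dtype=float)

    return Ensemble(
        topology=topology,
        coords=np.asarray(stack.coord, dtype=np.float64),
        frame_labels=frame_labels,
        state=state,
        replicate=replicate,
    )


def write_pdb_models(ensemble: Ensemble, path, sidecar: bool = True) -> None:
    """Write an ensemble as a multi-model PDB file (plus JSON sidecar)."""
    path = Path(path)
    top = ensemble.topology
    n = top.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.asarray(ensemble.coords[0], dtype=np.float32)
    array.chain_id = np.array([str(c) for c in top.chains], dtype="U4")
    array.res_id = np.asarray(top.resids, dtype=int)
    array.res_name = np.array([str(r) for r in top.resnames], dtype="U5")
    array.atom_name = np.array([str(a) for a in top.names], dtype="U6")
    array.element = np.array([str(e) for e in top.elements], dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([array] * ensemble.n_frames)
    stack.coord = np.asarray(ensemble.coords, dtype=np.float32)

    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    if sidecar:
        meta = {
            "state": ensemble.state,
            "replicate": int(ensemble.replicate),
            "frame_labels": np.asarray(ensemble.frame_labels, dtype=float).tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
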