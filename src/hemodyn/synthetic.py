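"""Two-state synthetic ensembles with planted, recoverable ground truth.

The generator emulates the study design every downstream stage expects:
two labelled states ("oxy"-like and "deoxy"-like) × several replicates of
i.i.d. frames for one ~400-residue toy chain, with

* a helix-like Cα backbone (3.8 Å spacing) split into two rigid domains,
* loop regions whose Gaussian fluctuation amplitude depends on the state,
* a flexible C-terminal tail (mimicking the disordered linker that
  dominates the first principal component in real functional units),
* a gate residue whose side chain has two rotamers — "open" (swung onto
  the outer shell surface, solvent exposed) and "closed" (plugging the
  shell aperture, buried) — drawn per frame with a state-dependent open
  probability,
* a spherical shell of pseudo-atoms enclosing a seed point with one
  circular aperture whose effective bottleneck is the open pore radius
  when the gate is open and the residual annular gap when it is closed,
* planted typed contacts (VDW / HBOND / IONIC) realised per frame with
  state-dependent probabilities by toggling pseudo-atom pairs between an
  in-contact and an out-of-contact distance, and
* a rigid rotation of domain II about an axis through the domain-I centre
  of mass, with a state-dependent mean angle and Gaussian jitter.

Frames are i.i.d. (no autocorrelation): every downstream analysis is an
ensemble statistic, so temporal correlation would only slow convergence
without testing anything extra.  Replicate ``r`` of state ``s`` uses the
stream ``seed + r + 10000·index(s)`` — one master seed, fixed documented
offsets.

The gate and contact pseudo-atoms are bookkept as side-chain atoms of
their residues but positioned directly at the shell aperture / contact
sites rather than being chained to their Cα — the geometry is a test
harness, not a protein model, and this keeps every planted quantity
(contact distance, aperture radius, exposure difference) exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import Ensemble
from .topology import Topology

__all__ = [
    "SpecValidationError",
    "LoopSpec",
    "GateSpec",
    "ShellSpec",
    "ContactSpec",
    "RotationSpec",
    "SyntheticSpec",
    "PlantedTruth",
    "ToyStructure",
    "build_toy_topology",
    "sample_ensemble",
    "planted_truth",
    "make_shell",
    "spec_from_dict",
]

CA_SPACING = 3.8  # Å

# in-contact / out-of-contact pseudo-atom distances and radii per type;
# chosen so each planted type satisfies exactly its own criterion
# (e.g. HBOND at 3.4 Å with 1.4 Å radii stays outside the VDW cutoff)
CONTACT_GEOMETRY = {
    "VDW": {"d_on": 3.85, "d_off": 6.5, "radius": 1.70, "element": "C"},
    "HBOND": {"d_on": 3.40, "d_off": 6.0, "radius": 1.40, "element": "O"},
    "IONIC": {"d_on": 3.80, "d_off": 6.4, "radius": 1.50, "element": "N"},
}


class SpecValidationError(ValueError):
    """Invalid generator specification; the message names the field."""


@dataclass
class LoopSpec:
    """A loop that moves as a rigid unit along a fixed direction.

    The collective displacement per frame is ``N(0, amplitude[state])``
    along a deterministic unit direction shared by all loop residues, on
    top of the baseline per-residue noise — so loops carry genuine
    collective modes whose directions are conserved between states while
    their amplitudes differ.
    """

    start: int
    end: int
    amplitude: dict  # state -> Å (collective Gaussian SD along the loop axis)

    def direction(self, index: int) -> np.ndarray:
        """Deterministic unit direction for loop number ``index``."""
        v = np.array([np.cos(2.4 * index + 0.3),
                      np.sin(2.4 * index + 0.3), 0.5])
        return v / np.linalg.norm(v)


@dataclass
class GateSpec:
    residue: int = 352
    open_prob: dict = field(default_factory=lambda: {"oxy": 0.1, "deoxy": 0.9})


@dataclass
class ShellSpec:
    radius: float = 9.0
    atom_radius: float = 1.8
    atom_spacing: float = 2.0
    pore_radius_open: float = 2.5
    pore_radius_closed: float = 0.4


@dataclass
class ContactSpec:
    res_i: int
    res_j: int
    kind: str
    prob: dict  # state -> occurrence probability


@dataclass
class RotationSpec:
    mean_deg: dict = field(default_factory=lambda: {"oxy": 1.46, "deoxy": 0.0})
    jitter_deg: float = 0.05


def _default_loops():
    return [
        LoopSpec(46, 56, {"oxy": 0.55, "deoxy": 1.5}),
        LoopSpec(374, 378, {"oxy": 0.55, "deoxy": 1.5}),
    ]


def _default_contacts():
    # the focal residue's network: state-exclusive and shared typed contacts
    return [
        ContactSpec(43, 352, "IONIC", {"oxy": 0.85, "deoxy": 0.20}),
        ContactSpec(62, 352, "HBOND", {"oxy": 0.85, "deoxy": 0.20}),
        ContactSpec(202, 352, "VDW", {"oxy": 0.85, "deoxy": 0.20}),
        ContactSpec(318, 352, "HBOND", {"oxy": 0.80, "deoxy": 0.80}),
        ContactSpec(349, 352, "VDW", {"oxy": 0.80, "deoxy": 0.80}),
        ContactSpec(352, 355, "VDW", {"oxy": 0.20, "deoxy": 0.85}),
    ]


@dataclass
class SyntheticSpec:
    """All knobs of the two-state toy system (defaults are the reference
    study conditions: 5 replicates × 1000 frames, ±0.5 Å loop contrast,
    0.9/0.1 gate asymmetry, 1.46° domain rotation)."""

    n_residues: int = 423
    domain_split: int = 305
    backbone_geometry: str = "serpentine"
    loop_ranges: list = field(default_factory=_default_loops)
    baseline_amplitude: float = 0.25
    tail_start: int = 408
    tail_amplitude: float = 1.2
    gate: GateSpec = field(default_factory=GateSpec)
    shell: ShellSpec = field(default_factory=ShellSpec)
    planted_contacts: list = field(default_factory=_default_contacts)
    rotation: RotationSpec = field(default_factory=RotationSpec)
    n_frames: int = 1000
    n_replicates: int = 5
    seed: int = 1234
    states: tuple = ("oxy", "deoxy")

    def validate(self) -> None:
        if self.n_residues < 10:
            raise SpecValidationError("n_residues must be at least 10")
        if not 1 <= self.domain_split < self.n_residues:
            raise SpecValidationError("domain_split must lie inside the chain")
        if self.n_frames < 2:
            raise SpecValidationError("n_frames must be >= 2")
        if self.n_replicates < 1:
            raise SpecValidationError("n_replicates must be >= 1")
        if self.baseline_amplitude < 0:
            raise SpecValidationError("baseline_amplitude must be >= 0")
        if self.tail_amplitude < 0:
            raise SpecValidationError("tail_amplitude must be >= 0")
        if len(self.states) != 2:
            raise SpecValidationError("states must name exactly two labels")
        for loop in self.loop_ranges:
            if not 1 <= loop.start <= loop.end <= self.n_residues:
                raise SpecValidationError(f"loop_ranges entry {loop.start}-{loop.end} out of range")
            for s, amp in loop.amplitude.items():
                if amp < 0:
                    raise SpecValidationError(f"loop amplitude for state {s!r} must be >= 0")
        if not 1 <= self.gate.residue <= self.n_residues:
            raise SpecValidationError("gate residue outside the chain")
        for s in self.states:
            p = self.gate.open_prob.get(s)
            if p is None or not 0 <= p <= 1:
                raise SpecValidationError(f"gate open_prob for state {s!r} must be in [0, 1]")
        if self.shell.pore_radius_open <= 0 or self.shell.pore_radius_closed <= 0:
            raise SpecValidationError("shell pore radii must be positive")
        if self.shell.pore_radius_open <= 2 * self.shell.pore_radius_closed:
            raise SpecValidationError(
                "shell pore_radius_open must exceed twice pore_radius_closed "
                "(the plug radius would not be positive)")
        for c in self.planted_contacts:
            if c.kind not in CONTACT_GEOMETRY:
                raise SpecValidationError(f"planted contact kind {c.kind!r} unsupported")
            if not (1 <= c.res_i <= self.n_residues and 1 <= c.res_j <= self.n_residues):
                raise SpecValidationError("planted contact residue outside the chain")
            if c.res_i == c.res_j:
                raise SpecValidationError("planted contact pairs a residue with itself")
            for s in self.states:
                p = c.prob.get(s)
                if p is None or not 0 <= p <= 1:
                    raise SpecValidationError("planted contact probability must be in [0, 1]")
        if self.rotation.jitter_deg < 0:
            raise SpecValidationError("rotation jitter must be >= 0")

    def state_index(self, state: str) -> int:
        if state not in self.states:
            raise ValueError(f"unknown state label {state!r}; expected one of {self.states}")
        return self.states.index(state)

    def residue_sd(self, state: str) -> np.ndarray:
        """Per-residue, per-coordinate SD (Å) of the independent noise.

        Loops are NOT included here: their state-dependent motion is the
        collective term (see :class:`LoopSpec`), layered on top of this
        baseline.  The flexible tail gets its own (state-independent)
        amplitude.
        """
        self.state_index(state)
        sd = np.full(self.n_residues, self.baseline_amplitude, dtype=float)
        if self.tail_start <= self.n_residues:
            sd[self.tail_start - 1:] = self.tail_amplitude
        return sd

    def loop_amplitude(self, state: str) -> np.ndarray:
        """Per-residue collective loop amplitude (Å) for a state."""
        self.state_index(state)
        amp = np.zeros(self.n_residues, dtype=float)
        for loop in self.loop_ranges:
            amp[loop.start - 1:loop.end] = loop.amplitude[state]
        return amp

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


def spec_from_dict(data: dict) -> SyntheticSpec:
    """Rebuild a spec from a parsed YAML/JSON mapping."""
    data = dict(data)
    if "loop_ranges" in data:
        data["loop_ranges"] = [LoopSpec(**d) for d in data["loop_ranges"]]
    if "gate" in data:
        data["gate"] = GateSpec(**data["gate"])
    if "shell" in data:
        data["shell"] = ShellSpec(**data["shell"])
    if "planted_contacts" in data:
        data["planted_contacts"] = [ContactSpec(**d) for d in data["planted_contacts"]]
    if "rotation" in data:
        data["rotation"] = RotationSpec(**data["rotation"])
    if "states" in data:
        data["states"] = tuple(data["states"])
    spec = SyntheticSpec(**data)
    spec.validate()
    return spec


@dataclass
class PlantedTruth:
    """Ground truth derivable from the spec without any sampling."""

    state: str
    per_residue_rmsf: np.ndarray       # √(3·SD² + loop_amplitude²), Å
    gate_open_fraction: float
    bottleneck_open: float             # Å, gate-open frames
    bottleneck_closed: float           # Å, gate-closed frames (sub-probe)
    contact_probs: dict                # (res_i, res_j, kind) -> probability
    rotation_offset_deg: float


@dataclass
class ToyStructure:
    """Topology plus reference coordinates and generator bookkeeping."""

    topology: Topology
    reference: np.ndarray
    ca_indices: np.ndarray
    domain2_ca: np.ndarray
    gate_atoms: np.ndarray
    gate_open_pos: np.ndarray
    gate_closed_pos: np.ndarray
    contact_movable: np.ndarray        # index of the movable atom per contact
    contact_sites: np.ndarray          # (K, 3) fixed-atom positions
    contact_on_pos: np.ndarray
    contact_off_pos: np.ndarray
    shell_center: np.ndarray
    seed_point: np.ndarray
    rotation_axis: np.ndarray
    rotation_origin: np.ndarray


def make_shell(center, radius, atom_radius, spacing, pores) -> np.ndarray:
    """Spherical shell of pseudo-atoms with circular apertures.

    ``pores`` is a list of ``(axis_unit_vector, aperture_radius)``; each
    aperture is rimmed by a 12-atom ring at exactly the chord distance
    ``aperture + atom_radius`` from the pore centre, so the free radius at
    the aperture centre equals the requested aperture radius.  Background
    atoms come from a deterministic golden-spiral lattice dense enough
    that every inter-atom gap stays far below typical probe radii.
    """
    center = np.asarray(center, dtype=float)
    n = max(int(np.ceil(4.0 * np.pi * radius ** 2 / spacing ** 2)), 64)
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    pts = np.stack([np.cos(theta) * np.sin(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(phi)], axis=1) * radius
    keep = np.ones(len(pts), dtype=bool)
    ring_atoms = []
    for axis, aperture in pores:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        pore_center = axis * radius
        chord = aperture + atom_radius
        clearance = chord + 0.6 * spacing
        keep &= np.linalg.norm(pts - pore_center, axis=1) >= clearance
        # ring at polar angle theta_ring: chord(theta) = 2 R sin(theta/2)
        theta_ring = 2.0 * np.arcsin(min(chord / (2.0 * radius), 1.0))
        ortho = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(ortho) < 1e-6:
            ortho = np.cross(axis, [0.0, 1.0, 0.0])
        ortho /= np.linalg.norm(ortho)
        ortho2 = np.cross(axis, ortho)
        for ang in np.linspace(0.0, 2.0 * np.pi, 12, endpoint=False):
            direction = (np.cos(theta_ring) * axis
                         + np.sin(theta_ring) * (np.cos(ang) * ortho + np.sin(ang) * ortho2))
            ring_atoms.append(direction * radius)
    coords = np.concatenate([pts[keep]] + ([np.asarray(ring_atoms)] if ring_atoms else []))
    return coords + center


def _backbone(geometry: str, n: int) -> np.ndarray:
    """Deterministic Cα trace for a compact toy chain.

    ``serpentine`` (default): residues snake through a rectangular lattice
    — 3.8 Å between consecutive residues within a row, 5.0 Å row and layer
    pitch, 8 residues per row and 8 rows per layer.  The larger pitch
    keeps all non-consecutive Cα pairs outside every contact cutoff so
    the baseline chain is contact-silent, while the fold stays compact
    (~30–40 Å) so planted domain rotations act over realistic lever arms.

    ``helix``: a straight 100°-turn, 1.5 Å-rise helix with exact 3.8 Å
    spacing — geometrically cleaner but very elongated; useful for
    debugging, not the default study condition.
    """
    if geometry == "serpentine":
        per_row, per_layer = 8, 64
        i = np.arange(n)
        layer = i // per_layer
        rem = i % per_layer
        row = rem // per_row
        col = rem % per_row
        col = np.where(row % 2 == 1, per_row - 1 - col, col)
        row = np.where(layer % 2 == 1, per_row - 1 - row, row)
        return np.stack([3.8 * col, 5.0 * row, 5.0 * layer], axis=1).astype(float)
    if geometry == "helix":
        idx = np.arange(n, dtype=float)
        angles = np.radians(100.0 * idx)
        return np.stack([2.3 * np.cos(angles), 2.3 * np.sin(angles), 1.5 * idx], axis=1)
    raise SpecValidationError(f"unknown backbone_geometry {geometry!r}")


def build_toy_topology(spec: SyntheticSpec) -> ToyStructure:
    """Deterministic topology + reference coordinates for a spec.

    The reference conformation has the gate open and every planted contact
    in its in-contact position, so a zero-amplitude, all-probability-one
    spec reproduces the reference bitwise in every frame.
    """
    spec.validate()
    n = spec.n_residues
    ca = _backbone(spec.backbone_geometry, n)

    names, elements, resids, resnames, chains = [], [], [], [], []
    radii, masses, charges, donors, acceptors = [], [], [], [], []
    coords = []

    def add_atom(name, element, resid, resname, chain, xyz,
                 radius=None, charge=0, donor=False, acceptor=False):
        names.append(name)
        elements.append(element)
        resids.append(resid)
        resnames.append(resname)
        chains.append(chain)
        from .topology import vdw_radius_for, mass_for
        radii.append(radius if radius is not None else vdw_radius_for(element))
        masses.append(mass_for(element))
        charges.append(charge)
        donors.append(donor)
        acceptors.append(acceptor)
        coords.append(np.asarray(xyz, dtype=float))
        return len(coords) - 1

    special = {spec.gate.residue: "GLU"}
    for i in range(n):
        add_atom("CA", "C", i + 1, special.get(i + 1, "GLY"), "A", ca[i])
    ca_indices = np.arange(n, dtype=np.intp)

    gate_ca = ca[spec.gate.residue - 1]
    # the shell sits clear of the chain on the +x side, at the gate's height
    shell_center = np.array([ca[:, 0].max() + spec.shell.radius + 12.0,
                             gate_ca[1], gate_ca[2]])
    pore_axis = np.array([1.0, 0.0, 0.0])
    aperture_center = shell_center + spec.shell.radius * pore_axis
    plug_radius = spec.shell.pore_radius_open - 2.0 * spec.shell.pore_radius_closed

    # gate rotamers: "closed" plugs the channel below/at the aperture
    # (buried, blocking); "open" keeps one atom lining the aperture rim
    # while the rest of the side chain extends into free solvent (exposed)
    gate_closed = np.stack([
        aperture_center,
        aperture_center - 2.2 * pore_axis,
        aperture_center - 4.4 * pore_axis,
    ])
    # the lining atom sits at exactly pore_radius + its own radius from the
    # aperture centre: it touches the open bottleneck without narrowing it
    side = np.array([0.0, 1.0, 0.0])
    lining_offset = spec.shell.pore_radius_open + plug_radius
    gate_open = np.stack([
        aperture_center + lining_offset * side,  # lines the open aperture
        aperture_center + (lining_offset + 3.0) * side + 1.0 * pore_axis,
        aperture_center + (lining_offset + 6.0) * side + 2.0 * pore_axis,
    ])
    gate_atoms = []
    for k, name in enumerate(("GB", "GG", "GD")):
        gate_atoms.append(add_atom(name, "C", spec.gate.residue, "GLU", "A",
                                   gate_open[k], radius=plug_radius))
    gate_atoms = np.asarray(gate_atoms, dtype=np.intp)

    # planted-contact pseudo-atom pairs at detached, well-separated sites
    contact_movable, contact_sites, contact_on, contact_off = [], [], [], []
    site_x = ca[:, 0].min() - 28.0
    for kk, contact in enumerate(spec.planted_contacts):
        geom = CONTACT_GEOMETRY[contact.kind]
        site = np.array([site_x, 0.0, 14.0 * kk])
        direction = np.array([-1.0, 0.0, 0.0])
        kwargs_i, kwargs_j = {}, {}
        if contact.kind == "HBOND":
            kwargs_i, kwargs_j = {"donor": True}, {"acceptor": True}
        elif contact.kind == "IONIC":
            kwargs_i, kwargs_j = {"charge": 1}, {"charge": -1}
        add_atom(f"P{kk}A", geom["element"], contact.res_i, "GLY", "A",
                 site, radius=geom["radius"], **kwargs_i)
        movable = add_atom(f"P{kk}B", geom["element"], contact.res_j, "GLY", "A",
                           site + geom["d_on"] * direction,
                           radius=geom["radius"], **kwargs_j)
        contact_movable.append(movable)
        contact_sites.append(site)
        contact_on.append(site + geom["d_on"] * direction)
        contact_off.append(site + geom["d_off"] * direction)

    shell_coords = make_shell(shell_center, spec.shell.radius, spec.shell.atom_radius,
                              spec.shell.atom_spacing,
                              [(pore_axis, spec.shell.pore_radius_open)])
    for si, xyz in enumerate(shell_coords):
        add_atom("SH", "C", si + 1, "SHL", "S", xyz, radius=spec.shell.atom_radius)

    topology = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=np.int64),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(chains, dtype=object),
        vdw_radii=np.array(radii, dtype=float),
        masses=np.array(masses, dtype=float),
        charges=np.array(charges, dtype=np.int8),
        donor_flags=np.array(donors, dtype=bool),
        acceptor_flags=np.array(acceptors, dtype=bool),
    )
    reference = np.stack(coords)

    core_end = min(spec.tail_start - 1, n)
    is_a = topology.chains == "A"
    topology.named_selections.update({
        "protein": np.flatnonzero(is_a),
        "protein_core": np.flatnonzero(is_a & (topology.resids <= core_end)),
        "calpha": np.flatnonzero(is_a & (topology.names == "CA")),
        "core": np.flatnonzero(is_a & (topology.names == "CA")
                               & (topology.resids <= core_end)),
        "domain1": np.flatnonzero(is_a & (topology.names == "CA")
                                  & (topology.resids <= spec.domain_split)),
        "domain2": np.flatnonzero(is_a & (topology.names == "CA")
                                  & (topology.resids > spec.domain_split)),
        "domain2_core": np.flatnonzero(is_a & (topology.names == "CA")
                                       & (topology.resids > spec.domain_split)
                                       & (topology.resids <= core_end)),
    })
    # rigid-domain selections exclude the planted loops (and the tail):
    # the conventional choice for domain-motion fitting, and the one that
    # keeps the rotation read-out free of loop-mode leakage
    in_loop = np.zeros(topology.n_atoms, dtype=bool)
    for loop in spec.loop_ranges:
        in_loop |= (topology.resids >= loop.start) & (topology.resids <= loop.end)
    topology.named_selections.update({
        "domain1_rigid": np.flatnonzero(
            is_a & (topology.names == "CA") & ~in_loop
            & (topology.resids <= spec.domain_split)),
        "domain2_rigid": np.flatnonzero(
            is_a & (topology.names == "CA") & ~in_loop
            & (topology.resids > spec.domain_split) & (topology.resids <= core_end)),
        "shell": np.flatnonzero(topology.chains == "S"),
        "gate_sidechain": gate_atoms.copy(),
        "tunnel": np.concatenate([np.flatnonzero(topology.chains == "S"), gate_atoms]),
    })

    dom1_ca = ca_indices[:spec.domain_split]
    dom2_ca = ca_indices[spec.domain_split:]
    c1 = ca[dom1_ca].mean(axis=0)
    v = ca[dom2_ca].mean(axis=0) - c1
    axis = np.cross(v, [1.0, 0.0, 0.0])
    if np.linalg.norm(axis) < 1e-8:
        axis = np.cross(v, [0.0, 1.0, 0.0])
    axis = axis / np.linalg.norm(axis)

    return ToyStructure(
        topology=topology, reference=reference, ca_indices=ca_indices,
        domain2_ca=dom2_ca, gate_atoms=gate_atoms,
        gate_open_pos=gate_open, gate_closed_pos=gate_closed,
        contact_movable=np.asarray(contact_movable, dtype=np.intp),
        contact_sites=np.asarray(contact_sites, dtype=float),
        contact_on_pos=np.asarray(contact_on, dtype=float),
        contact_off_pos=np.asarray(contact_off, dtype=float),
        shell_center=shell_center, seed_point=shell_center.copy(),
        rotation_axis=axis, rotation_origin=c1,
    )


def sample_ensemble(spec: SyntheticSpec, state: str, replicate: int = 0,
                    structure: ToyStructure = None) -> Ensemble:
    """Draw one replicate ensemble of i.i.d. frames for a state.

    Per frame: domain II Cα are rotated by N(mean, jitter) degrees about
    the planted axis; every Cα receives isotropic Gaussian noise with its
    residue's state SD; the gate rotamer is Bernoulli(open_prob); each
    planted contact toggles between its in/out distance with its state
    probability.  Passing a prebuilt ``structure`` skips rebuilding the
    topology (the build is deterministic either way).
    """
    spec.validate()
    s_index = spec.state_index(state)
    if replicate < 0 or replicate >= spec.n_replicates:
        raise ValueError(f"replicate {replicate} outside 0..{spec.n_replicates - 1}")
    toy = structure or build_toy_topology(spec)
    rng = np.random.default_rng(spec.seed + replicate + 10000 * s_index)
    F = spec.n_frames
    n_res = spec.n_residues

    thetas = rng.normal(spec.rotation.mean_deg[state], spec.rotation.jitter_deg, F)
    sd = spec.residue_sd(state)
    noise = rng.normal(size=(F, n_res, 3)) * sd[None, :, None]
    loop_etas = rng.normal(size=(F, len(spec.loop_ranges)))
    gate_open = rng.random(F) < spec.gate.open_prob[state]
    contact_on = rng.random((F, len(spec.planted_contacts)))
    probs = np.array([c.prob[state] for c in spec.planted_contacts])
    contact_on = contact_on < probs[None, :]

    coords = np.repeat(toy.reference[None, :, :], F, axis=0)
    if np.any(thetas != 0.0):
        rot = Rotation.from_rotvec(np.radians(thetas)[:, None] * toy.rotation_axis[None, :])
        mats = rot.as_matrix()                       # (F, 3, 3)
        block = coords[:, toy.domain2_ca, :] - toy.rotation_origin
        coords[:, toy.domain2_ca, :] = np.einsum("fij,faj->fai", mats, block) + toy.rotation_origin
    coords[:, toy.ca_indices, :] += noise
    for li, loop in enumerate(spec.loop_ranges):
        amp = loop.amplitude[state]
        if amp == 0.0:
            continue
        atoms = toy.ca_indices[loop.start - 1:loop.end]
        disp = (amp * loop_etas[:, li])[:, None] * loop.direction(li)[None, :]
        coords[:, atoms, :] += disp[:, None, :]
    for k, atom in enumerate(toy.gate_atoms):
        coords[:, atom, :] = np.where(gate_open[:, None],
                                      toy.gate_open_pos[k], toy.gate_closed_pos[k])
    for k, atom in enumerate(toy.contact_movable):
        coords[:, atom, :] = np.where(contact_on[:, k][:, None],
                                      toy.contact_on_pos[k], toy.contact_off_pos[k])

    return Ensemble(
        topology=toy.topology, coords=coords,
        frame_labels=np.arange(1, F + 1, dtype=float),
        state=state, replicate=int(replicate),
    )


def planted_truth(spec: SyntheticSpec, state: str) -> PlantedTruth:
    """Analytic ground truth for one state — no sampling involved."""
    spec.validate()
    spec.state_index(state)
    sd = spec.residue_sd(state)
    amp = spec.loop_amplitude(state)
    return PlantedTruth(
        state=state,
        per_residue_rmsf=np.sqrt(3.0 * sd ** 2 + amp ** 2),
        gate_open_fraction=float(spec.gate.open_prob[state]),
        bottleneck_open=float(spec.shell.pore_radius_open),
        bottleneck_closed=float(spec.shell.pore_radius_closed),
        contact_probs={(c.res_i, c.res_j, c.kind): float(c.prob[state])
                       for c in spec.planted_contacts},
        rotation_offset_deg=float(spec.rotation.mean_deg[state]),
    )
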