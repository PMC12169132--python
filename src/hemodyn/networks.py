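"""Typed residue interaction networks (RINs) from conformational ensembles.

Residues are nodes, noncovalent contacts are typed edges whose weight is
the fraction of analysed frames in which the contact is present, averaged
(unweighted) across replicates.  Edges present at frequency ≥ 0.3 in only
one state are that state's exclusive contacts; present in both, shared.

Geometric criteria (fixed, config-overridable; standard literature
cutoffs, applied per interaction type and skipping residue pairs closer
than 3 in sequence):

========== ===========================================================
VDW        d ≤ r_vdw,i + r_vdw,j + 0.5 Å (any heavy-atom pair)
HBOND      donor–acceptor heavy-atom distance ≤ 3.5 Å
IONIC      oppositely charged group atoms ≤ 4.0 Å
PIPISTACK  ring centroids ≤ 5.5 Å, inter-plane angle ≤ 30° or ≥ 150°
PICATION   cation to ring centroid ≤ 5.0 Å
========== ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .ensemble import Ensemble
from .topology import Topology

__all__ = [
    "ContactCriteria",
    "InteractionNetwork",
    "EdgeClassification",
    "INTERACTION_TYPES",
    "detect_contacts",
    "contact_frequencies",
    "classify_edges",
    "extract_neighborhood",
]

INTERACTION_TYPES = ("VDW", "HBOND", "IONIC", "PIPISTACK", "PICATION")


@dataclass(frozen=True)
class ContactCriteria:
    vdw_slack: float = 0.5
    hbond_distance: float = 3.5
    ionic_distance: float = 4.0
    pipistack_distance: float = 5.5
    pipistack_angle: float = 30.0
    pication_distance: float = 5.0
    min_sequence_separation: int = 3


@dataclass
class InteractionNetwork:
    """Residue nodes plus typed, frequency-weighted edges for one state."""

    state: str
    frequencies: dict      # (resA, resB, type) -> frequency in [0, 1]
    nodes: set = field(default_factory=set)

    def edges_at(self, threshold: float) -> set:
        return {k for k, f in self.frequencies.items() if f >= threshold}

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph(state=self.state)
        g.add_nodes_from(sorted(self.nodes))
        for (a, b, typ), freq in sorted(self.frequencies.items()):
            g.add_edge(a, b, key=typ, frequency=freq, interaction=typ)
        return g


@dataclass
class EdgeClassification:
    threshold: float
    exclusive_a: set
    exclusive_b: set
    shared: set
    absent: set

    def classify(self, key) -> str:
        if key in self.shared:
            return "shared"
        if key in self.exclusive_a:
            return "exclusive_a"
        if key in self.exclusive_b:
            return "exclusive_b"
        return "absent"


def _ring_geometry(coords, ring):
    pts = coords[np.asarray(ring, dtype=np.intp)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[2]


def detect_contacts(coords, topology: Topology, criteria: ContactCriteria = None,
                    selection=None) -> set:
    """Typed contacts in one frame as a set of (resA, resB, type) keys.

    Residues are keyed by their 1-based number; ``selection`` restricts
    the atoms considered.  Pairs separated by fewer than
    ``min_sequence_separation`` residues in the same chain are skipped,
    which removes trivial backbone adjacencies.
    """
    crit = criteria or ContactCriteria()
    coords = np.asarray(coords, dtype=float)
    sel = np.arange(topology.n_atoms) if selection is None else np.asarray(selection, dtype=np.intp)
    pos = coords[sel]
    resids = topology.resids[sel]
    chains = topology.chains[sel]
    radii = topology.vdw_radii[sel]
    charges = topology.charges[sel]
    donors = topology.donor_flags[sel]
    acceptors = topology.acceptor_flags[sel]

    def res_key(local_i):
        return int(resids[local_i])

    def separated(i, j):
        if chains[i] != chains[j]:
            return True
        return abs(int(resids[i]) - int(resids[j])) >= crit.min_sequence_separation

    contacts: set = set()
    tree = cKDTree(pos)
    max_cut = max(2 * radii.max() + crit.vdw_slack, crit.ionic_distance,
                  crit.hbond_distance)
    for i, j in tree.query_pairs(max_cut):
        if not separated(i, j):
            continue
        d = np.linalg.norm(pos[i] - pos[j])
        a, b = sorted((res_key(i), res_key(j)))
        if d <= radii[i] + radii[j] + crit.vdw_slack:
            contacts.add((a, b, "VDW"))
        if d <= crit.hbond_distance and (
                (donors[i] and acceptors[j]) or (donors[j] and acceptors[i])):
            contacts.add((a, b, "HBOND"))
        if d <= crit.ionic_distance and charges[i] * charges[j] < 0:
            contacts.add((a, b, "IONIC"))

    # ring-based interactions on the full topology's ring list
    ring_data = []
    sel_set = set(sel.tolist())
    for ring in topology.rings:
        if not all(ix in sel_set for ix in ring):
            continue
        centroid, normal = _ring_geometry(coords, ring)
        ring_data.append((int(topology.resids[ring[0]]),
                          str(topology.chains[ring[0]]), centroid, normal))
    for m in range(len(ring_data)):
        rm, cm, centm, nm = ring_data[m]
        for n in range(m + 1, len(ring_data)):
            rn, cn, centn, nn = ring_data[n]
            if cm == cn and abs(rm - rn) < crit.min_sequence_separation:
                continue
            if np.linalg.norm(centm - centn) <= crit.pipistack_distance:
                ang = np.degrees(np.arccos(np.clip(abs(np.dot(nm, nn)), 0, 1)))
                if ang <= crit.pipistack_angle:
                    a, b = sorted((rm, rn))
                    contacts.add((a, b, "PIPISTACK"))
    cations = np.flatnonzero(charges > 0)
    for rm, cm, centm, nm in ring_data:
        for ci in cations:
            if chains[ci] == cm and abs(int(resids[ci]) - rm) < crit.min_sequence_separation:
                continue
            if np.linalg.norm(pos[ci] - centm) <= crit.pication_distance:
                a, b = sorted((res_key(ci), rm))
                contacts.add((a, b, "PICATION"))
    return contacts


def contact_frequencies(ensembles, selection=None, criteria: ContactCriteria = None,
                        window=None, stride: int = 1) -> InteractionNetwork:
    """Per-state contact frequencies: per-replicate fractions of analysed
    frames containing the contact, averaged (unweighted) across replicates."""
    ensembles = list(ensembles)
    if not ensembles:
        raise ValueError("need at least one replicate ensemble")
    state = ensembles[0].state
    per_replicate = []
    nodes: set = set()
    for ens in ensembles:
        sub = ens.window(*(window or (None, None)), stride=stride)
        if sub.n_frames == 0:
            raise ValueError("analysis window removed every frame")
        counts: dict = {}
        for f in range(sub.n_frames):
            for key in detect_contacts(sub.coords[f], sub.topology,
                                       criteria=criteria, selection=selection):
                counts[key] = counts.get(key, 0) + 1
        per_replicate.append({k: c / sub.n_frames for k, c in counts.items()})
        sel = (np.arange(sub.topology.n_atoms) if selection is None
               else np.asarray(selection, dtype=np.intp))
        nodes.update(int(r) for r in sub.topology.resids[sel])
    keys = set().union(*per_replicate) if per_replicate else set()
    freqs = {k: float(np.mean([rep.get(k, 0.0) for rep in per_replicate]))
             for k in keys}
    return InteractionNetwork(state=state, frequencies=freqs, nodes=nodes)


def classify_edges(net_a: InteractionNetwork, net_b: InteractionNetwork,
                   threshold: float = 0.3) -> EdgeClassification:
    """Partition all observed (pair, type) keys by per-state presence.

    A contact is present in a state when its frequency ≥ threshold
    (boundary inclusive); presence is evaluated per interaction type.
    """
    universe = set(net_a.frequencies) | set(net_b.frequencies)
    in_a = net_a.edges_at(threshold)
    in_b = net_b.edges_at(threshold)
    return EdgeClassification(
        threshold=float(threshold),
        exclusive_a=in_a - in_b,
        exclusive_b=in_b - in_a,
        shared=in_a & in_b,
        absent=universe - in_a - in_b,
    )


def extract_neighborhood(network, focal: int, max_steps: int = 2,
                         threshold: float = 0.3,
                         classification: EdgeClassification = None) -> nx.MultiGraph:
    """Breadth-first neighbourhood of a focal residue over strong edges.

    ``network`` may be one :class:`InteractionNetwork` or a sequence of
    them (e.g. both states); an edge counts as traversable when its
    frequency reaches the threshold in any supplied network.  The returned
    subgraph keeps edge frequencies and, when a classification is given,
    each edge's exclusivity class.
    """
    nets = [network] if isinstance(network, InteractionNetwork) else list(network)
    all_nodes = set().union(*(n.nodes for n in nets))
    if focal not in all_nodes:
        raise ValueError(f"focal residue {focal} is not in the network")
    adjacency: dict = {}
    edge_info: dict = {}
    for net in nets:
        for (a, b, typ), freq in net.frequencies.items():
            info = edge_info.setdefault((a, b, typ), {})
            info[net.state] = max(info.get(net.state, 0.0), freq)
    strong = {k for k, info in edge_info.items()
              if max(info.values()) >= threshold}
    for a, b, _ in strong:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    depths = {focal: 0}
    frontier = [focal]
    for depth in range(1, max_steps + 1):
        nxt = []
        for node in frontier:
            for nb in adjacency.get(node, ()):
                if nb not in depths:
                    depths[nb] = depth
                    nxt.append(nb)
        frontier = nxt
    keep = set(depths)
    g = nx.MultiGraph(focal=focal, threshold=threshold, max_steps=max_steps)
    for node in sorted(keep):
        g.add_node(node, depth=depths[node])
    for (a, b, typ) in sorted(strong):
        if a in keep and b in keep:
            attrs = {"interaction": typ}
            attrs.update({f"freq_{s}": f for s, f in edge_info[(a, b, typ)].items()})
            if classification is not None:
                attrs["class"] = classification.classify((a, b, typ))
            g.add_edge(a, b, key=typ, **attrs)
    return g
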