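"""Interaction paths, gate residues, pair tables and triad cliques.

All residue indices are author numbers; sequence separation is the absolute
difference of author numbers.  Distances are C-alpha to C-alpha, consistent
with the coarse-grained model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .structure import CalphaChain
from .coupling import CouplingProfile

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayReport",
    "CliqueSet",
    "extract_pathways",
    "find_triad_cliques",
    "clique_cutoff_sweep",
]

DEFAULT_CT_THRESHOLD = 0.02
DEFAULT_PAIR_CUTOFF = 7.2
DEFAULT_MIN_PAIR_SEPARATION = 10
DEFAULT_CLIQUE_CUTOFF = 6.2
DEFAULT_CLIQUE_MIN_SEPARATION = 4
DEFAULT_CLIQUE_SWEEP = (6.0, 6.1, 6.2, 6.3, 6.4)


@dataclass(frozen=True)
class PathwayReport:
    """Thresholded coupling support organized into contact components."""

    chain_ref: str
    ct_threshold: float
    pair_cutoff: float
    min_pair_separation: int
    path_residues: frozenset
    components: tuple  # of frozensets of residue numbers
    gates: tuple  # of frozensets, parallel to components
    pair_table: tuple  # of (i, j, distance) with i < j

    @property
    def all_gates(self) -> frozenset:
        out = set()
        for g in self.gates:
            out |= g
        return frozenset(out)


@dataclass(frozen=True)
class CliqueSet:
    """Residue triads mutually in contact while distant along the sequence."""

    chain_ref: str
    cutoff: float
    min_separation: int
    triads: tuple  # of sorted (i, j, k) residue-number triples

    def __len__(self) -> int:
        return len(self.triads)

    @property
    def members(self) -> frozenset:
        return frozenset(r for t in self.triads for r in t)


def extract_pathways(
    chain: CalphaChain,
    profile: CouplingProfile,
    ct_threshold: float = DEFAULT_CT_THRESHOLD,
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF,
    min_pair_separation: int = DEFAULT_MIN_PAIR_SEPARATION,
) -> PathwayReport:
    """Interaction pathway: residues with non-zero (>= threshold) C_T.

    Components come from the contact graph (<= pair_cutoff) restricted to
    path residues.  Gates of a component are its subgraph extremities
    (degree <= 1) plus the member with the lowest contact count in the full
    chain, a surface-exposure proxy.  The pair table lists path-residue
    pairs within pair_cutoff separated by >= min_pair_separation along the
    sequence.
    """
    if not np.array_equal(profile.residue_ids, chain.res_ids):
        raise ValueError("profile was not computed on this chain")
    mask = profile.averaged_ct >= ct_threshold
    path_idx = np.nonzero(mask)[0]
    chain_ref = f"{chain.pdb_id}/{chain.chain_id}"
    if len(path_idx) == 0:
        logger.warning("empty interaction path at threshold %g", ct_threshold)
        return PathwayReport(
            chain_ref, ct_threshold, pair_cutoff, min_pair_separation,
            frozenset(), (), (), (),
        )

    dist = chain.distance_matrix()
    contact = dist <= pair_cutoff
    np.fill_diagonal(contact, False)
    full_degree = contact.sum(axis=1)

    res_ids = chain.res_ids
    sub = nx.Graph()
    sub.add_nodes_from(int(res_ids[i]) for i in path_idx)
    for a_pos, i in enumerate(path_idx):
        for j in path_idx[a_pos + 1:]:
            if contact[i, j]:
                sub.add_edge(int(res_ids[i]), int(res_ids[j]))

    id_to_idx = {int(r): i for i, r in enumerate(res_ids)}
    components, gates = [], []
    for comp in nx.connected_components(sub):
        comp = frozenset(comp)
        comp_gates = {r for r in comp if sub.degree[r] <= 1}
        exposure = min(comp, key=lambda r: (full_degree[id_to_idx[r]], r))
        comp_gates.add(exposure)
        components.append(comp)
        gates.append(frozenset(comp_gates))
    order = sorted(range(len(components)), key=lambda c: min(components[c]))
    components = tuple(components[c] for c in order)
    gates = tuple(gates[c] for c in order)

    pairs = []
    for a_pos, i in enumerate(path_idx):
        for j in path_idx[a_pos + 1:]:
            if not contact[i, j]:
                continue
            ri, rj = int(res_ids[i]), int(res_ids[j])
            if abs(rj - ri) < min_pair_separation:
                continue
            pairs.append((min(ri, rj), max(ri, rj), float(dist[i, j])))
    pairs.sort()

    return PathwayReport(
        chain_ref,
        ct_threshold,
        pair_cutoff,
        min_pair_separation,
        frozenset(int(res_ids[i]) for i in path_idx),
        components,
        gates,
        tuple(pairs),
    )


def find_triad_cliques(
    chain: CalphaChain,
    cutoff: float = DEFAULT_CLIQUE_CUTOFF,
    min_separation: int = DEFAULT_CLIQUE_MIN_SEPARATION,
) -> CliqueSet:
    """All residue triples with mutual contact (<= cutoff) and pairwise
    sequence separation >= min_separation."""
    if chain.n < 3:
        raise ValueError("need at least 3 residues")
    res_ids = chain.res_ids
    dist = chain.distance_matrix()
    sep = np.abs(res_ids[:, None] - res_ids[None, :])
    adj = (dist <= cutoff) & (sep >= min_separation)
    np.fill_diagonal(adj, False)

    triads = []
    rows, cols = np.nonzero(np.triu(adj, k=1))
    for i, j in zip(rows, cols):
        ks = np.nonzero(adj[i] & adj[j])[0]
        for k in ks[ks > j]:
            triads.append(tuple(sorted((int(res_ids[i]), int(res_ids[j]), int(res_ids[k])))))
    triads = tuple(sorted(set(triads)))
    return CliqueSet(
        chain_ref=f"{chain.pdb_id}/{chain.chain_id}",
        cutoff=cutoff,
        min_separation=min_separation,
        triads=triads,
    )


def clique_cutoff_sweep(
    chain: CalphaChain,
    cutoffs=DEFAULT_CLIQUE_SWEEP,
    min_separation: int = DEFAULT_CLIQUE_MIN_SEPARATION,
) -> dict:
    """Triad cliques at each cutoff; triad sets are monotone in the cutoff."""
    if len(cutoffs) == 0:
        raise ValueError("cutoff list must be nonempty")
    return {
        float(c): find_triad_cliques(chain, c, min_separation) for c in cutoffs
    }


def pair_table_to_tsv(report: PathwayReport, hub: int | None = None) -> str:
    """Pair listing: i, j, distance (1 decimal), hub flags."""
    lines = ["i\tj\tdist\ti_is_hub\tj_is_hub"]
    for i, j, d in report.pair_table:
        lines.append(f"{i}\t{j}\t{d:.1f}\t{int(i == hub)}\t{int(j == hub)}")
    return "\n".join(lines) + "\n"


def cliques_to_tsv(clique_sets) -> str:
    """Triad listing across one or more cutoffs."""
    if isinstance(clique_sets, CliqueSet):
        clique_sets = {clique_sets.cutoff: clique_sets}
    lines = ["cutoff\tres_i\tres_j\tres_k"]
    for cutoff in sorted(clique_sets):
        for i, j, k in clique_sets[cutoff].triads:
            lines.append(f"{cutoff:.1f}\t{i}\t{j}\t{k}")
    return "\n".join(lines) + "\n"
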