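"""Statistical-parsimony haplotype networks.

A pair of haplotypes is connectable when the number of substitutions
separating them does not exceed the parsimony connection limit: the largest
step count for which the probability that every substitution hit its own
site (no superimposed changes) still meets the requested confidence.  Under
uniform placement of j substitutions over m sites that probability is

    P(j, m) = prod_{i=0}^{j-1} (m - i) / m,

evaluated here by its recursion P(j) = P(j-1) * (m - j + 1) / m.  The limit
is non-decreasing in sequence length and collapses to single-step
connections as the confidence approaches 1.

Network construction simplifies full cladogram estimation to the part the
downstream analyses consume: haplotypes are agglomerated in increasing
distance order, pairs within the limit are connected (multi-step
connections materialise unobserved intermediate nodes), and network
membership equals the connected components of the distance-thresholded
graph.  Loops arising from distance-1 edges are retained, not broken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .model import TaxonPartition
from .seqdiv import HaplotypeTable, UNAMBIGUOUS

logger = logging.getLogger(__name__)


def parsimony_probability(n_steps: int, seq_length: int) -> float:
    """Probability that ``n_steps`` substitutions over ``seq_length`` sites
    all hit distinct sites, computed by the product recursion."""
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if n_steps > seq_length:
        return 0.0
    p = 1.0
    for i in range(n_steps):
        p *= (seq_length - i) / seq_length
    return p


def connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest number of mutational steps whose parsimony probability still
    meets ``confidence``.  Always at least 1: a single substitution cannot
    be superimposed."""
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    j = 1
    p = 1.0
    while j < seq_length:
        p_next = p * (seq_length - j) / seq_length
        if p_next < confidence:
            break
        p = p_next
        j += 1
    return j


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Thresholded single-step haplotype graph.

    ``graph`` holds observed haplotypes plus inferred unobserved
    intermediates (node attribute ``observed``); every edge represents one
    mutational step.  ``components`` partitions the *observed* haplotypes
    into separate networks.  ``dropped`` lists haplotypes excluded for
    carrying ambiguity codes.
    """

    graph: nx.Graph
    components: list[set[str]]
    limit: int
    dropped: list[str] = field(default_factory=list)

    @property
    def n_networks(self) -> int:
        return len(self.components)

    def component_of(self, haplotype_id: str) -> int:
        for i, comp in enumerate(self.components):
            if haplotype_id in comp:
                return i
        raise KeyError(haplotype_id)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b,
             "observed_a": self.graph.nodes[a]["observed"],
             "observed_b": self.graph.nodes[b]["observed"]}
            for a, b in sorted(self.graph.edges)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b",
                                           "observed_a", "observed_b"])


def hamming_distance(a: str, b: str, columns: list[int] | None = None) -> int:
    """Substitution count over the given columns (all columns if None)."""
    if columns is None:
        columns = range(len(a))  # type: ignore[assignment]
    return sum(1 for i in columns if a[i] != b[i])


def build_networks(
    hap: HaplotypeTable,
    confidence: float = 0.95,
    seq_length: int | None = None,
) -> HaplotypeNetwork:
    """Partition haplotypes into statistical-parsimony networks.

    Haplotypes containing IUPAC ambiguity codes are dropped first (logged);
    alignment columns that are gapped in any retained haplotype are excluded
    from the Hamming distances.  Pairs are processed in increasing
    (distance, id, id) order; a pair within the connection limit is linked —
    directly at distance 1, through a chain of unobserved intermediate nodes
    otherwise (only when the pair is not already connected, so single-step
    loops are kept but redundant long paths are not materialised).
    """
    seqs = {
        hid: seq
        for hid, seq in hap.haplotypes
        if set(seq) <= (UNAMBIGUOUS | {"-"})
    }
    dropped = [hid for hid, _ in hap.haplotypes if hid not in seqs]
    if dropped:
        logger.info("dropped %d haplotypes with ambiguity codes: %s",
                    len(dropped), dropped)
    if not seqs:
        raise ValueError("no unambiguous haplotypes to network")
    length = len(next(iter(seqs.values())))
    columns = [
        i for i in range(length)
        if all(seq[i] != "-" for seq in seqs.values())
    ]
    limit = connection_limit(
        seq_length if seq_length is not None else length, confidence
    )
    graph = nx.Graph()
    for hid in seqs:
        graph.add_node(hid, observed=True)
    pairs = sorted(
        (hamming_distance(seqs[a], seqs[b], columns), a, b)
        for a, b in combinations(sorted(seqs), 2)
    )
    n_unobserved = 0
    for d, a, b in pairs:
        if d > limit:
            continue
        if d <= 1:
            graph.add_edge(a, b)
        elif not nx.has_path(graph, a, b):
            chain = [a]
            for _ in range(d - 1):
                n_unobserved += 1
                node = f"U{n_unobserved}"
                graph.add_node(node, observed=False)
                chain.append(node)
            chain.append(b)
            for u, v in zip(chain, chain[1:]):
                graph.add_edge(u, v)
    components = [
        set(n for n in comp if graph.nodes[n]["observed"])
        for comp in nx.connected_components(graph)
    ]
    components.sort(key=lambda comp: min(comp))
    return HaplotypeNetwork(graph, components, limit, dropped)


def network_composition(
    net: HaplotypeNetwork, hap: HaplotypeTable, part: TaxonPartition
) -> pd.DataFrame:
    """Per-network composition table: haplotype, specimen count and the
    taxa carrying it — the tabular counterpart of a network figure legend."""
    rows = []
    for i, comp in enumerate(net.components):
        for hid in sorted(comp):
            members = hap.members_of(hid)
            taxa = sorted({part.assignments.get(s, "?") for s in members})
            rows.append(
                {
                    "network": i,
                    "haplotype": hid,
                    "n_specimens": len(members),
                    "taxa": ",".join(taxa),
                }
            )
    return pd.DataFrame(rows, columns=["network", "haplotype",
                                       "n_specimens", "taxa"])
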