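"""The metabolic reaction network (MRN).

Nodes are metabolites, edges are reaction pairs: substrate-product pairs of
single enzymatic reactions, paired by structural similarity (the KEGG
RPAIR concept).  The network is undirected — annotation propagation never
uses reaction direction — and parallel reaction pairs between the same two
metabolites collapse to a single edge that keeps the list of pair ids.

The "reaction step" between two metabolites is the number of edges on the
shortest path between them.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import networkx as nx
import pandas as pd

from .models import MetaboliteNode

log = logging.getLogger(__name__)

__all__ = [
    "ReactionPairNetwork",
    "build_mrn",
    "read_reaction_pairs",
    "read_compounds",
    "is_organic",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C6H12O6`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def is_organic(node: MetaboliteNode) -> bool:
    """Eligibility for annotation: a defined structure that contains carbon.

    Stands in for the curation step that excludes inorganic species and
    entries without a strict chemical structure from the annotatable
    chemical space; the rule is configurable in :func:`build_mrn`.
    """
    if not node.smiles:
        return False
    if not node.formula:
        return False
    try:
        counts = parse_formula(node.formula)
    except ValueError:
        return False
    return counts.get("C", 0) > 0


class ReactionPairNetwork:
    """Undirected reaction-pair graph plus the full compound registry."""

    def __init__(self, graph: nx.Graph, compounds: dict[str, MetaboliteNode]):
        self.graph = graph
        self.compounds = compounds

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in self.graph

    def node(self, metabolite_id: str) -> MetaboliteNode:
        return self.compounds[metabolite_id]

    def eligible_ids(self) -> set[str]:
        """Metabolites in the graph that may receive annotations."""
        return {n for n, d in self.graph.nodes(data=True) if d.get("eligible", False)}

    def neighbors_within(self, metabolite_id: str, max_steps: int = 1) -> dict[str, int]:
        """Breadth-first reaction-step distances from a node, excluding itself."""
        if metabolite_id not in self.graph:
            raise KeyError(f"metabolite {metabolite_id!r} not in the network")
        if max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        dist = nx.single_source_shortest_path_length(self.graph, metabolite_id, cutoff=max_steps)
        dist.pop(metabolite_id, None)
        return dist


def build_mrn(
    pairs: pd.DataFrame,
    compounds: pd.DataFrame | dict[str, MetaboliteNode],
    eligibility=is_organic,
) -> ReactionPairNetwork:
    """Assemble the network from a reaction-pair table and a compound table.

    ``pairs`` needs columns ``rp_id, from, to``; ``compounds`` needs
    ``id, name, formula, monoisotopic_mass, smiles``.  Pairs referencing
    unknown compounds are logged and dropped; self-pairs are ignored.
    Compounds never referenced by any pair stay in the registry but get no
    graph node.
    """
    if isinstance(compounds, pd.DataFrame):
        registry: dict[str, MetaboliteNode] = {}
        for _, row in compounds.iterrows():
            cid = str(row["id"])
            registry[cid] = MetaboliteNode(
                metabolite_id=cid,
                name=str(row.get("name", "") or ""),
                formula=str(row.get("formula", "") or ""),
                monoisotopic_mass=float(row.get("monoisotopic_mass", 0.0) or 0.0),
                smiles=str(row.get("smiles", "") or ""),
            )
    else:
        registry = dict(compounds)

    g = nx.Graph()
    n_dropped = 0
    for _, row in pairs.iterrows():
        a, b = str(row["from"]), str(row["to"])
        rp = str(row["rp_id"])
        if a == b:
            continue
        if a not in registry or b not in registry:
            n_dropped += 1
            log.warning("reaction pair %s references unknown compound (%s, %s); dropped", rp, a, b)
            continue
        if g.has_edge(a, b):
            g[a][b]["rp_ids"].append(rp)
        else:
            g.add_edge(a, b, rp_ids=[rp])
    if n_dropped:
        log.warning("%d reaction pairs dropped (unresolvable endpoints)", n_dropped)
    for n in g.nodes:
        g.nodes[n]["eligible"] = bool(eligibility(registry[n]))
    n_inelig = sum(1 for _, d in g.nodes(data=True) if not d["eligible"])
    log.info(
        "MRN built: %d nodes, %d edges; %d nodes ineligible for annotation",
        g.number_of_nodes(), g.number_of_edges(), n_inelig,
    )
    return ReactionPairNetwork(g, registry)


def read_reaction_pairs(path: str | Path) -> pd.DataFrame:
    """Read a reaction-pair table (CSV/TSV: ``rp_id,from,to``)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    need = {"rp_id", "from", "to"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: reaction-pair table needs columns {sorted(need)}")
    return df


def read_compounds(path: str | Path) -> pd.DataFrame:
    """Read a compound table (CSV/TSV: ``id,name,formula,monoisotopic_mass,smiles``)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "id" not in df.columns:
        raise ValueError(f"{path}: compound table needs an 'id' column")
    return df
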