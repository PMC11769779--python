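"""SNOMED CT-style concept graph and hierarchical comorbidity matching.

The three PESI comorbidities (history of cancer, heart failure, chronic
lung disease) are flagged from coded problem entries by hierarchical
matching: a problem code qualifies for a category if it equals, or is an
is-a descendant of, one of the category's root concepts and is not in the
category's exclusion set.

The package ships a small illustrative concept graph (a hand-built is-a
fragment over well-known SNOMED CT identifiers, ~10-20 codes per
category); institutional value sets differ between health systems, so a
loader for user-supplied edge lists and category files is provided.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

import networkx as nx
import pandas as pd

from .ehr_model import ProblemEntry, ProblemStatus

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "ConceptGraph",
    "ConceptGraphError",
    "ancestors",
    "match_category",
    "load_concept_graph",
    "default_concept_graph",
    "AMS_COMPLAINT_CODES",
]

#: The three PESI comorbidity categories.
CATEGORIES: Tuple[str, ...] = ("cancer", "heart_failure", "chronic_lung_disease")

#: Chief-complaint codes treated as "Altered Mental Status".
AMS_COMPLAINT_CODES: FrozenSet[str] = frozenset({"419284004"})

#: Statuses counted by default: active problem list + past medical history.
DEFAULT_STATUSES: FrozenSet[ProblemStatus] = frozenset(
    {ProblemStatus.active, ProblemStatus.history}
)


class ConceptGraphError(ValueError):
    """Structural problem in a concept graph (e.g. an is-a cycle)."""


@dataclass
class ConceptGraph:
    """Is-a edges (child -> parent) plus category root and exclusion sets.

    Acyclicity is validated at construction, so per-query traversals can
    assume a DAG. Descendant sets per category are memoized because the
    scoring engine queries them for every patient.
    """

    graph: nx.DiGraph
    category_roots: Dict[str, Set[str]]
    exclusions: Dict[str, Set[str]] = field(default_factory=dict)
    _members: Dict[str, FrozenSet[str]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        category_roots: Dict[str, Iterable[str]],
        exclusions: Dict[str, Iterable[str]] | None = None,
    ) -> "ConceptGraph":
        g = nx.DiGraph()
        g.add_edges_from((str(c), str(p)) for c, p in edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ConceptGraphError(f"is-a relation contains a cycle: {cycle}")
        roots = {c: {str(r) for r in rs} for c, rs in category_roots.items()}
        excl = {c: {str(e) for e in es} for c, es in (exclusions or {}).items()}
        for c, rs in roots.items():
            for r in rs - set(g.nodes):
                logger.warning("category %s root %s absent from concept graph", c, r)
                g.add_node(r)
            overlap = rs & excl.get(c, set())
            if overlap:
                raise ConceptGraphError(
                    f"category {c}: exclusions overlap roots: {sorted(overlap)}"
                )
        for c, es in excl.items():
            for e in es - set(g.nodes):
                logger.warning("category %s exclusion %s absent from concept graph", c, e)
        return cls(graph=g, category_roots=roots, exclusions=excl)

    def ancestors(self, code: str) -> Set[str]:
        """Transitive is-a closure of ``code``, excluding ``code`` itself.

        A code absent from the graph, or a top-level concept, has no
        ancestors.
        """
        code = str(code)
        if code not in self.graph:
            return set()
        return set(nx.descendants(self.graph, code))  # edges point child->parent

    def category_members(self, category: str) -> FrozenSet[str]:
        """All codes that match ``category``: roots plus their descendants,
        minus the category's exclusion set."""
        if category not in self.category_roots:
            raise KeyError(f"unknown category {category!r}; expected one of {CATEGORIES}")
        if category not in self._members:
            members: Set[str] = set()
            for root in self.category_roots[category]:
                members.add(root)
                if root in self.graph:
                    # nodes that can reach the root along child->parent edges
                    members |= set(nx.ancestors(self.graph, root))
            members -= self.exclusions.get(category, set())
            self._members[category] = frozenset(members)
        return self._members[category]


def ancestors(code: str, graph: ConceptGraph) -> Set[str]:
    """Functional alias for :meth:`ConceptGraph.ancestors`."""
    return graph.ancestors(code)


def match_category(
    entries: Iterable[ProblemEntry],
    category: str,
    graph: ConceptGraph,
    statuses: FrozenSet[ProblemStatus] = DEFAULT_STATUSES,
) -> Tuple[bool, List[ProblemEntry]]:
    """Flag a comorbidity category from coded problem entries.

    Returns ``(flag, evidence)`` where ``flag`` is true iff some entry
    with a counted status carries a code equal to or descending from a
    category root (and not excluded); ``evidence`` lists every qualifying
    entry in input order.
    """
    members = graph.category_members(category)
    evidence = [e for e in entries if e.status in statuses and e.snomed_code in members]
    return bool(evidence), evidence


def load_concept_graph(edges_csv: str | Path, categories_json: str | Path) -> ConceptGraph:
    """Load a concept graph from a ``child,parent`` CSV edge list plus a
    JSON category file ``{category: {roots: [...], exclusions: [...]}}``."""
    edges_df = pd.read_csv(edges_csv, dtype=str)
    if list(edges_df.columns[:2]) != ["child", "parent"]:
        raise ConceptGraphError(
            f"edge list must have columns child,parent; got {list(edges_df.columns)}"
        )
    with open(categories_json, "r", encoding="utf-8") as fh:
        cats = json.load(fh)
    return ConceptGraph.from_edges(
        edges=edges_df[["child", "parent"]].itertuples(index=False, name=None),
        category_roots={c: spec.get("roots", []) for c, spec in cats.items()},
        exclusions={c: spec.get("exclusions", []) for c, spec in cats.items()},
    )


def default_concept_graph() -> ConceptGraph:
    """The packaged illustrative concept graph (not an institutional set)."""
    data = resources.files("autopesi") / "data"
    return load_concept_graph(
        str(data / "concept_edges.csv"), str(data / "concept_categories.json")
    )
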