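"""Y-chromosomal and mitochondrial haplogroup calling.

A haplogroup tree is a rooted phylogeny whose edges carry defining variants:
a sample descending through an edge carries the derived state at every
variant on that edge.  Calling walks the observed haploid marker states
against the tree and returns the deepest node whose root-path variants are
sufficiently supported, with few derived states observed off the path.
Nodes carry geographic-origin labels so a call doubles as a statement of
patrilineal or matrilineal origin.

The package ships a small synthetic fixture phylogeny per lineage (abstract
haplogroup names, continental geography labels); real trees in the same
newick + variant-table format load through the same interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("forensnp.lineage")

GEOGRAPHIES = (
    "Africa",
    "Western Eurasia",
    "Eastern Eurasia",
    "South Asia",
    "Americas",
)


@dataclass(frozen=True)
class HaplogroupTree:
    """Rooted haplogroup phylogeny with edge-defining variants.

    ``parent`` maps every non-root node to its parent; ``edge_variants``
    maps a node to the marker ids defining the edge from its parent (the
    root has none); ``geography`` labels each node with a region of origin.
    """

    root: str
    parent: Mapping[str, str]
    edge_variants: Mapping[str, tuple[str, ...]]
    geography: Mapping[str, str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for node, variants in self.edge_variants.items():
            for v in variants:
                if v in seen:
                    raise ValueError(
                        f"defining variant {v} appears on edges of both "
                        f"{seen[v]} and {node}"
                    )
                seen[v] = node
        for node in self.parent:
            if not self._reaches_root(node):
                raise ValueError(f"node {node} not reachable from root")

    def _reaches_root(self, node: str, _limit: int = 10_000) -> bool:
        for _ in range(_limit):
            if node == self.root:
                return True
            if node not in self.parent:
                return False
            node = self.parent[node]
        return False

    @property
    def nodes(self) -> list[str]:
        return [self.root] + sorted(self.parent)

    @property
    def marker_ids(self) -> list[str]:
        out: list[str] = []
        for node in sorted(self.edge_variants):
            out.extend(self.edge_variants[node])
        return out

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parent.items() if p == node)

    def path_to_root(self, node: str) -> list[str]:
        """Nodes from root down to ``node`` inclusive."""
        path = [node]
        while node != self.root:
            node = self.parent[node]
            path.append(node)
        return path[::-1]

    def path_variants(self, node: str) -> list[str]:
        out: list[str] = []
        for n in self.path_to_root(node):
            out.extend(self.edge_variants.get(n, ()))
        return out

    def depth(self, node: str) -> int:
        return len(self.path_to_root(node)) - 1

    # -- serialisation --------------------------------------------------
    def to_files(self, newick_path: str | Path, table_path: str | Path) -> None:
        """Write newick topology + TSV of (node, marker, derived allele, geography)."""
        Path(newick_path).write_text(self._to_newick() + "\n")
        rows = []
        for node in self.nodes:
            variants = self.edge_variants.get(node, ())
            if variants:
                for v in variants:
                    rows.append((node, v, "1", self.geography.get(node, "")))
            else:
                rows.append((node, "", "", self.geography.get(node, "")))
        pd.DataFrame(
            rows, columns=["node", "marker_id", "derived_allele", "geography"]
        ).to_csv(table_path, sep="\t", index=False)

    def _to_newick(self) -> str:
        def render(node: str) -> str:
            kids = self.children(node)
            if not kids:
                return node
            return "(" + ",".join(render(k) for k in kids) + ")" + node

        return render(self.root) + ";"

    @classmethod
    def from_files(
        cls, newick_path: str | Path, table_path: str | Path
    ) -> "HaplogroupTree":
        import dendropy

        tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
        root_node = tree.seed_node
        parent: dict[str, str] = {}

        def name_of(n) -> str:
            return n.taxon.label if n.taxon is not None else n.label

        for node in tree.preorder_node_iter():
            if node is root_node:
                continue
            parent[name_of(node)] = name_of(node.parent_node)
        table = pd.read_csv(table_path, sep="\t", dtype=str).fillna("")
        edge_variants: dict[str, tuple[str, ...]] = {}
        geography: dict[str, str] = {}
        for node, grp in table.groupby("node", sort=False):
            geos = set(grp["geography"]) - {""}
            if geos:
                geography[node] = sorted(geos)[0]
            variants = tuple(m for m in grp["marker_id"] if m)
            if variants:
                edge_variants[node] = variants
        return cls(
            root=name_of(root_node),
            parent=parent,
            edge_variants=edge_variants,
            geography=geography,
        )


@dataclass(frozen=True)
class HaplogroupCall:
    """A haplogroup assignment with its path support."""

    node: str
    n_derived_observed: int
    n_expected_on_path: int
    n_path_non_missing: int
    conflicts: int
    geography: str

    @property
    def support(self) -> float:
        if self.n_path_non_missing == 0:
            return 1.0  # vacuous: the root carries no defining variants
        return self.n_derived_observed / self.n_path_non_missing


def call_haplogroup(
    states: Mapping[str, float],
    tree: HaplogroupTree,
    min_support: float = 0.8,
    max_conflicts: int = 1,
) -> HaplogroupCall | None:
    """Call the deepest supported haplogroup from haploid marker states.

    ``states`` maps marker id -> {0 ancestral, 1 derived, NaN missing}.
    A node qualifies when, among the non-missing variants on its root path,
    the derived fraction is >= ``min_support``, at most ``max_conflicts``
    derived states are observed off the path, and — so that wholly
    unobserved branches are never descended — at least one variant on the
    node's own defining edge is observed in the derived state.  Returns
    ``None`` (no call) when no marker of the tree is observed at all — for
    the Y tree this signals absence of male DNA.

    Ties at equal depth break on support fraction, then node name.
    """
    tree_markers = set(tree.marker_ids)
    extra = set(states) - tree_markers
    if extra:
        logger.warning(
            "%d observed markers absent from the haplogroup tree; ignored", len(extra)
        )
    observed = {
        m: int(v)
        for m, v in states.items()
        if m in tree_markers and v is not None and np.isfinite(v)
    }
    if not observed:
        return None
    derived_observed = {m for m, v in observed.items() if v == 1}

    best: tuple[int, float, str] | None = None
    best_call: HaplogroupCall | None = None
    for node in tree.nodes:
        path = tree.path_variants(node)
        path_set = set(path)
        non_missing = [m for m in path if m in observed]
        n_derived = sum(1 for m in non_missing if m in derived_observed)
        support = n_derived / len(non_missing) if non_missing else 1.0
        conflicts = len(derived_observed - path_set)
        if node != tree.root and not any(
            m in derived_observed for m in tree.edge_variants.get(node, ())
        ):
            continue  # no positive evidence on this node's own edge
        if support < min_support or conflicts > max_conflicts:
            continue
        key = (tree.depth(node), support, node)
        if best is None or key > best:
            best = key
            best_call = HaplogroupCall(
                node=node,
                n_derived_observed=n_derived,
                n_expected_on_path=len(path),
                n_path_non_missing=len(non_missing),
                conflicts=conflicts,
                geography=tree.geography.get(node, ""),
            )
    return best_call


# ---------------------------------------------------------------------------
# lineage vs biparental consistency
# ---------------------------------------------------------------------------

#: Default mapping from simulated reference-population labels to the
#: geographic vocabulary of the fixture trees.
DEFAULT_GEO_MAP = {
    "AFR": "Africa",
    "EUR": "Western Eurasia",
    "EAS": "Eastern Eurasia",
    "SAS": "South Asia",
    "AMR": "Americas",
}


@dataclass
class ConsistencyReport:
    """Cross-tabulation of uniparental origins against biparental ancestry."""

    paternal_geography: str | None
    maternal_geography: str | None
    biparental_assignment: str | None
    biparental_components: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    summary: str = ""

    @property
    def consistent(self) -> bool:
        return not self.flags


def lineage_consistency(
    call_y: HaplogroupCall | None,
    call_mt: HaplogroupCall | None,
    ancestry=None,
    geo_map: Mapping[str, str] = DEFAULT_GEO_MAP,
    minor_component: float = 0.2,
) -> ConsistencyReport:
    """Check uniparental geographic origins against biparental ancestry.

    A uniparental origin is *supported* when its geography matches any
    ancestry component with proportion above ``minor_component`` (or the
    single assigned group).  Disagreements are informative — they flag
    likely parental-line admixture — and never raise.
    """
    if call_y is None and call_mt is None and ancestry is None:
        raise ValueError("at least one of call_y, call_mt, ancestry required")
    y_geo = call_y.geography if call_y else None
    mt_geo = call_mt.geography if call_mt else None
    assignment = None
    components: dict[str, float] = {}
    flags: list[str] = []
    if ancestry is not None:
        assignment = ancestry.assignment
        components = {
            lab: float(q)
            for lab, q in zip(ancestry.labels, ancestry.q)
            if q > minor_component
        }
        supported_geos = {geo_map.get(lab, lab) for lab in components}
        if y_geo is not None and y_geo not in supported_geos:
            flags.append("paternal-line admixture")
        if mt_geo is not None and mt_geo not in supported_geos:
            flags.append("maternal-line admixture")
    parts = []
    if y_geo is not None:
        parts.append(f"paternal {y_geo}")
    if mt_geo is not None:
        parts.append(f"maternal {mt_geo}")
    if assignment is not None:
        parts.append(f"biparental {assignment}")
    return ConsistencyReport(
        paternal_geography=y_geo,
        maternal_geography=mt_geo,
        biparental_assignment=assignment,
        biparental_components=components,
        flags=flags,
        summary=" / ".join(parts),
    )


# ---------------------------------------------------------------------------
# synthetic fixture phylogenies
# ---------------------------------------------------------------------------

# (name suffix, geography, children) nested spec; every edge carries two
# defining variants named <lineage>:<node>:<i>.
_FIXTURE_TOPOLOGY = (
    ("A", "Africa", (("A1", "Africa", ()), ("A2", "Africa", ()))),
    (
        "E",
        "Africa",
        (("E1", "Africa", (("E1a", "Africa", ()),)), ("E2", "Western Eurasia", ())),
    ),
    (
        "R",
        "Western Eurasia",
        (
            ("R1", "Western Eurasia", (("R1a", "Western Eurasia", ()),)),
            ("R2", "South Asia", ()),
        ),
    ),
    (
        "C",
        "Eastern Eurasia",
        (("C1", "Eastern Eurasia", ()), ("C2", "Eastern Eurasia", ())),
    ),
    (
        "O",
        "Eastern Eurasia",
        (("O1", "Eastern Eurasia", (("O1a", "Eastern Eurasia", ()),)),),
    ),
    ("H", "South Asia", (("H1", "South Asia", ()), ("H2", "South Asia", ()))),
    ("Q", "Americas", (("Q1", "Americas", (("Q1a", "Americas", ()),)),)),
)

#: Representative haplogroup per reference population, used by the simulator
#: to hand out lineages consistent with an individual's ancestry.
FIXTURE_POP_HAPLOGROUPS = {
    "AFR": ("A1", "A2", "E1", "E1a"),
    "EUR": ("R1", "R1a", "E2"),
    "EAS": ("C1", "C2", "O1", "O1a"),
    "SAS": ("H1", "H2", "R2"),
    "AMR": ("Q1", "Q1a", "C1"),
}


def fixture_tree(lineage: str, variants_per_edge: int = 2) -> HaplogroupTree:
    """Deterministic ~30-node synthetic haplogroup phylogeny.

    ``lineage`` is ``"Y"`` or ``"mt"``; it only prefixes node and marker
    names so the two trees carry disjoint marker sets.
    """
    if lineage not in ("Y", "mt"):
        raise ValueError("lineage must be 'Y' or 'mt'")
    root = f"{lineage}ROOT"
    parent: dict[str, str] = {}
    edge_variants: dict[str, tuple[str, ...]] = {}
    geography: dict[str, str] = {root: ""}

    def add(spec, parent_name: str) -> None:
        suffix, geo, children = spec
        name = f"{lineage}-{suffix}"
        parent[name] = parent_name
        geography[name] = geo
        edge_variants[name] = tuple(
            f"{lineage}:{suffix}:{i}" for i in range(1, variants_per_edge + 1)
        )
        for child in children:
            add(child, name)

    for top in _FIXTURE_TOPOLOGY:
        add(top, root)
    return HaplogroupTree(
        root=root, parent=parent, edge_variants=edge_variants, geography=geography
    )


def calls_to_tsv(
    calls: Mapping[str, HaplogroupCall | None], path: str | Path
) -> pd.DataFrame:
    rows = []
    for sample, call in calls.items():
        if call is None:
            rows.append((sample, "no_call", 0, 0, 0, ""))
        else:
            rows.append(
                (
                    sample,
                    call.node,
                    call.n_derived_observed,
                    call.n_expected_on_path,
                    call.conflicts,
                    call.geography,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "haplogroup", "n_derived", "n_path", "conflicts", "geography"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
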