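"""Per-node morphometric features and node classification.

Every dendritic node gets a seven-feature vector:

=====  =======================================================
D      node diameter (2 x SWC radius), um
PD     parent diameter; soma diameter for initial nodes, um
IB     initial branch order: 1 at initial nodes, +1 after each
       branch point travelling away from the soma
TD     terminal degree: number of terminal tips in the subtree
PS     path distance from the soma, um
LP     longest downstream path to a terminal end, um
TL     total dendritic length rooted at the node, um
=====  =======================================================

and one of three mutually exclusive classes: *initial* (parent is a soma
node), *branching_child* (non-soma parent has >= 2 dendritic children) or
*continuing* (everything else).  Soma parentage wins over branching, and any
node with >= 2 children counts as a branch point (multifurcations included).
Terminal nodes have LP = TL = 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .swc import Morphology, MorphNode, SWCStructureError

__all__ = [
    "NodeClass",
    "NodeFeatures",
    "FEATURE_NAMES",
    "classify_nodes",
    "compute_features",
    "feature_table",
    "total_dendritic_length",
]

FEATURE_NAMES = ("PD", "IB", "TD", "PS", "LP", "TL")

TREE_LABELS = {3: "basal", 4: "apical"}


class NodeClass(str, enum.Enum):
    INITIAL = "initial"
    BRANCHING_CHILD = "branching_child"
    CONTINUING = "continuing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class NodeFeatures:
    node_id: int
    D: float
    PD: float
    IB: int
    TD: int
    PS: float
    LP: float
    TL: float
    node_class: NodeClass
    tree_label: str
    is_terminal: bool
    is_branch_point: bool

    def as_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "D": self.D, "PD": self.PD, "IB": self.IB, "TD": self.TD,
            "PS": self.PS, "LP": self.LP, "TL": self.TL,
            "node_class": self.node_class.value,
            "tree_label": self.tree_label,
            "is_terminal": self.is_terminal,
            "is_branch_point": self.is_branch_point,
        }
        return d


def tree_label(node: MorphNode) -> str:
    """Map SWC type code to a dendrite label: 4 apical, 3 basal, else generic."""
    return TREE_LABELS.get(node.type_code, "generic")


def _dendritic_order(m: Morphology) -> list[MorphNode]:
    """Dendritic nodes in parent-before-child order (iterative, input order)."""
    soma_ids = [n.node_id for n in m.nodes if n.type_code == 1]
    order: list[MorphNode] = []
    stack: list[MorphNode] = []
    for sid in reversed(soma_ids):
        stack.extend(reversed(m.dendritic_children(sid)))
    # DFS preserving the SWC child order
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(reversed(m.dendritic_children(n.node_id)))
    n_dend = len(m.dendritic_nodes())
    if len(order) != n_dend:
        raise SWCStructureError(
            "dendritic nodes not all reachable from the soma"
        )
    return order


def classify_nodes(m: Morphology) -> dict[int, NodeClass]:
    """Assign every dendritic node its class; soma nodes are excluded."""
    classes: dict[int, NodeClass] = {}
    for n in _dendritic_order(m):
        parent = m.parent(n)
        if parent is None:
            raise SWCStructureError(f"dendritic node {n.node_id} has no parent")
        if parent.type_code == 1:
            classes[n.node_id] = NodeClass.INITIAL
        elif len(m.dendritic_children(parent.node_id)) >= 2:
            classes[n.node_id] = NodeClass.BRANCHING_CHILD
        else:
            classes[n.node_id] = NodeClass.CONTINUING
    return classes


def segment_length(m: Morphology, node: MorphNode) -> float:
    """3D Euclidean length of the compartment between a node and its parent."""
    parent = m.parent(node)
    if parent is None:
        return 0.0
    return node.distance_to(parent)


def total_dendritic_length(m: Morphology) -> float:
    """Sum of segment lengths between dendritic nodes and dendritic parents.

    Soma-to-initial stems are excluded, so the total equals the sum of TL
    over initial nodes.
    """
    total = 0.0
    for n in m.dendritic_nodes():
        p = m.parent(n)
        if p is not None and m.is_dendritic(p):
            total += n.distance_to(p)
    return total


def compute_features(
    m: Morphology, ps_includes_soma_radius: bool = False
) -> dict[int, NodeFeatures]:
    """Compute the full feature vector for every dendritic node.

    PS is measured from the soma attachment point; the soma extent itself
    contributes 0 unless ``ps_includes_soma_radius`` is set, in which case the
    root-soma radius is added to every PS (a documented convention switch).
    """
    for n in m.dendritic_nodes():
        if n.radius <= 0:
            raise ValueError(f"node {n.node_id} has nonpositive radius")

    order = _dendritic_order(m)
    classes = classify_nodes(m)
    soma_d = m.soma_diameter
    ps_offset = m.soma_root.radius if ps_includes_soma_radius else 0.0

    seg = {n.node_id: segment_length(m, n) for n in order}
    ps: dict[int, float] = {}
    ib: dict[int, int] = {}
    for n in order:  # root-to-tip pass
        parent = m.parent(n)
        if classes[n.node_id] is NodeClass.INITIAL:
            ps[n.node_id] = ps_offset + seg[n.node_id]
            ib[n.node_id] = 1
        else:
            ps[n.node_id] = ps[parent.node_id] + seg[n.node_id]
            branched = len(m.dendritic_children(parent.node_id)) >= 2
            ib[n.node_id] = ib[parent.node_id] + (1 if branched else 0)

    td: dict[int, int] = {}
    lp: dict[int, float] = {}
    tl: dict[int, float] = {}
    for n in reversed(order):  # tip-to-root pass
        kids = m.dendritic_children(n.node_id)
        if not kids:
            td[n.node_id], lp[n.node_id], tl[n.node_id] = 1, 0.0, 0.0
        else:
            td[n.node_id] = sum(td[k.node_id] for k in kids)
            lp[n.node_id] = max(seg[k.node_id] + lp[k.node_id] for k in kids)
            tl[n.node_id] = sum(seg[k.node_id] + tl[k.node_id] for k in kids)

    out: dict[int, NodeFeatures] = {}
    for n in order:
        parent = m.parent(n)
        pd_ = soma_d if classes[n.node_id] is NodeClass.INITIAL else parent.diameter
        out[n.node_id] = NodeFeatures(
            node_id=n.node_id,
            D=n.diameter,
            PD=pd_,
            IB=ib[n.node_id],
            TD=td[n.node_id],
            PS=ps[n.node_id],
            LP=lp[n.node_id],
            TL=tl[n.node_id],
            node_class=classes[n.node_id],
            tree_label=tree_label(n),
            is_terminal=not m.dendritic_children(n.node_id),
            is_branch_point=len(m.dendritic_children(n.node_id)) >= 2,
        )
    return out


#: fixed, documented column order of the flat feature table
TABLE_COLUMNS = [
    "morphology", "archive", "node_id", "tree_label", "node_class",
    "is_terminal", "is_branch_point",
    "D", "PD", "IB", "TD", "PS", "LP", "TL",
]


def feature_table(morphologies, **feature_kwargs) -> pd.DataFrame:
    """One row per dendritic node across a collection of morphologies."""
    rows = []
    for i, m in enumerate(morphologies):
        feats = compute_features(m, **feature_kwargs)
        name = m.metadata.get("name", m.metadata.get("source", f"morphology_{i}"))
        archive = m.metadata.get("archive", "")
        for f in feats.values():
            row = f.as_dict()
            row["morphology"] = name
            row["archive"] = archive
            rows.append(row)
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Export the feature table as TSV in the documented column order."""
    df.to_csv(path, sep="\t", index=False, columns=TABLE_COLUMNS)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
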