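"""Diameter-prediction model containers and their on-disk format.

A :class:`DiameterModel` is a linear equation through the origin,
``D_hat = sum_i coef_i * feature_i`` with features drawn from
{PD, IB, TD, PS, LP, TL}; a :class:`ModelSet` holds one model per
(node class x dendrite label) for a cell type, plus provenance.

Model sets are serialized as YAML (documented schema below) and the
published per-cell-type equation tables ship with the package as such
files, loadable by name (``load_packaged_model_set("hippocampal")``).

Schema::

    name: <preset name>
    cell_type: <free text>
    provenance: {source: ..., train_ids: [...], seed: ...}
    models:
      - node_class: initial | branching_child | continuing
        tree_label: apical | basal | generic | any
        features: [PD, LP]
        coefficients: [0.0755, 0.0056]
        adj_r2: 0.7216          # optional, goodness of fit on training data
        n_train: 137            # optional
        note: <optional free-text caveat; surfaced as a warning when applied>
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .morphometry import FEATURE_NAMES, NodeClass

__all__ = [
    "DiameterModel",
    "ModelSet",
    "load_model_set",
    "save_model_set",
    "load_packaged_model_set",
    "packaged_model_names",
]


@dataclass(frozen=True)
class DiameterModel:
    """A no-intercept linear diameter equation for one node class."""

    node_class: NodeClass
    tree_label: str  # 'apical' | 'basal' | 'generic' | 'any'
    features: tuple[str, ...]
    coefficients: tuple[float, ...]
    adj_r2: float | None = None
    n_train: int | None = None
    note: str | None = None

    def __post_init__(self):
        if len(self.features) != len(self.coefficients):
            raise ValueError("features and coefficients differ in length")
        if len(self.features) > 2:
            raise ValueError("diameter models use at most two features")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")

    def evaluate(self, features: dict) -> float:
        """Predicted diameter (um) for one node's feature values."""
        return float(
            sum(c * float(features[f]) for f, c in zip(self.features, self.coefficients))
        )

    def equation(self) -> str:
        return " + ".join(
            f"{c:g} x {f}" for f, c in zip(self.features, self.coefficients)
        )


@dataclass
class ModelSet:
    """All diameter equations for one cell type, keyed by class and label."""

    name: str
    cell_type: str = ""
    models: list[DiameterModel] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def add(self, model: DiameterModel) -> None:
        self.models.append(model)

    def lookup(self, node_class: NodeClass, tree_label: str) -> DiameterModel:
        """Exact (class, label) match, then the class's 'any' model, then a
        basal-like fallback for unexpected labels."""
        node_class = NodeClass(node_class)
        for label in (tree_label, "any", "generic", "basal"):
            for mdl in self.models:
                if mdl.node_class is node_class and mdl.tree_label == label:
                    return mdl
        raise KeyError(
            f"model set {self.name!r} has no model for "
            f"({node_class.value}, {tree_label})"
        )

    def labels(self) -> set[str]:
        return {m.tree_label for m in self.models}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cell_type": self.cell_type,
            "provenance": self.provenance,
            "models": [
                {
                    "node_class": m.node_class.value,
                    "tree_label": m.tree_label,
                    "features": list(m.features),
                    "coefficients": [float(c) for c in m.coefficients],
                    **({"adj_r2": float(m.adj_r2)} if m.adj_r2 is not None else {}),
                    **({"n_train": int(m.n_train)} if m.n_train is not None else {}),
                    **({"note": m.note} if m.note else {}),
                }
                for m in self.models
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSet":
        ms = cls(
            name=d.get("name", ""),
            cell_type=d.get("cell_type", ""),
            provenance=dict(d.get("provenance", {})),
        )
        for md in d.get("models", []):
            ms.add(
                DiameterModel(
                    node_class=NodeClass(md["node_class"]),
                    tree_label=md["tree_label"],
                    features=tuple(md["features"]),
                    coefficients=tuple(float(c) for c in md["coefficients"]),
                    adj_r2=md.get("adj_r2"),
                    n_train=md.get("n_train"),
                    note=md.get("note"),
                )
            )
        return ms


def save_model_set(ms: ModelSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ms.to_dict(), fh, sort_keys=False)


def load_model_set(path) -> ModelSet:
    with open(path) as fh:
        return ModelSet.from_dict(yaml.safe_load(fh))


_PACKAGED = {
    "hippocampal": "hippocampal.yaml",
    "cerebellar": "cerebellar.yaml",
    "striatal": "striatal.yaml",
    "striatal-lai": "striatal_lai.yaml",
    "striatal-luebke": "striatal_luebke.yaml",
}


def packaged_model_names() -> list[str]:
    return sorted(_PACKAGED)


def load_packaged_model_set(name: str) -> ModelSet:
    """Load one of the shipped per-cell-type equation tables by short name."""
    key = name
    if key not in _PACKAGED:
        raise KeyError(
            f"unknown packaged model set {name!r}; "
            f"available: {packaged_model_names()}"
        )
    ref = importlib.resources.files("dendrodiam.data") / _PACKAGED[key]
    return ModelSet.from_dict(yaml.safe_load(ref.read_text()))
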