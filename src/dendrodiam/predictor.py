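"""Apply a diameter model set to a morphology, soma-outward.

Prediction starts at initial nodes, where the parent diameter is the soma
diameter, and proceeds away from the soma; every subsequent branching child
or continuing node is evaluated with the *predicted* parent diameter in
place of the original one.  All other features (IB, TD, PS, LP, TL) are
purely geometric and therefore taken once from the original morphology.

Options cover the published control variants: keeping original initial-node
diameters, and the uniform-diameter control (every dendritic node set to the
same diameter, e.g. 2.0 um).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, replace

from . import morphometry
from .models import ModelSet
from .morphometry import NodeClass
from .swc import Morphology, MorphNode, SWCStructureError

__all__ = ["PredictionOptions", "predict_diameters", "traversal_order"]


@dataclass(frozen=True)
class PredictionOptions:
    """Controls for diameter prediction.

    ``min_diameter`` floors every prediction (some published equations can go
    nonpositive near the soma); ``uniform_diameter`` switches to the constant-
    diameter control and bypasses the models entirely.
    """

    keep_original_initial: bool = False
    min_diameter: float = 0.05  # um
    uniform_diameter: float | None = None

    def __post_init__(self):
        if self.min_diameter <= 0:
            raise ValueError("min_diameter must be positive")


def traversal_order(m: Morphology) -> list[MorphNode]:
    """Dendritic nodes in an order where every parent precedes its children.

    Deterministic given the input node order; works for shuffled SWC ids.
    """
    return morphometry._dendritic_order(m)


def predict_diameters(
    m: Morphology,
    models: ModelSet | None,
    opts: PredictionOptions = PredictionOptions(),
) -> Morphology:
    """Return a new morphology with predicted dendritic diameters.

    Topology, coordinates and type codes are untouched; only radii change
    (soma and axon nodes keep theirs).  Raises ``KeyError`` when the model
    set lacks a model for a present (class, label) combination and a
    numerical error if any prediction is non-finite.
    """
    order = traversal_order(m)
    if opts.uniform_diameter is not None:
        radii = {n.node_id: opts.uniform_diameter / 2.0 for n in order}
        return _with_radii(m, radii)

    if models is None:
        raise ValueError("a ModelSet is required unless uniform_diameter is set")
    feats = morphometry.compute_features(m)
    # fail early if any needed model is missing
    needed = {(f.node_class, f.tree_label) for f in feats.values()}
    for node_class, label in needed:
        models.lookup(node_class, label)

    soma_d = m.soma_diameter
    predicted: dict[int, float] = {}
    radii: dict[int, float] = {}
    warned_notes: set[str] = set()
    for n in order:
        f = feats[n.node_id]
        model = models.lookup(f.node_class, f.tree_label)
        if model.note and model.note not in warned_notes:
            warned_notes.add(model.note)
            _warnings.warn(f"model {models.name}/{model.node_class.value}: {model.note}")
        if f.node_class is NodeClass.INITIAL:
            pd_hat = soma_d
        else:
            pd_hat = predicted[n.parent_id]
        values = f.as_dict()
        values["PD"] = pd_hat
        d_hat = model.evaluate(values)
        if f.node_class is NodeClass.INITIAL and opts.keep_original_initial:
            d_hat = n.diameter
        if not math.isfinite(d_hat):
            raise ArithmeticError(
                f"non-finite predicted diameter at node {n.node_id}"
            )
        d_hat = max(d_hat, opts.min_diameter)
        predicted[n.node_id] = d_hat
        radii[n.node_id] = d_hat / 2.0
    return _with_radii(m, radii)


def _with_radii(m: Morphology, radii: dict[int, float]) -> Morphology:
    new_nodes = [
        replace(n, radius=radii[n.node_id]) if n.node_id in radii else n
        for n in m.nodes
    ]
    out = m.with_nodes(new_nodes)
    out.metadata["predicted"] = True
    return out
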