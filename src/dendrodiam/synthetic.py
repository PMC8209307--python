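"""Synthetic dendritic morphologies with ground-truth diameter rules.

Trees are grown trunk-by-trunk from a 3-point soma: each node either
continues (one child) or bifurcates (probability ``branch_prob``) until a
maximum path depth, with segment lengths drawn from a truncated Gaussian and
small random angular deviations (z-drift damped so synthetic cells never look
like reconstruction artefacts).  Diameters are then assigned soma-outward by
a ground-truth rule — either a :class:`~dendrodiam.models.ModelSet` applied
exactly the way the predictor applies one, or an explicit taper callable —
plus truncated Gaussian noise floored at ``min_diameter``.

By default the chained parent diameter seen by the rule is the *noisy*
parent value, mimicking how reconstruction noise propagates through a real
archive; ``noisy_chaining=False`` switches to noise-free chaining for
exact-recovery tests.

``spec_for_model_set`` returns growth parameters tuned per packaged cell
type so that every published equation produces positive, realistic diameters
(soma sizes around 12 um, segments of a few um, arbors of several hundred to
a few thousand nodes — the scale of real reconstructions).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import morphometry
from .models import ModelSet
from .morphometry import NodeClass
from .swc import SOMA, Morphology, MorphNode

__all__ = [
    "SynthSpec",
    "generate_morphology",
    "generate_archive",
    "generate_feature_table",
    "spec_for_model_set",
    "default_taper_rule",
]


def default_taper_rule(features: dict) -> float:
    """Generic ground-truth taper: 2 um initial stems, gentle taper along
    unbranched runs, stronger step-down at branch points."""
    cls = features["node_class"]
    if cls == NodeClass.INITIAL.value:
        return 2.0
    if cls == NodeClass.BRANCHING_CHILD.value:
        return 0.8 * features["PD"]
    return 0.98 * features["PD"]


@dataclass(frozen=True)
class SynthSpec:
    """Growth and diameter-rule parameters for one synthetic archive."""

    seed: int                                  # mandatory
    n_initial: int = 4
    branch_prob: float = 0.15
    segment_length: tuple = (5.0, 1.0)         # (mean, sd) um
    initial_segment_length: tuple | None = None
    initial_stem_soma_factor: float | None = None  # stem ~ factor * soma diam
    max_depth: int = 40                        # nodes along any path
    soma_diameter: tuple = (12.0, 0.0)         # (mean, sd) um across cells
    tree_label: str = "basal"
    trees: tuple | None = None                 # ((label, n_trunks), ...) override
    diameter_rule: object = None               # ModelSet | callable | None
    noise_sd: float = 0.05                     # um
    min_diameter: float = 0.05                 # um
    noisy_chaining: bool = True

    def __post_init__(self):
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def tree_spec(self) -> tuple:
        return self.trees if self.trees else ((self.tree_label, self.n_initial),)


_LABEL_CODES = {"apical": 4, "basal": 3, "generic": 5}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _grow_topology(spec: SynthSpec, rng: np.random.Generator):
    """Return (nodes, positions) with placeholder radii; 3-point soma first."""
    mean_sd = spec.soma_diameter
    soma_d = max(1.0, rng.normal(mean_sd[0], mean_sd[1])) if mean_sd[1] > 0 else mean_sd[0]
    r = soma_d / 2.0
    nodes = [
        MorphNode(1, SOMA, 0.0, 0.0, 0.0, r, -1),
        MorphNode(2, SOMA, 0.0, -r, 0.0, r, 1),
        MorphNode(3, SOMA, 0.0, r, 0.0, r, 1),
    ]
    next_id = 4
    seg_mu, seg_sd = spec.segment_length
    ini = spec.initial_segment_length or spec.segment_length

    def seg_len(params):
        mu, sd = params
        return max(0.5, rng.normal(mu, sd))

    for label, n_trunks in spec.tree_spec():
        code = _LABEL_CODES.get(label, 5)
        for _ in range(n_trunks):
            # trunks differ in extent, as real dendrites do; this also keeps
            # path-length features informative across initial nodes
            depth_limit = int(rng.integers(
                max(2, int(0.55 * spec.max_depth)), spec.max_depth + 1
            ))
            direction = rng.normal(size=3)
            direction[2] *= 0.2  # damp z-drift
            direction = _unit(direction)
            if spec.initial_stem_soma_factor is not None:
                # larger cells put their first recorded node further out
                stem = max(0.5, spec.initial_stem_soma_factor * soma_d
                           + rng.normal(0.0, ini[1]))
            else:
                stem = seg_len(ini)
            pos = np.zeros(3) + direction * stem
            stack = [(1, pos, direction, 1)]  # parent id, position, dir, depth
            first = True
            while stack:
                pid, p, d, depth = stack.pop()
                nid = next_id
                next_id += 1
                nodes.append(
                    MorphNode(nid, code, float(p[0]), float(p[1]), float(p[2]),
                              0.5, pid)
                )
                if depth >= depth_limit:
                    first = False
                    continue
                n_children = 2 if (not first and rng.random() < spec.branch_prob) else 1
                first = False
                for _c in range(n_children):
                    dev = rng.normal(scale=0.35, size=3)
                    dev[2] *= 0.2
                    nd = _unit(d + dev)
                    stack.append((nid, p + nd * seg_len(spec.segment_length),
                                  nd, depth + 1))
    return nodes


def _rule_evaluate(rule, features: dict) -> float:
    if isinstance(rule, ModelSet):
        model = rule.lookup(NodeClass(features["node_class"]),
                            features["tree_label"])
        return model.evaluate(features)
    return float(rule(features))


def generate_morphology(spec: SynthSpec, name: str = "synthetic") -> Morphology:
    """Grow one morphology; reproducible byte-for-byte given the seed."""
    rng = np.random.default_rng(spec.seed)
    nodes = _grow_topology(spec, rng)
    skeleton = Morphology(nodes, metadata={"name": name, "archive": "synthetic"})
    feats = morphometry.compute_features(skeleton)
    rule = spec.diameter_rule if spec.diameter_rule is not None else default_taper_rule

    order = [n for n in skeleton.nodes if n.type_code != SOMA]
    soma_d = skeleton.soma_diameter
    chained: dict[int, float] = {}
    observed: dict[int, float] = {}
    n_nonpositive = 0
    for n in order:
        f = feats[n.node_id].as_dict()
        if f["node_class"] == NodeClass.INITIAL.value:
            f["PD"] = soma_d
        else:
            f["PD"] = chained[n.parent_id]
        d_clean = _rule_evaluate(rule, f)
        if d_clean <= 0:
            n_nonpositive += 1
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        d_obs = max(d_clean + noise, spec.min_diameter)
        observed[n.node_id] = d_obs
        chained[n.node_id] = d_obs if spec.noisy_chaining else max(
            d_clean, spec.min_diameter
        )
    if n_nonpositive > 0.5 * len(order):
        raise ValueError(
            f"diameter rule nonpositive on {n_nonpositive}/{len(order)} nodes "
            "before flooring; adjust the SynthSpec"
        )
    final = [
        replace(n, radius=observed[n.node_id] / 2.0) if n.node_id in observed else n
        for n in skeleton.nodes
    ]
    out = skeleton.with_nodes(final)
    out.metadata["seed"] = spec.seed
    out.metadata["ground_truth_rule"] = getattr(
        rule, "name", getattr(rule, "__name__", "callable")
    )
    return out


def generate_archive(spec: SynthSpec, n_cells: int) -> list[Morphology]:
    """Independent cells with per-cell sub-seeds derived from the master seed."""
    if n_cells < 2:
        raise ValueError("an archive needs at least 2 cells")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(n_cells)
    out = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cell_spec = replace(spec, seed=sub_seed)
        out.append(generate_morphology(cell_spec, name=f"synthetic_{i:03d}"))
    return out


def generate_feature_table(
    coefficients: dict[str, float],
    n: int,
    seed: int,
    noise_sd: float = 0.05,
    node_class: NodeClass = NodeClass.CONTINUING,
    tree_label: str = "generic",
) -> pd.DataFrame:
    """Random per-node feature rows with D built from a known linear rule.

    Features are drawn independently on realistic scales (diameters of a few
    um, path lengths of tens to hundreds of um), so features absent from
    ``coefficients`` are pure noise with respect to D.  Used by the feature-
    selection recovery harness.
    """
    rng = np.random.default_rng(seed)
    feats = {
        "PD": rng.uniform(0.5, 3.0, n),
        "IB": rng.integers(1, 9, n).astype(float),
        "TD": rng.integers(1, 30, n).astype(float),
        "PS": rng.uniform(5.0, 300.0, n),
        "LP": rng.uniform(0.0, 400.0, n),
        "TL": rng.uniform(10.0, 2000.0, n),
    }
    d = rng.normal(0.0, noise_sd, n)
    for f, c in coefficients.items():
        d = d + c * feats[f]
    df = pd.DataFrame(feats)
    df["D"] = d
    df["node_class"] = NodeClass(node_class).value
    df["tree_label"] = tree_label
    df["morphology"] = "synthetic_table"
    df["archive"] = "synthetic"
    df["node_id"] = np.arange(1, n + 1)
    df["is_terminal"] = False
    df["is_branch_point"] = False
    return df[morphometry.TABLE_COLUMNS]


def spec_for_model_set(name: str, seed: int) -> SynthSpec:
    """Growth parameters under which each packaged equation set yields
    positive, realistic diameters (used by the parameter-recovery harness).

    Hippocampal basal initial stems must sit far enough from the soma for
    the published initial-node equation (negative PD coefficient) to stay
    positive, hence the long initial segments and cell-to-cell soma-size
    variation (which also makes the two-feature initial designs
    identifiable).
    """
    key = name
    base = SynthSpec(seed=seed)
    if key == "hippocampal":
        return replace(
            base,
            trees=(("apical", 3), ("basal", 4)),
            soma_diameter=(13.0, 2.5),
            initial_segment_length=(34.0, 2.0),
            initial_stem_soma_factor=2.6,
            branch_prob=0.12,
            max_depth=45,
        )
    if key == "cerebellar":
        return replace(
            base,
            tree_label="generic",
            n_initial=2,
            soma_diameter=(14.0, 1.5),
            branch_prob=0.25,
            max_depth=30,
        )
    if key in ("striatal", "striatal-lai", "striatal-luebke"):
        return replace(
            base,
            tree_label="generic",
            n_initial=5,
            soma_diameter=(11.0, 1.0),
            branch_prob=0.12,
            max_depth=45,
        )
    raise KeyError(f"no synthetic growth profile for model set {name!r}")
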