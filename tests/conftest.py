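import warnings
from dataclasses import replace

import pytest

import dendrodiam as dd
from dendrodiam import synthetic
from dendrodiam.swc import MorphNode, Morphology

TOY5_SWC = """\
# toy fixture: soma + straight trunk + one bifurcation
1 1 0 0 0 5.0 -1
2 3 10 0 0 1.0 1
3 3 20 0 0 0.9 2
4 3 20 5 0 0.5 3
5 3 20 -5 0 0.5 3
"""


@pytest.fixture
def toy5():
    """soma(0,0,0) -> a(10,0,0) -> b(20,0,0) -> {c(20,5,0), d(20,-5,0)}."""
    return Morphology([
        MorphNode(1, 1, 0, 0, 0, 5.0, -1),
        MorphNode(2, 3, 10, 0, 0, 1.0, 1),
        MorphNode(3, 3, 20, 0, 0, 0.9, 2),
        MorphNode(4, 3, 20, 5, 0, 0.5, 3),
        MorphNode(5, 3, 20, -5, 0, 0.5, 3),
    ])


@pytest.fixture
def toy5_file(tmp_path):
    p = tmp_path / "toy5.swc"
    p.write_text(TOY5_SWC)
    return p


@pytest.fixture
def chain():
    """soma -> a -> b -> c straight chain."""
    return Morphology([
        MorphNode(1, 1, 0, 0, 0, 4.0, -1),
        MorphNode(2, 3, 5, 0, 0, 1.0, 1),
        MorphNode(3, 3, 10, 0, 0, 0.9, 2),
        MorphNode(4, 3, 15, 0, 0, 0.8, 3),
    ])


@pytest.fixture(scope="session")
def small_trees():
    """100 small random trees (<=100 nodes) for brute-force invariant checks."""
    spec = synthetic.SynthSpec(seed=0, n_initial=2, branch_prob=0.3, max_depth=7)
    return [
        synthetic.generate_morphology(replace(spec, seed=k + 1))
        for k in range(100)
    ]


@pytest.fixture(scope="session")
def striatal_archive():
    """Synthetic archive grown with the packaged pooled-striatal equations."""
    ms = dd.load_packaged_model_set("striatal")
    spec = replace(synthetic.spec_for_model_set("striatal", 11), diameter_rule=ms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.generate_archive(spec, 6)
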