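import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def fixture_dir(tmp_path):
    """Build a synthetic genome + signal + group file; returns a path dict."""
    from vapro import read_annotations
    from vapro.synthetic_fixtures import FixtureSpec, make_annotations, make_signal

    def build(spec: "FixtureSpec", sub="fx"):
        d = tmp_path / sub
        ann_path, truth = make_annotations(spec, d)
        annotations = read_annotations(ann_path)
        bg, wig = make_signal(spec, annotations, d)
        group = d / "group.txt"
        group.write_text("\n".join(truth["name"]) + "\n")
        return {"dir": d, "annotations_path": ann_path, "annotations": annotations,
                "truth": truth, "bedgraph": bg, "wig": wig, "group": group}

    return build


@pytest.fixture
def uniform_fixture(fixture_dir):
    from vapro.synthetic_fixtures import FixtureSpec
    return fixture_dir(FixtureSpec(seed=11, n_genes=6, pattern=("uniform", 2.0)))
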