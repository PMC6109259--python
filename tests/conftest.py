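import pytest

from genotiles.coords import Assembly
from genotiles.fixtures import FixtureSpec, make_demo


@pytest.fixture
def toy_assembly() -> Assembly:
    return Assembly([("chr1", 1000), ("chr2", 2000)])


@pytest.fixture(scope="session")
def demo_spec() -> FixtureSpec:
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def demo_paths(tmp_path_factory, demo_spec):
    """The demo-genome fixture files, generated once per session."""
    out = tmp_path_factory.mktemp("demo")
    return make_demo(out, seed=demo_spec.seed)


@pytest.fixture(scope="session")
def demo_assembly(demo_paths) -> Assembly:
    return Assembly.from_chromsizes(demo_paths["chromsizes"])
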