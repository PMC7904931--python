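import pytest

from lipospec.io_formats import (
    Compound,
    LipidSystem,
    Probe,
    SampleMeta,
)
from lipospec.synthetic import StudyDesign, generate_study


@pytest.fixture
def meta_popc_control():
    return SampleMeta(
        sample_id="s1",
        lipid_system=LipidSystem.POPC,
        compound=Compound.CONTROL,
        replicate=1,
        probe=Probe.DI8ANEPPS,
        compound_conc_uM=0.0,
    )


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """Full default study (both steady-state arms; TCSPC arm skipped for speed)."""
    out = tmp_path_factory.mktemp("study")
    design = StudyDesign(include_decays=False)
    manifest, truth = generate_study(design, seed=20250925, out_dir=out)
    return manifest, truth
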