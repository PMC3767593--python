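import pytest
from hypothesis import settings

import xistkit as xk

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def desk_bundle():
    return xk.build_scaffold(xk.desk_spec(), seed=1)


@pytest.fixture(scope="session")
def porcine_bundle():
    return xk.build_scaffold(xk.porcine_scale_spec(), seed=1)


@pytest.fixture(scope="session")
def desk_window(desk_bundle):
    """Promoter +/-2 kb window sequence and the 1-based TSS position in it."""
    return desk_bundle.truth.promoter_window_seq()


def mini_spec(**overrides):
    """A tiny multi-exon gene for fast parameter-recovery loops."""
    base = dict(
        exon_lengths=(300, 60, 80, 70, 90, 60, 120),
        intron_lengths=(40, 55, 30, 24, 35, 48),
        flank_lengths=(260, 160),
        cpg_window=200,
        promoter_cpg_offsets=(),
        motif_plants=(),
        gap=None,
    )
    base.update(overrides)
    return xk.GeneSpec(**base)


@pytest.fixture(scope="session")
def mini_spec_factory():
    return mini_spec
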