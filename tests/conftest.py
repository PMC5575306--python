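import pytest

from medipdiff import build_annotation, simulate_study


@pytest.fixture(scope="session")
def scene():
    """Default desk-scale study scene (2 x 1 Mb, 6 pairs, 100 planted DMRs)."""
    return simulate_study(1)


@pytest.fixture(scope="session")
def small_scene():
    """Cheap single-chromosome scene for pipeline/IO smoke tests."""
    return simulate_study(7, n_chrom=1, chrom_len=300_000, n_dmr=20, n_genes=40)


@pytest.fixture(scope="session")
def scene_annotation(scene):
    return build_annotation(scene.assembly, scene.genes, classify=False)
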