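import numpy as np
import pytest

from bsamap import capsmarker, synthio


@pytest.fixture(scope="session")
def sspi() -> capsmarker.Enzyme:
    return capsmarker.get_enzyme("SspI")


@pytest.fixture(scope="session")
def amplicons() -> tuple[str, str]:
    """Reconstructed 391-bp D/R allele amplicons."""
    return synthio.caps_amplicons()


@pytest.fixture(scope="session")
def sspi_assay(amplicons, sspi) -> capsmarker.CapsAssay:
    assays = capsmarker.design_caps(amplicons[0], amplicons[1], [sspi])
    assert len(assays) == 1
    return assays[0]


@pytest.fixture(scope="session")
def small_f2():
    """A small seeded F2 cross with a causal locus at 0.7 Mb of a 1 Mb chromosome."""
    rng = np.random.default_rng(42)
    snps = np.sort(rng.choice(np.arange(1, 1_000_001), 200, replace=False)).tolist()
    cfg = synthio.F2SimConfig(
        chrom_name="chr6", chrom_length_bp=1_000_000, n_individuals=400,
        snp_positions=snps, causal_pos_bp=700_000, seed=7)
    return cfg, synthio.simulate_f2(cfg)
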