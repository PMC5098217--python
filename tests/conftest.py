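import numpy as np
import pytest

import exodel as x

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def roundtrip_config(seed: int, total_length: int = 7500) -> "x.PipelineConfig":
    """Study conditions for the exact round-trip experiment: synthetic SSR
    fragment (variant rate 1%), error-free 500 bp reads, noise-free gel."""
    cfg = x.PipelineConfig(seed=seed, truth_kind="ssr",
                           output_dir="scratch/roundtrip")
    cfg.ssr.total_length = total_length
    cfg.ssr.variant_rate = 0.01
    cfg.selection.size_noise_sd_bp = 0.0
    cfg.reads.fixed_length = 500
    cfg.reads.error_rate = 0.0
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20161107)


@pytest.fixture(scope="session")
def ssr_fragment():
    """A paper-scale SSR fragment with truth annotation."""
    return x.generate_ssr_fragment(x.default_ssr_spec(seed=42))


@pytest.fixture(scope="session")
def small_construct():
    """A 2 kb construct for fast deletion-lab tests."""
    spec = x.SSRFragmentSpec(total_length=2000,
                             blocks=(("AAG", 250), ("AGT", 250)),
                             variant_rate=0.01, flank_lengths=(250, 250),
                             seed=7)
    frag = x.generate_ssr_fragment(spec)
    return x.Construct.from_insert(frag, seed=7)
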