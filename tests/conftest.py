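import numpy as np
import pytest

import seqtag as st


@pytest.fixture(scope="session")
def inventory():
    return st.auditory_inventory()


@pytest.fixture(scope="session")
def visual_inv():
    return st.visual_inventory()


@pytest.fixture(scope="session")
def structured_stream(inventory):
    """One structured block of 540 syllables."""
    return st.generate_structured_stream(inventory, n_blocks=1, block_tokens=540, seed=7)


@pytest.fixture(scope="session")
def long_structured_stream(inventory):
    """Five structured blocks, the full-exposure design."""
    return st.generate_structured_stream(inventory, n_blocks=5, block_tokens=540, seed=7)


@pytest.fixture(scope="session")
def probed_stream(structured_stream):
    return st.embed_one_back_probes(structured_stream, n_per_block=16, seed=11)


@pytest.fixture(scope="session")
def entrained_recording(long_structured_stream):
    """Five-block recording with one channel per ground-truth class."""
    spec = [
        st.ChannelSpec(id="upt", ground_truth_class="unit_plus_token"),
        st.ChannelSpec(id="uo", ground_truth_class="unit_only"),
        st.ChannelSpec(id="tok", ground_truth_class="token_only"),
        st.ChannelSpec(id="nz"),
    ]
    return st.synthesize_recording(long_structured_stream, spec, seed=13)


@pytest.fixture(scope="session")
def entrained_trials(entrained_recording, long_structured_stream):
    return st.segment_trials(entrained_recording, long_structured_stream)


def _make_pattern_recording(stream, scheme, n_channels=12, seed=0, amp=0.5):
    ids = [f"c{i}" for i in range(n_channels)]
    spec = [st.ChannelSpec(id=i, ground_truth_scheme=scheme) for i in ids]
    rec = st.synthesize_recording(
        stream, spec, params=st.EffectParams(pattern_amp=amp), seed=seed
    )
    return rec, ids


@pytest.fixture(scope="session")
def make_pattern_recording():
    """Factory for recordings whose patterns encode a given coding scheme."""
    return _make_pattern_recording
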