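import numpy as np
import pytest

from dshmm import TrackMeta, three_state_demo_model
from dshmm.simulate import scenario_tracks


@pytest.fixture
def tracks():
    """One undirected occupancy track plus one expression pair."""
    return scenario_tracks()


@pytest.fixture
def nuc_tracks():
    """Track set including a nucleosome track with the transcribed-dominates rule."""
    return (
        TrackMeta("tfiib", "undirected"),
        TrackMeta("nucleosome", "undirected", dominance_rule="transcribed_dominates"),
        TrackMeta("expr_fwd", "forward_specific", partner="expr_rev"),
        TrackMeta("expr_rev", "reverse_specific", partner="expr_fwd"),
    )


@pytest.fixture
def demo_model():
    """Known well-separated 3-state model with its track metadata."""
    return three_state_demo_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
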