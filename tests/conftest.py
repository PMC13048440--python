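import numpy as np
import pandas as pd
import pytest

from qualagree.coding_data import (
    Codebook,
    CodingMatrix,
    Segment,
    SpeakerRole,
)


def matrix_from_array(values, coder_id="coder", seg_ids=None, code_ids=None):
    """Build a CodingMatrix from a 0/1 array (segments x codes)."""
    values = np.asarray(values, dtype=bool)
    if values.ndim == 1:
        values = values[:, None]
    n_seg, n_codes = values.shape
    seg_ids = seg_ids or [f"T{i + 1:03d}" for i in range(n_seg)]
    code_ids = code_ids or [f"C{j + 1:02d}" for j in range(n_codes)]
    return CodingMatrix(
        coder_id=coder_id, values=pd.DataFrame(values, index=seg_ids, columns=code_ids)
    )


@pytest.fixture
def mini_transcript():
    """Tiny focus-group transcript with facilitator and participant turns,
    including two segments quoted in the study narrative."""
    return [
        Segment(
            id="T001",
            speaker_role=SpeakerRole.facilitator,
            text="Welcome everyone, today we will discuss the proposal in detail.",
        ),
        Segment(
            id="T002",
            speaker_role=SpeakerRole.participant,
            text=(
                "you can often read things and then you do a little bit of research "
                "around it and you find that actually the truth is perhaps even the opposite"
            ),
        ),
        Segment(
            id="T037",
            speaker_role=SpeakerRole.participant,
            text=(
                "We as individuals monitor how we respond. I mean, there are at "
                "least three of us in this room"
            ),
        ),
        Segment(
            id="T040",
            speaker_role=SpeakerRole.participant,
            text=(
                "The community aspect of it, about people being able to connect with "
                "people locally, maybe with the same condition or maybe just with the "
                "same exercise routines."
            ),
        ),
    ]


@pytest.fixture
def small_codebook():
    return Codebook.from_ids(["C01", "C02", "C03"])
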