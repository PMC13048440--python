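"""Bundled focus-group evaluation dataset.

The package ships the published in-text data of the focus-group evaluation
study it operationalizes, so the inductive comparison and the quote audit can
be recomputed end to end without external files:

* the inductive agreement table — 14 adjudicated codes scored 1-5 against the
  reference-standard panel analysis by two blinded human analysts and three
  automated coders (ChatGPT-5, Claude 4 Sonnet, QualiGPT);
* the quote-verification count block — per-model audited counts of exact,
  partial, no-match and researcher-segment quotes.

The deductive coding matrices themselves were deposited as supplementary
spreadsheets and are not bundled; deductive behaviour is exercised against
the study's reported design (124 segments x 10 codes, mean code prevalence
7.8% with SD 3.2%) via the synthetic generators, whose defaults encode those
conditions.
"""

from __future__ import annotations

import pandas as pd

from qualagree.audit import ModelAuditCounts
from qualagree.coding_data import LikertTable

HUMAN_ANALYSTS = ["Human Analyst 1", "Human Analyst 2"]
MODELS = ["ChatGPT-5", "Claude 4 Sonnet", "QualiGPT"]

INDUCTIVE_CODES = [
    "Desire for personalisation",
    "Truth and misinformation",
    "Harm from generic advice",
    "Need for flexibility and adaption",
    "NHS lack of personalisation",
    "Difficulty accessing healthcare",
    "Care continuity/fragmentation",
    "Desire for personalisation in AI interactions",
    "Need for human and social interaction",
    "Opinions of communities and peer support",
    "Feedback on AI development",
    "Scepticism surrounding security",
    "Scepticism of medical experts",
    "Peer support",
]

# columns: Human Analyst 1, Human Analyst 2, ChatGPT-5, Claude 4 Sonnet, QualiGPT
_INDUCTIVE_SCORES = [
    [4, 5, 4, 3, 3],
    [4, 5, 4, 4, 4],
    [5, 4, 4, 4, 1],
    [3, 3, 5, 5, 5],
    [2, 4, 4, 3, 5],
    [4, 5, 5, 5, 5],
    [5, 3, 5, 1, 4],
    [3, 4, 4, 3, 3],
    [4, 4, 2, 4, 5],
    [3, 4, 4, 5, 3],
    [3, 4, 3, 3, 5],
    [4, 5, 4, 5, 5],
    [4, 2, 5, 2, 4],
    [3, 5, 4, 4, 3],
]

# per-model audited quote counts: (exact, partial, no_match, researcher_segment)
_AUDIT_COUNTS = {
    "ChatGPT-5": (31, 2, 0, 1),
    "QualiGPT": (45, 3, 2, 5),
    "Claude 4 Sonnet": (71, 0, 0, 8),
}

# deductive design constants of the study
DEDUCTIVE_N_SEGMENTS = 124
DEDUCTIVE_N_CODES = 10
PREVALENCE_MEAN = 0.078
PREVALENCE_SD = 0.032


def inductive_likert_table() -> LikertTable:
    """The study's 14-code x 5-analyst inductive agreement table."""
    df = pd.DataFrame(
        _INDUCTIVE_SCORES, index=INDUCTIVE_CODES, columns=HUMAN_ANALYSTS + MODELS
    )
    return LikertTable(scores=df)


def audit_counts() -> list[ModelAuditCounts]:
    """The study's audited per-model quote-verification counts."""
    return [
        ModelAuditCounts(
            model_id=m, exact=e, partial=p, no_match=nm, researcher_segment=rs
        )
        for m, (e, p, nm, rs) in _AUDIT_COUNTS.items()
    ]
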