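"""Quote-verification audit: check model-emitted evidence quotes against the
transcript, classify each into a four-class taxonomy, and compute error rates.

Classes (mutually exclusive, exhaustive):

* ``exact`` — the normalized quote is a verbatim substring of the claimed
  segment (or, with no segment claimed, of some participant segment);
* ``partial`` — not verbatim, but the similarity to the best segment reaches
  the policy threshold (borderline evidence);
* ``no_match`` — the quoted text appears nowhere: fabricated evidence
  ("strict hallucination");
* ``researcher_segment`` — the matched or claimed segment is facilitator
  speech, which must never be coded; this instruction violation takes
  precedence over the text-match classes, so a verbatim facilitator quote is
  still a violation.

Similarity is the normalized longest-common-substring ratio: the length of
the longest common substring of the normalized quote and segment text,
divided by the length of the shorter of the two. An exact substring therefore
scores 1. Normalization case-folds, collapses whitespace, maps typographic
quotes/dashes to ASCII and strips terminal punctuation. The published audit
this reproduces was human judgement; the ``manual_override`` field on a
record replays such a judgement verbatim and always wins.

Per-model rates (as percentages of total quotes emitted):

* strict hallucination rate = no_match / total
* expanded hallucination rate = (no_match + researcher_segment) / total
* comprehensive error rate = (no_match + researcher_segment + partial) / total
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterable, Sequence

import numpy as np

from qualagree.coding_data import MatchClass, QuoteRecord, Segment, SpeakerRole

logger = logging.getLogger(__name__)

_QUOTE_MAP = str.maketrans(
    {
        "‘": "'",
        "’": "'",
        "“": '"',
        "”": '"',
        "–": "-",
        "—": "-",
        "…": "...",
        " ": " ",
    }
)


def normalize_text(text: str) -> str:
    """Case-fold, map typographic punctuation to ASCII, collapse whitespace
    runs, and strip terminal punctuation."""
    t = unicodedata.normalize("NFC", text).translate(_QUOTE_MAP).casefold()
    t = re.sub(r"\s+", " ", t).strip()
    return t.strip(".,;:!?\"' ")


def quote_similarity(quote: str, text: str) -> float:
    """Normalized longest-common-substring ratio relative to the shorter
    string; 1.0 iff one normalized string contains the other."""
    a, b = normalize_text(quote), normalize_text(text)
    if not a or not b:
        return 0.0
    short = min(len(a), len(b))
    match = SequenceMatcher(None, a, b, autojunk=False).find_longest_match(
        0, len(a), 0, len(b)
    )
    return match.size / short


@dataclass
class MatchPolicy:
    """Reproducible default matching criterion for the audit taxonomy."""

    partial_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.partial_threshold < 1:
            raise ValueError("partial_threshold must lie in (0, 1)")


def classify_quote(
    record: QuoteRecord,
    transcript: Sequence[Segment],
    policy: MatchPolicy | None = None,
) -> MatchClass:
    """Assign one of the four audit classes to a quote record.

    A claimed segment id anchors the comparison; an unknown claimed id is
    logged and classed no_match (not an exception). With no claimed id the
    quote is matched against the whole transcript and the best-matching
    segment's role decides the researcher_segment precedence.
    """
    policy = policy or MatchPolicy()
    if record.manual_override is not None:
        return record.manual_override

    by_id = {s.id: s for s in transcript}
    quote_norm = normalize_text(record.quote)

    if record.segment_id is not None:
        seg = by_id.get(record.segment_id)
        if seg is None:
            logger.warning(
                "quote record claims unknown segment %r; classed as no_match",
                record.segment_id,
            )
            return MatchClass.no_match
        if seg.speaker_role is SpeakerRole.facilitator:
            return MatchClass.researcher_segment
        return _text_class(quote_norm, seg, policy)

    if not quote_norm or not transcript:
        return MatchClass.no_match
    best_seg, best_sim = None, -1.0
    for seg in transcript:
        sim = quote_similarity(record.quote, seg.text)
        if sim > best_sim:
            best_seg, best_sim = seg, sim
    if best_sim >= policy.partial_threshold and best_seg is not None:
        if best_seg.speaker_role is SpeakerRole.facilitator:
            return MatchClass.researcher_segment
        return _text_class(quote_norm, best_seg, policy)
    return MatchClass.no_match


def _text_class(quote_norm: str, seg: Segment, policy: MatchPolicy) -> MatchClass:
    if not quote_norm:
        return MatchClass.no_match
    text_norm = normalize_text(seg.text)
    if quote_norm in text_norm:
        return MatchClass.exact
    if quote_similarity(quote_norm, text_norm) >= policy.partial_threshold:
        return MatchClass.partial
    return MatchClass.no_match


def classify_records(
    records: Iterable[QuoteRecord],
    transcript: Sequence[Segment],
    policy: MatchPolicy | None = None,
) -> list[QuoteRecord]:
    """Classify every record in place (returns the same list for chaining)."""
    records = list(records)
    for r in records:
        r.match_class = classify_quote(r, transcript, policy)
    return records


# ---------------------------------------------------------------------------
# Error rates
# ---------------------------------------------------------------------------

@dataclass
class ModelAuditCounts:
    """One model's audited quote counts and derived error rates (percent)."""

    model_id: str
    exact: int
    partial: int
    no_match: int
    researcher_segment: int

    @property
    def total(self) -> int:
        return self.exact + self.partial + self.no_match + self.researcher_segment

    def _pct(self, count: int) -> float:
        if self.total == 0:
            raise ValueError(f"model {self.model_id!r}: no quote records, rates undefined")
        return 100.0 * count / self.total

    @property
    def strict_rate(self) -> float:
        return self._pct(self.no_match)

    @property
    def expanded_rate(self) -> float:
        return self._pct(self.no_match + self.researcher_segment)

    @property
    def comprehensive_rate(self) -> float:
        return self._pct(self.no_match + self.researcher_segment + self.partial)


def error_rates(records: Sequence[QuoteRecord]) -> ModelAuditCounts:
    """Tally one model's classified records into counts and rates."""
    if not records:
        raise ValueError("no quote records to audit")
    model_ids = {r.model_id for r in records}
    if len(model_ids) != 1:
        raise ValueError(f"records mix models: {sorted(model_ids)}")
    unclassified = [r for r in records if r.match_class is None]
    if unclassified:
        raise ValueError(f"{len(unclassified)} records are not yet classified")
    tally = {cls: 0 for cls in MatchClass}
    for r in records:
        tally[r.match_class] += 1
    return ModelAuditCounts(
        model_id=model_ids.pop(),
        exact=tally[MatchClass.exact],
        partial=tally[MatchClass.partial],
        no_match=tally[MatchClass.no_match],
        researcher_segment=tally[MatchClass.researcher_segment],
    )


@dataclass
class ErrorRateSummary:
    """Across-model summary: unweighted mean and sample SD (n-1) of the
    per-model count block and of the per-model rate percentages."""

    per_model: list[ModelAuditCounts]
    count_mean: dict[str, float] = field(default_factory=dict)
    count_sd: dict[str, float] = field(default_factory=dict)
    rate_mean: dict[str, float] = field(default_factory=dict)
    rate_sd: dict[str, float] = field(default_factory=dict)


def summarize_across_models(per_model: Sequence[ModelAuditCounts]) -> ErrorRateSummary:
    """Mean/SD of counts and of error-rate percentages across models.

    With a single model the means are reported and the SDs are NaN."""
    if not per_model:
        raise ValueError("no models to summarize")
    summary = ErrorRateSummary(per_model=list(per_model))
    count_fields = ["exact", "partial", "no_match", "researcher_segment", "total"]
    rate_fields = ["strict_rate", "expanded_rate", "comprehensive_rate"]
    for name in count_fields:
        vals = np.array([float(getattr(m, name)) for m in per_model])
        summary.count_mean[name] = float(vals.mean())
        summary.count_sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    for name in rate_fields:
        vals = np.array([getattr(m, name) for m in per_model])
        summary.rate_mean[name] = float(vals.mean())
        summary.rate_sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return summary
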