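"""Data model and readers/writers for transcripts, codebooks, coding matrices,
Likert tables, and quote-verification records.

All interchange formats are plain text: JSON for transcripts, coding matrices
and quote records; CSV (or JSON) for Likert tables. Text is UTF-8 throughout;
quotes may contain typographic apostrophes and dashes, which are normalized
only inside the audit module, never at read time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class CodingDataError(ValueError):
    """Format or validation error in a coding-data file or structure."""


class SpeakerRole(str, Enum):
    participant = "participant"
    facilitator = "facilitator"


class MatchClass(str, Enum):
    """Audit taxonomy for a model-emitted evidence quote.

    ``researcher_segment`` (the model coded facilitator speech, an
    instruction violation) takes precedence over the text-match classes.
    """

    exact = "exact"
    partial = "partial"
    no_match = "no_match"
    researcher_segment = "researcher_segment"


@dataclass(frozen=True)
class Segment:
    """One speaker turn of a transcript."""

    id: str
    speaker_role: SpeakerRole
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise CodingDataError("segment id must be non-empty")
        if not isinstance(self.speaker_role, SpeakerRole):
            object.__setattr__(self, "speaker_role", SpeakerRole(self.speaker_role))
        if not self.text:
            raise CodingDataError(f"segment {self.id!r}: text must be non-empty")


@dataclass(frozen=True)
class Code:
    id: str
    label: str = ""
    definition: str = ""
    theme: str = ""


@dataclass
class Codebook:
    """Ordered list of codes, each belonging to exactly one theme."""

    codes: list[Code]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.codes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CodingDataError(f"duplicate code ids: {dupes}")

    @property
    def code_ids(self) -> list[str]:
        return [c.id for c in self.codes]

    @property
    def themes(self) -> list[str]:
        seen: list[str] = []
        for c in self.codes:
            if c.theme not in seen:
                seen.append(c.theme)
        return seen

    @classmethod
    def from_ids(cls, code_ids: Sequence[str]) -> "Codebook":
        return cls([Code(id=c, label=c, theme=c) for c in code_ids])


@dataclass
class CodingMatrix:
    """One coder's binary labels over participant segments x codes.

    ``values`` is a complete boolean rectangle: index = segment ids (ordered),
    columns = code ids (ordered). The study-sized instance is 124 x 10 = 1240
    cells.
    """

    coder_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise CodingDataError("duplicate segment or code ids in coding matrix")
        if self.values.isna().any().any():
            raise CodingDataError("coding matrix has missing cells")
        self.values = self.values.astype(bool)

    @property
    def segment_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def code_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return int(self.values.size)

    def same_universe(self, other: "CodingMatrix") -> bool:
        return (
            self.segment_ids == other.segment_ids
            and self.code_ids == other.code_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodingMatrix):
            return NotImplemented
        return self.same_universe(other) and bool(
            (self.values.values == other.values.values).all()
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-code (or pooled) 2x2 table of a coder against the reference.

    The reference standard is the truth axis: tp counts cells coded true by
    both, fn cells true in the reference but missed by the coder.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise CodingDataError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class LikertTable:
    """code x analyst integer agreement scores on a 1-5 scale."""

    scores: pd.DataFrame  # index = code labels, columns = analyst ids

    def __post_init__(self) -> None:
        df = self.scores
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise CodingDataError("duplicate code labels or analyst ids")
        if df.isna().any().any():
            raise CodingDataError("Likert table has missing cells (ragged input?)")
        as_int = df.astype(int)
        if not (as_int == df.astype(float)).all().all():
            raise CodingDataError("Likert scores must be integers")
        if ((as_int < 1) | (as_int > 5)).any().any():
            bad = as_int[(as_int < 1) | (as_int > 5)].stack().index[0]
            raise CodingDataError(f"Likert score out of 1..5 range at {tuple(bad)}")
        self.scores = as_int

    @property
    def code_labels(self) -> list[str]:
        return list(self.scores.index)

    @property
    def analyst_ids(self) -> list[str]:
        return list(self.scores.columns)

    def column(self, analyst_id: str) -> list[int]:
        return [int(v) for v in self.scores[analyst_id]]


@dataclass
class QuoteRecord:
    """One model-emitted (segment, quote, code) evidence claim.

    ``match_class`` is assigned by the audit; ``manual_override``, when set,
    replays a human audit decision verbatim (the class taxonomy was defined by
    manual review; the automatic matcher is the reproducible default).
    ``truth_class`` carries the generating class on synthetic records only.
    """

    model_id: str
    quote: str
    code_id: str
    segment_id: str | None = None
    match_class: MatchClass | None = None
    manual_override: MatchClass | None = None
    truth_class: MatchClass | None = None


# ---------------------------------------------------------------------------
# Transcript IO
# ---------------------------------------------------------------------------

def read_transcript(path: str | Path) -> list[Segment]:
    """Read a JSON transcript: an array of {"id", "speaker_role", "text"}.

    Facilitator segments are retained (the quote audit needs them) but carry
    their role so deductive readers can exclude them.
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, list):
        raise CodingDataError("transcript file must contain a JSON array")
    segments: list[Segment] = []
    seen: set[str] = set()
    for rec in raw:
        for key in ("id", "speaker_role", "text"):
            if key not in rec:
                raise CodingDataError(f"transcript record missing field {key!r}: {rec}")
        if rec["id"] in seen:
            raise CodingDataError(f"duplicate segment id {rec['id']!r}")
        seen.add(rec["id"])
        try:
            role = SpeakerRole(rec["speaker_role"])
        except ValueError:
            raise CodingDataError(
                f"segment {rec['id']!r}: unknown speaker role {rec['speaker_role']!r}"
            ) from None
        segments.append(Segment(id=rec["id"], speaker_role=role, text=rec["text"]))
    return segments


def write_transcript(segments: Iterable[Segment], path: str | Path) -> None:
    recs = [
        {"id": s.id, "speaker_role": s.speaker_role.value, "text": s.text}
        for s in segments
    ]
    Path(path).write_text(json.dumps(recs, indent=1, ensure_ascii=False), encoding="utf-8")


def participant_segments(segments: Iterable[Segment]) -> list[Segment]:
    return [s for s in segments if s.speaker_role is SpeakerRole.participant]


# ---------------------------------------------------------------------------
# Coding matrix IO
# ---------------------------------------------------------------------------

def read_coding_matrix(
    path: str | Path,
    codebook: Codebook,
    segments: Sequence[Segment],
) -> CodingMatrix:
    """Read a coder's label file into a complete boolean rectangle.

    Dense dialect: {"coder_id", "codes", "segments", "labels": {seg: {code: bool}}}.
    Sparse dialect sets "mode": "sparse" and lists only the true cells as
    "true_cells": [[seg, code], ...] over the declared universe; everything
    else defaults to false. In dense mode a missing cell is an error.

    Labels on facilitator segments are rejected: researcher speech is not
    coded in the deductive task.
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    coder_id = raw.get("coder_id", Path(path).stem)
    declared_segs = list(raw["segments"])
    declared_codes = list(raw["codes"])

    roles = {s.id: s.speaker_role for s in segments}
    unknown_segs = [s for s in declared_segs if s not in roles]
    if unknown_segs:
        raise CodingDataError(f"coding file references unknown segments: {unknown_segs}")
    unknown_codes = [c for c in declared_codes if c not in codebook.code_ids]
    if unknown_codes:
        raise CodingDataError(f"coding file references unknown codes: {unknown_codes}")

    part_segs = [s for s in declared_segs if roles[s] is SpeakerRole.participant]

    mode = raw.get("mode", "dense")
    if mode == "sparse":
        df = pd.DataFrame(False, index=part_segs, columns=declared_codes)
        for seg, code in raw.get("true_cells", []):
            if seg not in roles:
                raise CodingDataError(f"label references unknown segment {seg!r}")
            if code not in declared_codes:
                raise CodingDataError(f"label references unknown code {code!r}")
            if roles[seg] is SpeakerRole.facilitator:
                raise CodingDataError(
                    f"segment {seg!r} is researcher/facilitator speech and must not be coded"
                )
            df.loc[seg, code] = True
    elif mode == "dense":
        labels: Mapping[str, Mapping[str, bool]] = raw["labels"]
        for seg, row in labels.items():
            if seg not in roles:
                raise CodingDataError(f"label references unknown segment {seg!r}")
            if roles[seg] is SpeakerRole.facilitator and any(row.values()):
                raise CodingDataError(
                    f"segment {seg!r} is researcher/facilitator speech and must not be coded"
                )
        df = pd.DataFrame(index=part_segs, columns=declared_codes, dtype=object)
        for seg in part_segs:
            if seg not in labels:
                raise CodingDataError(f"dense coding file missing segment {seg!r}")
            for code in declared_codes:
                if code not in labels[seg]:
                    raise CodingDataError(
                        f"dense coding file missing cell ({seg!r}, {code!r})"
                    )
                df.loc[seg, code] = bool(labels[seg][code])
    else:
        raise CodingDataError(f"unknown coding-file mode {mode!r}")

    return CodingMatrix(coder_id=coder_id, values=df)


def write_coding_matrix(
    matrix: CodingMatrix, path: str | Path, sparse: bool = False
) -> None:
    doc: dict = {
        "coder_id": matrix.coder_id,
        "codes": matrix.code_ids,
        "segments": matrix.segment_ids,
    }
    if sparse:
        doc["mode"] = "sparse"
        doc["true_cells"] = [
            [seg, code]
            for seg in matrix.segment_ids
            for code in matrix.code_ids
            if bool(matrix.values.loc[seg, code])
        ]
    else:
        doc["mode"] = "dense"
        doc["labels"] = {
            seg: {code: bool(matrix.values.loc[seg, code]) for code in matrix.code_ids}
            for seg in matrix.segment_ids
        }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Likert table IO
# ---------------------------------------------------------------------------

def read_likert_table(path: str | Path) -> LikertTable:
    """Read a code x analyst Likert table from CSV (first column = code label)
    or from JSON ({"codes", "analysts", "scores": row-major list of lists})."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text(encoding="utf-8"))
        rows = raw["scores"]
        widths = {len(r) for r in rows}
        if len(widths) > 1:
            raise CodingDataError("ragged rows in Likert JSON")
        df = pd.DataFrame(rows, index=raw["codes"], columns=raw["analysts"])
    else:
        try:
            df = pd.read_csv(path, index_col=0)
        except pd.errors.ParserError as exc:
            raise CodingDataError(f"malformed Likert CSV: {exc}") from exc
    return LikertTable(scores=df)


def write_likert_table(table: LikertTable, path: str | Path) -> None:
    table.scores.to_csv(Path(path), index_label="code")


# ---------------------------------------------------------------------------
# Quote record IO
# ---------------------------------------------------------------------------

def read_quote_records(path: str | Path) -> list[QuoteRecord]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    records = []
    for rec in raw:
        records.append(
            QuoteRecord(
                model_id=rec["model_id"],
                quote=rec["quote"],
                code_id=rec["code_id"],
                segment_id=rec.get("segment_id"),
                match_class=MatchClass(rec["match_class"]) if rec.get("match_class") else None,
                manual_override=(
                    MatchClass(rec["manual_override"]) if rec.get("manual_override") else None
                ),
            )
        )
    return records


def write_quote_records(records: Iterable[QuoteRecord], path: str | Path) -> None:
    raw = []
    for r in records:
        rec: dict = {"model_id": r.model_id, "quote": r.quote, "code_id": r.code_id}
        if r.segment_id is not None:
            rec["segment_id"] = r.segment_id
        if r.match_class is not None:
            rec["match_class"] = r.match_class.value
        if r.manual_override is not None:
            rec["manual_override"] = r.manual_override.value
        raw.append(rec)
    Path(path).write_text(json.dumps(raw, indent=1, ensure_ascii=False), encoding="utf-8")
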