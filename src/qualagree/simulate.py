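"""Synthetic-data generators for every input the evaluation pipeline consumes.

The deductive generator emulates the study conditions: a reference standard
of 124 participant segments x 10 binary codes whose per-code prevalences are
drawn from a clipped normal around mean 0.078 (SD 0.032), and coders defined
by a (sensitivity, specificity) operating point against that reference —
defaults (0.34, 0.97) for human analysts and (0.30, 0.98) for models, the
group operating points of the deductive comparison. Cells are independent
across segments and codes; no co-occurrence structure is imposed.

The Likert generator produces code x analyst integer scores 1-5 as
round-and-clamp of (per-code base mean + analyst shift + normal noise).

The transcript generator builds pseudo-word segments with facilitator and
participant roles and emits quote records realizing a prescribed mixture of
audit classes (verbatim substrings, truncated-and-corrupted substrings,
fabricated text, verbatim facilitator quotes), storing the generating class
on each record as hidden truth for closed-loop testing.

Population-level (infinite-n) pooled metrics for a given prevalence vector
and operating point are available in closed form via ``population_metrics``;
``solve_sensitivity_for_ac1`` inverts AC1 in the sensitivity argument, which
is how boundary-case simulations (true effect exactly at the margin) are
constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from qualagree.coding_data import (
    CodingMatrix,
    LikertTable,
    MatchClass,
    QuoteRecord,
    Segment,
    SpeakerRole,
)

#: Deductive study conditions: coder group operating points vs the reference.
HUMAN_OPERATING_POINT = (0.34, 0.97)
MODEL_OPERATING_POINT = (0.30, 0.98)


@dataclass
class DeductiveSimSpec:
    """Study-shaped deductive simulation: 124 segments x 10 codes, prevalence
    ~N(0.078, 0.032) clipped to (0.005, 0.5) and frozen at construction."""

    n_segments: int = 124
    n_codes: int = 10
    seed: int = 0
    prevalence_mean: float = 0.078
    prevalence_sd: float = 0.032
    prevalence: np.ndarray | None = None
    human_profile: tuple[float, float] = HUMAN_OPERATING_POINT
    model_profile: tuple[float, float] = MODEL_OPERATING_POINT

    def __post_init__(self) -> None:
        if self.n_segments * self.n_codes < 30:
            raise ValueError("need at least 30 cells for stable metrics")
        if self.prevalence is None:
            # separate stream from the cell draws so the frozen prevalence
            # vector and the reference cells are independent under one seed
            rng = np.random.default_rng([self.seed, 0])
            p = rng.normal(self.prevalence_mean, self.prevalence_sd, self.n_codes)
            self.prevalence = np.clip(p, 0.005, 0.5)
        else:
            self.prevalence = np.asarray(self.prevalence, dtype=float)
            if self.prevalence.size != self.n_codes:
                raise ValueError("prevalence vector length must equal n_codes")
            if ((self.prevalence < 0) | (self.prevalence > 1)).any():
                raise ValueError("prevalences must lie in [0, 1]")


def _matrix(values: np.ndarray, coder_id: str, n_seg: int, n_codes: int) -> CodingMatrix:
    seg_ids = [f"T{i + 1:03d}" for i in range(n_seg)]
    code_ids = [f"C{j + 1:02d}" for j in range(n_codes)]
    return CodingMatrix(
        coder_id=coder_id,
        values=pd.DataFrame(values, index=seg_ids, columns=code_ids),
    )


def generate_reference(spec: DeductiveSimSpec, coder_id: str = "reference") -> CodingMatrix:
    """Reference-standard matrix: independent Bernoulli cells per code at
    that code's frozen prevalence."""
    rng = np.random.default_rng([spec.seed, 1])
    u = rng.random((spec.n_segments, spec.n_codes))
    return _matrix(u < spec.prevalence[None, :], coder_id, spec.n_segments, spec.n_codes)


def simulate_coder(
    reference: CodingMatrix,
    sensitivity: float,
    specificity: float,
    seed: int,
    coder_id: str = "coder",
) -> CodingMatrix:
    """Coder at a fixed operating point: each true reference cell is kept
    with probability ``sensitivity``; each false cell is flipped on with
    probability ``1 - specificity``; cells independent."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = reference.values.values
    u = rng.random(ref.shape)
    labels = np.where(ref, u < sensitivity, u < (1 - specificity))
    return _matrix(labels, coder_id, *ref.shape)


# ---------------------------------------------------------------------------
# Closed-form population metrics (infinite-n oracles)
# ---------------------------------------------------------------------------

def population_metrics(
    prevalence: float | Sequence[float], sensitivity: float, specificity: float
) -> dict[str, float]:
    """Pooled population values of the agreement metrics for a coder at a
    fixed operating point against a reference with the given per-code
    prevalence(s). Pooling averages cell probabilities over codes."""
    p = np.atleast_1d(np.asarray(prevalence, dtype=float))
    tp = float(np.mean(p * sensitivity))
    fn = float(np.mean(p * (1 - sensitivity)))
    fp = float(np.mean((1 - p) * (1 - specificity)))
    tn = float(np.mean((1 - p) * specificity))
    p_o = tp + tn
    p1 = tp + fn
    p2 = tp + fp
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    pi = (p1 + p2) / 2
    gamma_e = 2 * pi * (1 - pi)
    return {
        "p_o": p_o,
        "kappa": (p_o - p_e) / (1 - p_e),
        "ac1": (p_o - gamma_e) / (1 - gamma_e),
        "jaccard": tp / (tp + fp + fn),
        "f1": 2 * tp / (2 * tp + fp + fn),
        "sensitivity": sensitivity,
        "specificity": specificity,
    }


def solve_sensitivity_for_ac1(
    target_ac1: float, specificity: float, prevalence: float | Sequence[float]
) -> float:
    """Sensitivity at which the population pooled AC1 equals ``target_ac1``
    (specificity and prevalence held fixed); AC1 is monotone in sensitivity.

    At low prevalence AC1 is dominated by specificity, so only a narrow AC1
    band is reachable through sensitivity alone; a target outside that band
    raises ValueError (use :func:`solve_specificity_for_ac1` instead).
    """

    def f(s: float) -> float:
        return population_metrics(prevalence, s, specificity)["ac1"] - target_ac1

    lo, hi = f(1e-9), f(1 - 1e-9)
    if lo * hi > 0:
        raise ValueError(
            f"target AC1 {target_ac1:.4f} unreachable via sensitivity at "
            f"specificity {specificity}: range [{target_ac1 + lo:.4f}, {target_ac1 + hi:.4f}]"
        )
    return float(brentq(f, 1e-9, 1 - 1e-9))


def solve_specificity_for_ac1(
    target_ac1: float, sensitivity: float, prevalence: float | Sequence[float]
) -> float:
    """Specificity at which the population pooled AC1 equals ``target_ac1``
    (sensitivity and prevalence held fixed). At low prevalence AC1 responds
    strongly to specificity, so this is the natural knob for placing a coder
    exactly on a non-inferiority margin boundary."""

    def f(sp: float) -> float:
        return population_metrics(prevalence, sensitivity, sp)["ac1"] - target_ac1

    lo, hi = f(1e-9), f(1 - 1e-9)
    if lo * hi > 0:
        raise ValueError(
            f"target AC1 {target_ac1:.4f} unreachable via specificity at "
            f"sensitivity {sensitivity}: range [{target_ac1 + lo:.4f}, {target_ac1 + hi:.4f}]"
        )
    return float(brentq(f, 1e-9, 1 - 1e-9))


# ---------------------------------------------------------------------------
# Likert simulation
# ---------------------------------------------------------------------------

@dataclass
class LikertSimSpec:
    """Inductive-task simulation: 14 codes scored by humans and shifted models.

    ``base_means`` are per-code human agreement levels on the 1-5 scale (drawn
    uniformly in [3.0, 4.7] when not given, matching the upper-middle range of
    observed human scores); models add ``model_shift`` before noise. Noise is
    normal with SD ``noise_sd`` before round-and-clamp to {1..5}.
    """

    n_codes: int = 14
    human_ids: tuple[str, ...] = ("human_1", "human_2")
    model_ids: tuple[str, ...] = ("model_1", "model_2", "model_3")
    model_shift: float = 0.0
    noise_sd: float = 0.8
    base_means: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_means is None:
            rng = np.random.default_rng(self.seed)
            self.base_means = rng.uniform(3.0, 4.7, self.n_codes)
        else:
            self.base_means = np.asarray(self.base_means, dtype=float)
            if self.base_means.size != self.n_codes:
                raise ValueError("base_means length must equal n_codes")


def generate_likert(spec: LikertSimSpec) -> LikertTable:
    """score = clamp(round(base + shift + noise), 1, 5), integer-valued."""
    rng = np.random.default_rng(spec.seed)
    codes = [f"code_{i + 1:02d}" for i in range(spec.n_codes)]
    cols: dict[str, np.ndarray] = {}
    for analyst in spec.human_ids:
        noise = rng.normal(0.0, spec.noise_sd, spec.n_codes)
        cols[analyst] = np.clip(np.rint(spec.base_means + noise), 1, 5).astype(int)
    for analyst in spec.model_ids:
        noise = rng.normal(0.0, spec.noise_sd, spec.n_codes)
        cols[analyst] = np.clip(
            np.rint(spec.base_means + spec.model_shift + noise), 1, 5
        ).astype(int)
    return LikertTable(scores=pd.DataFrame(cols, index=codes))


# ---------------------------------------------------------------------------
# Transcript + quote-record simulation
# ---------------------------------------------------------------------------

_CONSONANTS = "bcdfghklmnprstvw"
_VOWELS = "aeiou"
#: fabricated-token alphabet is disjoint in character bigrams from the
#: vocabulary, keeping no_match similarity far below any sane threshold
_JUNK = "xqzj"


@dataclass
class TranscriptSimSpec:
    """Synthetic focus-group transcript with injected quote-error classes.

    ``class_rates`` gives the mixture (exact, partial, no_match,
    researcher_segment) of generated quote records; corruption in partial
    records is constructed to land well inside (threshold, 1), and fabricated
    records well below the threshold, so truth and audit class coincide.
    """

    n_segments: int = 40
    facilitator_fraction: float = 0.2
    n_records: int = 100
    class_rates: tuple[float, float, float, float] = (0.85, 0.05, 0.02, 0.08)
    model_id: str = "model_1"
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.class_rates, dtype=float)
        if (r < 0).any() or not np.isclose(r.sum(), 1.0):
            raise ValueError("class_rates must be non-negative and sum to 1")
        if not 0 <= self.facilitator_fraction < 1:
            raise ValueError("facilitator_fraction must lie in [0, 1)")


def _word(rng: np.random.Generator) -> str:
    n_syl = int(rng.integers(2, 4))
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syl)
    )


def _junk_word(rng: np.random.Generator) -> str:
    return "".join(_JUNK[rng.integers(len(_JUNK))] for _ in range(int(rng.integers(4, 8))))


def generate_transcript_with_quotes(
    spec: TranscriptSimSpec,
) -> tuple[list[Segment], list[QuoteRecord]]:
    """Generate segments plus quote records realizing the injected class mix.

    Each record's generating class is stored in ``truth_class``; the audit
    must recover it when overrides are disabled.
    """
    rng = np.random.default_rng(spec.seed)
    n_fac = int(round(spec.n_segments * spec.facilitator_fraction))
    if spec.class_rates[3] > 0 and n_fac == 0:
        n_fac = 1
    roles = [SpeakerRole.facilitator] * n_fac + [SpeakerRole.participant] * (
        spec.n_segments - n_fac
    )
    rng.shuffle(roles)  # type: ignore[arg-type]

    segments = []
    for i, role in enumerate(roles):
        n_words = int(rng.integers(12, 25))
        text = " ".join(_word(rng) for _ in range(n_words)).capitalize() + "."
        segments.append(Segment(id=f"T{i + 1:03d}", speaker_role=role, text=text))
    participants = [s for s in segments if s.speaker_role is SpeakerRole.participant]
    facilitators = [s for s in segments if s.speaker_role is SpeakerRole.facilitator]

    classes = list(MatchClass)
    draw = rng.choice(4, size=spec.n_records, p=np.asarray(spec.class_rates))
    records = []
    for k, cls_idx in enumerate(draw):
        cls = classes[cls_idx]
        code_id = f"C{int(rng.integers(1, 6)):02d}"
        if cls is MatchClass.exact:
            seg = participants[rng.integers(len(participants))]
            quote = _verbatim_span(seg.text, rng, min_words=5)
            seg_id: str | None = seg.id
        elif cls is MatchClass.partial:
            seg = participants[rng.integers(len(participants))]
            kept = _verbatim_span(seg.text, rng, min_words=6)
            # ~70% of the quote's characters stay verbatim: similarity lands
            # near 0.7, safely above the 0.5 threshold yet not a substring
            junk = " ".join(_junk_word(rng) for _ in range(max(2, len(kept.split()) // 3)))
            quote = kept + " " + junk
            seg_id = seg.id
        elif cls is MatchClass.no_match:
            seg_id = None
            quote = " ".join(_junk_word(rng) for _ in range(int(rng.integers(6, 12))))
        else:  # researcher_segment
            seg = facilitators[rng.integers(len(facilitators))]
            quote = _verbatim_span(seg.text, rng, min_words=5)
            seg_id = seg.id
        records.append(
            QuoteRecord(
                model_id=spec.model_id,
                quote=quote,
                code_id=code_id,
                segment_id=seg_id,
                truth_class=cls,
            )
        )
    return segments, records


def _verbatim_span(text: str, rng: np.random.Generator, min_words: int) -> str:
    words = text.rstrip(".").split()
    span = int(rng.integers(min_words, max(min_words + 1, min(len(words), 9) + 1)))
    start = int(rng.integers(0, len(words) - span + 1))
    return " ".join(words[start : start + span])
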