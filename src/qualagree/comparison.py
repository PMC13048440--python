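"""Non-inferiority and superiority testing of automated coders against the
mean of blinded human analysts.

Deductive task: the effect for model m is
    Delta_m = AC1(m vs reference) - mean_h AC1(h vs reference),
tested one-sided against H0: Delta <= -delta (margin delta = 0.03 AC1 units
by default) with a segment-level paired bootstrap: each replicate draws ONE
segment resample shared by the model and every human, recomputes Delta on it,
and the p-value is the add-one fraction of replicates at or below -delta,
    p = (1 + #{Delta* <= -delta}) / (B + 1).
Superiority reuses the machinery with margin 0.

Inductive task: per-code Likert differences d_i = score(m, i) - mean_h
score(h, i) are treated as approximately interval data; H0: mean(d) <= -delta
(margin 0.5 points on the 5-point scale) is tested with a one-sample,
one-sided t-test, t = (dbar + delta) / (s_d / sqrt(n)), df = n - 1.

Within each task, raw p-values are Holm-adjusted across the models compared
(separately for the non-inferiority and superiority families); verdicts are
read off the adjusted p-values at the family alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from qualagree.agreement import (
    BootstrapConfig,
    UndefinedMetricError,
    _k_gwet_ac1,
    confusion_counts,
    gwet_ac1,
    resample_metric,
    segment_confusion_counts,
)
from qualagree.coding_data import CodingDataError, CodingMatrix, LikertTable


@dataclass
class DeductiveTestConfig:
    """Bootstrap AC1-difference test settings (margin 0.03, B=1000)."""

    margin: float = 0.03
    b: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("non-inferiority margin must be positive")
        if self.b < 1:
            raise ValueError("bootstrap replicate count must be >= 1")


@dataclass
class InductiveTestConfig:
    """Likert t-test settings (margin 0.5 points on the 5-point scale)."""

    margin: float = 0.5
    alpha: float = 0.05
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("non-inferiority margin must be positive")


@dataclass
class ComparisonResult:
    """One model's comparison against the human mean.

    ``effect`` is the model statistic minus the human-mean statistic; p-values
    for the superiority test (margin 0) ride along in ``p_sup_*``. Verdicts
    are derived from the Holm-adjusted p-values only.
    """

    model_id: str
    effect: float
    margin: float
    p_raw: float
    p_holm: float = math.nan
    p_sup_raw: float = math.nan
    p_sup_holm: float = math.nan
    verdict_noninferior: bool = False
    verdict_superior: bool = False
    ci: tuple[float, float] = (math.nan, math.nan)
    degenerate: bool = False


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for j, k in enumerate(order):
        running = max(running, min(1.0, (m - j) * p[k]))
        adj[k] = running
    return [float(v) for v in adj]


# ---------------------------------------------------------------------------
# Deductive task
# ---------------------------------------------------------------------------

def deductive_noninferiority(
    models: Sequence[CodingMatrix],
    humans: Sequence[CodingMatrix],
    reference: CodingMatrix,
    cfg: DeductiveTestConfig | None = None,
) -> list[ComparisonResult]:
    """Paired-bootstrap non-inferiority (and superiority) of each model's AC1
    against the mean AC1 of the human analysts."""
    cfg = cfg or DeductiveTestConfig()
    if not humans:
        raise CodingDataError("need at least one human analyst matrix")
    if not models:
        raise CodingDataError("need at least one model matrix")

    human_counts = [segment_confusion_counts(reference, h) for h in humans]
    human_points = [gwet_ac1(confusion_counts(reference, h)) for h in humans]
    n_seg = human_counts[0].shape[0]
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n_seg, size=(cfg.b, n_seg))
    human_star = np.stack(
        [resample_metric(_k_gwet_ac1, hc, idx) for hc in human_counts]
    ).mean(axis=0)

    results = []
    for model in models:
        model_point = gwet_ac1(confusion_counts(reference, model))
        model_star = resample_metric(
            _k_gwet_ac1, segment_confusion_counts(reference, model), idx
        )
        delta_star = model_star - human_star
        defined = delta_star[~np.isnan(delta_star)]
        if defined.size < delta_star.size / 2:
            raise UndefinedMetricError(
                f"AC1 undefined in {delta_star.size - defined.size}/{delta_star.size} "
                f"replicates for coder {model.coder_id!r}"
            )
        b = defined.size
        p_ni = (1 + int(np.sum(defined <= -cfg.margin))) / (b + 1)
        p_sup = (1 + int(np.sum(defined <= 0.0))) / (b + 1)
        alpha = 1 - 0.95
        lo, hi = np.quantile(defined, [alpha / 2, 1 - alpha / 2])
        results.append(
            ComparisonResult(
                model_id=model.coder_id,
                effect=model_point - float(np.mean(human_points)),
                margin=cfg.margin,
                p_raw=p_ni,
                p_sup_raw=p_sup,
                ci=(float(lo), float(hi)),
            )
        )
    _apply_holm(results, cfg.alpha)
    return results


# ---------------------------------------------------------------------------
# Inductive task
# ---------------------------------------------------------------------------

def likert_mean_ci(
    scores: Sequence[int | float], ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Mean and t-based CI of Likert scores treated as interval data.

    Uses the sample SD (n-1 denominator) and the t distribution with n-1
    degrees of freedom; a single score yields a point with a degenerate
    interval at the point itself.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty score list")
    mean = float(x.mean())
    if x.size == 1:
        return mean, mean, mean
    sd = float(x.std(ddof=1))
    half = stats.t.ppf(1 - (1 - ci_level) / 2, df=x.size - 1) * sd / math.sqrt(x.size)
    return mean, mean - half, mean + half


def _one_sided_t(d: np.ndarray, margin: float) -> tuple[float, bool]:
    """Upper-tail p for H0: mean(d) <= -margin; flags the zero-spread case."""
    n = d.size
    dbar = float(d.mean())
    s = float(d.std(ddof=1)) if n > 1 else 0.0
    if s == 0.0:
        return (0.0 if dbar > -margin else 1.0), True
    t = (dbar + margin) / (s / math.sqrt(n))
    return float(stats.t.sf(t, df=n - 1)), False


def inductive_noninferiority(
    table: LikertTable,
    model_ids: Sequence[str],
    human_ids: Sequence[str],
    cfg: InductiveTestConfig | None = None,
) -> list[ComparisonResult]:
    """One-sided t-tests of each model's Likert agreement against the
    unweighted per-code mean of the human analysts."""
    cfg = cfg or InductiveTestConfig()
    for col in list(model_ids) + list(human_ids):
        if col not in table.analyst_ids:
            raise CodingDataError(f"analyst {col!r} not present in Likert table")
    if len(table.code_labels) < 2:
        raise CodingDataError("need at least 2 codes for the inductive test")

    human_mean = table.scores[list(human_ids)].mean(axis=1).values.astype(float)
    results = []
    for m in model_ids:
        d = table.scores[m].values.astype(float) - human_mean
        p_ni, degen_ni = _one_sided_t(d, cfg.margin)
        p_sup, _ = _one_sided_t(d, 0.0)
        dbar, lo, hi = likert_mean_ci(d, cfg.ci_level)
        results.append(
            ComparisonResult(
                model_id=m,
                effect=dbar,
                margin=cfg.margin,
                p_raw=p_ni,
                p_sup_raw=p_sup,
                ci=(lo, hi),
                degenerate=degen_ni,
            )
        )
    _apply_holm(results, cfg.alpha)
    return results


def _apply_holm(results: list[ComparisonResult], alpha: float) -> None:
    ni = holm_adjust([r.p_raw for r in results])
    sup = holm_adjust([r.p_sup_raw for r in results])
    for r, p_ni, p_sup in zip(results, ni, sup):
        r.p_holm = p_ni
        r.p_sup_holm = p_sup
        r.verdict_noninferior = p_ni <= alpha
        r.verdict_superior = p_sup <= alpha
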