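"""Chance-corrected and accuracy-style agreement between a coder and the
reference standard (or between two coders).

Two chance-corrected coefficients are central. For a 2x2 table with observed
agreement p_o = (tp + tn)/n, reference positive rate p1 = (tp + fn)/n and
coder positive rate p2 = (tp + fp)/n:

* Cohen's kappa uses the marginal-product chance term
  p_e = p1 p2 + (1 - p1)(1 - p2);  kappa = (p_o - p_e) / (1 - p_e).
* Gwet's AC1 uses the mean positive propensity pi = (p1 + p2)/2 and chance
  term gamma_e = 2 pi (1 - pi);    AC1 = (p_o - gamma_e) / (1 - gamma_e).

At low code prevalence p_e approaches 1 and kappa is strongly attenuated even
when raw agreement is high (the "prevalence paradox"); gamma_e instead
approaches 0, so AC1 tracks raw agreement. Both are reported, alongside
percent agreement, Jaccard, sensitivity, specificity and F1.

Confidence intervals are percentile bootstrap over SEGMENTS: a resample draws
whole segments with replacement and all code labels of a drawn segment move
together, preserving within-segment dependence across codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from qualagree.coding_data import CodingDataError, CodingMatrix, ConfusionCounts


class UndefinedMetricError(ValueError):
    """Raised when a metric's preconditions (n > 0, valid replicates) fail.

    Degenerate-but-expected cases (e.g. kappa with both raters constant and
    equal, which bootstrap resampling produces routinely at ~8% prevalence)
    do NOT raise; they return NaN so replicates can be dropped and counted.
    """


@dataclass
class AgreementMetrics:
    """Point estimates (optionally with CIs) for one coder vs the reference."""

    p_o: float
    kappa: float
    ac1: float
    jaccard: float
    sensitivity: float
    specificity: float
    f1: float
    ci: dict[str, tuple[float, float]] | None = None


@dataclass
class BootstrapConfig:
    """Segment-level percentile bootstrap settings (default B=1000, 95% CI)."""

    b: int = 1000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("bootstrap replicate count must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    n_undefined: int = 0


# ---------------------------------------------------------------------------
# Confusion counts
# ---------------------------------------------------------------------------

def confusion_counts(
    reference: CodingMatrix, coder: CodingMatrix, code: str | None = None
) -> ConfusionCounts:
    """2x2 counts of ``coder`` against ``reference`` (reference = truth axis).

    ``code=None`` pools all segment x code cells into one binary vector; a
    code id restricts to that code's column.
    """
    _check_universe(reference, coder)
    if code is None:
        ref = reference.values.values.ravel()
        cod = coder.values.values.ravel()
    else:
        if code not in reference.code_ids:
            raise CodingDataError(f"unknown code {code!r}")
        ref = reference.values[code].values
        cod = coder.values[code].values
    tp = int(np.sum(ref & cod))
    fp = int(np.sum(~ref & cod))
    fn = int(np.sum(ref & ~cod))
    tn = int(np.sum(~ref & ~cod))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _check_universe(a: CodingMatrix, b: CodingMatrix) -> None:
    if not a.same_universe(b):
        only_a = sorted(set(a.segment_ids) ^ set(b.segment_ids))
        only_c = sorted(set(a.code_ids) ^ set(b.code_ids))
        raise CodingDataError(
            f"coding matrices have mismatched universes; disjoint segments={only_a}, codes={only_c}"
        )


# ---------------------------------------------------------------------------
# Vectorized metric kernels on (tp, fp, fn, tn) arrays; NaN where undefined
# ---------------------------------------------------------------------------

def _k_percent_agreement(tp, fp, fn, tn):
    n = tp + fp + fn + tn
    return np.where(n > 0, (tp + tn) / np.maximum(n, 1), np.nan)


def _k_cohen_kappa(tp, fp, fn, tn):
    n = tp + fp + fn + tn
    with np.errstate(invalid="ignore", divide="ignore"):
        p_o = (tp + tn) / n
        p1 = (tp + fn) / n
        p2 = (tp + fp) / n
        p_e = p1 * p2 + (1 - p1) * (1 - p2)
        out = (p_o - p_e) / (1 - p_e)
    return np.where((n > 0) & ~np.isclose(p_e, 1.0), out, np.nan)


def _k_gwet_ac1(tp, fp, fn, tn):
    n = tp + fp + fn + tn
    with np.errstate(invalid="ignore", divide="ignore"):
        p_o = (tp + tn) / n
        pi = ((tp + fn) / n + (tp + fp) / n) / 2
        gamma_e = 2 * pi * (1 - pi)  # <= 0.5 for binary labels
        out = (p_o - gamma_e) / (1 - gamma_e)
    return np.where(n > 0, out, np.nan)


def _k_jaccard(tp, fp, fn, tn):
    d = tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = tp / d
    return np.where(d > 0, out, np.nan)


def _k_f1(tp, fp, fn, tn):
    d = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2 * tp / d
    return np.where(d > 0, out, np.nan)


def _k_sensitivity(tp, fp, fn, tn):
    d = tp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = tp / d
    return np.where(d > 0, out, np.nan)


def _k_specificity(tp, fp, fn, tn):
    d = tn + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        out = tn / d
    return np.where(d > 0, out, np.nan)


def _scalar(kernel: Callable, c: ConfusionCounts) -> float:
    if c.n == 0:
        raise UndefinedMetricError("metric undefined on an empty 2x2 table (n = 0)")
    val = kernel(
        np.asarray(float(c.tp)),
        np.asarray(float(c.fp)),
        np.asarray(float(c.fn)),
        np.asarray(float(c.tn)),
    )
    return float(val)


def percent_agreement(c: ConfusionCounts) -> float:
    """Observed agreement proportion (tp + tn) / n."""
    return _scalar(_k_percent_agreement, c)


def cohen_kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa; NaN when both raters are constant and equal (p_e = 1)."""
    return _scalar(_k_cohen_kappa, c)


def gwet_ac1(c: ConfusionCounts) -> float:
    """Gwet's AC1 (two-rater binary form)."""
    return _scalar(_k_gwet_ac1, c)


def jaccard(c: ConfusionCounts) -> float:
    """tp / (tp + fp + fn); NaN when no cell is positive for either rater."""
    return _scalar(_k_jaccard, c)


def f1(c: ConfusionCounts) -> float:
    """2 tp / (2 tp + fp + fn); equals 2J/(1+J) against the Jaccard index J."""
    return _scalar(_k_f1, c)


def sensitivity(c: ConfusionCounts) -> float:
    return _scalar(_k_sensitivity, c)


def specificity(c: ConfusionCounts) -> float:
    return _scalar(_k_specificity, c)


_KERNELS: dict[Callable, Callable] = {}


def _register_kernels() -> None:
    _KERNELS[percent_agreement] = _k_percent_agreement
    _KERNELS[cohen_kappa] = _k_cohen_kappa
    _KERNELS[gwet_ac1] = _k_gwet_ac1
    _KERNELS[jaccard] = _k_jaccard
    _KERNELS[f1] = _k_f1
    _KERNELS[sensitivity] = _k_sensitivity
    _KERNELS[specificity] = _k_specificity


_register_kernels()


def compute_all_metrics(c: ConfusionCounts) -> AgreementMetrics:
    return AgreementMetrics(
        p_o=percent_agreement(c),
        kappa=cohen_kappa(c),
        ac1=gwet_ac1(c),
        jaccard=jaccard(c),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        f1=f1(c),
    )


def per_code_kappa(reference: CodingMatrix, coder: CodingMatrix) -> dict[str, float]:
    """Cohen's kappa computed independently for each code; NaN flags codes
    with degenerate marginals (e.g. neither rater ever used the code)."""
    _check_universe(reference, coder)
    return {
        code: cohen_kappa(confusion_counts(reference, coder, code))
        for code in reference.code_ids
    }


# ---------------------------------------------------------------------------
# Segment-level bootstrap
# ---------------------------------------------------------------------------

def segment_confusion_counts(
    reference: CodingMatrix, coder: CodingMatrix, code: str | None = None
) -> np.ndarray:
    """(n_segments, 4) array of per-segment (tp, fp, fn, tn) contributions."""
    _check_universe(reference, coder)
    if code is None:
        ref = reference.values.values
        cod = coder.values.values
    else:
        ref = reference.values[[code]].values
        cod = coder.values[[code]].values
    tp = (ref & cod).sum(axis=1)
    fp = (~ref & cod).sum(axis=1)
    fn = (ref & ~cod).sum(axis=1)
    tn = (~ref & ~cod).sum(axis=1)
    return np.stack([tp, fp, fn, tn], axis=1).astype(float)


def resample_metric(
    kernel: Callable, seg_counts: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Evaluate a metric kernel on bootstrap resamples given by an index
    matrix of shape (B, n_segments)."""
    counts = seg_counts[idx].sum(axis=1)  # (B, 4)
    return kernel(counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3])


def _metric_kernel(metric_fn: Callable) -> Callable:
    kernel = _KERNELS.get(metric_fn)
    if kernel is not None:
        return kernel

    def fallback(tp, fp, fn, tn):
        tp, fp, fn, tn = (np.atleast_1d(a) for a in (tp, fp, fn, tn))
        out = np.empty(tp.shape)
        for i in range(tp.size):
            try:
                out[i] = metric_fn(
                    ConfusionCounts(int(tp[i]), int(fp[i]), int(fn[i]), int(tn[i]))
                )
            except UndefinedMetricError:
                out[i] = np.nan
        return out

    return fallback


def _percentile_interval(values: np.ndarray, ci_level: float) -> tuple[float, float]:
    alpha = 1 - ci_level
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def bootstrap_ci(
    metric_fn: Callable,
    reference: CodingMatrix,
    coder: CodingMatrix,
    cfg: BootstrapConfig | None = None,
    code: str | None = None,
) -> BootstrapResult:
    """Percentile bootstrap CI for ``metric_fn`` with segment-level resampling.

    Replicates where the metric is undefined (degenerate marginals) are
    dropped and counted; more than 50% undefined replicates is an error.
    """
    cfg = cfg or BootstrapConfig()
    point = metric_fn(confusion_counts(reference, coder, code))
    seg_counts = segment_confusion_counts(reference, coder, code)
    n_seg = seg_counts.shape[0]
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n_seg, size=(cfg.b, n_seg))
    vals = resample_metric(_metric_kernel(metric_fn), seg_counts, idx)
    return _finish_bootstrap(point, vals, cfg)


def bootstrap_mean_ci(
    metric_fn: Callable,
    reference: CodingMatrix,
    coders: Sequence[CodingMatrix],
    cfg: BootstrapConfig | None = None,
    code: str | None = None,
) -> BootstrapResult:
    """Bootstrap CI for the arithmetic mean of a metric over several coders.

    All coders share the same segment resample in each replicate, so the
    replicate statistic is the mean over coders on identical segments (the
    construction behind "human mean" / "model mean" summary rows).
    """
    cfg = cfg or BootstrapConfig()
    if not coders:
        raise CodingDataError("need at least one coder")
    kernel = _metric_kernel(metric_fn)
    points = [metric_fn(confusion_counts(reference, c, code)) for c in coders]
    point = float(np.mean(points))
    all_counts = [segment_confusion_counts(reference, c, code) for c in coders]
    n_seg = all_counts[0].shape[0]
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n_seg, size=(cfg.b, n_seg))
    per_coder = np.stack([resample_metric(kernel, sc, idx) for sc in all_counts])
    vals = per_coder.mean(axis=0)  # NaN propagates if any coder undefined
    return _finish_bootstrap(point, vals, cfg)


def _finish_bootstrap(
    point: float, vals: np.ndarray, cfg: BootstrapConfig
) -> BootstrapResult:
    defined = vals[~np.isnan(vals)]
    n_undef = int(vals.size - defined.size)
    if n_undef > vals.size / 2:
        raise UndefinedMetricError(
            f"metric undefined in {n_undef}/{vals.size} bootstrap replicates; "
            "marginals too degenerate for a stable interval"
        )
    if defined.size == 0:
        raise UndefinedMetricError("no defined bootstrap replicates")
    lo, hi = _percentile_interval(defined, cfg.ci_level)
    if math.isnan(point):
        lo = hi = float("nan")
    return BootstrapResult(point=point, ci_low=lo, ci_high=hi, n_undefined=n_undef)
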