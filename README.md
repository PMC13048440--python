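# qualagree

Blinded, metric-based evaluation of automated coders — large language models
or any other annotator — against human analysts and an adjudicated reference
standard in qualitative thematic coding.

Qualitative researchers increasingly hand focus-group and interview
transcripts to LLMs for coding. Deciding whether a model codes "as well as" a
human analyst requires more than raw percent agreement: when a codebook's
codes are rare (prevalence well under 10%), two coders who almost always say
*false* agree almost always by construction. This package implements the
evaluation framework such a comparison needs, end to end:

* **Deductive coding** (segment × code binary labels vs. an adjudicated
  reference): percent agreement, Cohen's κ, Gwet's AC1, Jaccard, sensitivity,
  specificity and F1, per code and pooled, with segment-level percentile
  bootstrap CIs. For a 2×2 table with observed agreement p_o and marginal
  positive rates p₁ (reference) and p₂ (coder),

      κ   = (p_o − p_e) / (1 − p_e),   p_e = p₁p₂ + (1−p₁)(1−p₂)
      AC1 = (p_o − γ_e) / (1 − γ_e),   γ_e = 2π̂(1−π̂),  π̂ = (p₁+p₂)/2

  Under low prevalence p_e → 1 and κ collapses (the "prevalence paradox")
  while AC1 tracks raw agreement — the package exposes both so the contrast
  is visible rather than hidden.
* **Non-inferiority / superiority testing** of each model against the mean of
  the blinded human analysts: a paired segment-resampling bootstrap of the
  AC1 difference (margin δ = 0.03) for the deductive task, and one-sided
  t-tests on per-code Likert differences (margin δ = 0.5 points on the
  5-point scale) for the inductive task, with Holm step-down adjustment
  across the models compared.
* **Quote-verification audit**: every model-emitted (segment, quote, code)
  evidence claim is checked against the transcript and classed exact /
  partial / no-match / researcher-segment, giving strict hallucination,
  expanded hallucination, and comprehensive error rates per model.
* **Synthetic data** for every input: reference standards at controlled code
  prevalence, coders with known sensitivity/specificity, Likert profiles with
  known shifts, and transcripts with injected quote errors — so the whole
  pipeline is testable closed-loop, including CI coverage and type-I error of
  the non-inferiority test.

The package bundles the published focus-group evaluation tables it
operationalizes (the 14-code × 5-analyst inductive Likert table and the
per-model quote-audit count block), so those analyses recompute from source.

## Worked example

The numbered scripts under `analysis/` run the full story; the inductive
comparison alone:

```bash
python analysis/04_inductive_comparison.py
```

prints

```
column means (95% CI):
  Human Analyst 1: 3.643 (3.157-4.129)
  Human Analyst 2: 4.071 (3.542-4.601)
  ChatGPT-5: 4.071 (3.593-4.550)
  Claude 4 Sonnet: 3.643 (2.941-4.345)
  QualiGPT: 3.929 (3.232-4.625)
non-inferiority at margin 0.5 (Holm-adjusted):
  ChatGPT-5: p_holm=0.043 -> non-inferior
  Claude 4 Sonnet: p_holm=0.198 -> not established
  QualiGPT: p_holm=0.175 -> not established
```

Each column mean is the analyst's average Likert agreement with the
reference-standard panel over the 14 inductive codes (t-based 95% CI). The
test compares each model's per-code scores with the per-code mean of the two
humans: only ChatGPT-5's deficit is bounded above −0.5 points with Holm-
adjusted p ≤ 0.05, i.e. only one model demonstrates non-inferiority.

The same library surface is scriptable:

```python
from qualagree import study_data, inductive_noninferiority

table = study_data.inductive_likert_table()
results = inductive_noninferiority(table, study_data.MODELS, study_data.HUMAN_ANALYSTS)
```

The deductive stages run on simulated study-shaped data
(`analysis/01_simulate_fixtures.py` … `03_deductive_noninferiority.py`), and
`analysis/05_quote_audit.py` renders the audit table (across-model mean
strict / expanded / comprehensive rates 1.2% / 8.6% / 12.4%) plus a synthetic
closed loop. A `qualagree` console command exposes the same stages
(`qualagree --help`).

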