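"""Inductive comparison on the bundled study Likert table.

Recomputes the per-analyst column means with parametric 95% CIs and runs the
Holm-adjusted one-sided t-test of each model against the per-code human mean
at the 0.5-point margin. Expected finding: ChatGPT-5 is the only model to
reach non-inferiority, with a Holm-adjusted p that prints as 0.043.
"""

import argparse
import json
from pathlib import Path

from qualagree.cli import RunConfig, _compare_inductive_stage


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--likert", default="", help="Likert CSV/JSON; default = bundled table")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()
    cfg = RunConfig(task="noninferiority-inductive", out_dir=args.out)
    path = _compare_inductive_stage(cfg, Path(args.likert) if args.likert else None)
    payload = json.loads(path.read_text())
    print("column means (95% CI):")
    for analyst, m in payload["column_means"].items():
        print(f"  {analyst}: {m['mean']:.3f} ({m['ci_low']:.3f}-{m['ci_high']:.3f})")
    print("non-inferiority at margin 0.5 (Holm-adjusted):")
    for row in payload["inductive"]:
        verdict = "non-inferior" if row["noninferior"] else "not established"
        print(f"  {row['model']}: p_holm={row['p_holm']:.3f} -> {verdict}")


if __name__ == "__main__":
    main()
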