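"""Generate the synthetic study fixtures every later stage consumes.

Writes, under results/fixtures/: a reference-standard coding matrix (124
participant segments x 10 codes at ~7.8% mean prevalence), two human analysts
at operating point (0.34, 0.97) and three models at (0.30, 0.98), a 14-code
Likert table, and a pseudo-word transcript with quote records realizing a
known mixture of audit classes.
"""

import argparse

from qualagree.cli import RunConfig, run


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--data", default="results/fixtures")
    args = parser.parse_args()
    run(RunConfig(task="simulate", seed=args.seed, data_dir=args.data))
    print(f"fixtures written to {args.data} (seed {args.seed})")


if __name__ == "__main__":
    main()
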