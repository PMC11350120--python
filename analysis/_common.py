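"""Shared run configuration for the numbered analysis scripts.

All scripts operate on the same output directory (``results/study`` by
default) so they can be run in order; pass ``--seed`` / ``--outdir`` to any
of them to work on a different replicate.
"""

import argparse

from dendrowue.pipeline import RunConfig


def get_config(description: str) -> RunConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results/study")
    parser.add_argument("--tree-fraction", type=float, default=1.0)
    args = parser.parse_args()
    return RunConfig(
        outdir=args.outdir, seed=args.seed, tree_fraction=args.tree_fraction
    )
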