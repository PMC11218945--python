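#!/usr/bin/env python
"""Optional validation against externally published genome-scale collections.

The community-scale results (honeybee gut microbiome pairwise competition
rates, the phyllosphere panel against Pantoea eucalypti 299R, the
Desulfovibrio vulgaris / Methanococcus maripaludis and Geobacter
sulfurreducens / Rhodoferax ferrireducens co-cultures) depend on model
collections that must be downloaded separately; they are not part of the
bundled desk-scale test surface.  Once the SBML/JSON files are on disk, this
script runs the identical pipeline on them.

Usage::

    python scripts/validate_external.py MODEL1 MODEL2 [MODEL3 ...] -o results/

Notes on sourcing the collections (public repositories of the original
studies): the phyllosphere strain models ship with the cusper competition
study's repository; the honeybee gut models with the ReMIND repository; the
syntrophic pair models with the synthetic-ecology model archive.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from commacparma.pipeline import RunConfig, run_pipeline, write_reports


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("models", nargs="+", type=Path)
    parser.add_argument("-o", "--out", type=Path, default=Path("results/external"))
    parser.add_argument("--alpha", type=float, default=0.1)
    parser.add_argument("--beta", type=float, default=0.01)
    parser.add_argument("--epsilon", type=float, default=0.01)
    args = parser.parse_args()
    if len(args.models) < 2:
        parser.error("need at least two model files")
    for path in args.models:
        if not path.exists():
            parser.error(f"model file not found: {path} (collections must be downloaded first)")
    config = RunConfig(alpha=args.alpha, beta=args.beta, epsilon=args.epsilon,
                       output_dir=str(args.out))
    bundle = run_pipeline([str(p) for p in args.models], config)
    write_reports(bundle, config, args.out)
    print(f"wrote reports for {len(bundle.pairs)} pairs to {args.out}")


if __name__ == "__main__":
    main()
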