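#!/usr/bin/env python
"""Stage 3: entropy weights and TOPSIS/SAW ranking of the ten drugs.

Runs the staged MCDM chain from the published normalized decision matrix
(the mode that reproduces the published tables; the documented
alternative recomputes the matrix from the fixture graphs), writes every
stage table under results/mcdm/, and prints both final rankings.
"""

import json
from pathlib import Path

import pandas as pd

from topodrug.pipeline import RunConfig, run_pipeline

OUT = Path("results/mcdm")


def main() -> None:
    summary = run_pipeline(RunConfig(decision_matrix="published", out_dir=str(OUT)))

    print("Entropy weights:")
    for crit, w in summary["weights"].items():
        print(f"  {crit:4s} {w:.6f}")

    topsis = pd.read_csv(OUT / "topsis.csv", index_col=0)
    saw = pd.read_csv(OUT / "saw.csv", index_col=0)
    print("\nTOPSIS ranking (relative closeness):")
    print(topsis[["closeness", "rank"]])
    print("\nSAW ranking (weighted score):")
    print(saw)
    print(f"\nTop candidate under both methods: {summary['topsis_top']}")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
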