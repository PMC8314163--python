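#!/usr/bin/env python
"""Pool day features over each PHQ-8 assessment window and label the rows.

Responses with fewer than 8 retained days in their 14-day window are
excluded; exact duplicate rows are collapsed. Prints the class split the
downstream classifiers must cope with.
"""

import argparse
from pathlib import Path

import pandas as pd

from phenodep import pooling, preprocess


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    responses = pd.read_csv(args.data / "responses.csv")
    days = pd.read_csv(args.out / "day_summaries.csv")
    feats = pd.read_csv(args.out / "day_features.csv")

    retained = preprocess.filter_responses(responses, days)
    pooled = pooling.deduplicate(pooling.pool_samples(feats, retained))
    pooled.to_csv(args.out / "pooled_samples.csv", index=False)

    n = len(pooled)
    dep = int(pooled["label"].sum())
    print(
        f"retained {len(retained)}/{len(responses)} responses; pooled table "
        f"has {n} samples after deduplication: {n - dep} nondepressed "
        f"({100 * (n - dep) / n:.2f}%), {dep} depressed ({100 * dep / n:.2f}%)"
    )


if __name__ == "__main__":
    main()
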