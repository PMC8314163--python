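#!/usr/bin/env python
"""Assemble the plain-text study report from the stage outputs."""

import argparse
from pathlib import Path

import pandas as pd

from phenodep.pipeline import RunManifest, write_summary


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    def _maybe(path: Path):
        return pd.read_csv(path) if path.exists() else None

    responses = _maybe(args.data / "responses.csv")
    days = _maybe(args.out / "day_summaries.csv")
    pooled = _maybe(args.out / "pooled_samples.csv")
    profiles = _maybe(args.data / "profiles.csv")
    manifest = RunManifest(
        seed=0,
        config={},
        counts={
            "participants": len(profiles) if profiles is not None else 0,
            "responses_in": len(responses) if responses is not None else 0,
            "responses_retained": len(pooled) if pooled is not None else 0,
            "days_retained": len(days) if days is not None else 0,
        },
    )
    text = write_summary(
        manifest,
        responses=responses,
        days=days,
        associations=_maybe(args.out / "associations.csv"),
        cv_summary=_maybe(args.out / "cv_summary.csv"),
        baselines={
            k: v
            for k, v in {
                "RWC": _maybe(args.out / "baseline_rwc.csv"),
                "DT": _maybe(args.out / "baseline_dt.csv"),
            }.items()
            if v is not None
        },
        importance=_maybe(args.out / "importance.csv"),
    )
    (args.out / "report.txt").write_text(text)
    print(text)


if __name__ == "__main__":
    main()
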