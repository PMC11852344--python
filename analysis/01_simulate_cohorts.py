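#!/usr/bin/env python
"""Generate the three synthetic study cohorts and record their ground truth.

Three subjects per arm (isolated myectomy, myectomy + AMVLE, healthy
controls), each realised as independent calibrated tube segments (ascending
aorta, LVOT, aortic and mitral valve) with velocity noise, background phase
offsets and venc wrapping.  Writes the per-subject true targets to
results/cohort_truth.csv; pass --export-dir (e.g. scratch/cohorts) to also
dump the HDF5 containers for inspection with the `flow4d` CLI.
"""

import argparse
from pathlib import Path

import pandas as pd

from flow4d import AnalysisConfig
from flow4d.io import write_dataset
from flow4d.phantom import make_cohort
from flow4d.targets import STUDY_GROUPS

SEED = 20240
N_SUBJECTS = 3


def build_cohorts(seed: int = SEED):
    cfg = AnalysisConfig(seed=seed)
    return cfg, {
        group: make_cohort(group, N_SUBJECTS, cfg, seed=seed + i)
        for i, group in enumerate(STUDY_GROUPS)
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=SEED)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--export-dir", type=Path, default=None)
    args = ap.parse_args()

    _, cohorts = build_cohorts(args.seed)
    rows = []
    for group, subjects in cohorts.items():
        for s in subjects:
            rows.append({"subject_id": s.subject_id, "group": group,
                         **{k: round(v, 4) for k, v in s.true_targets.items()}})
            if args.export_dir is not None:
                args.export_dir.mkdir(parents=True, exist_ok=True)
                for name, b in s.segments.items():
                    write_dataset(args.export_dir / f"{s.subject_id}_{name}.h5",
                                  b.field, b.magnitude, b.masks)
    args.out.mkdir(parents=True, exist_ok=True)
    truth = pd.DataFrame(rows)
    truth.to_csv(args.out / "cohort_truth.csv", index=False)
    print(truth.to_string(index=False))
    print(f"\n{len(rows)} subjects; group-mean truths match the published "
          f"columns by construction (moment-matched draws).")


if __name__ == "__main__":
    main()
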