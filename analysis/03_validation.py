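"""Validation phase: qPCR quantification and ROC screening of the candidate
panel in the independent simulated cohort.

Reads the Ct table from 01_simulate_cohorts.py and the candidate panel from
02_discovery.py, then runs replicate collapse, the two-step median Ct
normalization, per-marker fold changes (control group mean = 1), per-marker
ROC with specificity at 100% detection rate (exact binomial CI), and
logistic combinations of the top-3 and top-7 panels. Writes the fold-change
and screening tables under results/validation/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from mirnascreen.data import read_ct_table, read_sample_metadata
from mirnascreen.pipeline import run_validation
from mirnascreen.simulate import CALIBRATOR_ASSAY, SPIKE_IN_ASSAYS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--panel", type=Path,
                    default=Path("results/discovery/candidate_panel.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results/validation"))
    args = ap.parse_args()

    ct = read_ct_table(args.datadir / "validation_ct.csv",
                       CALIBRATOR_ASSAY, SPIKE_IN_ASSAYS)
    metas = read_sample_metadata(args.datadir / "validation_meta.csv")
    panel = pd.read_csv(args.panel)["marker_id"].tolist()
    panel = [m for m in panel if m in set(ct.records["assay_id"])]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_validation(ct, metas, panel)
    report.write(args.outdir)

    flagged = int(report.cv_qc["flagged"].sum())
    print(f"panel of {len(panel)} markers; "
          f"{flagged} replicate cells with CV >= 2%")
    best = (report.roc_table.query("time_point == 'A'")
            .sort_values("auc", ascending=False).iloc[0])
    print(f"best single marker at time point A: {best['marker_id']} "
          f"({best['outcome']}): AUC {best['auc']:.3f}, specificity at 100% "
          f"DR {best['specificity_100dr_pct']:.1f}% "
          f"[{best['ci95_low_pct']:.1f}, {best['ci95_high_pct']:.1f}]")
    print(report.combined_table.to_string(index=False))
    print(f"tables written to {args.outdir}")


if __name__ == "__main__":
    main()
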