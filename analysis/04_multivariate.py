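"""Multivariate structure of the discovery profiles: UV-scaled PCA and
PLS-DA with seven-round cross-validated Q²Y.

Quantifies (a) how much of the profile variance is patient-to-patient rather
than gestational-age structure (PCA score dispersion within vs between
patients) and (b) the supervised separability of outcome groups at each time
point (PLS-DA R²Y and Q²Y). Writes summary tables under
results/multivariate/.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from mirnascreen.data import meta_frame, read_count_matrix, read_sample_metadata
from mirnascreen.multivariate import pca_nipals, plsda, q2y_crossval, uv_scale
from mirnascreen.pipeline import run_discovery


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/multivariate"))
    ap.add_argument("--components", type=int, default=2)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = read_count_matrix(args.datadir / "discovery_counts.csv",
                               args.datadir / "discovery_probes.csv")
    metas = read_sample_metadata(args.datadir / "discovery_meta.csv")
    report = run_discovery(counts, metas)
    values = np.log2(report.normalized.values[report.retained_markers] + 1.0)
    mf = meta_frame(metas).loc[values.index]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled, _ = uv_scale(values)
    pca = pca_nipals(scaled, args.components)
    scores = pd.DataFrame(pca.scores, index=scaled.index,
                          columns=[f"t{a+1}" for a in range(args.components)])
    scores.join(mf).to_csv(args.outdir / "pca_scores.csv")

    # patient clustering: mean pairwise score distance within a patient's
    # serial samples vs between patients
    pts = mf["patient_id"]
    d = np.sqrt(((pca.scores[:, None, :] - pca.scores[None, :, :]) ** 2).sum(-1))
    same = (pts.to_numpy()[:, None] == pts.to_numpy()[None, :])
    np.fill_diagonal(same, False)
    within = d[same].mean()
    between = d[~same & ~np.eye(len(d), dtype=bool)].mean()
    print(f"PCA: R2X per component {np.round(pca.r2x, 3)}")
    print(f"patient clustering: mean within-patient score distance "
          f"{within:.2f} vs between-patient {between:.2f} "
          f"(ratio {within / between:.2f})")

    rows = []
    for tp in ("A", "B", "C"):
        for case in ("PRETERM", "SHORT"):
            ids = mf.index[(mf["time_point"] == tp)
                           & mf["outcome"].isin(["TERM", case])]
            y = (mf.loc[ids, "outcome"] == case).astype(int).to_numpy()
            x = scaled.loc[ids]
            model = plsda(x, y, args.components)
            q2 = q2y_crossval(x, y, args.components, seed=args.seed)
            rows.append({"time_point": tp, "comparison": f"{case}_vs_TERM",
                         "r2y": model.r2y[-1], "q2y": q2[-1],
                         "n": len(ids)})
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "plsda_summary.csv", index=False)
    print(table.round(3).to_string(index=False))
    print(f"tables written to {args.outdir}")


if __name__ == "__main__":
    main()
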