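"""Generate the synthetic discovery and validation cohorts.

Writes the three delimited formats the pipeline consumes: probe-level count
matrix + probe annotation and sample metadata for the discovery cohort
(16 TERM / 13 PRETERM / 24 SHORT patients, three serial samples each), and a
qPCR Ct table + metadata for the independent validation cohort
(84 TERM / 17 PRETERM / 28 SHORT at the A time point layout).
"""

import argparse
from pathlib import Path

from mirnascreen.data import (
    write_count_matrix,
    write_ct_table,
    write_sample_metadata,
)
from mirnascreen.simulate import SimConfig, simulate_cohort, simulate_qpcr


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    disc_cfg = SimConfig(seed=args.seed, haemolysis_fraction=0.02)
    counts, metas, truth = simulate_cohort(disc_cfg)
    write_count_matrix(counts, args.outdir / "discovery_counts.csv",
                       args.outdir / "discovery_probes.csv")
    write_sample_metadata(metas, args.outdir / "discovery_meta.csv")
    (args.outdir / "true_markers.txt").write_text(
        "\n".join(sorted(truth.markers)) + "\n")

    val_cfg = SimConfig(seed=args.seed + 1,
                        n_per_group={"TERM": 84, "PRETERM": 17, "SHORT": 28})
    _, vmetas, vtruth = simulate_cohort(val_cfg)
    ct = simulate_qpcr(val_cfg, vmetas, vtruth)
    write_ct_table(ct, args.outdir / "validation_ct.csv")
    write_sample_metadata(vmetas, args.outdir / "validation_meta.csv")

    print(f"discovery cohort: {counts.counts.shape[0]} samples × "
          f"{counts.counts.shape[1]} probes, "
          f"{len(truth.haemolysed_samples)} haemolysed")
    print(f"validation cohort: {len(vmetas)} samples, "
          f"{len(ct.records)} qPCR records")
    print(f"written to {args.outdir}")


if __name__ == "__main__":
    main()
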