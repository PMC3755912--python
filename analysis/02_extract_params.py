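"""Extract the five distribution parameters (x0, xd, xb at 10/15/20/25%
cutoffs, xm, xy) for every strain of the simulated panel, with QC flags,
and summarise the wild-type birth-size reference."""

import argparse
from pathlib import Path

import numpy as np

from birthsize import categories, distio, params


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--out", type=Path, default=Path("results/params.tsv"))
    args = ap.parse_args()

    wt_ids = [l.strip() for l in
              (args.panel / "wildtype_ids.txt").read_text().splitlines()
              if l.strip()]
    records = distio.read_distribution_matrix(
        args.panel / "distributions.tsv", wildtype_ids=wt_ids)
    params.extract_panel(records)
    table = params.params_table(records)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)

    qc = params.qc_summary(records)
    print(f"extracted parameters for {qc['ingested']} strains: "
          f"{qc['pass']} pass, {qc['abnormal_no_daughter_range']} abnormal, "
          f"{qc['manual_excluded']} excluded")
    ref = categories.wt_reference(records)
    print(f"wild-type xb(0.20): {ref.mu_wt:.2f} fl +/- {ref.sd_wt:.2f} "
          f"(n = {ref.n_wt} replicates)")
    mut = table[table.role == "mutant"]
    print(f"mutant xb(0.20): median {np.median(mut.xb_20):.2f} fl, "
          f"range {mut.xb_20.min():.2f}-{mut.xb_20.max():.2f} fl")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
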