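"""Assign small/normal/large birth-size categories under both schemes
(wild-type +/- 2 SD outliers, and 5% quantile tails of the mutant pool)
and tabulate how the two schemes overlap."""

import argparse
from pathlib import Path

from birthsize import categories, distio, params


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/categories.tsv"))
    ap.add_argument("--tail", type=float, default=0.05)
    args = ap.parse_args()

    wt_ids = [l.strip() for l in
              (args.panel / "wildtype_ids.txt").read_text().splitlines()
              if l.strip()]
    records = distio.read_distribution_matrix(
        args.panel / "distributions.tsv", wildtype_ids=wt_ids)
    params.extract_panel(records)

    ref = categories.wt_reference(records)
    wt_sd = categories.categorize_wt_sd(records, ref)
    quant = categories.categorize_quantile(records, tail=args.tail)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    categories.assignments_table(wt_sd + quant).to_csv(args.out, sep="\t",
                                                       index=False)

    def tally(assignments):
        labels = [a.label for a in assignments]
        return {lab: labels.count(lab) for lab in categories.LABELS}

    print(f"wt_sd scheme (mu {ref.mu_wt:.2f}, sd {ref.sd_wt:.2f}, "
          f"thresholds {ref.lower:.2f}/{ref.upper:.2f} fl): {tally(wt_sd)}")
    print(f"quantile scheme ({args.tail:.0%} tails): {tally(quant)}")
    overlap = categories.compare_schemes(wt_sd, quant)
    overlap.to_csv(args.out.parent / "scheme_overlap.tsv", sep="\t")
    print("scheme overlap (rows wt_sd, columns quantile):")
    print(overlap.to_string())
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
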