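"""Correlate birth size with mean size, fitness rank and %G1 per
category under both schemes; compare category means; and compute the
birth-to-budding size increase implied by the 35 fl budding size."""

import argparse
from pathlib import Path

from birthsize import association, categories, distio, params

# printed population birth sizes at the 10% and 25% cutoffs, and the
# elutriation-calibrated budding size, used for the increase arithmetic
BIRTH_10, BIRTH_25, BUDDING = 21.84, 27.40, 35.0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    wt_ids = [l.strip() for l in
              (args.panel / "wildtype_ids.txt").read_text().splitlines()
              if l.strip()]
    records = distio.read_distribution_matrix(
        args.panel / "distributions.tsv", wildtype_ids=wt_ids)
    records = distio.join_panel(records, distio.read_phenotype_table(
        args.panel / "phenotypes.tsv"))
    params.extract_panel(records)
    ref = categories.wt_reference(records)
    by_scheme = {
        categories.SCHEME_WT_SD: categories.categorize_wt_sd(records, ref),
        categories.SCHEME_QUANTILE: categories.categorize_quantile(records),
    }
    results, comparisons = [], []
    for assignments in by_scheme.values():
        for phenotype in association.PHENOTYPES:
            results += association.per_category_association(
                records, assignments, phenotype)
            comparisons += association.group_mean_comparison(
                records, assignments, phenotype, holm=True)
    args.out.mkdir(parents=True, exist_ok=True)
    association.associations_table(results).to_csv(
        args.out / "associations.tsv", sep="\t", index=False)
    association.comparisons_table(comparisons).to_csv(
        args.out / "group_comparisons.tsv", sep="\t", index=False)

    show = {(r.scheme, r.phenotype, r.category): r for r in results}
    r = show[("wt_sd", "mean_size", "overall")]
    print(f"xb vs mean size, overall: rho = {r.rho:.2f} (n = {r.n})")
    for cat in ("small", "large"):
        r = show[("wt_sd", "mean_size", cat)]
        print(f"xb vs mean size, {cat}: rho = "
              f"{'NA' if r.rho is None else f'{r.rho:.2f}'} (n = {r.n})")
    r = show[("wt_sd", "pct_g1", "overall")]
    print(f"xb vs %G1, overall: rho = {r.rho:.2f} (n = {r.n})")
    comp = {(c.scheme, c.phenotype, c.pair): c for c in comparisons}
    c = comp[("quantile", "pct_g1", ("small", "normal"))]
    print(f"%G1 small vs normal (quantile): mean diff {c.mean_diff:+.2f}, "
          f"Welch p = {c.welch_t_p:.2e}, Mann-Whitney p = "
          f"{c.mann_whitney_p:.2e}")

    for label, xb in (("10%", BIRTH_10), ("25%", BIRTH_25)):
        pct, rounded = association.birth_to_budding_increase(xb, BUDDING)
        print(f"birth-to-budding increase at the {label} cutoff: "
              f"{rounded}% ({pct:.1f}% unrounded, birth {xb} fl -> "
              f"budding {BUDDING} fl)")
    print(f"wrote association tables to {args.out}")


if __name__ == "__main__":
    main()
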