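"""Regenerate the screen's figure panels from the association outputs:
birth size vs mean size and vs fitness (scatter, categories coloured),
and %G1 by category (boxplots with the band at the group mean)."""

import argparse
from pathlib import Path

from birthsize import association, categories, distio, params, plots


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--out", type=Path, default=Path("results/figures"))
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
    results = []
    for assignments in by_scheme.values():
        for phenotype in association.PHENOTYPES:
            results += association.per_category_association(
                records, assignments, phenotype)
    paths = plots.save_association_figures(records, by_scheme, results,
                                           args.out)
    for p in paths:
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
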