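# Data directory

The published deletion-screen checks in `tests/test_acceptance.py` look
for the original supplementary spreadsheet here:

- `data/file_s1.xlsx` — the original deletion screen's supplementary
  dataset (the sheet named `asynchronous` holds the bins-by-strains
  count matrix; sizes in fl in the first column, one column per ORF).
  It is not redistributed with this package; obtain it from the
  original study's supporting information and place it here to enable
  those tests.

- `exclusion_list.txt` — template for the ORFs removed as abnormal
  profiles (one per line, `#` comments ignored). Populate it after
  curating the downloaded dataset; pass it via
  `birthsize params --exclude data/exclusion_list.txt ...` or the
  `support.exclusion_list` config key.
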