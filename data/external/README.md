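# Externally published reference data (not redistributed)

Two acceptance checks compare this package against files published in the
original reconciliation tool's public repository
(https://github.com/pitt-miskov-zivanov-lab/VIOLIN). Those files are not
redistributed here; download them into this directory to enable the checks
(any of `.tsv`, `.csv` or `.xlsx` is accepted):

- `baseline_a.*` — the larger curated baseline interaction table
  (179 nodes / 266 edges; 21 input and 9 output nodes).
- `baseline_b.*` — the smaller curated baseline interaction table
  (39 nodes / 70 edges; 5 input and 1 output node).
- `group5_baseline.*`, `group5_interactions.*`, `group5_expected.*` — the
  expert-labeled benchmark: its baseline table, the 831-interaction list,
  and the expert category labels (a column named `category`, `expected`
  or `label`).

Without these files the corresponding tests in `tests/test_acceptance.py`
fail with a pointer to this README; everything else in the suite is
self-contained.
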