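#!/usr/bin/env python
"""Clean the simulated cohort with the post-imputation QC preset: variant
call rate >= 0.95, MAF >= 0.01, tiered exact-HWE filters (1e-5 in both
strata, 1e-6 in controls, 1e-10 in cases), sample call rate >= 0.9 and
PI-HAT >= 0.1875 relatedness exclusion on an LD-pruned panel.

Reads results/cohort/, writes the filtered PLINK triplet and the per-step QC
report under results/qc/.
"""

from pathlib import Path

from epinet.io import read_plink, write_plink, write_results_tsv
from epinet.pipeline import _qc_report_rows
from epinet.qc import PRESETS, apply_qc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = read_plink(ROOT / "cohort" / "cohort")
    filtered, report = apply_qc(dataset, PRESETS["imputed"], min_overlap=100)
    out = ROOT / "qc"
    write_plink(filtered, out / "cohort_qc")
    rows, row_type = _qc_report_rows(report)
    write_results_tsv(rows, out / "qc_report.tsv", record_type=row_type)
    print(f"QC: {report.input_samples} -> {report.output_samples} samples, "
          f"{report.input_variants} -> {report.output_variants} variants")
    for step in report.steps:
        print(f"  {step['step']}: -{len(step['removed_variant_ids'])} variants, "
              f"-{len(step['removed_sample_ids'])} samples")


if __name__ == "__main__":
    main()
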