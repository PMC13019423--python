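#!/usr/bin/env python
"""Outlier QC on the raw spectra: reduced Hotelling T² vs reduced Q.

Reads results/spectra_raw.csv, writes the per-particle QC report and the
surviving spectra.  Flags are the union rule (either reduced statistic
above 1 at 95% confidence), on a PCA model holding 90% of the variance
of the mean-centered raw matrix.
"""

import argparse
from pathlib import Path

from evspec.qc import run_qc
from evspec.spectra_io import read_spectra, write_spectra


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    spectra = read_spectra(args.outdir / "spectra_raw.csv")
    report, survivors = run_qc(spectra)
    report.to_frame().to_csv(args.outdir / "qc_report.csv", index=False)
    write_spectra(survivors, args.outdir / "spectra_qc.csv")

    n_flag = int(report.flagged.sum())
    print(f"PCA model: {report.n_components} components at 95% confidence")
    print(f"flagged {n_flag} of {spectra.n} particles "
          f"({n_flag / spectra.n:.0%}); {survivors.n} survive")
    print(f"wrote qc_report.csv, spectra_qc.csv under {args.outdir}/")


if __name__ == "__main__":
    main()
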