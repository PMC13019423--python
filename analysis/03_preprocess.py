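#!/usr/bin/env python
"""Preprocess the QC survivors: iterative polynomial baseline correction
(order 5) followed by total-intensity normalisation, row by row."""

import argparse
from pathlib import Path

from evspec.preprocess import preprocess_pipeline
from evspec.spectra_io import read_spectra, write_spectra


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--order", type=int, default=5)
    args = ap.parse_args()

    spectra = read_spectra(args.outdir / "spectra_qc.csv")
    pre = preprocess_pipeline(spectra, order=args.order)
    write_spectra(pre, args.outdir / "spectra_preprocessed.csv")
    print(f"baseline-corrected and normalised {pre.n} spectra "
          f"(polynomial order {args.order}); every row now sums to 1")
    print(f"wrote spectra_preprocessed.csv under {args.outdir}/")


if __name__ == "__main__":
    main()
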