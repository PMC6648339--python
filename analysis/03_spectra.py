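#!/usr/bin/env python
"""Compare the 96-class spectra of the two mutational pathways.

Reads the spectrum tables produced by 02_process_reads.py, reports the
C>T fraction of every arm's spectrum and the pairwise cosine
similarities, and writes a summary table under results/spectra/.
The TLS arms put essentially all mass in C>T classes carried by the
purine strand component (A misinsertion read as G>A), and the two-hit
deamination arms concentrate in the deaminated dimer contexts.
"""

import glob
import os
import sys

import pandas as pd

from uvmut.pipeline import compare_spectra
from uvmut.spectrum import class_substitution

PIPE = os.path.join(os.path.dirname(__file__), "..", "results", "pipeline")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "spectra")


def main() -> int:
    paths = sorted(glob.glob(os.path.join(PIPE, "spectrum_*.tsv")))
    if not paths:
        print("run analysis/02_process_reads.py first", file=sys.stderr)
        return 1
    os.makedirs(OUT, exist_ok=True)
    named, rows = {}, []
    for path in paths:
        arm = os.path.basename(path)[len("spectrum_") : -len(".tsv")]
        df = pd.read_csv(path, sep="\t")
        total = df["combined_mean"].sum()
        ct = df.loc[
            [class_substitution(c) == "C>T" for c in df["class"]], "combined_mean"
        ].sum()
        pyr = df["pyr_mean"].sum()
        named[arm] = df["combined_mean"].to_numpy()
        rows.append(
            {
                "arm": arm,
                "total_mass_pct": total,
                "ct_fraction": ct / total if total else float("nan"),
                "pyrimidine_strand_fraction": pyr / total if total else float("nan"),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(OUT, "spectrum_summary.tsv"), sep="\t", index=False)
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    mat = compare_spectra(named)
    mat.to_csv(os.path.join(OUT, "cosine_matrix.tsv"), sep="\t")
    print("\npairwise cosine similarity:")
    print(mat.to_string(float_format=lambda x: f"{x:.3f}"))
    return 0


if __name__ == "__main__":
    sys.exit(main())
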