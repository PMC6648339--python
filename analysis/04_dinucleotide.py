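#!/usr/bin/env python
"""Dinucleotide analyses: CC>TT calls, 3' bias, deamination ratios.

Re-analyses the simulated reads in memory (event calling needs per-read
alignments, not just the frequency tables) and writes per-site CC>TT
frequencies, the 5'C/3'C single-transition bias at purine-flanked CC
sites, and the TpCpR-vs-RpCpT deamination ratio to
results/dinucleotide/.
"""

import glob
import os
import sys

from uvmut import pipeline as pl
from uvmut.amplicon import load_references
from uvmut.reads import parse_fastq

SIM = os.path.join(os.path.dirname(__file__), "..", "scratch", "sim")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "dinucleotide")

ARMS = [
    "first_hit_only:poldelta",
    "first_hit_only:poldelta_tls",
    "two_hit_complete:poldelta",
    "two_hit_complete:poldelta_tls",
    "unirradiated:poldelta",
    "unirradiated:poldelta_tls",
]


def main() -> int:
    if not os.path.isdir(SIM):
        print("run analysis/01_simulate_protocols.py first", file=sys.stderr)
        return 1
    os.makedirs(OUT, exist_ok=True)
    templates, layout = load_references(
        os.path.join(SIM, "references.fasta"), os.path.join(SIM, "annotations.tsv")
    )
    by_id = {t.template_id: t for t in templates}
    reads = {
        arm: parse_fastq(os.path.join(SIM, f"{arm.replace(':', '_')}.fastq"))
        for arm in ARMS
    }
    analyses = pl.analyze_arms(reads, templates)

    for arm in ("first_hit_only:poldelta", "first_hit_only:poldelta_tls"):
        d = pl.arm_dinucleotide_summary(analyses[arm], by_id)
        d.to_csv(
            os.path.join(OUT, f"cc_sites_{arm.replace(':', '_')}.tsv"),
            sep="\t", index=False,
        )
        print(
            f"{arm}: mean CC>TT {d.cc_tt_frequency.mean():.3f}% "
            f"(other multinucleotide subs {d.other_multi_sub_frequency.mean():.4f}%)"
        )
    bias = pl.arm_cc_bias(analyses["two_hit_complete:poldelta"], by_id)
    bias.to_csv(os.path.join(OUT, "cc_positional_bias.tsv"), sep="\t", index=False)
    if len(bias):
        print(
            f"two-hit Pol delta-only, RpCpCpR sites (n={len(bias)}): "
            f"5'C {bias.c_to_t_5prime.mean():.3f}%  3'C {bias.c_to_t_3prime.mean():.3f}%"
        )
    ratios = pl.arm_deamination_ratio(
        analyses["two_hit_complete:poldelta"],
        analyses["two_hit_complete:poldelta_tls"],
        by_id,
    )
    ratios.to_csv(os.path.join(OUT, "deamination_ratio.tsv"), sep="\t", index=False)
    print("\nPol delta-only / TLS C>T frequency ratio by template context:")
    print(ratios.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    return 0


if __name__ == "__main__":
    sys.exit(main())
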