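"""End-to-end orchestration: reads -> qualified pileups -> frequencies ->
spectra -> dinucleotide analyses -> similarity report.

The building blocks are usable in memory (tests, simulations) or through
``run_all`` on files.  Arms are named ``<protocol>:<mode>``; every arm is
paired with the unirradiated control of the same replication mode for
background subtraction unless an explicit pairing is given.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentScoring, build_pileup
from .amplicon import AmpliconLayout, TemplateSpec, find_dipyrimidine_sites, load_references
from .dinucleotide import (
    call_multinuc_events,
    cc_positional_bias,
    cc_tt_site_frequencies,
    deamination_ratio,
)
from .errors import ConfigurationError, DataError
from .frequency import FreqTable, aggregation_view, misincorporation_frequency, subtract_background
from .reads import QualifiedReadSet, ReadRecord, demultiplex, parse_fastq, qualify_reads
from .spectrum import MutSpectrum96, SignatureVector, build_spectrum, cosine_similarity


@dataclass
class SampleAnalysis:
    """Everything derived from one (arm, template) read bin."""

    template_id: str
    qset: QualifiedReadSet
    pileup: object
    freq: FreqTable  # raw per-position frequencies


@dataclass
class ArmAnalysis:
    arm: str
    samples: dict[str, SampleAnalysis]
    n_unassigned: int = 0
    adjusted: dict[str, FreqTable] = field(default_factory=dict)  # subtracted+aggregated
    spectrum: MutSpectrum96 | None = None


def process_arm(
    arm: str,
    reads: list[ReadRecord],
    templates: list[TemplateSpec],
    scoring: AlignmentScoring = AlignmentScoring(),
    min_mean_quality: float = 20.0,
    max_ambiguous: int = 2,
    max_barcode_mismatches: int = 0,
) -> ArmAnalysis:
    """Demultiplex one arm's reads by template barcode and qualify them."""
    layout = templates[0].layout
    table = {t.template_id: t.barcode for t in templates}
    bins = demultiplex(reads, table, layout.barcode_region, max_barcode_mismatches)
    by_id = {t.template_id: t for t in templates}
    samples = {}
    for tid, tmpl in by_id.items():
        qset = qualify_reads(
            bins.get(tid, []), tmpl, scoring, min_mean_quality, max_ambiguous
        )
        qset.rejection_counts["no_barcode"] = 0
        pileup = build_pileup(qset.aligned, tmpl.product_reference)
        freq = (
            misincorporation_frequency(pileup, sample_id=f"{arm}:{tid}", template_id=tid)
            if pileup.n_full_length
            else None
        )
        samples[tid] = SampleAnalysis(tid, qset, pileup, freq)
    return ArmAnalysis(arm=arm, samples=samples, n_unassigned=len(bins.get("unassigned", [])))


def default_control(arm: str) -> str:
    """Unirradiated control arm of the same replication mode."""
    mode = arm.rsplit(":", 1)[1] if ":" in arm else ""
    return f"unirradiated:{mode}" if mode else "unirradiated"


def analyze_arms(
    arm_reads: dict[str, list[ReadRecord]],
    templates: list[TemplateSpec],
    control_map: dict[str, str] | None = None,
    scoring: AlignmentScoring = AlignmentScoring(),
    **kwargs,
) -> dict[str, ArmAnalysis]:
    """Process all arms, subtract controls, restrict to the aggregation
    region, and build per-arm 96-class spectra."""
    layout = templates[0].layout
    by_id = {t.template_id: t for t in templates}
    analyses = {
        arm: process_arm(arm, reads, templates, scoring, **kwargs)
        for arm, reads in arm_reads.items()
    }
    for arm, ana in analyses.items():
        control_arm = (control_map or {}).get(arm, default_control(arm))
        if arm == control_arm or control_arm not in analyses:
            continue
        control = analyses[control_arm]
        for tid, sample in ana.samples.items():
            if sample.freq is None:
                raise DataError(
                    f"arm {arm!r} template {tid!r}: no qualified full-length products"
                )
            ctrl_freq = control.samples[tid].freq
            if ctrl_freq is None:
                raise DataError(
                    f"control arm {control_arm!r} template {tid!r}: "
                    "no qualified full-length products"
                )
            adj = subtract_background(sample.freq, ctrl_freq)
            ana.adjusted[tid] = aggregation_view(adj, layout)
        ana.spectrum = build_spectrum(list(ana.adjusted.values()), by_id, layout)
    return analyses


def compare_spectra(named: dict[str, object]) -> pd.DataFrame:
    """Symmetric cosine-similarity matrix over spectra / signatures / vectors.

    Zero vectors are excluded with a warning column left out of the matrix.
    """
    import warnings

    vecs = {}
    for name, obj in named.items():
        if isinstance(obj, MutSpectrum96):
            v = obj.vector()
        elif isinstance(obj, SignatureVector):
            v = obj.vector()
        else:
            v = np.asarray(obj, dtype=float)
        if np.linalg.norm(v) == 0:
            warnings.warn(f"spectrum {name!r} is all-zero; excluded", stacklevel=2)
            continue
        vecs[name] = v
    names = list(vecs)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            s = cosine_similarity(vecs[a], vecs[b])
            mat.loc[a, b] = s
            mat.loc[b, a] = s
    return mat


def arm_dinucleotide_summary(
    ana: ArmAnalysis, templates: dict[str, TemplateSpec]
) -> pd.DataFrame:
    """Per-CpC-site CC>TT / other multinucleotide frequencies for one arm."""
    rows = []
    for tid, sample in ana.samples.items():
        tmpl = templates[tid]
        sites = find_dipyrimidine_sites(tmpl)
        n_full = sample.pileup.n_full_length
        if n_full == 0:
            continue
        events = call_multinuc_events(sample.qset.aligned, sites, tmpl.product_reference)
        for summ in cc_tt_site_frequencies(events, n_full, sites, tmpl):
            rows.append(
                {
                    "arm": ana.arm,
                    "template_id": tid,
                    "t5": summ.site.five_prime,
                    "t3": summ.site.three_prime,
                    "cc_tt_frequency": summ.cc_tt_frequency,
                    "other_multi_sub_frequency": summ.other_multi_sub_frequency,
                    "purine_flanked": summ.purine_flanked,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "arm",
            "template_id",
            "t5",
            "t3",
            "cc_tt_frequency",
            "other_multi_sub_frequency",
            "purine_flanked",
        ],
    )


def arm_cc_bias(ana: ArmAnalysis, templates: dict[str, TemplateSpec]) -> pd.DataFrame:
    """Pooled 5'C/3'C single-transition bias at RpCpCpR sites (adjusted tables)."""
    frames = []
    for tid, adj in ana.adjusted.items():
        tmpl = templates[tid]
        df = cc_positional_bias(adj, tmpl, find_dipyrimidine_sites(tmpl))
        if len(df):
            frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["template_id", "t5", "t3", "c_to_t_5prime", "c_to_t_3prime"]
        )
    return pd.concat(frames, ignore_index=True)


def arm_deamination_ratio(
    ana_no_tls: ArmAnalysis,
    ana_tls: ArmAnalysis,
    templates: dict[str, TemplateSpec],
    floor: float = 0.05,
) -> pd.DataFrame:
    pairs = [
        (ana_no_tls.adjusted[tid], ana_tls.adjusted[tid], templates[tid])
        for tid in ana_no_tls.adjusted
        if tid in ana_tls.adjusted
    ]
    return deamination_ratio(pairs, floor=floor)


def accounting_frame(analyses: dict[str, ArmAnalysis]) -> pd.DataFrame:
    rows = []
    for arm, ana in analyses.items():
        for tid, s in ana.samples.items():
            row = {
                "arm": arm,
                "template_id": tid,
                "n_input": s.qset.n_input,
                "n_qualified": s.qset.n_qualified,
                "n_full_length": s.pileup.n_full_length,
            }
            row.update(
                {f"rej_{k}": v for k, v in sorted(s.qset.rejection_counts.items())}
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based run


@dataclass
class PipelineConfig:
    reads: dict[str, str]  # arm name -> FASTQ path
    reference_fasta: str
    annotation_tsv: str
    out_dir: str
    control_map: dict[str, str] = field(default_factory=dict)
    signatures: dict[str, str] = field(default_factory=dict)  # label -> TSV path
    genome_triplet_tsv: str | None = None
    min_mean_quality: float = 20.0
    max_ambiguous: int = 2
    max_barcode_mismatches: int = 0
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    seed: int = 0


@dataclass
class RunReport:
    accounting: pd.DataFrame
    cosine_matrix: pd.DataFrame
    out_dir: str
    config_hash: str
    paths: dict[str, str] = field(default_factory=dict)


def run_all(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline on files and persist every intermediate."""
    from .spectrum import load_signature, load_triplet_frequencies, normalize_signature

    os.makedirs(config.out_dir, exist_ok=True)
    templates, layout = load_references(config.reference_fasta, config.annotation_tsv)
    by_id = {t.template_id: t for t in templates}
    arm_reads = {arm: parse_fastq(path) for arm, path in config.reads.items()}
    analyses = analyze_arms(
        arm_reads,
        templates,
        control_map=config.control_map or None,
        scoring=config.scoring,
        min_mean_quality=config.min_mean_quality,
        max_ambiguous=config.max_ambiguous,
        max_barcode_mismatches=config.max_barcode_mismatches,
    )
    paths = {}
    acc = accounting_frame(analyses)
    acc_path = os.path.join(config.out_dir, "read_accounting.tsv")
    acc.to_csv(acc_path, sep="\t", index=False)
    paths["accounting"] = acc_path
    named: dict[str, object] = {}
    for arm, ana in analyses.items():
        safe = arm.replace(":", "_")
        for tid, sample in ana.samples.items():
            if sample.freq is not None:
                p = os.path.join(config.out_dir, f"freq_raw_{safe}_{tid}.tsv")
                sample.freq.to_tsv(p)
        for tid, adj in ana.adjusted.items():
            p = os.path.join(config.out_dir, f"freq_adjusted_{safe}_{tid}.tsv")
            adj.to_tsv(p)
        if ana.spectrum is not None:
            p = os.path.join(config.out_dir, f"spectrum_{safe}.tsv")
            ana.spectrum.to_tsv(p)
            paths[f"spectrum:{arm}"] = p
            named[arm] = ana.spectrum
        dinuc = arm_dinucleotide_summary(ana, by_id)
        if len(dinuc):
            p = os.path.join(config.out_dir, f"dinucleotide_{safe}.tsv")
            dinuc.to_csv(p, sep="\t", index=False)
            paths[f"dinucleotide:{arm}"] = p
    triplet_freqs = (
        load_triplet_frequencies(config.genome_triplet_tsv)
        if config.genome_triplet_tsv
        else None
    )
    for label, path in config.signatures.items():
        sig = load_signature(path, label=label)
        if triplet_freqs is not None:
            sig = normalize_signature(sig, triplet_freqs)
        named[label] = sig
    cosine = compare_spectra(named) if len(named) >= 2 else pd.DataFrame()
    cos_path = os.path.join(config.out_dir, "cosine_matrix.tsv")
    cosine.to_csv(cos_path, sep="\t")
    paths["cosine_matrix"] = cos_path
    cfg_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True
        ).encode()
    ).hexdigest()[:16]
    manifest = {
        "config_hash": cfg_hash,
        "arms": sorted(config.reads),
        "outputs": paths,
    }
    with open(os.path.join(config.out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return RunReport(
        accounting=acc, cosine_matrix=cosine, out_dir=config.out_dir,
        config_hash=cfg_hash, paths=paths,
    )


def reprocess_published(data_dir: str, out_dir: str) -> RunReport:
    """Reprocess a local copy of the study's deposited amplicon reads.

    Expects ``data_dir`` to contain ``references.fasta``,
    ``annotations.tsv`` and ``arms.tsv`` (columns: arm, fastq, control)
    describing the deposited per-arm FASTQ files.  The deposit itself is
    distributed separately and must be downloaded by the user.
    """
    refs = os.path.join(data_dir, "references.fasta")
    ann = os.path.join(data_dir, "annotations.tsv")
    arms_tsv = os.path.join(data_dir, "arms.tsv")
    for p in (refs, ann, arms_tsv):
        if not os.path.exists(p):
            raise FileNotFoundError(
                f"published-data manifest not found: {p}; download the deposited "
                "reads and template table, then lay them out as described in the "
                "reprocess_published docstring"
            )
    arms = pd.read_csv(arms_tsv, sep="\t")
    config = PipelineConfig(
        reads={r.arm: os.path.join(data_dir, r.fastq) for r in arms.itertuples()},
        reference_fasta=refs,
        annotation_tsv=ann,
        out_dir=out_dir,
        control_map={
            r.arm: r.control for r in arms.itertuples() if isinstance(r.control, str)
        },
    )
    return run_all(config)
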