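"""Strand-resolved 96-trinucleotide mutation spectra and comparisons.

The 96 classes are the six pyrimidine-centered substitutions (C>A, C>G,
C>T, T>A, T>C, T>G) crossed with the 16 flanking-base combinations,
ordered substitution-major / flanks alphabetical.  Because the assay
reads a defined strand, each class carries two components: the
*pyrimidine* component (the extending-strand reference base is C/T) and
the *purine* component (the complementary events, observed as purine
changes on the extending strand).  Genome sequencing cannot distinguish
the two; here they are tracked separately and stacked for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import AmpliconLayout, TemplateSpec, pyrimidine_centered_class
from .errors import DataError
from .frequency import FreqTable

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
FLANKS = "ACGT"

SPECTRUM_CLASSES: list[str] = [
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in FLANKS for f3 in FLANKS
]
_CLASS_INDEX = {c: i for i, c in enumerate(SPECTRUM_CLASSES)}


def class_label(triplet: str, substitution: str) -> str:
    return f"{triplet[0]}[{substitution}]{triplet[2]}"


def class_triplet(label: str) -> str:
    return label[0] + label[2] + label[-1]


def class_substitution(label: str) -> str:
    return label[2:5]


@dataclass
class MutSpectrum96:
    """Mean +- SD frequency per 96 class, with strand provenance.

    ``n_sites`` counts the template positions (across the pooled
    aggregation regions) whose pyrimidine-centered triplet matches the
    class triplet, in either orientation; the SD is computed across those
    per-site values (sites with zero frequency included).
    """

    table: pd.DataFrame  # index: class; pyr_mean pur_mean combined_mean sd n_sites ...
    provenance: list[str] = field(default_factory=list)
    excluded_positions: int = 0

    def vector(self, channel: str = "combined_mean") -> np.ndarray:
        return self.table[channel].to_numpy(dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.table["combined_mean"].sum())

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "class", out.index)
        out.to_csv(path, sep="\t", index=False)


def build_spectrum(
    freq_tables: list[FreqTable],
    templates: dict[str, TemplateSpec],
    layout: AmpliconLayout | None = None,
) -> MutSpectrum96:
    """Aggregate background-subtracted frequency tables into a 96 spectrum.

    Every position of every table contributes its three substitution
    frequencies to the classes of its triplet; zeros contribute to means
    and SDs.  Positions whose triplet would extend outside the sequenced
    read are excluded and counted.
    """
    pyr_vals: dict[str, list[float]] = {c: [] for c in SPECTRUM_CLASSES}
    pur_vals: dict[str, list[float]] = {c: [] for c in SPECTRUM_CLASSES}
    excluded = 0
    provenance = []
    for ft in freq_tables:
        provenance.append(ft.sample_id)
        tmpl = templates[ft.template_id]
        ref = tmpl.product_reference
        for pos in ft.data.index:
            refbase = ft.data.loc[pos, "ref_base"]
            if pos < 2 or pos > len(ref) - 1:
                excluded += 1
                continue
            for obs in "ACGT":
                if obs == refbase:
                    continue
                triplet, sub, strand = pyrimidine_centered_class(ref, pos, obs)
                label = class_label(triplet, sub)
                val = float(ft.data.loc[pos, obs])
                (pyr_vals if strand == "pyrimidine" else pur_vals)[label].append(val)
    rows = []
    for c in SPECTRUM_CLASSES:
        pv, uv = pyr_vals[c], pur_vals[c]
        pyr_mean = float(np.mean(pv)) if pv else 0.0
        pur_mean = float(np.mean(uv)) if uv else 0.0
        pooled = np.array(pv + uv, dtype=float)
        sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
        rows.append(
            {
                "pyr_mean": pyr_mean,
                "pur_mean": pur_mean,
                "combined_mean": pyr_mean + pur_mean,
                "sd": sd,
                "n_sites": pooled.size,
                "n_pyr": len(pv),
                "n_pur": len(uv),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(SPECTRUM_CLASSES, name="class"))
    return MutSpectrum96(table=table, provenance=provenance, excluded_positions=excluded)


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two spectrum vectors (inner product / norms)."""
    va = a.vector() if isinstance(a, MutSpectrum96) else np.asarray(a, dtype=float)
    vb = b.vector() if isinstance(b, MutSpectrum96) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise DataError(f"vector length mismatch: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise DataError("cosine similarity is undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


@dataclass
class SignatureVector:
    """An external 96-class signature (weights summing to 1)."""

    weights: pd.Series  # index: class labels in SPECTRUM_CLASSES order
    label: str = "signature"
    normalization: str = "raw"  # raw | genome-normalized

    def __post_init__(self) -> None:
        w = self.weights.reindex(SPECTRUM_CLASSES)
        if w.isna().any():
            missing = [c for c in SPECTRUM_CLASSES if c not in self.weights.index]
            raise DataError(f"signature {self.label!r} missing classes, e.g. {missing[:3]}")
        if (w < 0).any():
            raise DataError(f"signature {self.label!r} has negative weights")
        total = float(w.sum())
        if total <= 0:
            raise DataError(f"signature {self.label!r} has zero total weight")
        self.weights = w / total

    def vector(self) -> np.ndarray:
        return self.weights.to_numpy(dtype=float)


def normalize_signature(sig: SignatureVector, genome_triplet_freqs) -> SignatureVector:
    """Divide class weights by genome triplet frequencies and rescale to 1.

    ``genome_triplet_freqs`` maps each of the 32 pyrimidine-centered
    triplets to a positive frequency (mapping or pandas Series).
    """
    freqs = dict(genome_triplet_freqs)
    w = sig.weights.copy()
    for c in SPECTRUM_CLASSES:
        t = class_triplet(c)
        f = freqs.get(t)
        if f is None or f <= 0:
            raise DataError(f"genome triplet frequency for {t!r} must be positive")
        w[c] = w[c] / f
    return SignatureVector(weights=w, label=sig.label, normalization="genome-normalized")


def fraction_by_substitution(spec: MutSpectrum96) -> dict[str, float]:
    """Fraction of total spectrum mass in each of the six substitutions."""
    total = spec.total_mass
    if total <= 0:
        raise DataError("spectrum has zero total mass")
    out = {}
    for sub in SUBSTITUTIONS:
        mask = [class_substitution(c) == sub for c in spec.table.index]
        out[sub] = float(spec.table.loc[mask, "combined_mean"].sum()) / total
    return out


def load_signature(path, label: str | None = None) -> SignatureVector:
    df = pd.read_csv(path, sep="\t")
    return SignatureVector(
        weights=pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0]),
        label=label or str(path),
    )


def load_triplet_frequencies(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
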