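"""Forward simulator of UV mutagenesis protocols on defined templates.

Molecules are pushed through protocol steps — irradiation (first-order
dimer formation and photoreversion at dipyrimidine sites), incubation
(first-order deamination of dimer cytosines, C->U and 5mC->T),
CpG methylation, UDG treatment (monomerised uracils become abasic),
replication (high-fidelity Pol delta, optionally followed by TLS
polymerases applying the A-rule across unresolved dimers), and
sequencing with substitution and homopolymer-indel noise.  Two mutagenic
pathways emerge:

* **TLS pathway** — A insertion opposite dimer bases: error-free over
  T, mutagenic (C>T, and tandem CC>TT) over dimer cytosines;
* **deamination pathway** — dimer Cs deaminate during incubation; once
  the dimer is photoreverted, Pol delta copies the U (or T from 5mC)
  faithfully, producing TLS-independent C>T.

All rates are first-order; probabilities over a step of size ``x`` are
``1 - exp(-k x)`` (half-life form ``1 - 2^(-t/t_half)`` for deamination).
Simulation state is vectorised over molecules; every stochastic draw
goes through a seeded generator, so a config (including its seed)
reproduces byte-identical reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .amplicon import (
    AmpliconLayout,
    DipyrimidineSite,
    TemplateSpec,
    find_dipyrimidine_sites,
    reverse_complement,
)
from .errors import ConfigurationError
from .reads import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LesionModel:
    """Photochemistry and bypass parameters (all rates config-exposed).

    ``k_form_uvb`` is calibrated so that ~50% of molecules carry at least
    one dimer at 10 kJ/m^2 UVB on the seven-template fixture (the dose at
    which full-length Pol delta products drop ~50%); UVC is 10x as potent
    at dimer formation and far more effective at photoreversion.
    The 3'-slot deamination half-life sits in the fast 2-20 h range
    reported for dimer cytosines; the 5' slot is distinctly slower, as
    required jointly by the 3'-biased single transitions, the TC-over-CT
    deamination-ratio contrast, and the rarity of double deamination.
    TLS misinsertion probabilities are set so that per-site C>T at TpC
    dimer sites lands in the observed 1-4% range.
    """

    k_form_uvb: float = 0.0053  # dimer formation per kJ/m^2 per site (UVB)
    uvc_potency: float = 10.0  # formation multiplier for UVC
    k_rev_uvb: float = 0.02  # photoreversion per kJ/m^2 (UVB)
    k_rev_uvc: float = 0.5
    uu_reversion_multiplier: float = 1.0  # optional poorer reversion of UU dimers
    t_half_5prime: float = 60.0  # h; deamination of a dimer C in the 5' slot
    t_half_3prime: float = 8.0  # h; 3' slot (includes the C of a TC dimer)
    # in a CC dimer the two Cs compete; after one deaminates the partner's
    # rate is multiplied by this factor (double deamination is rare)
    partner_deamination_factor: float = 0.02
    p_mis_tc: float = 0.5  # P(A | TLS bypass of a dimer C with template T 5' of it)
    p_mis_other: float = 0.25
    polymerase_error_rate: float = 1e-5


@dataclass(frozen=True)
class SequencingModel:
    substitution_rate: float = 0.002
    homopolymer_indel_rate: float = 0.001  # per homopolymer run per read
    contaminant_fraction: float = 0.03  # template-extension products lacking 10G
    phred_quality: int = 30


@dataclass
class SimulationConfig:
    n_molecules: int = 20000  # per template per arm
    seed: int = 0
    lesion: LesionModel = field(default_factory=LesionModel)
    sequencing: SequencingModel = field(default_factory=SequencingModel)
    arms: dict[str, list[tuple]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# closed-form expectations (used by validation tests and reports)


def formation_probability(dose: float, wavelength: str, lesion: LesionModel) -> float:
    pot = {"UVB": 1.0, "UVC": lesion.uvc_potency}.get(wavelength)
    if pot is None:
        raise ConfigurationError(f"unknown wavelength {wavelength!r}")
    return 1.0 - math.exp(-lesion.k_form_uvb * pot * dose)


def reversion_probability(dose: float, wavelength: str, lesion: LesionModel) -> float:
    k = {"UVB": lesion.k_rev_uvb, "UVC": lesion.k_rev_uvc}.get(wavelength)
    if k is None:
        raise ConfigurationError(f"unknown wavelength {wavelength!r}")
    return 1.0 - math.exp(-k * dose)


def deamination_probability(hours: float, t_half: float) -> float:
    return 1.0 - 2.0 ** (-hours / t_half)


def replicable_sites(template: TemplateSpec) -> list[DipyrimidineSite]:
    """Dipyrimidine sites whose bases are both copied during extension."""
    v0 = template.layout.variable_region[0]
    return [
        s
        for s in find_dipyrimidine_sites(template)
        if s.read_positions is not None and s.read_positions[0] >= v0
    ]


def expected_block_fraction(
    template: TemplateSpec, dose: float, wavelength: str, lesion: LesionModel
) -> float:
    """P(molecule carries >=1 dimer) after one acute dose: 1 - prod(1 - p).

    Overlap exclusion does not perturb the >=1-dimer event, so the
    site-wise product formula is exact.
    """
    p = formation_probability(dose, wavelength, lesion)
    return 1.0 - (1.0 - p) ** len(replicable_sites(template))


def calibrate_k_form(
    templates: list[TemplateSpec],
    dose: float = 10.0,
    target_block_fraction: float = 0.5,
) -> float:
    """Solve k_form (UVB) so the mean blocked-molecule fraction hits the target."""
    from scipy.optimize import brentq

    counts = [len(replicable_sites(t)) for t in templates]

    def f(k):
        p = 1.0 - math.exp(-k * dose)
        return np.mean([(1.0 - p) ** c for c in counts]) - (1.0 - target_block_fraction)

    return float(brentq(f, 1e-8, 2.0))


def expected_first_hit_tls_ct(
    template: TemplateSpec, lesion: LesionModel, dose: float = 10.0, wavelength: str = "UVB"
) -> dict[int, float]:
    """Closed-form per-site C>T probability for a single-hit TLS arm.

    Restricted to dimer cytosines of *isolated* dipyrimidine sites (no
    overlapping neighbour site), where P(dimerised) equals the raw
    formation probability.  Keys are template positions of the C.
    """
    p_form = formation_probability(dose, wavelength, lesion)
    sites = replicable_sites(template)
    t5s = {s.five_prime for s in sites}
    t3s = {s.three_prime for s in sites}
    out: dict[int, float] = {}
    for s in sites:
        # a neighbour site sharing a base would be (t5-1, t5) or (t3, t3+1)
        isolated = s.five_prime not in t3s and s.three_prime not in t5s
        if not isolated:
            continue
        for tpos in s.template_positions:
            if template.template_base(tpos) != "C":
                continue
            prev = template.template_base(tpos - 1) if tpos > 1 else "N"
            p_mis = lesion.p_mis_tc if prev == "T" else lesion.p_mis_other
            out[tpos] = p_form * p_mis
    return out


# ---------------------------------------------------------------------------
# template fixtures

_PRIMER_SUFFIX = "ACTGTCAGGTCACT"  # primer positions 7-20; position 10 is the G marker


def _make_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    codes: list[str] = []
    while len(codes) < n:
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if all(sum(a != b for a, b in zip(cand, c)) >= 3 for c in codes):
            codes.append(cand)
    return codes


def generate_templates(
    n_templates: int = 7,
    seed: int = 0,
    template_length: int = 99,
    layout: AmpliconLayout | None = None,
    n_homopolymer_free: int = 4,
    methylate: bool = False,
) -> list[TemplateSpec]:
    """Build fixture templates with the assay architecture.

    Variable regions are random 53-mers; the first ``n_homopolymer_free``
    templates contain no homomultimers (no two equal adjacent bases), the
    rest are unconstrained.  Template 3' ends are the reverse complement
    of a per-template barcoded primer, except for the deliberate marker
    mismatch opposite primer position 10.
    """
    layout = layout or AmpliconLayout()
    rng = np.random.default_rng(seed)
    b0, b1 = layout.barcode_region
    barcodes = _make_barcodes(n_templates, b1 - b0 + 1, rng)
    primer_len = layout.primer_region[1]
    var_len = layout.variable_region[1] - layout.variable_region[0] + 1
    adaptor_len = template_length - primer_len - var_len
    if adaptor_len < 0:
        raise ConfigurationError("template_length shorter than the read region")
    templates = []
    for i in range(n_templates):
        tid = chr(ord("A") + i)
        primer = barcodes[i] + _PRIMER_SUFFIX
        assert primer[layout.marker_position - 1] == layout.marker_base
        if i < n_homopolymer_free:
            var = ["ACGT"[rng.integers(0, 4)]]
            while len(var) < var_len:
                b = "ACGT"[rng.integers(0, 4)]
                if b != var[-1]:
                    var.append(b)
            var = "".join(var)
        else:
            var = "".join("ACGT"[j] for j in rng.integers(0, 4, size=var_len))
        adaptor = "".join("ACGT"[j] for j in rng.integers(0, 4, size=adaptor_len))
        tail = list(reverse_complement(primer))
        # the template base opposite primer position 10 must not pair with
        # the marker G (perfect pairing would need a template C)
        tail[primer_len - layout.marker_position] = "T"
        # template coordinates 5'->3': adaptor | variable | primer-binding
        seq = adaptor + var + "".join(tail)
        tmpl = TemplateSpec(
            template_id=tid, template_sequence=seq, barcode=barcodes[i], layout=layout
        )
        if methylate:
            tmpl = replace(tmpl, methylated_positions=tmpl.cpg_positions())
        templates.append(tmpl)
    return templates


# ---------------------------------------------------------------------------
# per-arm vectorised simulation


class _ArmSimulator:
    """Vectorised lesion/deamination state for one template x one arm."""

    def __init__(self, template, n_molecules, lesion, rng):
        self.template = template
        self.n = n_molecules
        self.lesion = lesion
        self.rng = rng
        lay = template.layout
        L = template.template_length
        self.var_start = lay.variable_region[0]
        self.var_len = lay.variable_region[1] - lay.variable_region[0] + 1
        self.sites = replicable_sites(template)
        S = len(self.sites)
        self.t5 = np.array([s.five_prime for s in self.sites], dtype=int)
        self.t3 = np.array([s.three_prime for s in self.sites], dtype=int)
        # column index within the variable region, read order (3' template base first)
        self.col5 = (L - lay.primer_region[1]) - self.t5
        self.col3 = (L - lay.primer_region[1]) - self.t3
        seq = template.template_sequence
        self.isC5 = np.array([seq[t - 1] == "C" for t in self.t5])
        self.isC3 = np.array([seq[t - 1] == "C" for t in self.t3])
        # only a 3' C can be a CpG cytosine (the 5' C is followed by a pyrimidine)
        cpg = template.cpg_positions()
        self.cpg3 = np.array([t in cpg for t in self.t3]) if S else np.zeros(0, bool)
        prev5 = np.array([seq[t - 2] if t >= 2 else "N" for t in self.t5])
        self.p_mis5 = np.where(prev5 == "T", lesion.p_mis_tc, lesion.p_mis_other)
        prev3 = np.array([seq[t - 1] for t in self.t5])  # 5' partner base
        self.p_mis3 = np.where(prev3 == "T", lesion.p_mis_tc, lesion.p_mis_other)
        # overlap chains: consecutive sites sharing a base
        self.overlap_next = (
            (self.t3[:-1] == self.t5[1:]) if S > 1 else np.zeros(0, dtype=bool)
        )
        self.chains: list[list[int]] = []
        cur = [0] if S else []
        for i in range(S - 1):
            if self.overlap_next[i]:
                cur.append(i + 1)
            else:
                self.chains.append(cur)
                cur = [i + 1]
        if cur:
            self.chains.append(cur)
        self.dimer = np.zeros((self.n, S), dtype=bool)
        self.deam5 = np.zeros((self.n, S), dtype=bool)
        self.deam3 = np.zeros((self.n, S), dtype=bool)
        self.abasic5 = np.zeros((self.n, S), dtype=bool)
        self.abasic3 = np.zeros((self.n, S), dtype=bool)
        self.methylated = False

    # -- shared-position bookkeeping: the 3' base of site i can be the 5' base
    #    of site i+1; keep their deamination/abasic slots synchronised
    def _sync_shared(self):
        for i in np.nonzero(self.overlap_next)[0]:
            merged = self.deam3[:, i] | self.deam5[:, i + 1]
            self.deam3[:, i] = merged
            self.deam5[:, i + 1] = merged
            merged = self.abasic3[:, i] | self.abasic5[:, i + 1]
            self.abasic3[:, i] = merged
            self.abasic5[:, i + 1] = merged

    def methylate(self):
        self.methylated = True

    def irradiate(self, wavelength: str, dose: float):
        if dose < 0:
            raise ConfigurationError("dose must be >= 0")
        if dose == 0 or not self.sites:
            return
        les = self.lesion
        p_rev = reversion_probability(dose, wavelength, les)
        if les.uu_reversion_multiplier != 1.0:
            k = {"UVB": les.k_rev_uvb, "UVC": les.k_rev_uvc}[wavelength]
            p_rev_uu = 1.0 - math.exp(-k * les.uu_reversion_multiplier * dose)
            uu = self.deam5 & self.deam3
            p_rev_mat = np.where(uu, p_rev_uu, p_rev)
            revert = self.dimer & (self.rng.random(self.dimer.shape) < p_rev_mat)
        else:
            revert = self.dimer & (self.rng.random(self.dimer.shape) < p_rev)
        self.dimer &= ~revert
        # formation on free sites (positions not inside an existing dimer)
        p_form = formation_probability(dose, wavelength, les)
        occupied = self.dimer.copy()
        blocked = np.zeros_like(occupied)
        if len(self.overlap_next):
            idx = np.nonzero(self.overlap_next)[0]
            blocked[:, idx] |= occupied[:, idx + 1]
            blocked[:, idx + 1] |= occupied[:, idx]
        wants = (~occupied) & (~blocked) & (
            self.rng.random(self.dimer.shape) < p_form
        )
        priority = self.rng.random(self.dimer.shape)
        new = wants.copy()
        # resolve overlap conflicts by random sequential order within chains
        for chain in self.chains:
            if len(chain) < 2:
                continue
            sub = wants[:, chain]
            conflict_rows = np.nonzero(sub.sum(axis=1) >= 2)[0]
            for row in conflict_rows:
                order = sorted(
                    (c for c in chain if wants[row, c]),
                    key=lambda c: -priority[row, c],
                )
                taken = set(
                    c for c in chain if self.dimer[row, c]
                )
                accepted = []
                for c in order:
                    if any(
                        abs(c - a) == 1 and self.t3[min(c, a)] == self.t5[max(c, a)]
                        for a in list(taken) + accepted
                    ):
                        new[row, c] = False
                    else:
                        accepted.append(c)
        self.dimer |= new

    def incubate(self, hours: float):
        if hours < 0:
            raise ConfigurationError("hours must be >= 0")
        if hours == 0 or not self.sites:
            return
        les = self.lesion
        lam5 = math.log(2.0) / les.t_half_5prime
        lam3 = math.log(2.0) / les.t_half_3prime
        f = les.partner_deamination_factor
        shape = self.dimer.shape
        both_c = self.isC5[None, :] & self.isC3[None, :]
        # single-C dimers (TC / CT): plain first-order kinetics
        p5 = deamination_probability(hours, les.t_half_5prime)
        p3 = deamination_probability(hours, les.t_half_3prime)
        single5 = self.dimer & self.isC5[None, :] & ~both_c & ~self.deam5
        single3 = self.dimer & self.isC3[None, :] & ~both_c & ~self.deam3
        self.deam5 |= single5 & (self.rng.random(shape) < p5)
        self.deam3 |= single3 & (self.rng.random(shape) < p3)
        # CC dimers: the two Cs compete; the loser's rate is scaled by f
        fresh = self.dimer & both_c & ~self.deam5 & ~self.deam3
        lam_tot = lam5 + lam3
        t1 = self.rng.exponential(1.0 / lam_tot, size=shape)
        first = fresh & (t1 < hours)
        first_is_5 = self.rng.random(shape) < lam5 / lam_tot
        remaining = np.maximum(hours - t1, 0.0)
        # second event of a freshly-hit dimer, at the suppressed rate
        t2_after5 = self.rng.exponential(1.0 / max(lam3 * f, 1e-300), size=shape)
        t2_after3 = self.rng.exponential(1.0 / max(lam5 * f, 1e-300), size=shape)
        self.deam5 |= first & first_is_5
        self.deam3 |= first & ~first_is_5
        self.deam3 |= first & first_is_5 & (t2_after5 < remaining)
        self.deam5 |= first & ~first_is_5 & (t2_after3 < remaining)
        # CC dimers already carrying one deamination from an earlier step
        half5 = self.dimer & both_c & self.deam3 & ~self.deam5 & ~first
        half3 = self.dimer & both_c & self.deam5 & ~self.deam3 & ~first
        self.deam5 |= half5 & (self.rng.random(shape) < 1.0 - math.exp(-lam5 * f * hours))
        self.deam3 |= half3 & (self.rng.random(shape) < 1.0 - math.exp(-lam3 * f * hours))
        self._sync_shared()

    def udg(self):
        # uracils (deaminated C, not 5mC) outside a current dimer become abasic
        if self.methylated:
            meth3 = np.broadcast_to(self.cpg3[None, :], self.dimer.shape)
        else:
            meth3 = np.zeros_like(self.dimer)
        self.abasic5 |= self.deam5 & ~self.dimer
        self.abasic3 |= self.deam3 & ~self.dimer & ~meth3
        self._sync_shared()

    def replicate(self, mode: str):
        """Return (full_length mask, product byte matrix for full-length molecules)."""
        if mode not in ("poldelta", "poldelta_tls"):
            raise ConfigurationError(f"unknown replication mode {mode!r}")
        n, V = self.n, self.var_len
        in_dimer = np.zeros((n, V), dtype=bool)
        deam = np.zeros((n, V), dtype=bool)
        abasic = np.zeros((n, V), dtype=bool)
        for arr_site, col in (
            (self.dimer, self.col5),
            (self.dimer, self.col3),
        ):
            for s in range(len(self.sites)):
                in_dimer[:, col[s]] |= arr_site[:, s]
        for arr_site, col in ((self.deam5, self.col5), (self.deam3, self.col3)):
            for s in range(len(self.sites)):
                deam[:, col[s]] |= arr_site[:, s]
        for arr_site, col in ((self.abasic5, self.col5), (self.abasic3, self.col3)):
            for s in range(len(self.sites)):
                abasic[:, col[s]] |= arr_site[:, s]

        if mode == "poldelta":
            full = ~(in_dimer.any(axis=1) | abasic.any(axis=1))
            mutA = deam & ~in_dimer
        else:
            full = ~abasic.any(axis=1)
            mutA = deam.copy()
            mis = np.zeros((n, len(self.sites)), dtype=bool)
            for slot, (isC, deam_slot, p_mis, col) in enumerate(
                (
                    (self.isC5, self.deam5, self.p_mis5, self.col5),
                    (self.isC3, self.deam3, self.p_mis3, self.col3),
                )
            ):
                elig = self.dimer & isC[None, :] & ~deam_slot
                draw = self.rng.random(elig.shape) < p_mis[None, :]
                mis = elig & draw
                for s in range(len(self.sites)):
                    mutA[:, col[s]] |= mis[:, s]

        ref = np.frombuffer(
            self.template.product_reference.encode(), dtype=np.uint8
        ).copy()
        products = np.tile(ref, (int(full.sum()), 1))
        mutA_full = mutA[full]
        rows, cols = np.nonzero(mutA_full)
        products[rows, cols + self.var_start - 1] = ord("A")
        # baseline polymerase errors across the extended region
        perr = self.lesion.polymerase_error_rate
        if perr > 0 and products.size:
            err = self.rng.random((products.shape[0], V)) < perr
            er, ec = np.nonzero(err)
            if er.size:
                cur = products[er, ec + self.var_start - 1]
                cur_idx = np.searchsorted(_BASES, cur)
                shift = self.rng.integers(1, 4, size=er.size)
                products[er, ec + self.var_start - 1] = _BASES[(cur_idx + shift) % 4]
        return full, products


# ---------------------------------------------------------------------------
# sequencing


def _apply_homopolymer_indel(seq: str, rng: np.random.Generator) -> str:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j))
        i = j
    if not runs:
        return seq
    s, e = runs[rng.integers(0, len(runs))]
    if rng.random() < 0.5:
        return seq[:s] + seq[s] + seq[s:]  # insertion: run grows by one
    return seq[:s] + seq[s + 1 :]  # deletion: run shrinks by one


def sequence_reads(
    products: np.ndarray,
    template: TemplateSpec,
    seq_model: SequencingModel,
    rng: np.random.Generator,
    arm: str = "arm",
) -> list[ReadRecord]:
    """Emit FASTQ-ready reads: barcoded products plus optional contaminants.

    Contaminants emulate template-extension products: the same read
    except that the marker position shows the template base instead of
    the primer's deliberate mismatch.
    """
    n_products = products.shape[0] if products.size else 0
    frac = seq_model.contaminant_fraction
    n_cont = 0
    if frac > 0 and n_products:
        n_cont = int(rng.binomial(n_products, frac / (1.0 - frac)))
    reads_mat = products
    if n_cont:
        cont = np.frombuffer(
            reverse_complement(template.template_sequence)[
                : template.layout.read_length
            ].encode(),
            dtype=np.uint8,
        )
        reads_mat = np.vstack([products, np.tile(cont, (n_cont, 1))])
    reads_mat = reads_mat.copy()
    if seq_model.substitution_rate > 0 and reads_mat.size:
        err = rng.random(reads_mat.shape) < seq_model.substitution_rate
        er, ec = np.nonzero(err)
        if er.size:
            cur_idx = np.searchsorted(_BASES, reads_mat[er, ec])
            shift = rng.integers(1, 4, size=er.size)
            reads_mat[er, ec] = _BASES[(cur_idx + shift) % 4]
    total = reads_mat.shape[0] if reads_mat.size else 0
    qual = np.full(template.layout.read_length, seq_model.phred_quality, dtype=np.int16)
    out: list[ReadRecord] = []
    hp_rate = seq_model.homopolymer_indel_rate
    for i in range(total):
        seq = reads_mat[i].tobytes().decode()
        if hp_rate > 0:
            # per-run Bernoulli, approximated by one per-read draw scaled by run count
            n_runs = sum(
                1
                for k in range(1, len(seq))
                if seq[k] == seq[k - 1] and (k < 2 or seq[k - 1] != seq[k - 2])
            )
            if n_runs and rng.random() < 1.0 - (1.0 - hp_rate) ** n_runs:
                seq = _apply_homopolymer_indel(seq, rng)
        kind = "cont" if i >= n_products else "prod"
        q = qual if len(seq) == len(qual) else np.full(len(seq), seq_model.phred_quality, dtype=np.int16)
        out.append(
            ReadRecord(
                read_id=f"{arm}:{template.template_id}:{kind}:{i}",
                bases=seq,
                qualities=q,
            )
        )
    return out


# ---------------------------------------------------------------------------
# protocol driver


STANDARD_ARM_STEPS: dict[str, list[tuple]] = {
    "unirradiated": [],
    "first_hit_only": [("irradiate", "UVB", 10.0)],
    "two_hit_complete": [
        ("methylate",),
        ("irradiate", "UVB", 10.0),
        ("incubate", 48.0),
        ("irradiate", "UVC", 1.0),
    ],
    "two_hit_uvb_second": [
        ("methylate",),
        ("irradiate", "UVB", 10.0),
        ("incubate", 48.0),
        ("irradiate", "UVB", 10.0),
    ],
    "two_hit_no_incubation": [
        ("methylate",),
        ("irradiate", "UVB", 10.0),
        ("irradiate", "UVC", 1.0),
    ],
    "two_hit_no_second_hit": [
        ("methylate",),
        ("irradiate", "UVB", 10.0),
        ("incubate", 48.0),
    ],
    "six_cycles": [("methylate",)]
    + [("irradiate", "UVB", 10.0), ("incubate", 24.0)] * 6,
    "single_60": [("methylate",), ("irradiate", "UVB", 60.0)],
    "udg": [("methylate",)]
    + [("irradiate", "UVB", 10.0), ("incubate", 24.0)] * 6
    + [("udg",)],
}


def standard_arms(
    arm_names: list[str] | None = None,
    modes: tuple[str, ...] = ("poldelta", "poldelta_tls"),
) -> dict[str, list[tuple]]:
    """Cross named protocol arms with replication modes.

    Arm keys are ``<protocol>:<mode>``; every mode gets an unirradiated
    control arm for background subtraction.
    """
    names = arm_names or list(STANDARD_ARM_STEPS)
    if "unirradiated" not in names:
        names = ["unirradiated"] + names
    arms = {}
    for name in names:
        if name not in STANDARD_ARM_STEPS:
            raise ConfigurationError(f"undefined protocol arm {name!r}")
        for mode in modes:
            arms[f"{name}:{mode}"] = STANDARD_ARM_STEPS[name] + [("replicate", mode)]
    return arms


@dataclass
class ArmResult:
    arm: str
    reads: list[ReadRecord]
    ledger: pd.DataFrame  # realized pre-sequencing mutation counts
    n_molecules: dict[str, int]
    n_full_length: dict[str, int]


def run_arm(
    arm: str,
    steps: list[tuple],
    templates: list[TemplateSpec],
    config: SimulationConfig,
) -> ArmResult:
    reads: list[ReadRecord] = []
    ledger_rows = []
    n_mol = {}
    n_full = {}
    arm_index = sorted(config.arms).index(arm) if arm in config.arms else 0
    for ti, tmpl in enumerate(templates):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), arm_index, ti])
        )
        sim = _ArmSimulator(tmpl, config.n_molecules, config.lesion, rng)
        products = None
        for step in steps:
            op = step[0]
            if op == "methylate":
                sim.methylate()
            elif op == "irradiate":
                sim.irradiate(step[1], float(step[2]))
            elif op == "incubate":
                sim.incubate(float(step[1]))
            elif op == "udg":
                sim.udg()
            elif op == "replicate":
                full, products = sim.replicate(step[1])
            else:
                raise ConfigurationError(f"unknown protocol step {op!r}")
        if products is None:
            raise ConfigurationError(f"arm {arm!r} has no replicate step")
        n_mol[tmpl.template_id] = config.n_molecules
        n_full[tmpl.template_id] = int(products.shape[0])
        ref = np.frombuffer(tmpl.product_reference.encode(), dtype=np.uint8)
        if products.size:
            mism = products != ref[None, :]
            rows, cols = np.nonzero(mism)
            for col in np.unique(cols):
                obs = products[rows[cols == col], col]
                for b in np.unique(obs):
                    ledger_rows.append(
                        {
                            "arm": arm,
                            "template_id": tmpl.template_id,
                            "read_pos": int(col) + 1,
                            "ref_base": chr(ref[col]),
                            "obs_base": chr(b),
                            "count": int((obs == b).sum()),
                            "n_full_length": int(products.shape[0]),
                        }
                    )
        reads.extend(sequence_reads(products, tmpl, config.sequencing, rng, arm=arm))
    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "arm",
            "template_id",
            "read_pos",
            "ref_base",
            "obs_base",
            "count",
            "n_full_length",
        ],
    )
    return ArmResult(
        arm=arm, reads=reads, ledger=ledger, n_molecules=n_mol, n_full_length=n_full
    )


def run_protocol(
    config: SimulationConfig, templates: list[TemplateSpec]
) -> dict[str, ArmResult]:
    """Run every configured arm; deterministic given the config seed."""
    if not config.arms:
        raise ConfigurationError("no arms configured")
    return {
        arm: run_arm(arm, steps, templates, config)
        for arm, steps in sorted(config.arms.items())
    }


def write_protocol_outputs(results: dict[str, ArmResult], outdir) -> None:
    """Persist per-arm FASTQ and the ground-truth ledger TSV."""
    import os

    from .reads import write_fastq

    os.makedirs(outdir, exist_ok=True)
    ledgers = []
    for arm, res in results.items():
        write_fastq(res.reads, os.path.join(outdir, f"{arm.replace(':', '_')}.fastq"))
        ledgers.append(res.ledger)
    pd.concat(ledgers, ignore_index=True).to_csv(
        os.path.join(outdir, "ground_truth.tsv"), sep="\t", index=False
    )
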