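# Methods

## Reference system and coordinates

All coordinates are 1-based closed intervals.  Two systems are kept
distinct: *read positions* 1..73 on the sequenced product (the
extending strand, 5′→3′) and *template positions* 1..L on the
UV-exposed strand (5′→3′, L = 99 for the fixtures).  Because synthesis
runs 3′→5′ along the template, read position r pairs with template
position L + 1 − r.  The default layout is: primer #1–20 (barcode at
#1–6, marker G at #10), variable region #21–73, aggregation region
#22–71 (the position adjacent to the primer and the last two variable
positions are excluded; 50 nt per template, 350 nt pooled over seven
templates).

The product reference is the reverse complement of the template's 3′
portion with the barcode and the 10G marker substituted into the primer
region.  The marker is a deliberate primer–template mismatch, so a read
showing G at #10 derives from primer extension; template-extension
contaminants show the template base there and are excluded.  Marker
screening is applied after alignment, not at a raw string offset, so a
sequencer indel upstream of #10 cannot shift the marker out of
register.

## Read qualification

Quality screen: mean Phred ≥ 20, no ambiguous base in the primer
region, ≤ 2 elsewhere (the screen is part of the assay design; the
exact thresholds are this package's defaults and are config-exposed).  Barcode assignment
is by Hamming distance over the barcode region, default 0 mismatches,
ties always to the unassigned bin.  Qualified reads carry the 10G
marker; every frequency is expressed per *full-length* product — a read
whose alignment calls all 73 reference positions (deletions count as
calls, since the sequencing design already selects products carrying
both adaptors).

## Alignment

The reference is a fixed 73-mer, so reads are aligned with a bespoke
affine-gap Gotoh aligner rather than a general mapper: match +1,
mismatch −2, gap open −3, gap extend −1 (a gap of length k costs
−3 − k).  The read 5′ end is anchored; the read 3′ overhang (adaptor
remnant) is free once the reference is covered; a read that exhausts
itself early leaves the reference tail `not_covered`.  All scores are
integers, so traceback is exact; indels are left-aligned within
homopolymers (the convention shared with standard variant
normalisation); insertions are anchored to the reference position 5′ of
the insert and counted as events, not base calls.  The aligner is
tested for exact optimality against an exhaustive-enumeration oracle on
random small instances.  Reads whose direct mapping has ≤ 1 mismatch
skip the DP — a gapless alignment losing 3 per mismatch provably beats
any gapped alternative (minimum gap cost 4) in that regime.  Reads
scoring below 30 are rejected as unalignable.

## Frequencies and background subtraction

Misincorporation frequency = 100 × count / n_full_length, per position
and channel (A/C/G/T/deletion/insertion; insertions per anchor
position, same denominator).  The unirradiated arm of the same
replication mode is subtracted per position and channel.  Negative
adjusted values are clamped to zero for spectrum use — negative bars
have no physical meaning — while the signed difference is retained in a
separate channel for QC.  The same operation realises difference
spectra between two experimental arms (only the provenance labels
differ).

## The 96-class spectrum

Each aggregation-region position contributes its three substitution
frequencies to the classes of its pyrimidine-centered triplet; when the
extending-strand reference base is a purine, the triplet is
reverse-complemented and the substitution complemented, and the value
is tracked in the *purine strand component* (the assay distinguishes
complementary substitutions; genome sequencing cannot).  Per class, the
pyrimidine and purine components are averaged over their own
contributing sites (zero-frequency sites included) and the displayed
class value is their sum; the SD is computed across the pooled per-site
values (ddof = 1), matching the convention of averaging over triplet
occurrences rather than sequencing replicates.  n per class is the
triplet occurrence count; the counts over the 32 triplets partition the
350 pooled positions exactly.

Cosine similarity is the inner product over the product of norms of two
96-vectors; spectra enter via their combined-mean channel.  External
signatures are divided by user-supplied genome triplet frequencies and
rescaled to sum 1 before comparison.

## Dinucleotide analyses

A multinucleotide event requires *both* positions of a dipyrimidine
site to deviate from the reference in the same read (both substituted,
both deleted, or mixed — mixed is reported as its own class, a case the
source assay leaves undefined).  CC>TT is a CC site with both
extending-strand calls A (template-centric GG>AA).  The 5′C/3′C single-
transition bias is evaluated only at RpCpCpR sites (purine-flanked CC)
so a single dimer explains the signal.  The deamination ratio divides
the Pol δ-only C>T frequency by the TLS-arm frequency per template C in
TpCpR or RpCpT context; positions with TLS frequency below 0.05% (of
full-length products) are excluded to avoid division blow-ups (floor
config-exposed).

## The simulator

Molecules are vectorised over (molecule × dipyrimidine site).  Only
sites whose bases are both copied during extension (read positions
within the variable region) participate; dimers under the annealed
primer or in the unsequenced adaptor are outside the model.

**Irradiation.**  Existing dimers monomerise with probability
1 − exp(−k_rev(λ)·dose); free sites then dimerise with probability
1 − exp(−k_form·potency(λ)·dose).  A base can belong to at most one
dimer: within runs of overlapping sites, formation draws are resolved
in random sequential order.  This exclusion leaves the ≥1-dimer event
untouched, so P(blocked) = 1 − Π(1 − p) exactly — the formula the
Monte-Carlo tests check.  Defaults: k_form(UVB) calibrated so that
~50% of molecules carry a dimer at 10 kJ/m² UVB on the seven fixture
templates (`calibrate_k_form`, a deterministic scalar solve); UVC is
10× as potent at formation; k_rev(UVC) = 0.5 /kJ·m⁻², k_rev(UVB) =
0.02 /kJ·m⁻² (dimers absorb UVB poorly).  A multiplier for the
reversion of doubly-deaminated (UU) dimers is exposed but defaults to
1.

**Deamination.**  Only cytosines inside a *current* dimer deaminate
(monomeric deamination is negligible on experimental timescales):
C→U, 5mC→T, half-life form 1 − 2^(−t/t½).  Defaults: t½ = 8 h for the
3′ slot (including the C of a TC dimer) — inside the fast 2–20 h range
reported for dimer cytosines — and t½ = 60 h for the 5′ slot (the C of
a CT dimer and the 5′C of CC).  The slower 5′ slot is required jointly
by three observations the package reproduces: the 3′-biased single
transitions at CC sites, the higher Pol δ/TLS ratio at TpCpR than at
RpCpT (which vanishes if both contexts saturate during a 48 h
incubation), and the weakness of NpCpT classes in Pol δ-only spectra.
In a CC dimer the two cytosines compete as first-order rivals; after
the first deamination the partner's rate is multiplied by 0.02
(config-exposed), because double deamination of CC dimers is rare even
after days of incubation — this is what confines tandem CC>TT to the
TLS pathway.

**UDG.**  Every uracil outside a current dimer becomes abasic
(replication-blocking); thymine from 5mC deamination is untouched, so
after UDG the deamination pathway survives only at methylated CpG
sites.  CpG methylation is a protocol step; note that only the 3′ C of
a dipyrimidine can be a CpG cytosine (the 5′ C is followed by a
pyrimidine).

**Replication.**  Pol δ mode blocks at any unresolved dimer or abasic
site (no product); TLS mode applies the A-rule at dimers — A opposite
dimer T (correct), A opposite dimer U (mutation), A with probability
p_mis opposite dimer C (else correct G).  p_mis defaults to 0.5 when
the template base 5′ of the C is T and 0.25 otherwise; with ~5% per-site
dimer occupancy these produce per-site C>T of ~1–4% at TpC sites, the
scale the assay reports.  Monomerised U/T are copied faithfully
(producing the C>T / 5mC>T mutations); elsewhere a baseline polymerase
error of 1e-5 per base applies.

**Sequencing.**  Full-length products are emitted with a constant
Phred-30 quality, substitution errors at 0.002 per base, homopolymer
indels at 0.001 per run per read (±1 base, Ion-Torrent-like), and a 3%
admixture of template-extension contaminants lacking the 10G marker
(the assay reports 1–5%).  A ground-truth ledger of pre-noise mutation
counts per (template, position, base) supports exact recovery tests.

All stochastic steps draw from a generator seeded per (arm, template)
from the config seed; a config reproduces byte-identical FASTQ.

## What the synthetic data do and do not emulate

Emulated: the amplicon architecture (barcodes, 10G, adaptor remnants),
dose-response of blocking, wavelength asymmetry of formation and
reversion, context- and slot-dependent deamination, the two replication
modes, UDG, CpG methylation, and sequencer noise.  Not emulated:
wavelength spectra and the (6-4)-photoproduct/Dewar channel, NER or any
repair, TLS by Pol ι/κ/Rev1 (below quantifiable levels in the source
assay), quality-score realism, PCR (the assay sequences without
amplification), and template-sequence idiosyncrasies — the fixture
templates are random 53-mers with the same architecture, not the
study's actual sequences, so site counts (e.g. how many RpCpCpR sites
exist) are fixture properties and are never asserted as constants.
Passing round-trip tests therefore demonstrates that the pipeline
recovers what the generative model plants at realistic scale and noise;
it does not validate the photochemical parameter values themselves
against wet-lab data.

## Problem sizes and numerical conventions

Tests and the acceptance script run at 2,860–10,000 molecules per
template per arm (≈20,000 reads per fully-bypassed arm, mirroring the
qualified-read counts of a typical sample), with stochastic checks
asserted within 3 SE of closed forms, using variance terms for the
planted binomial plus sequencing noise where both contribute.
Deterministic conventions: alignment traceback prefers
match > deletion > insertion on ties; endpoint ties prefer full
reference coverage; demultiplexing ties go to unassigned; spectrum
classes are ordered substitution-major (C>A, C>G, C>T, T>A, T>C, T>G),
flanks alphabetical.

## Known limitations

The one-step irradiation model (revert, then form, within a single
dose) has no photo-steady-state: a very large single dose overshoots
dimer occupancy rather than converging to the formation/reversion
equilibrium, so doses far outside the protocol range (≫ 10 kJ/m² UVB
equivalents in one step) should not be interpreted quantitatively.
The deamination competition factor and the 5′-slot half-life are
calibrations chosen to reproduce the assay's qualitative contrasts, not
measured constants.  The pipeline reports means, SDs and ratios only;
significance testing between arms is out of scope.
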