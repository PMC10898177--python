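"""Synthetic genome and differential-table generator with ground truth.

The generator emits the exact dialects the reader consumes — genome FASTA,
Ensembl-style GTF, differential splicing-event and gene-expression TSVs —
plus a ground-truth TSV recording every injected effect, so the entire
analysis stack can be validated by parameter recovery.

Gene models are built from a base exon/intron chain whose every junction
carries generator-sampled splice signals: a 9-nt donor and 23-nt acceptor
site drawn from generator PWMs, a branchpoint heptamer planted at a
controlled distance from the acceptor, and a pyrimidine-rich tract between
the two.  Alternative isoforms (cassette exons, retained introns,
alternative first/last exons, alternative 5'/3' splice sites, mutually
exclusive exons) are defined over that chain.  Regulated event subsets
carry injected cis-feature shifts:

* splice-site strength shifts (in bits) realized by sampling sites from a
  temperature-tilted PWM, with the temperature calibrated so that the
  expected log-odds score changes by exactly the requested number of bits
  (the expectation is computed analytically, so the calibration is exact);
* branchpoint-distance shifts (nt) applied to the planted distance;
* GC shifts applied to the event region's background composition;
* intron-length scaling and a Beta-distributed position bias selecting
  which intron of the host gene is "retained".

All randomness flows from one numpy Generator seeded from the spec, so
identical (spec, seed) pairs produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from cisplice.annotation_io import (
    EVENT_COLUMNS,
    EXPRESSION_COLUMNS,
    GeneModel,
    SequenceAccessor,
    TranscriptModel,
    write_gtf,
)
from cisplice.cis_features import Pwm, shipped_branch_pwm

BASES = "ACGT"

# Generator donor PWM: 3 exonic + 6 intronic positions around the canonical
# (C/A)AG|GTAAGT junction; GT nearly invariant.
DONOR_PROBS = np.array(
    [
        [0.33, 0.36, 0.19, 0.12],
        [0.60, 0.13, 0.14, 0.13],
        [0.09, 0.04, 0.79, 0.08],
        [0.00167, 0.00167, 0.995, 0.00166],
        [0.00167, 0.00167, 0.00166, 0.995],
        [0.60, 0.04, 0.33, 0.03],
        [0.70, 0.08, 0.10, 0.12],
        [0.06, 0.05, 0.84, 0.05],
        [0.16, 0.15, 0.21, 0.48],
    ]
)

# Generator acceptor PWM: 20 intronic + 3 exonic positions — a moderately
# informative polypyrimidine stretch, a pyrimidine at -3, the invariant AG,
# and a G-biased first exonic base.
_PPT_ROW = [0.18, 0.25, 0.18, 0.39]
_MILD_ROW = [0.22, 0.28, 0.18, 0.32]
ACCEPTOR_PROBS = np.array(
    [_PPT_ROW] * 15
    + [_MILD_ROW] * 2
    + [[0.10, 0.35, 0.10, 0.45]]  # -3 pyrimidine
    + [[0.995, 0.00167, 0.00167, 0.00166]]  # invariant A
    + [[0.00167, 0.00167, 0.995, 0.00166]]  # invariant G
    + [[0.25, 0.15, 0.45, 0.15]]  # exon +1
    + [[0.25, 0.25, 0.25, 0.25]] * 2
)

# Composition of the polypyrimidine tract filled between branchpoint and
# acceptor; low adenosine keeps the planted branch A identifiable.
PPT_FILL = np.array([0.08, 0.30, 0.07, 0.55])


@dataclass(frozen=True)
class EffectProfile:
    """Injected cis-feature shifts for one regulated event class.

    Zero shifts / unit scale mean the class is drawn from the background
    (null) distribution.
    """

    ss3_shift_bits: float = 0.0
    ss5_shift_bits: float = 0.0
    bp_distance_shift_nt: float = 0.0
    gc_shift: float = 0.0
    intron_length_scale: float = 1.0
    position_beta: tuple[float, float] = (1.0, 1.0)

    @property
    def is_null(self) -> bool:
        return (
            self.ss3_shift_bits == 0.0
            and self.ss5_shift_bits == 0.0
            and self.bp_distance_shift_nt == 0.0
            and self.gc_shift == 0.0
            and self.intron_length_scale == 1.0
            and self.position_beta == (1.0, 1.0)
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated genome + regulated-event injection.

    Default effect sizes encode the study conditions recovered by the
    validation harness: up-regulated cassette exons with a 3'ss weakened by
    2 bits; down-regulated cassette exons with a 3'ss strengthened by 1 bit,
    a branchpoint 10 nt closer to the acceptor and GC lowered by 0.08;
    up-regulated retained introns at half the reference length with a
    Beta(3,1) (3'-biased) position within the transcription unit.
    """

    n_genes: int = 1300
    n_up_ec: int = 200
    n_down_ec: int = 200
    n_ref_ec: int = 500
    n_up_ir: int = 200
    n_ir_annot: int = 60
    n_misc_per_pattern: int = 10  # ALE, AFE, ALT5SS, ALT3SS, MXE hosts each
    intronless_fraction: float = 0.05

    # architecture distributions (log-normal, clipped)
    exon_len_log_mean: float = math.log(130.0)
    exon_len_log_sd: float = 0.35
    exon_len_range: tuple[int, int] = (60, 400)
    intron_len_log_mean: float = math.log(250.0)
    intron_len_log_sd: float = 0.55
    intron_len_range: tuple[int, int] = (90, 3000)
    intronless_len_log_mean: float = math.log(600.0)
    intronless_len_log_sd: float = 0.5

    # base composition per compartment (GC fractions)
    gc_exon: float = 0.52
    gc_intron: float = 0.42
    gc_intergenic: float = 0.40

    bp_distance_mean: float = 35.0
    bp_distance_sd: float = 6.0

    up_ec: EffectProfile = EffectProfile(ss3_shift_bits=-2.0)
    down_ec: EffectProfile = EffectProfile(
        ss3_shift_bits=1.0, bp_distance_shift_nt=-10.0, gc_shift=-0.08
    )
    up_ir: EffectProfile = EffectProfile(
        intron_length_scale=0.5, position_beta=(3.0, 1.0)
    )

    # expression model (baseline in log2 FPKM)
    expr_mean: float = 3.0
    expr_sd: float = 1.8
    as_expr_shift_log2: float = 1.0  # splicing-regulated genes sit higher
    n_ge_up: int = 150
    n_ge_down: int = 150
    ge_effect_log2fc: float = 1.0  # minimum |log2FC| of regulated genes
    ge_up_intronless_frac: float = 0.5

    genes_per_chrom: int = 300
    intergenic_gap: int = 200

    def required_hosts(self) -> int:
        return (
            self.n_up_ec
            + self.n_down_ec
            + self.n_ref_ec
            + self.n_up_ir
            + self.n_ir_annot
            + 5 * self.n_misc_per_pattern
        )

    def n_intronless(self) -> int:
        return min(
            round(self.intronless_fraction * self.n_genes),
            max(0, self.n_genes - self.required_hosts()),
        )

    def validate(self) -> None:
        if self.required_hosts() > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} cannot host "
                f"{self.required_hosts()} event genes"
            )
        if self.intron_len_range[0] < 80:
            raise ValueError("minimum intron length must be >= 80 nt to fit splice signals")

    @classmethod
    def sized(cls, n_genes: int, **overrides) -> "SyntheticSpec":
        """Scale the default regulated/reference set sizes to a genome of
        ``n_genes`` genes, keeping the default proportions."""
        base = cls()
        f = n_genes / base.n_genes
        spec = replace(
            base,
            n_genes=n_genes,
            n_up_ec=max(10, int(base.n_up_ec * f)),
            n_down_ec=max(10, int(base.n_down_ec * f)),
            n_ref_ec=max(20, int(base.n_ref_ec * f)),
            n_up_ir=max(10, int(base.n_up_ir * f)),
            n_ir_annot=max(5, int(base.n_ir_annot * f)),
            n_misc_per_pattern=max(2, int(base.n_misc_per_pattern * f)),
            n_ge_up=max(10, int(base.n_ge_up * f)),
            n_ge_down=max(10, int(base.n_ge_down * f)),
            **overrides,
        )
        spec.validate()
        return spec


def null_spec(**overrides) -> SyntheticSpec:
    """The type-I-error harness: identical structure, all effect sizes zero,
    so every "regulated" set is a random draw from the background."""
    null = EffectProfile()
    return replace(SyntheticSpec(), up_ec=null, down_ec=null, up_ir=null, **overrides)


# ---------------------------------------------------------------------------
# PWM tilting


def expected_logodds(probs: np.ndarray, background: np.ndarray | None = None) -> float:
    """Expected log2-odds score of a site sampled from its own PWM."""
    probs = np.asarray(probs, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lo = np.log2(probs / bg)
    return float((probs * lo).sum())


def _tilt(probs: np.ndarray, inv_temp: float) -> np.ndarray:
    q = probs**inv_temp
    return q / q.sum(axis=1, keepdims=True)


def tilt_pwm_to_shift(
    probs: np.ndarray, delta_bits: float, score_lo: np.ndarray | None = None
) -> np.ndarray:
    """Temperature-tilt a PWM so sites sampled from the tilted matrix score
    ``delta_bits`` higher/lower in expectation under the scoring matrix the
    analysis applies (``score_lo``; defaults to the original matrix's
    uniform-background log-odds).  Calibration is an exact analytic
    bisection on the inverse temperature.

    delta < 0 flattens toward uniform (weaker sites); delta > 0 sharpens
    toward the consensus (stronger sites).
    """
    probs = np.asarray(probs, dtype=float)
    if delta_bits == 0.0:
        return probs
    lo = np.log2(probs / 0.25) if score_lo is None else np.asarray(score_lo, float)

    def mean_score(inv_temp: float) -> float:
        return float((_tilt(probs, inv_temp) * lo).sum())

    target = mean_score(1.0) + delta_bits
    lo_bound, hi_bound = mean_score(1e-3), mean_score(60.0)
    if not (lo_bound - 1e-9 <= target <= hi_bound + 1e-9):
        raise ValueError(
            f"requested shift {delta_bits:+.2f} bits unattainable "
            f"(range {lo_bound - mean_score(1.0):+.2f} "
            f"to {hi_bound - mean_score(1.0):+.2f})"
        )
    lo_u, hi_u = 1e-3, 60.0
    for _ in range(200):
        mid = 0.5 * (lo_u + hi_u)
        if mean_score(mid) < target:
            lo_u = mid
        else:
            hi_u = mid
    return _tilt(probs, 0.5 * (lo_u + hi_u))


def _clipped_lognormal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    from scipy import stats as sstats

    dist = sstats.lognorm(s=sd, scale=math.exp(mu))
    mid = dist.expect(lb=lo, ub=hi)
    return lo * dist.cdf(lo) + mid + hi * dist.sf(hi)


def expected_genome_background(spec: "SyntheticSpec") -> np.ndarray:
    """Expected genome-wide base frequencies, from the spec's compartment
    compositions and expected compartment sizes (splice-signal and
    polypyrimidine skews are neglected)."""
    e_ex = _clipped_lognormal_mean(
        spec.exon_len_log_mean, spec.exon_len_log_sd, *spec.exon_len_range
    )
    e_in = _clipped_lognormal_mean(
        spec.intron_len_log_mean, spec.intron_len_log_sd, *spec.intron_len_range
    )
    e_il = _clipped_lognormal_mean(
        spec.intronless_len_log_mean, spec.intronless_len_log_sd, 150, 4000
    )
    n_plain6 = spec.n_up_ir + max(
        0, spec.n_genes - spec.required_hosts() - spec.n_intronless()
    )
    counts = {
        "cassette": (spec.n_up_ec + spec.n_down_ec + spec.n_ref_ec, 5),
        "plain6": (n_plain6, 6),
        "ir_annot": (spec.n_ir_annot, 3),
        "ale": (spec.n_misc_per_pattern, 4),
        "afe": (spec.n_misc_per_pattern, 4),
        "alt5": (spec.n_misc_per_pattern, 3),
        "alt3": (spec.n_misc_per_pattern, 3),
        "mxe": (spec.n_misc_per_pattern, 4),
    }
    exon_nt = sum(c * k * e_ex for c, k in counts.values()) + spec.n_intronless() * e_il
    intron_nt = sum(c * (k - 1) * e_in for c, k in counts.values())
    inter_nt = (spec.n_genes + 4) * spec.intergenic_gap
    total = exon_nt + intron_nt + inter_nt
    gc = (
        exon_nt * spec.gc_exon + intron_nt * spec.gc_intron + inter_nt * spec.gc_intergenic
    ) / total
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def expected_constitutive_junctions(spec: "SyntheticSpec") -> int:
    """Expected number of constitutive introns available for PWM training."""
    n_plain6 = spec.n_up_ir + max(
        0, spec.n_genes - spec.required_hosts() - spec.n_intronless()
    )
    return (
        2 * (spec.n_up_ec + spec.n_down_ec + spec.n_ref_ec)
        + 5 * n_plain6
        + spec.n_ir_annot
        + 4 * spec.n_misc_per_pattern  # ALE, AFE, ALT5SS, ALT3SS: one each
    )


def effective_score_matrix(
    probs: np.ndarray, n_train: int, background: np.ndarray
) -> np.ndarray:
    """The log-odds matrix the analysis will effectively score with: the
    generator matrix smoothed as if trained (pseudocount 1) on ``n_train``
    junctions, against the expected genome background."""
    p_hat = (n_train * np.asarray(probs, float) + 1.0) / (n_train + 4.0)
    return np.log2(p_hat / np.asarray(background, float))


# ---------------------------------------------------------------------------
# sequence sampling helpers


def _comp_probs(gc: float) -> np.ndarray:
    gc = min(max(gc, 0.02), 0.98)
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _fill(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    """n iid draws from a base distribution (inverse-CDF, vectorized)."""
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def _sample_site(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One site drawn position-wise from a (width, 4) PWM."""
    cum = np.cumsum(probs, axis=1)
    return (rng.random(probs.shape[0])[:, None] > cum).sum(axis=1)


_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# gene construction


@dataclass
class _GenePlan:
    role: str  # cassette | plain6 | ir_annot | ale | afe | alt5 | alt3 | mxe | intronless
    reg_class: str | None = None  # up_ec | down_ec | ref_ec | up_ir | None
    strand: str = "+"


@dataclass
class _BuiltGene:
    plan: _GenePlan
    sense_seq: np.ndarray
    exons_sense: list[tuple[int, int]]  # base chain, sense coords
    transcripts_sense: list[list[tuple[int, int]]]
    event_sense: tuple[int, int] | None  # variable region of the headline event
    event_pattern: str | None
    extra: dict = field(default_factory=dict)


def _intron_codes(
    rng, L: int, d_bp: int, donor_probs, acceptor_probs, branch_probs, gc_bg
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build one equipped intron: returns (intron codes, 3 exonic donor nt,
    3 exonic acceptor nt) — the exonic parts overwrite the flanking exons."""
    donor = _sample_site(rng, donor_probs)
    acceptor = _sample_site(rng, acceptor_probs)
    branch = _sample_site(rng, branch_probs)
    codes = _fill(rng, _comp_probs(gc_bg), L)
    codes[:6] = donor[3:]
    i = L - 1 - d_bp  # 0-based branch A index
    codes[i - 5 : i + 2] = branch
    codes[i + 2 : L - 20] = _fill(rng, PPT_FILL, L - 20 - (i + 2))
    codes[L - 20 :] = acceptor[:20]
    return codes, donor[:3], acceptor[20:]


def _draw_lengths(rng, spec: SyntheticSpec, n: int, kind: str) -> np.ndarray:
    if kind == "exon":
        mu, sd, (lo, hi) = spec.exon_len_log_mean, spec.exon_len_log_sd, spec.exon_len_range
    else:
        mu, sd, (lo, hi) = spec.intron_len_log_mean, spec.intron_len_log_sd, spec.intron_len_range
    return np.clip(np.round(rng.lognormal(mu, sd, n)).astype(int), lo, hi)


def _draw_bp_distance(rng, spec, L: int, shift: float = 0.0) -> int:
    d = int(round(rng.normal(spec.bp_distance_mean + shift, spec.bp_distance_sd)))
    return int(np.clip(d, 21, min(60, L - 14)))


_N_EXONS = {"cassette": 5, "plain6": 6, "ir_annot": 3, "ale": 4, "afe": 4,
             "alt5": 3, "alt3": 3, "mxe": 4}


def _build_gene(rng, spec: SyntheticSpec, plan: _GenePlan, tilts=None) -> _BuiltGene:
    role = plan.role
    if role == "intronless":
        L = int(np.clip(round(rng.lognormal(spec.intronless_len_log_mean,
                                            spec.intronless_len_log_sd)), 150, 4000))
        codes = _fill(rng, _comp_probs(spec.gc_exon), L)
        return _BuiltGene(plan, codes, [(0, L)], [[(0, L)]], None, None)

    n_exons = _N_EXONS[role]
    exon_lens = _draw_lengths(rng, spec, n_exons, "exon")
    intron_lens = _draw_lengths(rng, spec, n_exons - 1, "intron")
    if role in ("alt5", "alt3"):
        intron_lens[0 if role == "alt5" else 0] = max(intron_lens[0], 160)

    effect = EffectProfile()
    cassette_idx = 2  # internal exon of the 5-exon cassette hosts
    ir_intron_idx = None
    if plan.reg_class in ("up_ec", "down_ec", "ref_ec"):
        effect = {"up_ec": spec.up_ec, "down_ec": spec.down_ec,
                  "ref_ec": EffectProfile()}[plan.reg_class]
        if effect.gc_shift:
            pass  # applied below via per-compartment GC
    if plan.reg_class == "up_ir":
        effect = spec.up_ir
        # pick which intron is retained: a Beta-distributed position along
        # the transcription unit, snapped to the nearest intron *rank* (the
        # rank grid is length-independent, so a Beta(1,1) draw selects every
        # intron with equal probability)
        b = rng.beta(*effect.position_beta)
        fracs = (np.arange(n_exons - 1) + 0.5) / (n_exons - 1)
        ir_intron_idx = int(np.argmin(np.abs(fracs - b)))
        intron_lens[ir_intron_idx] = max(
            spec.intron_len_range[0],
            int(round(intron_lens[ir_intron_idx] * effect.intron_length_scale)),
        )

    # sense layout of the base chain
    exons, introns = [], []
    pos = 0
    for j in range(n_exons):
        exons.append((pos, pos + int(exon_lens[j])))
        pos += int(exon_lens[j])
        if j < n_exons - 1:
            introns.append((pos, pos + int(intron_lens[j])))
            pos += int(intron_lens[j])
    total = pos

    # per-compartment GC (event shifts applied to the cassette exon and its
    # flanking introns)
    exon_gc = [spec.gc_exon] * n_exons
    intron_gc = [spec.gc_intron] * (n_exons - 1)
    if role == "cassette" and effect.gc_shift:
        exon_gc[cassette_idx] += effect.gc_shift
        intron_gc[cassette_idx - 1] += effect.gc_shift
        intron_gc[cassette_idx] += effect.gc_shift

    # per-intron site PWMs (the cassette exon's 3'ss is the acceptor of its
    # upstream intron; its 5'ss the donor of its downstream intron)
    acc_probs = [ACCEPTOR_PROBS] * (n_exons - 1)
    don_probs = [DONOR_PROBS] * (n_exons - 1)
    bp_shift = [0.0] * (n_exons - 1)
    if role == "cassette":
        up_intron = cassette_idx - 1
        down_intron = cassette_idx
        if effect.ss3_shift_bits:
            acc_probs[up_intron] = tilts("acc", effect.ss3_shift_bits)
        if effect.ss5_shift_bits:
            don_probs[down_intron] = tilts("don", effect.ss5_shift_bits)
        bp_shift[up_intron] = effect.bp_distance_shift_nt
    if plan.reg_class == "up_ir":
        if effect.ss3_shift_bits:
            acc_probs[ir_intron_idx] = tilts("acc", effect.ss3_shift_bits)
        if effect.ss5_shift_bits:
            don_probs[ir_intron_idx] = tilts("don", effect.ss5_shift_bits)
        bp_shift[ir_intron_idx] = effect.bp_distance_shift_nt

    branch_probs = shipped_branch_pwm().probs
    seq = np.empty(total, dtype=np.int64)
    for j, (s, e) in enumerate(exons):
        seq[s:e] = _fill(rng, _comp_probs(exon_gc[j]), e - s)
    bp_distances = []
    for j, (s, e) in enumerate(introns):
        L = e - s
        d = _draw_bp_distance(rng, spec, L, bp_shift[j])
        bp_distances.append(d)
        codes, don_ex, acc_ex = _intron_codes(
            rng, L, d, don_probs[j], acc_probs[j], branch_probs, intron_gc[j]
        )
        seq[s:e] = codes
        seq[s - 3 : s] = don_ex  # last 3 nt of the upstream exon
        seq[e : e + 3] = acc_ex  # first 3 nt of the downstream exon

    # transcripts + headline event per role
    ev_sense = ev_pattern = None
    extra: dict = {}
    if role == "cassette":
        t1 = list(exons)
        t2 = [ex for j, ex in enumerate(exons) if j != cassette_idx]
        txs = [t1, t2]
        ev_sense, ev_pattern = exons[cassette_idx], "EC"
    elif role == "plain6":
        txs = [list(exons)]
        if plan.reg_class == "up_ir":
            ev_sense, ev_pattern = introns[ir_intron_idx], "IR"
            extra["ir_intron_idx"] = ir_intron_idx
    elif role == "ir_annot":
        t1 = list(exons)
        t2 = [exons[0], (exons[1][0], exons[2][1])]  # intron 1 retained
        txs = [t1, t2]
        ev_sense, ev_pattern = introns[1], "IR"
    elif role == "ale":
        txs = [[exons[0], exons[1], exons[2]], [exons[0], exons[1], exons[3]]]
        ev_sense, ev_pattern = exons[3], "ALE"
    elif role == "afe":
        txs = [[exons[0], exons[2], exons[3]], [exons[1], exons[2], exons[3]]]
        ev_sense, ev_pattern = exons[1], "AFE"
    elif role == "alt5":
        delta = int(rng.integers(12, 26))
        s0, e0 = introns[0]
        donor = _sample_site(rng, DONOR_PROBS)
        seq[s0 + delta - 3 : s0 + delta + 6] = donor
        long_exon = (exons[0][0], exons[0][1] + delta)
        txs = [[exons[0], exons[1], exons[2]], [long_exon, exons[1], exons[2]]]
        ev_sense, ev_pattern = (exons[0][1], exons[0][1] + delta), "ALT5SS"
    elif role == "alt3":
        delta = int(rng.integers(26, 41))
        s0, e0 = introns[0]
        acceptor = _sample_site(rng, ACCEPTOR_PROBS)
        seq[e0 - delta - 20 : e0 - delta] = acceptor[:20]
        seq[e0 - delta : e0 - delta + 3] = acceptor[20:]
        long_exon = (exons[1][0] - delta, exons[1][1])
        txs = [[exons[0], exons[1], exons[2]], [exons[0], long_exon, exons[2]]]
        ev_sense, ev_pattern = (exons[1][0] - delta, exons[1][0]), "ALT3SS"
    elif role == "mxe":
        txs = [[exons[0], exons[1], exons[3]], [exons[0], exons[2], exons[3]]]
        ev_sense, ev_pattern = exons[1], "MXE"
    else:  # pragma: no cover
        raise ValueError(role)

    extra["bp_distances"] = bp_distances
    extra["introns_sense"] = introns
    return _BuiltGene(plan, seq, exons, txs, ev_sense, ev_pattern, extra)


def _sense_to_genomic(interval, gene_start, total, strand):
    a, b = interval
    if strand == "+":
        return (gene_start + a, gene_start + b)
    return (gene_start + total - b, gene_start + total - a)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SyntheticBundle:
    """In-memory result of generate(): gene models, chromosome sequences,
    differential tables and the ground truth."""

    spec: SyntheticSpec
    seed: int
    genes: list[GeneModel]
    sequences: dict[str, str]
    events: pd.DataFrame
    expression: pd.DataFrame
    truth: pd.DataFrame

    def accessor(self) -> SequenceAccessor:
        return SequenceAccessor(self.sequences)

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "events": outdir / "events.tsv",
            "expression": outdir / "expression.tsv",
            "truth": outdir / "truth.tsv",
        }
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        with open(paths["fasta"], "w") as fh:
            seqio_write(records, fh, "fasta")
        write_gtf(self.genes, paths["gtf"])
        self.events.to_csv(paths["events"], sep="\t", index=False, float_format="%.6g")
        self.expression.to_csv(paths["expression"], sep="\t", index=False,
                               float_format="%.6g")
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
        return paths


def _plan_genes(rng, spec: SyntheticSpec) -> list[_GenePlan]:
    plans: list[_GenePlan] = []
    plans += [_GenePlan("cassette", "up_ec") for _ in range(spec.n_up_ec)]
    plans += [_GenePlan("cassette", "down_ec") for _ in range(spec.n_down_ec)]
    plans += [_GenePlan("cassette", "ref_ec") for _ in range(spec.n_ref_ec)]
    plans += [_GenePlan("plain6", "up_ir") for _ in range(spec.n_up_ir)]
    plans += [_GenePlan("ir_annot") for _ in range(spec.n_ir_annot)]
    for role in ("ale", "afe", "alt5", "alt3", "mxe"):
        plans += [_GenePlan(role) for _ in range(spec.n_misc_per_pattern)]
    plans += [_GenePlan("intronless") for _ in range(spec.n_intronless())]
    plans += [_GenePlan("plain6") for _ in range(spec.n_genes - len(plans))]
    order = rng.permutation(len(plans))
    strands = rng.random(len(plans)) < 0.5
    return [
        replace(plans[i], strand="-" if strands[k] else "+")
        for k, i in enumerate(order)
    ]


def generate(spec: SyntheticSpec, seed: int) -> SyntheticBundle:
    """Generate the full synthetic bundle for (spec, seed).

    Deterministic: identical arguments give byte-identical written files.
    Infeasible constraints raise before any sequence is emitted.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    plans = _plan_genes(rng, spec)

    # injected splice-site shifts are calibrated against the scoring matrix
    # the analysis will effectively use: trained (smoothed) probabilities
    # against the expected genome background
    eff_bg = expected_genome_background(spec)
    n_train = expected_constitutive_junctions(spec)
    _eff = {
        "acc": effective_score_matrix(ACCEPTOR_PROBS, n_train, eff_bg),
        "don": effective_score_matrix(DONOR_PROBS, n_train, eff_bg),
    }
    _base = {"acc": ACCEPTOR_PROBS, "don": DONOR_PROBS}
    _tilt_cache: dict = {}

    def tilts(kind: str, delta: float) -> np.ndarray:
        key = (kind, delta)
        if key not in _tilt_cache:
            _tilt_cache[key] = tilt_pwm_to_shift(_base[kind], delta, _eff[kind])
        return _tilt_cache[key]

    genes: list[GeneModel] = []
    chrom_parts: dict[str, list] = {}
    chrom_pos: dict[str, int] = {}
    truth_rows = []
    event_rows = []
    host_of_event: dict[str, str] = {}
    ev_counter = 0

    def _next_event_id():
        nonlocal ev_counter
        ev_counter += 1
        return f"EV{ev_counter:06d}"

    gap_probs = _comp_probs(spec.gc_intergenic)
    for gi, plan in enumerate(plans):
        chrom = f"chr{gi // spec.genes_per_chrom + 1}"
        if chrom not in chrom_parts:
            chrom_parts[chrom] = [_fill(rng, gap_probs, spec.intergenic_gap)]
            chrom_pos[chrom] = spec.intergenic_gap
        built = _build_gene(rng, spec, plan, tilts)
        total = built.sense_seq.size
        gene_start = chrom_pos[chrom]
        strand = plan.strand
        placed = built.sense_seq if strand == "+" else (3 - built.sense_seq)[::-1]
        chrom_parts[chrom].append(placed)
        chrom_parts[chrom].append(_fill(rng, gap_probs, spec.intergenic_gap))
        chrom_pos[chrom] = gene_start + total + spec.intergenic_gap

        gene_id = f"G{gi + 1:05d}"
        transcripts = []
        for ti, tx in enumerate(built.transcripts_sense):
            exons = sorted(
                _sense_to_genomic(ex, gene_start, total, strand) for ex in tx
            )
            transcripts.append(TranscriptModel(f"{gene_id}.T{ti + 1}", tuple(exons)))
        genes.append(GeneModel(gene_id, chrom, strand, tuple(transcripts)))

        if built.event_sense is None:
            continue
        ev_start, ev_end = _sense_to_genomic(built.event_sense, gene_start, total, strand)
        reg = plan.reg_class in ("up_ec", "down_ec", "up_ir")
        eid = _next_event_id()
        host_of_event[eid] = gene_id
        direction = {"up_ec": "up", "down_ec": "down", "up_ir": "up"}.get(
            plan.reg_class, "up"
        )
        effect = {"up_ec": spec.up_ec, "down_ec": spec.down_ec,
                  "up_ir": spec.up_ir}.get(plan.reg_class, EffectProfile())
        if reg:
            p_value = 10.0 ** rng.uniform(-8.0, math.log10(0.04))
            fold_change = 2.0 ** rng.uniform(1.0, 3.0)
        else:
            direction = "up" if rng.random() < 0.5 else "down"
            p_value = rng.uniform(0.0, 1.0)
            fold_change = 2.0 ** rng.uniform(0.0, 0.95)
        emit_row = reg or plan.reg_class == "ref_ec" or plan.role == "ir_annot"
        if emit_row:
            event_rows.append(
                dict(
                    event_id=eid, gene_id=gene_id, pattern=built.event_pattern,
                    chrom=chrom, start=ev_start, end=ev_end, strand=strand,
                    direction=direction, fold_change=fold_change, p_value=p_value,
                )
            )
        truth_rows.append(
            dict(
                event_id=eid, gene_id=gene_id, pattern=built.event_pattern,
                chrom=chrom, start=ev_start, end=ev_end, strand=strand,
                direction=direction if reg else "none", regulated=reg,
                in_event_table=emit_row,
                annotated=not (plan.reg_class == "up_ir"),
                ss3_shift_bits=effect.ss3_shift_bits if reg else 0.0,
                ss5_shift_bits=effect.ss5_shift_bits if reg else 0.0,
                bp_distance_shift_nt=effect.bp_distance_shift_nt if reg else 0.0,
                gc_shift=effect.gc_shift if reg else 0.0,
                intron_length_scale=effect.intron_length_scale if reg else 1.0,
                position_beta_a=effect.position_beta[0] if reg else 1.0,
                position_beta_b=effect.position_beta[1] if reg else 1.0,
            )
        )

    sequences = {
        chrom: decode(np.concatenate(parts)) for chrom, parts in chrom_parts.items()
    }
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    sig = (events["p_value"] <= 0.05) & (events["fold_change"] >= 2.0)
    as_hosts = {host_of_event[e] for e in events.loc[sig, "event_id"]}
    expression = _expression_table(rng, spec, genes, plans, as_hosts)
    return SyntheticBundle(spec, seed, genes, sequences, events, expression, truth)


def _expression_table(rng, spec, genes, plans, as_regulated_hosts) -> pd.DataFrame:
    n = len(genes)
    baseline = rng.normal(spec.expr_mean, spec.expr_sd, n)
    gene_ids = [g.gene_id for g in genes]
    intronless = np.array([p.role == "intronless" for p in plans])
    as_reg = np.array([gid in as_regulated_hosts for gid in gene_ids])
    baseline = baseline + spec.as_expr_shift_log2 * as_reg

    # GE-regulated sets: upregulated genes enriched for intronless/small genes
    free = ~as_reg
    idx_intronless = np.flatnonzero(intronless & free)
    idx_other = np.flatnonzero(~intronless & free)
    n_up_from_intronless = min(
        int(round(spec.n_ge_up * spec.ge_up_intronless_frac)), idx_intronless.size
    )
    up_idx = np.concatenate([
        rng.choice(idx_intronless, n_up_from_intronless, replace=False),
        rng.choice(idx_other, spec.n_ge_up - n_up_from_intronless, replace=False),
    ])
    remaining = np.setdiff1d(idx_other, up_idx)
    down_idx = rng.choice(remaining, min(spec.n_ge_down, remaining.size), replace=False)

    log2_fc = np.clip(rng.normal(0.0, 0.3, n), -0.99, 0.99)
    p = rng.uniform(0.0, 1.0, n)
    sig_p = lambda k: 10.0 ** rng.uniform(-8.0, math.log10(0.04), k)
    log2_fc[up_idx] = spec.ge_effect_log2fc + rng.exponential(0.8, up_idx.size)
    log2_fc[down_idx] = -(spec.ge_effect_log2fc + rng.exponential(0.8, down_idx.size))
    p[up_idx] = sig_p(up_idx.size)
    p[down_idx] = sig_p(down_idx.size)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2_fc": log2_fc,
            "p_value": p,
            "baseline_expr": baseline,
        }
    )[list(EXPRESSION_COLUMNS)]
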