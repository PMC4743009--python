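"""Mechanistic model of canonical (AG) versus cryptic (AG') acceptor choice.

The model encodes the two-regime view of 3'ss selection by the U2 snRNP:

* **WT regime** — U2 binds branchpoints promiscuously and the final acceptor
  choice is driven by U2AF recruitment: each usable acceptor ``a`` gets
  weight ``exp(u2af_affinity(a) / tau)``, where ``u2af_affinity = ppt *
  (1 + g_bonus * [plus-one base is G])`` captures the U2AF2 polypyrimidine
  preference and the U2AF1 AG-G motif preference.
* **MUT regime** — mutant SF3B1 imposes a stringent branchpoint requirement
  with a short BP-to-AG spacing (the 11-14 nt BP' geometry): each acceptor is
  weighted ``exp(best pairing score at MUT-valid spacing / tau)``.

A sample with mutant transcript fraction ``f`` mixes the two regimes
linearly: ``usage(f) = (1 - f) * WT + f * MUT``.

Two usability rules make abolished states representable. First, an acceptor
needs a branchpoint with pairing score >= ``s_floor`` in the regime's search
window, and a branchpoint cannot serve an acceptor when a rival candidate AG
lies between the branch A and that acceptor (the scanning constraint: the
first AG downstream of the branch is committed first). Second, an acceptor
whose best branchpoint pairs more than ``dominance_margin`` (one full
Watson-Crick pair by default) worse than the best branchpoint of any
competitor is outcompeted outright — this is what lets a perfect-consensus
canonical branchpoint extinguish AG' usage in both regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .branchpoint import BranchpointCandidate, enumerate_candidates, pairing_score
from .seq_context import window_index

__all__ = [
    "AcceptorCandidate",
    "SpliceChoicePrediction",
    "Mutation",
    "Construct",
    "ModelParams",
    "ModelError",
    "u2af_affinity",
    "predict_usage",
    "apply_mutations",
    "derive_acceptors",
    "mutagenesis_truth_table",
    "agprime_index",
    "tmem14c_like_construct",
    "enosf1_like_construct",
    "CONSTRUCT_PARAMS",
]


class ModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelParams:
    """Tunable knobs of the acceptor-choice model."""

    tau: float = 0.7
    g_bonus: float = 0.5
    s_floor: float = 3.0
    dominance_margin: float = 1.0
    #: promiscuous WT-regime search spans both canonical and short spacings
    wt_bp_window: tuple[int, int] = (-44, -9)
    mut_bp_window: tuple[int, int] = (-18, -9)
    min_dist: int = 6
    ppt_window: tuple[int, int] = (-20, -3)


@dataclass(frozen=True)
class AcceptorCandidate:
    """A candidate 3'ss: an AG dinucleotide with its local architecture.

    ``offset`` is relative to the reference (canonical) acceptor, 0 for the
    reference itself; ``bp_options`` hold branchpoint candidates with offsets
    relative to *this* acceptor.
    """

    offset: int
    plus_one: str
    ppt: float
    bp_options: tuple[BranchpointCandidate, ...] = ()

    def best_bp(self, window: tuple[int, int], s_floor: float) -> BranchpointCandidate | None:
        lo, hi = window
        pool = [
            b for b in self.bp_options
            if lo <= b.offset <= hi and b.pairing_score >= s_floor
        ]
        if not pool:
            return None
        return max(pool, key=lambda b: (b.pairing_score, b.ppt_score, -abs(b.offset)))


def u2af_affinity(candidate: AcceptorCandidate, g_bonus: float = 0.5) -> float:
    """U2AF recruitment strength: PPT content with an AG-G bonus."""
    bonus = 1.0 + g_bonus if candidate.plus_one.upper() == "G" else 1.0
    return candidate.ppt * bonus


@dataclass(frozen=True)
class SpliceChoicePrediction:
    """Per-acceptor usage fractions in each regime and at a mixture f_mut."""

    acceptors: tuple[AcceptorCandidate, ...]
    wt_usage: tuple[float, ...]
    mut_usage: tuple[float, ...]
    f_mut: float

    @property
    def usage(self) -> tuple[float, ...]:
        return tuple(
            (1.0 - self.f_mut) * w + self.f_mut * m
            for w, m in zip(self.wt_usage, self.mut_usage)
        )

    def usage_of(self, offset: int) -> float:
        for a, u in zip(self.acceptors, self.usage):
            if a.offset == offset:
                return u
        return 0.0

    @property
    def agprime_index(self) -> float | None:
        """AG'/AG usage ratio, where AG' is the most-used non-reference
        acceptor; +inf when AG usage is zero but AG' is used."""
        ag = self.usage_of(0)
        alts = [u for a, u in zip(self.acceptors, self.usage) if a.offset != 0]
        agp = max(alts) if alts else 0.0
        return agprime_index(agp, ag, infinite=True)


def agprime_index(agprime: float, ag: float, infinite: bool = False) -> float | None:
    """AG'/AG ratio; ``None`` (or +inf with ``infinite=True``) when AG is 0
    but AG' is positive, and ``None`` when both are 0."""
    if ag < 0 or agprime < 0:
        raise ValueError("usages/counts must be non-negative")
    if ag == 0:
        if agprime == 0:
            return None
        return math.inf if infinite else None
    return agprime / ag


def _softmax(scores: Sequence[float | None], tau: float) -> list[float]:
    live = [s for s in scores if s is not None]
    if not live:
        return [0.0] * len(scores)
    top = max(live)
    w = [math.exp((s - top) / tau) if s is not None else 0.0 for s in scores]
    z = sum(w)
    return [x / z for x in w]


def predict_usage(
    acceptors: Sequence[AcceptorCandidate],
    f_mut: float,
    params: ModelParams = ModelParams(),
) -> SpliceChoicePrediction:
    """Usage fractions over competing acceptors at mutant fraction ``f_mut``."""
    if not 0.0 <= f_mut <= 1.0:
        raise ValueError("f_mut must lie in [0, 1]")
    if not acceptors:
        raise ModelError("no acceptor candidates supplied")

    def mode_scores(window) -> list[float | None]:
        best = [a.best_bp(window, params.s_floor) for a in acceptors]
        scores = [b.pairing_score if b is not None else None for b in best]
        live = [s for s in scores if s is not None]
        if live:
            cutoff = max(live) - params.dominance_margin
            scores = [s if s is not None and s >= cutoff else None for s in scores]
        return scores

    wt_bp = mode_scores(params.wt_bp_window)
    mut_bp = mode_scores(params.mut_bp_window)
    if all(s is None for s in wt_bp) and all(s is None for s in mut_bp):
        raise ModelError("no acceptor has a usable branchpoint in either regime")

    wt_scores = [
        u2af_affinity(a, params.g_bonus) if s is not None else None
        for a, s in zip(acceptors, wt_bp)
    ]
    wt = _softmax(wt_scores, params.tau)
    mut = _softmax(mut_bp, params.tau)
    # a regime with no usable acceptor collapses onto the other's choice
    if all(s is None for s in wt_bp):
        wt = mut
    if all(s is None for s in mut_bp):
        mut = wt
    return SpliceChoicePrediction(
        acceptors=tuple(acceptors), wt_usage=tuple(wt), mut_usage=tuple(mut), f_mut=f_mut
    )


# ---------------------------------------------------------------------------
# Constructs and in-silico mutagenesis


@dataclass(frozen=True)
class Mutation:
    """A point substitution, e.g. ``Mutation(-17, "A", "G")`` for -17A>G.

    Positions are transcript oriented relative to the canonical AG
    (-1 = last intronic base; no position 0). The reference base is checked
    against the construct before substitution.
    """

    position: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Construct:
    """A minigene-like sequence: one intron 3' region plus downstream exon,
    transcript oriented, with the canonical AG at positions -2/-1."""

    sequence: str
    intron_len: int

    def __post_init__(self) -> None:
        if self.sequence[self.intron_len - 2 : self.intron_len] != "AG":
            raise ValueError("construct must carry AG at positions -2/-1")

    def index(self, pos: int) -> int:
        return window_index(pos, self.intron_len)

    def base(self, pos: int) -> str:
        return self.sequence[self.index(pos)]


def apply_mutations(construct: Construct, mutations: Iterable[Mutation]) -> Construct:
    """Substitute bases, checking each reference base first."""
    seq = list(construct.sequence)
    for m in mutations:
        i = construct.index(m.position)
        if seq[i] != m.ref.upper():
            raise ModelError(
                f"reference mismatch at position {m.position}: construct has "
                f"{seq[i]}, mutation says {m.ref}"
            )
        if m.ref.upper() == m.alt.upper():
            raise ModelError(f"position {m.position}: substitution equals reference")
        seq[i] = m.alt.upper()
    return Construct(sequence="".join(seq), intron_len=construct.intron_len)


def derive_acceptors(
    construct: Construct, params: ModelParams = ModelParams()
) -> list[AcceptorCandidate]:
    """Scan a construct for candidate acceptors and their branchpoints.

    Every intronic AG dinucleotide (including the reference at -2/-1) is a
    candidate; each gets a PPT fraction over ``params.ppt_window`` relative
    to itself and branchpoint options from the union of both regime windows,
    subject to the scanning constraint (no rival candidate AG between a
    branch A and the acceptor it would serve).
    """
    seq = construct.sequence.upper()
    n_int = construct.intron_len
    # acceptor offsets: x such that positions x-2, x-1 hold AG (x <= 0)
    offsets = []
    for x in range(0, -(n_int - 2), -1):
        a_i = n_int + x - 2
        if a_i < 0:
            break
        if seq[a_i : a_i + 2] == "AG":
            offsets.append(x)

    lo_all = min(params.wt_bp_window[0], params.mut_bp_window[0])
    ppt_lo, ppt_hi = params.ppt_window
    out = []
    for x in offsets:
        # transcript-oriented intron piece ending at this acceptor's -1
        end = n_int + x
        if end <= 0:
            continue
        intron_piece = seq[:end]
        cands = enumerate_candidates(
            intron_piece, min_dist=params.min_dist, max_dist=-lo_all
        )
        kept = []
        for b in cands:
            a_abs = x + b.offset  # branch A position relative to reference AG
            blocked = any(
                a_abs < (r - 2) and r < x for r in offsets if r != x
            )
            if not blocked:
                kept.append(b)
        # PPT over the acceptor's own upstream window
        idx = [end + p for p in range(ppt_lo, ppt_hi + 1)]
        idx = [i for i in idx if 0 <= i < len(seq)]
        ppt = sum(1 for i in idx if seq[i] in "CT") / len(idx) if idx else 0.0
        plus_one_i = n_int + x if x < 0 else n_int
        plus_one = seq[plus_one_i] if plus_one_i < len(seq) else "N"
        out.append(
            AcceptorCandidate(offset=x, plus_one=plus_one, ppt=ppt, bp_options=tuple(kept))
        )
    return out


_OUTCOME_EPS = 0.01


def _label(offset: int, base: SpliceChoicePrediction, mut: SpliceChoicePrediction,
           existed: bool) -> str:
    if not existed:
        return "new_site"
    b, m = base.usage_of(offset), mut.usage_of(offset)
    if b > _OUTCOME_EPS and m <= _OUTCOME_EPS:
        return "abolished"
    if m > b + _OUTCOME_EPS:
        return "strengthened"
    if abs(m - b) <= _OUTCOME_EPS:
        return "unchanged"
    if m > _OUTCOME_EPS:
        return "used"
    return "unchanged"


def mutagenesis_truth_table(
    construct: Construct,
    series: Mapping[str, Sequence[Mutation]],
    f_pair: tuple[float, float] = (0.0, 0.3),
    params: ModelParams = ModelParams(),
) -> dict[str, dict]:
    """Qualitative outcomes of a mutation series on a construct.

    For each named mutant, predictions are made at both mutant fractions of
    ``f_pair`` and every acceptor present in mutant or baseline is labelled
    (``used`` / ``abolished`` / ``strengthened`` / ``unchanged`` /
    ``new_site``); labels are taken at the high-f_mut member, with
    ``abolished`` requiring loss at *both* fractions.
    """
    base_acc = derive_acceptors(construct, params)
    if not any(a.offset == 0 for a in base_acc):
        raise ModelError("construct lacks the canonical acceptor")
    f_lo, f_hi = f_pair
    base_lo = predict_usage(base_acc, f_lo, params)
    base_hi = predict_usage(base_acc, f_hi, params)
    base_offsets = {a.offset for a in base_acc}

    out: dict[str, dict] = {}
    for name, muts in series.items():
        mutated = apply_mutations(construct, muts)
        acc = derive_acceptors(mutated, params)
        pred_lo = predict_usage(acc, f_lo, params)
        pred_hi = predict_usage(acc, f_hi, params)
        labels = {}
        for offset in sorted({a.offset for a in acc} | base_offsets):
            if offset not in {a.offset for a in acc}:
                labels[offset] = "abolished"
                continue
            lab = _label(offset, base_hi, pred_hi, offset in base_offsets)
            if lab == "abolished" and pred_lo.usage_of(offset) > _OUTCOME_EPS:
                lab = "used"  # lost only in the mutant regime
            labels[offset] = lab
        out[name] = {
            "labels": labels,
            "usage_low_f": {a.offset: u for a, u in zip(pred_lo.acceptors, pred_lo.usage)},
            "usage_high_f": {a.offset: u for a, u in zip(pred_hi.acceptors, pred_hi.usage)},
            "baseline_low_f": {a.offset: u for a, u in zip(base_lo.acceptors, base_lo.usage)},
            "baseline_high_f": {a.offset: u for a, u in zip(base_hi.acceptors, base_hi.usage)},
        }
    return out


# ---------------------------------------------------------------------------
# Synthetic constructs mirroring the validated minigene architectures


def _assemble_intron(pieces: Sequence[tuple[int, str]], intron_len: int = 60) -> str:
    """Lay out sequence pieces at transcript offsets onto a pyrimidine fill."""
    fill = list(("TC" * intron_len)[:intron_len])
    for start, text in pieces:
        for k, b in enumerate(text):
            fill[intron_len + start + k] = b
    return "".join(fill)


#: Parameters for the minigene constructs: the canonical branchpoint of the
#: TMEM14C-like architecture sits only 6 nt from its AG, so both regime
#: windows are relaxed to a 6-nt minimum spacing (the same relaxation the
#: upstream BP predictors need for these genes).
CONSTRUCT_PARAMS = ModelParams(wt_bp_window=(-44, -6), mut_bp_window=(-18, -6))


def tmem14c_like_construct() -> tuple[Construct, dict[str, tuple[Mutation, ...]]]:
    """A synthetic construct with the TMEM14C-like two-branchpoint layout.

    Architecture (offsets relative to the canonical AG): cryptic AG' at -16
    with a non-G +1 base; alternative branchpoint BP' serving the AG' at -13
    relative to the AG' (branch A at -29, heptamer ``CGCTAAC``, pairing 4.5,
    with two adjacent adenosines as in the endogenous gene); canonical BP at
    -6 (heptamer ``CGCTGAC``, pairing 4.0, a single adenosine); one neutral
    adenosine at -22. The sequence is synthetic — positions and relative
    branchpoint strengths, not the genomic sequence, are what is modelled.
    """
    intron = _assemble_intron(
        [
            (-34, "CGCTAAC"),  # BP' heptamer, branch A at -29
            (-27, "CCTCCATCC"),  # spacer carrying the neutral A at -22
            (-18, "AGC"),  # AG' dinucleotide + its +1 base (C)
            (-15, "TCCT"),
            (-11, "CGCTGAC"),  # BP heptamer, branch A at -6
            (-4, "TC"),
            (-2, "AG"),  # canonical acceptor
        ]
    )
    exon = "G" + "GTCCTGCTGGTCCTGCTGG"
    construct = Construct(sequence=intron + exon, intron_len=60)
    series = {
        "bp_prime_destroyed": (Mutation(-30, "A", "G"), Mutation(-29, "A", "G")),
        "bp_destroyed": (Mutation(-6, "A", "G"),),
        "ag_prime_destroyed": (Mutation(-18, "A", "G"),),
        "neutral_a": (Mutation(-22, "A", "G"),),
        "ag_prime_plus_one_g": (Mutation(-16, "C", "G"),),
        "bp_perfect": (Mutation(-11, "C", "T"), Mutation(-10, "G", "A"), Mutation(-7, "G", "A")),
        "bp_suboptimal": (Mutation(-8, "T", "C"),),
        "bp_swap": (Mutation(-30, "A", "G"), Mutation(-7, "G", "A")),
    }
    return construct, series


def enosf1_like_construct() -> tuple[Construct, dict[str, tuple[Mutation, ...]]]:
    """Variant with an AAG at the cryptic acceptor, whose middle-A mutation
    replaces the AG' by a new acceptor one base upstream (AAG > AGG)."""
    base, _ = tmem14c_like_construct()
    seq = list(base.sequence)
    seq[base.index(-19)] = "A"
    construct = Construct(sequence="".join(seq), intron_len=base.intron_len)
    series = {
        "ag_prime_shifted": (Mutation(-18, "A", "G"),),
    }
    return construct, series
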