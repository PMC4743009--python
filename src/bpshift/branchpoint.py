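"""Branchpoint candidate enumeration, U2 snRNA pairing score and assignment.

The branchpoint (BP) is an intronic adenosine, typically ~25 nt upstream of
the 3'ss, that base-pairs with the U2 snRNA branch-recognition sequence with
the branch A bulged out of the duplex. Candidates are scored by a transparent
pairing scheme over the heptamer around the branch A (positions A-5 .. A+1,
branch A fixed at heptamer position 6, 1-based — the UACUAAC convention):
the six non-bulged positions pair antiparallel with U2 bases A,U,G,A,U,G
(the GUAGUA region read 3'->5'); a Watson-Crick pair scores 1.0, a G.U
wobble 0.5, anything else 0. The consensus UACUAAC therefore scores 6.0.

This scoring scheme stands in for the SVM of dedicated BP predictors; its
values are on a 0-6 pairing scale, not an SVM decision-function scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .junction_io import AcceptorSite, extract_window

__all__ = [
    "BranchpointCandidate",
    "BranchAssignment",
    "pairing_score",
    "enumerate_candidates",
    "best_candidate",
    "assign_branchpoints",
    "bp_distance_distribution",
    "overlap_with_catalogue",
    "bp_motif_contrast",
    "BRANCH_POS",
    "HEPTAMER_LEN",
]

HEPTAMER_LEN = 7
#: 1-based heptamer position of the bulged branch adenosine.
BRANCH_POS = 6

# U2 partner base (RNA alphabet) for heptamer positions 1..5 and 7.
_U2_PARTNER = {1: "A", 2: "U", 3: "G", 4: "A", 5: "U", 7: "G"}

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

_PYRIMIDINES = frozenset("CTU")


@dataclass(frozen=True)
class BranchpointCandidate:
    """An adenosine upstream of a 3'ss, scored for U2 pairing and PPT context.

    ``offset`` locates the branch A relative to the 3'ss in transcript
    orientation (-1 = last intronic base), ``genomic_pos`` its genomic
    coordinate when known.
    """

    offset: int
    heptamer: str
    pairing_score: float
    ppt_score: float
    genomic_pos: int | None = None


@dataclass(frozen=True)
class BranchAssignment:
    """BP (canonical AG side) and BP' (AG' side) chosen for one alt-3' event."""

    event_id: str
    bp: BranchpointCandidate | None
    bp_prime: BranchpointCandidate | None

    @property
    def bp_unassigned(self) -> bool:
        return self.bp is None

    @property
    def bp_prime_unassigned(self) -> bool:
        return self.bp_prime is None


def pairing_score(heptamer: str, wobble_weight: float = 0.5) -> float:
    """U2 base-pairing potential of a branchpoint heptamer, in [0, 6].

    T and U spellings are equivalent. Raises if the heptamer is not 7 letters
    or position 6 is not the branch adenosine.
    """
    h = heptamer.upper().replace("T", "U")
    if len(h) != HEPTAMER_LEN:
        raise ValueError(f"heptamer must have length 7, got {len(h)}")
    if h[BRANCH_POS - 1] != "A":
        raise ValueError(f"heptamer position {BRANCH_POS} must be the branch A: {heptamer!r}")
    score = 0.0
    for pos, partner in _U2_PARTNER.items():
        pair = (h[pos - 1], partner)
        if pair in _WC:
            score += 1.0
        elif pair in _WOBBLE:
            score += wobble_weight
    return score


def pyrimidine_content(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for b in seq.upper() if b in _PYRIMIDINES) / len(seq)


def enumerate_candidates(
    intron_seq: str,
    min_dist: int = 6,
    max_dist: int = 100,
    wobble_weight: float = 0.5,
    offset_to_genomic=None,
) -> list[BranchpointCandidate]:
    """All adenosine candidates in ``[-max_dist, -min_dist]`` of a 3'ss.

    ``intron_seq`` is the transcript-oriented intronic sequence ending at the
    acceptor: its last character is position -1. The heptamer of a candidate
    at offset ``o`` covers positions ``o-5 .. o+1``; candidates whose heptamer
    would run off the supplied sequence are skipped. ``offset_to_genomic`` may
    map an offset to a genomic coordinate for bookkeeping.
    """
    n = len(intron_seq)
    seq = intron_seq.upper()
    out: list[BranchpointCandidate] = []
    for offset in range(-min(max_dist, n), -min_dist + 1):
        idx = n + offset
        if seq[idx] != "A":
            continue
        lo, hi = idx - 5, idx + 2
        if lo < 0 or hi > n:
            continue
        heptamer = seq[lo:hi]
        ppt = pyrimidine_content(seq[idx + 1 :])
        out.append(
            BranchpointCandidate(
                offset=offset,
                heptamer=heptamer,
                pairing_score=pairing_score(heptamer, wobble_weight),
                ppt_score=ppt,
                genomic_pos=offset_to_genomic(offset) if offset_to_genomic else None,
            )
        )
    return out


def best_candidate(
    candidates: Iterable[BranchpointCandidate],
    window: tuple[int, int],
    prior_center: float,
) -> BranchpointCandidate | None:
    """Highest-pairing candidate within ``window`` (inclusive offsets).

    Ties break by higher polypyrimidine score, then by proximity to the
    distance prior, then toward the more upstream (more negative) offset.
    """
    lo, hi = window
    pool = [c for c in candidates if lo <= c.offset <= hi]
    if not pool:
        return None
    return min(
        pool,
        key=lambda c: (
            -c.pairing_score,
            -c.ppt_score,
            abs(c.offset - prior_center),
            c.offset,
        ),
    )


def assign_branchpoints(
    event,
    genome,
    bp_window_ag: tuple[int, int] = (-44, -16),
    bpprime_window: tuple[int, int] = (-18, -9),
    min_dist: int = 6,
    max_dist: int = 100,
    bp_prior: float = -25.0,
    bpprime_prior: float = -12.5,
    wobble_weight: float = 0.5,
) -> BranchAssignment:
    """Assign BP (for the canonical AG) and BP' (for the AG') of an alt-3' event.

    ``event`` needs ``event_id``, ``event_class == "alt3"`` and the two
    :class:`~bpshift.junction_io.AcceptorSite` attributes ``canonical_site``
    and ``alternative_site``. Sides with no adenosine in their search window
    are flagged unassigned.
    """
    if getattr(event, "event_class", "alt3") != "alt3":
        raise ValueError(f"{event.event_id}: branchpoints are assigned for alt3 events only")

    def side(site: AcceptorSite, window, prior):
        flank = max(max_dist + 6, -window[0] + 6)
        seq = extract_window(genome, site, intron_flank=flank, exon_flank=0)
        cands = enumerate_candidates(
            seq,
            min_dist=min_dist,
            max_dist=max_dist,
            wobble_weight=wobble_weight,
            offset_to_genomic=site.genomic,
        )
        return best_candidate(cands, window, prior)

    bp = side(event.canonical_site, bp_window_ag, bp_prior)
    bpp = side(event.alternative_site, bpprime_window, bpprime_prior)
    return BranchAssignment(event_id=event.event_id, bp=bp, bp_prime=bpp)


def bp_distance_distribution(
    assignments: Sequence[BranchAssignment],
    insensitive: Sequence[BranchpointCandidate] = (),
) -> dict[str, dict]:
    """Histograms of |branch A to 3'ss| distances per side, with modes.

    Returns a mapping with keys ``ag_prime`` (BP' relative to AG'), ``ag``
    (BP relative to AG) and ``insensitive``; each value holds an integer
    ``histogram`` Counter over distances and the ``mode`` (smallest distance
    on ties; ``None`` when empty).
    """
    sides = {
        "ag": [a.bp.offset for a in assignments if a.bp is not None],
        "ag_prime": [a.bp_prime.offset for a in assignments if a.bp_prime is not None],
        "insensitive": [c.offset for c in insensitive],
    }
    out = {}
    for name, offsets in sides.items():
        hist = Counter(-o for o in offsets)
        mode = None
        if hist:
            mode = min(hist, key=lambda d: (-hist[d], d))
        out[name] = {"histogram": dict(sorted(hist.items())), "mode": mode, "n": len(offsets)}
    return out


def overlap_with_catalogue(
    agprime_a_positions: Sequence[tuple[str, int, str]],
    catalogue: Sequence[tuple[str, int, str]],
    upstream_window: int = 50,
) -> dict:
    """Coincidence of catalogued BP adenosines with the A of AG' dinucleotides.

    ``agprime_a_positions`` are ``(chrom, genomic position of the AG' A,
    strand)``; a site *coincides* when a catalogue entry sits at exactly that
    base on the same strand. For non-coincident sites with a catalogue BP
    within ``upstream_window`` nt upstream (transcript orientation), the mean
    upstream offset is reported.
    """
    cat = set(catalogue)
    by_chrom: dict[tuple[str, str], set[int]] = {}
    for chrom, pos, strand in catalogue:
        by_chrom.setdefault((chrom, strand), set()).add(pos)

    n_coincident = 0
    n_with_bp = 0
    upstream_offsets = []
    for chrom, pos, strand in agprime_a_positions:
        positions = by_chrom.get((chrom, strand), set())
        if (chrom, pos, strand) in cat:
            n_coincident += 1
            n_with_bp += 1
            continue
        # nearest catalogued BP upstream of the AG' A
        step = -1 if strand == "+" else 1
        found = None
        for d in range(1, upstream_window + 1):
            if pos + step * d in positions:
                found = d
                break
        if found is not None:
            n_with_bp += 1
            upstream_offsets.append(found)
    fraction = n_coincident / n_with_bp if n_with_bp else None
    return {
        "n_total": len(agprime_a_positions),
        "n_with_catalogue_bp": n_with_bp,
        "n_coincident": n_coincident,
        "coincident_fraction": fraction,
        "mean_upstream_offset": float(np.mean(upstream_offsets)) if upstream_offsets else None,
    }


def bp_motif_contrast(
    canonical: Sequence[str],
    alternative: Sequence[str],
    insensitive: Sequence[str],
) -> "pd.DataFrame":
    """Per-position 3x4 chi-square contrast of BP heptamer composition.

    Positions are reported both in heptamer indexing (1..7, branch A at 6)
    and in the alternative labelling that places the branch A at +5
    (``labelled_pos = pos - 1``).
    """
    import pandas as pd

    groups = {"canonical": canonical, "alternative": alternative, "insensitive": insensitive}
    for name, seqs in groups.items():
        if len(seqs) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    bases = "ACGT"
    for pos in range(1, HEPTAMER_LEN + 1):
        table = []
        for seqs in groups.values():
            col = Counter(s.upper().replace("U", "T")[pos - 1] for s in seqs)
            table.append([col.get(b, 0) for b in bases])
        table = np.asarray(table)
        keep = table.sum(axis=0) > 0
        trimmed = table[:, keep]
        if trimmed.shape[1] < 2 or np.any(trimmed.sum(axis=1) == 0):
            stat, p, dof = 0.0, 1.0, 0
        else:
            stat, p, dof, _ = stats.chi2_contingency(trimmed, correction=False)
        rows.append(
            {
                "heptamer_pos": pos,
                "branch_a_plus5_pos": pos - 1,
                "chi2": float(stat),
                "p_value": float(p),
                "dof": int(dof),
            }
        )
    return pd.DataFrame(rows)
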