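"""Sequence context statistics around splice acceptors.

Windows are transcript oriented with ``intron_flank`` intronic and
``exon_flank`` exonic nucleotides (default 50 + 50, i.e. a 100-nt window
with the AG dinucleotide at its centre); logo-style position probability
matrices use raw frequencies (probability units) unless a Laplace
pseudocount is requested for rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .junction_io import AcceptorSite, WindowError, extract_window

__all__ = [
    "PositionMatrix",
    "window_index",
    "build_matrix",
    "plus_one_composition",
    "pyrimidine_fraction",
    "composition_contrast",
]

_BASES = "ACGT"


def window_index(pos: int, intron_flank: int) -> int:
    """String index of transcript position ``pos`` in an extracted window."""
    if pos == 0:
        raise ValueError("position 0 does not exist (+1/-1 convention)")
    return intron_flank + pos if pos < 0 else intron_flank + pos - 1


@dataclass(frozen=True)
class PositionMatrix:
    """Per-position base probabilities and information content over a window."""

    probabilities: pd.DataFrame  # columns A,C,G,T; one row per window position
    information: np.ndarray  # bits, 2 - Shannon entropy
    n_sites: int
    intron_flank: int
    exon_flank: int

    @property
    def positions(self) -> list[int]:
        return list(self.probabilities.index)

    def to_frame(self) -> pd.DataFrame:
        df = self.probabilities.copy()
        df["information_bits"] = self.information
        return df


def _window_positions(intron_flank: int, exon_flank: int) -> list[int]:
    return list(range(-intron_flank, 0)) + list(range(1, exon_flank + 1))


def _extract_all(
    sites: Sequence[AcceptorSite], genome, intron_flank: int, exon_flank: int
) -> list[str]:
    seqs = []
    for site in sites:
        try:
            seqs.append(extract_window(genome, site, intron_flank, exon_flank))
        except (WindowError, KeyError) as exc:
            warnings.warn(f"skipping unextractable site {site}: {exc}", stacklevel=3)
    return seqs


def build_matrix(
    sites: Sequence[AcceptorSite],
    genome,
    intron_flank: int = 50,
    exon_flank: int = 50,
    laplace: float = 0.0,
) -> PositionMatrix:
    """Position probability matrix over acceptor windows.

    Probabilities are raw base frequencies per position (optionally with a
    Laplace pseudocount); information content is 2 - H in bits, so a fixed
    base scores 2 and a uniform position 0.
    """
    seqs = _extract_all(sites, genome, intron_flank, exon_flank)
    if not seqs:
        raise ValueError("no extractable sites")
    length = intron_flank + exon_flank
    counts = np.zeros((length, 4))
    for seq in seqs:
        for i, b in enumerate(seq):
            k = _BASES.find(b)
            if k >= 0:
                counts[i, k] += 1
    counts += laplace
    totals = counts.sum(axis=1, keepdims=True)
    probs = counts / np.maximum(totals, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    df = pd.DataFrame(probs, columns=list(_BASES),
                      index=_window_positions(intron_flank, exon_flank))
    df.index.name = "position"
    return PositionMatrix(
        probabilities=df,
        information=np.clip(info, 0.0, 2.0),
        n_sites=len(seqs),
        intron_flank=intron_flank,
        exon_flank=exon_flank,
    )


def plus_one_composition(sites: Sequence[AcceptorSite], genome) -> dict[str, float]:
    """Base proportions at the first exonic position (+1) over a site set."""
    seqs = _extract_all(sites, genome, intron_flank=0, exon_flank=1)
    if not seqs:
        raise ValueError("no extractable sites")
    counts = {b: 0 for b in _BASES}
    for s in seqs:
        if s in counts:
            counts[s] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous +1 bases")
    return {b: counts[b] / total for b in _BASES}


def pyrimidine_fraction(
    window_seq: str, intron_flank: int, window: tuple[int, int] = (-20, -3)
) -> float:
    """(#C + #T) / length over transcript positions ``window`` (inclusive)."""
    lo, hi = window
    idx = [window_index(p, intron_flank) for p in range(lo, hi + 1) if p != 0]
    if min(idx) < 0 or max(idx) >= len(window_seq):
        raise WindowError(f"window {window} outside extracted sequence")
    piece = window_seq.upper()
    return sum(1 for i in idx if piece[i] in "CT") / len(idx)


def composition_contrast(
    sites_a: Sequence[AcceptorSite],
    sites_b: Sequence[AcceptorSite],
    genome,
    position: int,
    collapse_to: str | None = None,
) -> tuple[float, float]:
    """Pearson chi-square contrast of base composition at one position.

    Builds a 2x4 contingency table of base counts at ``position`` (2x2 when
    ``collapse_to`` names a base, e.g. ``"G"`` for a G-vs-not-G contrast).
    Emits a warning when more than 20% of expected cells fall below 5.
    """
    flank_in = max(0, -position)
    flank_ex = max(0, position)

    def base_counts(sites):
        counts = {b: 0 for b in _BASES}
        for seq in _extract_all(sites, genome, flank_in, flank_ex):
            b = seq[window_index(position, flank_in)]
            if b in counts:
                counts[b] += 1
        return counts

    if not len(sites_a) or not len(sites_b):
        raise ValueError("both site groups must be non-empty")
    ca, cb = base_counts(sites_a), base_counts(sites_b)
    if collapse_to is not None:
        t = collapse_to.upper()
        table = np.array(
            [
                [ca[t], sum(ca.values()) - ca[t]],
                [cb[t], sum(cb.values()) - cb[t]],
            ]
        )
    else:
        table = np.array([[ca[b] for b in _BASES], [cb[b] for b in _BASES]])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 1.0
    stat, p, _, expected = sps.chi2_contingency(table, correction=False)
    if np.mean(expected < 5) > 0.2:
        warnings.warn("more than 20% of expected cells below 5; chi-square may be unreliable",
                      stacklevel=2)
    return float(stat), float(p)
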