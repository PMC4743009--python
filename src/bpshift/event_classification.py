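"""Pairing and classification of differential junctions.

A differential junction is paired with canonical partners that share its
donor (alternative 3'ss candidate) or its acceptor (alternative 5'ss
candidate). Exactly one side pairing gives the class (alt3 / alt5); both or
neither give ambiguous_both, mirroring the joint "ambiguous or both" class.
Acceptor distances are signed in transcript orientation: negative means the
alternative acceptor lies upstream (intron-wards) of the canonical one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .junction_io import AcceptorSite, acceptor_of

__all__ = [
    "JunctionEvent",
    "EventSummary",
    "build_pairs",
    "acceptor_distance",
    "donor_distance",
    "periodicity_stat",
    "summarize_events",
    "events_to_frame",
]


@dataclass(frozen=True)
class JunctionEvent:
    """A (canonical, alternative) junction pair with its classification."""

    event_id: str
    canonical_id: str
    alternative_id: str
    event_class: str  # alt3 | alt5 | ambiguous_both
    chrom: str
    strand: str
    acceptor_distance: int | None
    donor_distance: int | None
    novel: bool
    canonical_site: AcceptorSite | None = None
    alternative_site: AcceptorSite | None = None


@dataclass(frozen=True)
class EventSummary:
    class_counts: dict
    n_within_window: int
    distance_histogram: dict
    inframe_fraction: float | None
    inframe_p: float | None
    novel_fraction: float | None
    window: tuple[int, int]


def _row_donor(row) -> int:
    return row["start"] if row["strand"] == "+" else row["end"]


def _row_acceptor(row) -> int:
    return row["end"] if row["strand"] == "+" else row["start"]


def acceptor_distance(canonical, alternative, strand: str) -> int:
    """Signed alternative-minus-canonical acceptor distance in transcript nt.

    Arguments are rows (or anything exposing ``start``/``end`` items) of the
    junction table. Negative = alternative acceptor upstream of canonical.
    """
    if strand == "+":
        return int(alternative["end"] - canonical["end"])
    return int(canonical["start"] - alternative["start"])


def donor_distance(canonical, alternative, strand: str) -> int:
    """Signed donor distance; negative = alternative donor upstream (exon-wards)."""
    if strand == "+":
        return int(canonical["start"] - alternative["start"])
    return int(alternative["end"] - canonical["end"])


def build_pairs(
    differential_ids: Sequence[str],
    junctions: pd.DataFrame,
    annotation: set[str],
    mean_counts: pd.Series | None = None,
) -> list[JunctionEvent]:
    """Classify each differential junction against its sharing partners.

    Partners are sought among all other junctions in the table (annotated or
    merely expressed); the canonical partner on the classifying side is the
    annotated junction with the highest mean count (annotated partners are
    preferred over unannotated ones; ties break toward the smaller absolute
    distance). ``mean_counts`` defaults to the mean of the numeric count
    columns in ``junctions``.
    """
    if mean_counts is None:
        count_cols = [
            c for c in junctions.columns
            if c not in ("id", "chrom", "start", "end", "strand")
            and pd.api.types.is_numeric_dtype(junctions[c])
        ]
        mean_counts = junctions[count_cols].mean(axis=1)

    donors: dict[tuple, list[str]] = {}
    acceptors: dict[tuple, list[str]] = {}
    for jid, row in junctions.iterrows():
        dkey = (row["chrom"], row["strand"], _row_donor(row))
        akey = (row["chrom"], row["strand"], _row_acceptor(row))
        donors.setdefault(dkey, []).append(jid)
        acceptors.setdefault(akey, []).append(jid)

    def pick_partner(candidates: list[str], row, distance_fn) -> str:
        annotated = [c for c in candidates if c in annotation]
        pool = annotated if annotated else candidates
        return min(
            pool,
            key=lambda c: (
                -float(mean_counts.loc[c]),
                abs(distance_fn(junctions.loc[c], row, row["strand"])),
                c,
            ),
        )

    events: list[JunctionEvent] = []
    for n, jid in enumerate(differential_ids):
        if jid not in junctions.index:
            raise KeyError(f"differential junction {jid!r} absent from the junction table")
        row = junctions.loc[jid]
        dkey = (row["chrom"], row["strand"], _row_donor(row))
        akey = (row["chrom"], row["strand"], _row_acceptor(row))
        share_donor = [c for c in donors.get(dkey, []) if c != jid]
        share_acceptor = [c for c in acceptors.get(akey, []) if c != jid]

        novel = jid not in annotation
        if share_donor and not share_acceptor:
            can_id = pick_partner(share_donor, row, acceptor_distance)
            can = junctions.loc[can_id]
            events.append(
                JunctionEvent(
                    event_id=f"ev{n:05d}",
                    canonical_id=can_id,
                    alternative_id=jid,
                    event_class="alt3",
                    chrom=row["chrom"],
                    strand=row["strand"],
                    acceptor_distance=acceptor_distance(can, row, row["strand"]),
                    donor_distance=None,
                    novel=novel,
                    canonical_site=acceptor_of(_as_junction(can)),
                    alternative_site=acceptor_of(_as_junction(row)),
                )
            )
        elif share_acceptor and not share_donor:
            can_id = pick_partner(share_acceptor, row, donor_distance)
            can = junctions.loc[can_id]
            events.append(
                JunctionEvent(
                    event_id=f"ev{n:05d}",
                    canonical_id=can_id,
                    alternative_id=jid,
                    event_class="alt5",
                    chrom=row["chrom"],
                    strand=row["strand"],
                    acceptor_distance=None,
                    donor_distance=donor_distance(can, row, row["strand"]),
                    novel=novel,
                )
            )
        else:
            events.append(
                JunctionEvent(
                    event_id=f"ev{n:05d}",
                    canonical_id="",
                    alternative_id=jid,
                    event_class="ambiguous_both",
                    chrom=row["chrom"],
                    strand=row["strand"],
                    acceptor_distance=None,
                    donor_distance=None,
                    novel=novel,
                )
            )
    return events


def _as_junction(row):
    from .junction_io import Junction

    return Junction(
        id=row["id"],
        chrom=row["chrom"],
        intron_start=int(row["start"]),
        intron_end=int(row["end"]),
        strand=row["strand"],
        counts=(0,),
    )


def periodicity_stat(
    distances: Iterable[int],
    window: tuple[int, int] = (-50, -1),
    alternative: str = "greater",
) -> tuple[float, float] | None:
    """Fraction of distances that are multiples of 3 and an exact binomial
    test against the null rate 1/3, over distances inside ``window``."""
    lo, hi = window
    d = [x for x in distances if lo <= x <= hi]
    if not d:
        return None
    k = sum(1 for x in d if x % 3 == 0)
    test = sps.binomtest(k, len(d), p=1.0 / 3.0, alternative=alternative)
    return k / len(d), test.pvalue


def summarize_events(
    events: Sequence[JunctionEvent], window: tuple[int, int] = (-50, -1)
) -> EventSummary:
    classes = {"alt3": 0, "alt5": 0, "ambiguous_both": 0}
    for e in events:
        classes[e.event_class] += 1
    distances = [e.acceptor_distance for e in events if e.event_class == "alt3"]
    lo, hi = window
    in_window = [d for d in distances if lo <= d <= hi]
    hist: dict[int, int] = {}
    for d in in_window:
        hist[d] = hist.get(d, 0) + 1
    per = periodicity_stat(distances, window)
    frac, p = per if per is not None else (None, None)
    novel_fraction = (
        sum(1 for e in events if e.novel) / len(events) if events else None
    )
    return EventSummary(
        class_counts=classes,
        n_within_window=len(in_window),
        distance_histogram=dict(sorted(hist.items())),
        inframe_fraction=frac,
        inframe_p=p,
        novel_fraction=novel_fraction,
        window=window,
    )


def events_to_frame(events: Sequence[JunctionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "class": e.event_class,
                "canonical": e.canonical_id,
                "alternative": e.alternative_id,
                "chrom": e.chrom,
                "strand": e.strand,
                "acceptor_distance": e.acceptor_distance,
                "donor_distance": e.donor_distance,
                "novel": e.novel,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "class", "canonical", "alternative", "chrom",
            "strand", "acceptor_distance", "donor_distance", "novel",
        ],
    )
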