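"""Synthetic cohorts carrying the SF3B1-mutant cryptic-3'ss signature.

Each acceptor is a two-exon locus on its own contig. A configurable fraction
of acceptors is *sensitive*: the intron additionally carries a cryptic
acceptor AG' 12-24 nt (mostly) upstream of the canonical AG, an alternative
branchpoint BP' 11-14 nt upstream of the AG' whose U2-pairing score strictly
exceeds that of the canonical BP (planted ~25 nt upstream of the AG), and a
depleted G at the AG' +1 position (~20% vs ~50% at AG). Junction read counts
are negative binomial; in mutant samples a Binomial share of each sensitive
acceptor's reads is redirected from the AG to the AG' junction in proportion
to the sample's mutant transcript fraction, on top of a small wild-type leak.

Draws are keyed by (seed, acceptor index[, sample index]) so enlarging the
cohort never perturbs existing loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import junction_io
from .branchpoint import pairing_score
from .junction_io import Junction, SampleSheet, reverse_complement

__all__ = [
    "SyntheticConfig",
    "Cohort",
    "GeometryError",
    "generate_cohort",
    "expected_agprime_usage",
    "generate_null_counts",
    "BP_HEPTAMER",
    "BP_PRIME_HEPTAMER",
]

#: Canonical branchpoint heptamer planted at ``bp_offset_ag`` (score 5.0).
BP_HEPTAMER = "TGCTGAC"
#: Alternative branchpoint heptamer planted upstream of the AG' (score 6.0,
#: strictly stronger U2 pairing than the canonical one).
BP_PRIME_HEPTAMER = "TACTAAC"


class GeometryError(RuntimeError):
    """Planted elements could not be placed without collision."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults are the desk-scale cohort: 16 mutant vs 56 wild-type samples,
    200 acceptors of which 30% are sensitive, effect size psi = 0.5 (share of
    a fully mutant transcriptome's reads redirected to the AG'), wild-type
    AG' leak 0.02, NB counts with mean 200 and dispersion 0.05
    (var = mu + alpha*mu^2).
    """

    n_mut: int = 16
    n_wt: int = 56
    n_acceptors: int = 200
    sensitive_fraction: float = 0.3
    shift_psi: float = 0.5
    baseline_leak: float = 0.02
    mutant_fractions: tuple[float, ...] | None = None
    nb_mean: float = 200.0
    nb_dispersion: float = 0.05
    # AG' offset distribution: support -50..-3, plateau on -24..-12, with
    # multiples of 3 enriched by rho ("every three nucleotides" periodicity).
    distance_support: tuple[int, int] = (-50, -3)
    distance_core: tuple[int, int] = (-24, -12)
    distance_outside_weight: float = 0.1
    inframe_enrichment: float = 3.0
    agprime_plus_one_g: float = 0.20
    ag_plus_one_g: float = 0.50
    bp_offset_ag: int = -25
    bpprime_offset_range: tuple[int, int] = (-14, -11)
    agprime_annotated_fraction: float = 0.12
    exon_len: int = 100
    intron_len: int = 200
    ppt_len: int = 50
    ppt_composition: tuple[float, float, float, float] = (0.1, 0.4, 0.1, 0.4)  # A,C,G,T
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitive_fraction", "shift_psi", "baseline_leak",
                     "agprime_plus_one_g", "ag_plus_one_g", "agprime_annotated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_mut < 1 or self.n_wt < 1:
            raise ValueError("n_mut and n_wt must each be >= 1")
        if self.mutant_fractions is not None and len(self.mutant_fractions) != self.n_mut:
            raise ValueError("mutant_fractions must have one entry per MUT sample")

    def resolved_mutant_fractions(self) -> np.ndarray:
        if self.mutant_fractions is not None:
            return np.asarray(self.mutant_fractions, dtype=float)
        if self.n_mut == 1:
            return np.array([0.4])
        return np.linspace(0.2, 0.6, self.n_mut)

    def distance_weights(self) -> pd.Series:
        lo, hi = self.distance_support
        core_lo, core_hi = self.distance_core
        offsets = np.arange(lo, hi + 1)
        w = np.where((offsets >= core_lo) & (offsets <= core_hi), 1.0,
                     self.distance_outside_weight)
        w = np.where(offsets % 3 == 0, w * self.inframe_enrichment, w)
        return pd.Series(w / w.sum(), index=offsets)


@dataclass
class Cohort:
    """In-memory synthetic cohort: genome, counts, annotation, sheet, truth."""

    config: SyntheticConfig
    genome: dict[str, str]
    junctions: pd.DataFrame
    annotation: set[str]
    sample_sheet: SampleSheet
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "junctions": outdir / "junctions.tsv",
            "annotation": outdir / "annotation.tsv",
            "samples": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
        }
        junction_io.write_fasta(self.genome, paths["genome"])
        juncs = junction_io.frame_to_junctions(self.junctions, self.sample_sheet.ids)
        junction_io.write_junction_bed(juncs, paths["junctions"], self.sample_sheet)
        ann = self.junctions.loc[self.junctions["id"].isin(self.annotation)]
        with open(paths["annotation"], "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for _, r in ann.iterrows():
                fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['id']}\t0\t{r['strand']}\n")
        junction_io.write_sample_sheet(self.sample_sheet, paths["samples"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng([int(k) for k in key])


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float, size=None):
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _draw_base(rng: np.random.Generator, probs) -> str:
    return "ACGT"[rng.choice(4, p=probs)]


def _plant(seq: list[str], offset_index: Mapping[int, int], start_offset: int, text: str) -> None:
    for k, base in enumerate(text):
        seq[offset_index[start_offset + k]] = base


def _build_locus(cfg: SyntheticConfig, rng: np.random.Generator, sensitive: bool):
    """Transcript-oriented locus sequence plus planted element offsets."""
    exon, intron, ppt = cfg.exon_len, cfg.intron_len, cfg.ppt_len
    comp = np.asarray(cfg.ppt_composition)
    exon1 = [_draw_base(rng, [0.25] * 4) for _ in range(exon)]
    intron_seq = [
        _draw_base(rng, [0.25] * 4) if i < intron - ppt else _draw_base(rng, comp)
        for i in range(intron)
    ]
    exon2 = [_draw_base(rng, [0.25] * 4) for _ in range(exon)]
    # offset -k (intronic) lives at intron index intron - k
    idx = {-k: intron - k for k in range(1, intron + 1)}

    _plant(intron_seq, idx, -2, "AG")
    exon2[0] = "G" if rng.random() < cfg.ag_plus_one_g else "ACT"[rng.integers(3)]

    d = o_prime = None
    blocked: list[tuple[int, int]] = []
    if sensitive:
        weights = cfg.distance_weights()
        lo_p, hi_p = cfg.bpprime_offset_range
        d = int(rng.choice(weights.index.to_numpy(), p=weights.to_numpy()))
        o_prime = int(rng.integers(lo_p, hi_p + 1))
        if d + o_prime - 5 < -intron:
            raise GeometryError("BP' heptamer falls outside the intron")
        blocked = [(d - 2, d), (d + o_prime - 5, d + o_prime + 1)]
        _plant(intron_seq, idx, d - 2, "AG")
        plus_one = "G" if rng.random() < cfg.agprime_plus_one_g else "ACT"[rng.integers(3)]
        _plant(intron_seq, idx, d, plus_one)
        _plant(intron_seq, idx, d + o_prime - 5, BP_PRIME_HEPTAMER)

    # The canonical BP goes at bp_offset_ag, sliding upstream when the drawn
    # AG'/BP' occupy that space (as for real sensitive introns, where the
    # cryptic acceptor sits inside the canonical branchpoint region).
    bp = None
    for shift in range(0, 40):
        b = cfg.bp_offset_ag - shift
        span = (b - 5, b + 1)
        if span[0] < -intron:
            break
        if all(span[1] < lo or hi < span[0] for lo, hi in blocked):
            bp = b
            break
    if bp is None:
        raise GeometryError("could not place the canonical BP heptamer")
    _plant(intron_seq, idx, bp - 5, BP_HEPTAMER)

    strand = "+" if rng.random() < 0.5 else "-"
    sense = "".join(exon1 + intron_seq + exon2)
    return sense, strand, d, o_prime, bp


def generate_cohort(config: SyntheticConfig | None = None, **overrides) -> Cohort:
    """Generate a full cohort; identical config implies byte-identical output."""
    cfg = config or SyntheticConfig()
    if overrides:
        cfg = replace(cfg, **overrides)

    ids = tuple(
        [f"MUT{i:03d}" for i in range(cfg.n_mut)] + [f"WT{i:03d}" for i in range(cfg.n_wt)]
    )
    groups = ("MUT",) * cfg.n_mut + ("WT",) * cfg.n_wt
    fractions = tuple(cfg.resolved_mutant_fractions()) + (0.0,) * cfg.n_wt
    sheet = SampleSheet(ids=ids, groups=groups, mutant_fraction=fractions)

    n_sensitive = int(round(cfg.n_acceptors * cfg.sensitive_fraction))
    exon, intron = cfg.exon_len, cfg.intron_len
    genome: dict[str, str] = {}
    truth_rows = []
    junction_rows = []
    annotation: set[str] = set()

    for i in range(cfg.n_acceptors):
        sensitive = i < n_sensitive
        rng_locus = _rng(cfg.seed, i)
        sense, strand, d, o_prime, bp_offset = _build_locus(cfg, rng_locus, sensitive)
        locus = f"locus{i:05d}"
        genome[locus] = sense if strand == "+" else reverse_complement(sense)
        L = len(sense)

        can_id, alt_id = f"acc{i:05d}.can", f"acc{i:05d}.alt"
        can_start, can_end = exon, exon + intron  # symmetric on both strands
        if sensitive:
            if strand == "+":
                alt_start, alt_end = can_start, can_end + d
            else:
                alt_start, alt_end = can_start - d, can_end

        can_counts = np.zeros(sheet.n, dtype=int)
        alt_counts = np.zeros(sheet.n, dtype=int)
        for s in range(sheet.n):
            rng_c = _rng(cfg.seed, i, s)
            total = int(_nb_draw(rng_c, cfg.nb_mean, cfg.nb_dispersion))
            if sensitive:
                p = min(1.0, cfg.baseline_leak + cfg.shift_psi * fractions[s])
                k_alt = int(rng_c.binomial(total, p)) if total > 0 else 0
                alt_counts[s] = k_alt
                can_counts[s] = total - k_alt
            else:
                can_counts[s] = total

        junction_rows.append(
            {"id": can_id, "chrom": locus, "start": can_start, "end": can_end,
             "strand": strand, **dict(zip(ids, can_counts))}
        )
        annotation.add(can_id)
        if sensitive:
            junction_rows.append(
                {"id": alt_id, "chrom": locus, "start": alt_start, "end": alt_end,
                 "strand": strand, **dict(zip(ids, alt_counts))}
            )
            if rng_locus.random() < cfg.agprime_annotated_fraction:
                annotation.add(alt_id)
        truth_rows.append(
            {
                "acceptor": f"acc{i:05d}",
                "chrom": locus,
                "strand": strand,
                "sensitive": sensitive,
                "canonical_junction": can_id,
                "alternative_junction": alt_id if sensitive else "",
                "agprime_offset": d if sensitive else np.nan,
                "bp_offset": bp_offset,
                "bpprime_offset": o_prime if sensitive else np.nan,
                "bp_heptamer": BP_HEPTAMER,
                "bpprime_heptamer": BP_PRIME_HEPTAMER if sensitive else "",
            }
        )

    junctions = pd.DataFrame(junction_rows).set_index("id", drop=False)
    truth = pd.DataFrame(truth_rows)
    assert pairing_score(BP_PRIME_HEPTAMER) > pairing_score(BP_HEPTAMER)
    return Cohort(
        config=cfg,
        genome=genome,
        junctions=junctions,
        annotation=annotation,
        sample_sheet=sheet,
        truth=truth,
    )


def expected_agprime_usage(config: SyntheticConfig, sheet: SampleSheet, sample: str) -> float:
    """Analytic expected AG' read share for one sample of a sensitive acceptor."""
    f = sheet.fraction_of(sample)  # raises KeyError for unknown samples
    return min(1.0, config.baseline_leak + config.shift_psi * f)


def generate_null_counts(
    n_junctions: int,
    n_mut: int = 16,
    n_wt: int = 56,
    mean: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Pure NB count matrix with no group effect, for calibration checks."""
    rng = _rng(seed, 987654321)
    ids = tuple([f"MUT{i:03d}" for i in range(n_mut)] + [f"WT{i:03d}" for i in range(n_wt)])
    groups = ("MUT",) * n_mut + ("WT",) * n_wt
    sheet = SampleSheet(ids=ids, groups=groups)
    counts = _nb_draw(rng, mean, dispersion, size=(n_junctions, n_mut + n_wt))
    df = pd.DataFrame(counts, columns=list(ids))
    df.insert(0, "id", [f"null{i:05d}" for i in range(n_junctions)])
    df.insert(1, "chrom", "chrN")
    df.insert(2, "start", 100)
    df.insert(3, "end", 300)
    df.insert(4, "strand", "+")
    df["start"] = 100 + 300 * np.arange(n_junctions)
    df["end"] = df["start"] + 150
    return df.set_index("id", drop=False), sheet
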