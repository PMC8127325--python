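"""Per-intron and per-gene sequence features.

Implements the intron features that separate essential from nonessential
genes: the density of the "GC" dinucleotide motif, GC content with the
motif contribution removed, unusual (non GT..AG) splice boundaries,
CpG-island presence via the Takai-Jones sliding-window criteria, and
length/count statistics.  The seven per-gene features are

    average intron size, number of introns, total intronic bp,
    GC-motif density (first intron), GC-motif density (mean over later
    introns), GC content excluding motifs (first intron), and GC content
    excluding motifs (mean over later introns).

"Later intron" means ordinal >= 2; for single-intron genes the later
fields are undefined and flagged missing (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import GeneRecord, IntronRecord

__all__ = [
    "gc_motif_density",
    "gc_content",
    "gc_content_excl_motifs",
    "SpliceDialect",
    "splice_dialect",
    "CpgIslandCriteria",
    "find_cpg_islands",
    "cpg_island_present",
    "FeatureVector",
    "gene_feature_vector",
    "intron_table",
    "gene_table",
    "FEATURE_COLUMNS",
]


def _count_overlapping(sequence: str, motif: str) -> int:
    """Count motif occurrences by exhaustive scan (overlaps allowed)."""
    n = 0
    i = sequence.find(motif)
    while i != -1:
        n += 1
        i = sequence.find(motif, i + 1)
    return n


def gc_motif_density(sequence: str, motif: str = "GC") -> float:
    """Occurrences of ``motif`` per base of sequence.

    Ambiguity codes never match the motif (matching is literal), so an
    'N' interrupts a potential occurrence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return _count_overlapping(sequence, motif) / len(sequence)


def gc_content(sequence: str) -> float:
    """(#G + #C) / length; ambiguity codes count toward length only."""
    if not sequence:
        raise ValueError("empty sequence")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def gc_content_excl_motifs(sequence: str, motif: str = "GC") -> float:
    """GC content with the G/C bases inside motif occurrences subtracted.

    For the default motif this is (#G + #C - 2 * n_GC) / L, which obeys
    the identity  gc_content == gc_content_excl_motifs + 2 * gc_motif_density.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = _count_overlapping(sequence, motif)
    motif_gc = motif.count("G") + motif.count("C")
    value = (sequence.count("G") + sequence.count("C") - motif_gc * n) / len(sequence)
    # overlapping occurrences of unusual motifs can double-subtract; clamp
    return max(value, 0.0)


@dataclass(frozen=True)
class SpliceDialect:
    """Whether an intron deviates from the canonical 5'-GT ... AG-3' boundaries."""

    unusual_5p: bool
    unusual_3p: bool


def splice_dialect(sequence: str) -> SpliceDialect:
    """Classify the splice boundaries of a strand-corrected intron.

    The 5' site is unusual when the first two bases are not exactly "GT",
    the 3' site when the last two are not exactly "AG"; an ambiguity code
    at a boundary therefore counts as unusual.
    """
    if len(sequence) < 4:
        raise ValueError(f"intron shorter than 4 bp ({len(sequence)} bp)")
    return SpliceDialect(
        unusual_5p=sequence[:2] != "GT",
        unusual_3p=sequence[-2:] != "AG",
    )


@dataclass(frozen=True)
class CpgIslandCriteria:
    """Takai-Jones CpG-island criteria.

    Defaults follow the Takai-Jones algorithm: 200-bp scanning window,
    GC fraction >= 0.55, observed/expected CpG >= 0.65, reported islands
    >= 500 bp, with islands closer than ``merge_gap`` bp merged.
    """

    min_gc: float = 0.55
    min_obs_exp: float = 0.65
    min_length: int = 500
    window: int = 200
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.min_gc < 1.0:
            raise ValueError("min_gc must lie in (0, 1)")
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")


def _region_ok(
    cum_c: np.ndarray, cum_g: np.ndarray, cum_cg: np.ndarray, s: int, e: int,
    crit: CpgIslandCriteria,
) -> bool:
    """Do the three criteria (except length) hold on [s, e)?"""
    n = e - s
    c = int(cum_c[e] - cum_c[s])
    g = int(cum_g[e] - cum_g[s])
    obs = int(cum_cg[e - 1] - cum_cg[s]) if e - 1 > s else 0
    if (c + g) / n < crit.min_gc:
        return False
    if c * g == 0:
        return False
    # obs/exp >= r  with  exp = c*g/n, rearranged to avoid division
    return obs * n >= crit.min_obs_exp * c * g


def find_cpg_islands(
    sequence: str, criteria: CpgIslandCriteria | None = None
) -> list[tuple[int, int]]:
    """Detect CpG islands with the Takai-Jones sliding-window procedure.

    A seed window of ``criteria.window`` bp qualifies when its GC fraction
    and observed/expected CpG ratio (ExpCpG = #C * #G / window) meet the
    thresholds.  Runs of qualifying window starts are unioned into
    candidate regions, regions closer than ``merge_gap`` bp are merged,
    each merged region is trimmed one base from both ends until the whole
    region meets the criteria, and regions >= ``min_length`` are reported
    as 0-based half-open intervals.  Sequences shorter than the window
    yield an empty list.
    """
    crit = criteria or CpgIslandCriteria()
    L = len(sequence)
    w = crit.window
    if L < w:
        return []
    a = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_c = (a == ord("C")).astype(np.int64)
    is_g = (a == ord("G")).astype(np.int64)
    is_cg = ((a[:-1] == ord("C")) & (a[1:] == ord("G"))).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    # window sums at every start position
    starts = np.arange(L - w + 1)
    c_w = cum_c[starts + w] - cum_c[starts]
    g_w = cum_g[starts + w] - cum_g[starts]
    obs_w = cum_cg[starts + w - 1] - cum_cg[starts]
    ok = ((c_w + g_w) / w >= crit.min_gc) & (c_w * g_w > 0) & (
        obs_w * w >= crit.min_obs_exp * c_w * g_w
    )

    # maximal runs of qualifying starts -> candidate regions
    regions: list[list[int]] = []
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            regions.append([int(run_start), int(prev) + w])
            run_start = i
        prev = i
    regions.append([int(run_start), int(prev) + w])

    # merge regions separated by less than merge_gap
    merged: list[list[int]] = [regions[0]]
    for s, e in regions[1:]:
        if s - merged[-1][1] < crit.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # trim symmetrically until the whole region qualifies; enforce length
    islands: list[tuple[int, int]] = []
    for s, e in merged:
        while e - s >= crit.min_length and not _region_ok(
            cum_c, cum_g, cum_cg, s, e, crit
        ):
            s += 1
            e -= 1
        if e - s >= crit.min_length:
            islands.append((s, e))
    return islands


def cpg_island_present(
    intron: IntronRecord | str, criteria: CpgIslandCriteria | None = None
) -> bool:
    """True iff the intron contains at least one CpG island."""
    seq = intron if isinstance(intron, str) else intron.sequence
    return bool(find_cpg_islands(seq, criteria))


# ---------------------------------------------------------------------------
# Per-gene feature vector

#: Order of the seven features as used by the feature model.
FEATURE_COLUMNS = [
    "avg_intron_size",
    "n_introns",
    "total_intronic_bp",
    "gc_density_first",
    "gc_density_later",
    "gc_count_excl_first",
    "gc_count_excl_later",
]


@dataclass(frozen=True)
class FeatureVector:
    gene_id: str
    avg_intron_size: float
    n_introns: int
    total_intronic_bp: int
    gc_density_first: float
    gc_density_later: float  # NaN for single-intron genes
    gc_count_excl_first: float
    gc_count_excl_later: float  # NaN for single-intron genes

    @property
    def later_missing(self) -> bool:
        return math.isnan(self.gc_density_later)

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.avg_intron_size,
            float(self.n_introns),
            float(self.total_intronic_bp),
            self.gc_density_first,
            self.gc_density_later,
            self.gc_count_excl_first,
            self.gc_count_excl_later,
        )


def gene_feature_vector(gene: GeneRecord, motif: str = "GC") -> FeatureVector:
    """Compute the 7-entry feature vector of a gene.

    Later-intron entries are unweighted means over introns with
    ordinal >= 2 and are NaN for single-intron genes.
    """
    if not gene.introns:
        raise ValueError(f"gene {gene.gene_id} has no introns")
    first = gene.introns[0]
    if first.ordinal != 1:
        raise ValueError(f"gene {gene.gene_id}: first intron has ordinal != 1")
    later = [i for i in gene.introns if i.ordinal >= 2]
    lengths = [i.length for i in gene.introns]

    def _mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else float("nan")

    return FeatureVector(
        gene_id=gene.gene_id,
        avg_intron_size=float(np.mean(lengths)),
        n_introns=gene.n_introns,
        total_intronic_bp=gene.total_intronic_bp,
        gc_density_first=gc_motif_density(first.sequence, motif),
        gc_density_later=_mean([gc_motif_density(i.sequence, motif) for i in later]),
        gc_count_excl_first=gc_content_excl_motifs(first.sequence, motif),
        gc_count_excl_later=_mean(
            [gc_content_excl_motifs(i.sequence, motif) for i in later]
        ),
    )


def intron_table(
    genes: list[GeneRecord],
    motif: str = "GC",
    criteria: CpgIslandCriteria | None = None,
    with_cpg: bool = True,
) -> pd.DataFrame:
    """Per-intron feature table (one row per intron)."""
    rows = []
    for g in genes:
        cat = g.label.category if g.label else "NA"
        binary = g.label.binary if g.label else "NA"
        for i in g.introns:
            dial = splice_dialect(i.sequence)
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "ordinal": i.ordinal,
                    "position": "first" if i.is_first else "later",
                    "category": cat,
                    "binary": binary,
                    "length": i.length,
                    "gc_density": gc_motif_density(i.sequence, motif),
                    "gc_content": gc_content(i.sequence),
                    "gc_excl": gc_content_excl_motifs(i.sequence, motif),
                    "unusual_5p": dial.unusual_5p,
                    "unusual_3p": dial.unusual_3p,
                    "cpg_present": (
                        cpg_island_present(i.sequence, criteria) if with_cpg else None
                    ),
                }
            )
    return pd.DataFrame(rows)


def gene_table(genes: list[GeneRecord], motif: str = "GC") -> pd.DataFrame:
    """Per-gene feature table: the 7 features plus identifiers and labels."""
    rows = []
    for g in genes:
        fv = gene_feature_vector(g, motif)
        rows.append(
            {
                "gene_id": g.gene_id,
                "category": g.label.category if g.label else "NA",
                "binary": g.label.binary if g.label else "NA",
                **{col: getattr(fv, col) for col in FEATURE_COLUMNS},
            }
        )
    return pd.DataFrame(rows)
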