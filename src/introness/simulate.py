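"""Synthetic gene/intron corpora with planted class structure.

The generator emulates the statistical structure that separates
essential, conditional and nonessential genes:

* first introns of nonessential genes are on average 3.3x longer than
  those of essential genes, with conditional genes in between;
* GC-motif density is higher in first than later introns, with
  first/later ratios of 1.35 (essential), 1.22 (conditional) and
  1.13 (nonessential);
* essential genes carry more introns per gene than conditional genes,
  which carry more than nonessential genes;
* unusual (non GT..AG) splice boundaries are rarest in essential genes
  and commonest in nonessential genes;
* each class intersperses its own short discriminative motif so that a
  sequence classifier has learnable signal.

Intron lengths are log-normal (right-skewed and strictly positive, in
keeping with the notched-box summaries of real intron lengths where the
mean sits well above the median); intron counts are shifted Poisson so
every gene has at least one intron.  Sequence synthesis plants "GC"
dinucleotides on an i.i.d. background in a way that makes the *expected*
measured GC-motif density exactly equal to the requested target (see
:func:`synthesize_intron`).

:func:`emit_corpus` writes the corpus as genome FASTA + GFF3 + label TSV
so the full annotation-reading path can be exercised and round-tripped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .annotation_io import assign_label
from .records import GeneRecord, IntronRecord

__all__ = [
    "ClassParams",
    "CorpusConfig",
    "default_config",
    "synthesize_intron",
    "generate_corpus",
    "emit_corpus",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Unusual splice-site pairs are drawn from restricted sets chosen so that
# a boundary base can never form a chance "GC" with the adjacent
# background base; this keeps the planted GC-motif density exactly
# calibrated.  (The canonical GT/AG pairs satisfy the same property.)
ALLOWED_UNUSUAL_5P = [
    p + q for p in "ACGT" for q in "ACT" if p + q not in ("GT", "GC")
]
ALLOWED_UNUSUAL_3P = [
    p + q for p in "AGT" for q in "ACGT" if p + q not in ("AG", "GC")
]


def _validate_motif(motif: str) -> None:
    if "GC" in motif:
        raise ValueError("discriminative motif must not contain the 'GC' dinucleotide")
    if motif and (motif[0] == "C" or motif[-1] == "G"):
        raise ValueError(
            "motif must not start with 'C' or end with 'G' (would create "
            "chance GC dinucleotides at its flanks)"
        )
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be plain ACGT")


@dataclass
class ClassParams:
    """Generative parameters of one essentiality class."""

    n_genes: int
    intron_count_mean: float
    first_len_mean: float
    later_len_mean: float
    len_dispersion: float  # sigma of the log-normal length law
    gc_density_first: float
    gc_density_later: float
    base_gc: float
    p_unusual_5p: float
    p_unusual_3p: float
    motif: str
    motif_insert_rate: float  # expected motif copies per bp

    def validate(self, name: str) -> list[str]:
        errs = []
        for f in ("p_unusual_5p", "p_unusual_3p", "base_gc"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}.{f}={v} outside [0, 1]")
        for f in ("intron_count_mean", "first_len_mean", "later_len_mean",
                  "len_dispersion"):
            if getattr(self, f) <= 0:
                errs.append(f"{name}.{f} must be > 0")
        if self.motif:
            try:
                _validate_motif(self.motif)
            except ValueError as e:
                errs.append(f"{name}.motif: {e}")
        return errs


@dataclass
class CorpusConfig:
    essential: ClassParams
    conditional: ClassParams
    nonessential: ClassParams
    min_intron_len: int = 70
    seed: int = 0

    def classes(self) -> dict[str, ClassParams]:
        return {
            "essential": self.essential,
            "conditional": self.conditional,
            "nonessential": self.nonessential,
        }

    def validate(self) -> list[str]:
        errs = []
        for name, p in self.classes().items():
            errs.extend(p.validate(name))
        e, c, n = self.essential, self.conditional, self.nonessential
        ratio = n.first_len_mean / e.first_len_mean
        if abs(ratio - 3.3) > 1e-6:
            errs.append(
                f"nonessential/essential first-intron mean ratio is {ratio:.4g}, "
                "expected 3.3"
            )
        for name, p, want in (
            ("essential", e, 1.35), ("conditional", c, 1.22),
            ("nonessential", n, 1.13),
        ):
            got = p.gc_density_first / p.gc_density_later
            if abs(got - want) > 1e-6:
                errs.append(
                    f"{name} first/later GC-density ratio is {got:.4g}, "
                    f"expected {want}"
                )
        if not (e.intron_count_mean > c.intron_count_mean > n.intron_count_mean):
            errs.append("intron count means must be ordered essential > "
                        "conditional > nonessential")
        if not (e.p_unusual_5p < c.p_unusual_5p < n.p_unusual_5p):
            errs.append("p_unusual_5p must be ordered essential < conditional "
                        "< nonessential")
        if not (e.p_unusual_3p < c.p_unusual_3p < n.p_unusual_3p):
            errs.append("p_unusual_3p must be ordered essential < conditional "
                        "< nonessential")
        return errs

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            essential=ClassParams(**raw["essential"]),
            conditional=ClassParams(**raw["conditional"]),
            nonessential=ClassParams(**raw["nonessential"]),
            min_intron_len=raw.get("min_intron_len", 70),
            seed=raw.get("seed", 0),
        )


def default_config(scale: float = 1.0, seed: int = 0) -> CorpusConfig:
    """The default study conditions, at 100 genes per class per unit scale.

    Per-class intron-count means (12.9 / 11.0 / 9.2) follow the observed
    introns-per-gene of curated human essential, conditional and
    nonessential genes.  Absolute intron lengths are model choices (only
    the 3.3 first-intron ratio and the orderings are prescribed):
    essential first introns average 1,200 bp, nonessential 3,960 bp.
    GC-motif densities are anchored at later-intron values near 0.06/bp
    with the first-intron values set by the class ratios.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    n = int(round(100 * scale))
    if n < 1:
        raise ValueError("scale too small: zero genes per class")
    common = dict(len_dispersion=0.7, base_gc=0.38)
    cfg = CorpusConfig(
        essential=ClassParams(
            n_genes=n, intron_count_mean=12.9,
            first_len_mean=1200.0, later_len_mean=700.0,
            gc_density_first=0.081, gc_density_later=0.060,
            p_unusual_5p=0.010, p_unusual_3p=0.008,
            motif="TAACGTTGGAT", motif_insert_rate=0.003, **common,
        ),
        conditional=ClassParams(
            n_genes=n, intron_count_mean=11.0,
            first_len_mean=2400.0, later_len_mean=900.0,
            gc_density_first=0.07076, gc_density_later=0.058,
            p_unusual_5p=0.020, p_unusual_3p=0.015,
            motif="ATTGAACCTGA", motif_insert_rate=0.002, **common,
        ),
        nonessential=ClassParams(
            n_genes=n, intron_count_mean=9.2,
            first_len_mean=3960.0, later_len_mean=1100.0,
            gc_density_first=0.06328, gc_density_later=0.056,
            p_unusual_5p=0.035, p_unusual_3p=0.030,
            motif="TGGATAACTTA", motif_insert_rate=0.0004, **common,
        ),
        seed=seed,
    )
    violations = cfg.validate()
    assert not violations, violations
    return cfg


def synthesize_intron(
    length: int,
    gc_density_target: float,
    base_gc: float,
    unusual_5p: bool = False,
    unusual_3p: bool = False,
    motif: str | None = None,
    motif_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Generate one intron whose expected GC-motif density equals the target.

    Construction: (1) draw an i.i.d. background at ``base_gc`` G+C
    composition; (2) fix the splice boundaries (GT..AG, or a pair drawn
    from the allowed unusual sets when flagged); (3) overwrite
    Poisson-many copies of the discriminative ``motif`` at uniform
    non-overlapping interior positions; (4) plant K extra "GC"
    dinucleotides at free interior positions at least 3 bp apart.

    Boundary pairs, motif alphabet and plant spacing are constrained so
    that every base pair of the sequence either carries an independent
    chance of being "GC" (probability (base_gc/2)^2) or is
    deterministically not "GC" -- except the planted pairs, which are
    "GC" with certainty.  K is therefore solvable in closed form (and
    randomized between floor and ceiling) so that the expected occurrence
    count is exactly ``gc_density_target * length``.

    Raises ``ValueError`` when the target is infeasible: above 0.5
    (dinucleotides cannot tile denser), below the background chance rate,
    or when the sequence has too little free space to hold the plants.
    """
    rng = rng or np.random.default_rng()
    m = len(motif) if motif else 0
    if length < 4 + m:
        raise ValueError(f"length {length} too short (need >= {4 + m})")
    if gc_density_target > 0.5:
        raise ValueError("GC-motif density target cannot exceed 0.5")
    p_gc_pair = (base_gc / 2.0) ** 2

    probs = np.array(
        [(1 - base_gc) / 2, base_gc / 2, base_gc / 2, (1 - base_gc) / 2]
    )
    arr = _BASES[rng.choice(4, size=length, p=probs)]
    fixed = np.zeros(length, dtype=bool)

    # splice boundaries
    five = (
        ALLOWED_UNUSUAL_5P[rng.integers(len(ALLOWED_UNUSUAL_5P))]
        if unusual_5p
        else "GT"
    )
    three = (
        ALLOWED_UNUSUAL_3P[rng.integers(len(ALLOWED_UNUSUAL_3P))]
        if unusual_3p
        else "AG"
    )
    arr[0:2] = np.frombuffer(five.encode(), dtype=np.uint8)
    arr[length - 2 : length] = np.frombuffer(three.encode(), dtype=np.uint8)
    fixed[0:2] = fixed[length - 2 : length] = True

    # discriminative motif copies at uniform non-overlapping positions
    if motif and motif_rate > 0.0:
        _validate_motif(motif)
        mbytes = np.frombuffer(motif.encode(), dtype=np.uint8)
        n_copies = rng.poisson(motif_rate * length)
        lo, hi = 2, length - 2 - m
        placed = 0
        attempts = 0
        while placed < n_copies and attempts < 20 * max(n_copies, 1) and hi >= lo:
            s = int(rng.integers(lo, hi + 1))
            attempts += 1
            if not fixed[s : s + m].any():
                arr[s : s + m] = mbytes
                fixed[s : s + m] = True
                placed += 1

    # solve for the number of planted GC dinucleotides
    pair_free = ~fixed[:-1] & ~fixed[1:]
    n_free = int(pair_free.sum())
    target_count = gc_density_target * length
    k_real = (target_count - n_free * p_gc_pair) / (1.0 - 3.0 * p_gc_pair)
    if k_real < -0.5:
        raise ValueError(
            f"GC-motif density target {gc_density_target} below the "
            f"background chance rate for base_gc={base_gc}"
        )
    k = int(np.floor(k_real))
    if rng.random() < k_real - k:
        k += 1
    k = max(k, 0)

    if k:
        # candidate plant starts: pairs j-1, j, j+1 all free
        ok = pair_free[:-2] & pair_free[1:-1] & pair_free[2:]
        candidates = np.flatnonzero(ok) + 1
        order = rng.permutation(len(candidates))
        blocked = np.zeros(length, dtype=bool)
        accepted = []
        for j in candidates[order]:
            if not blocked[j]:
                accepted.append(int(j))
                blocked[max(0, j - 2) : j + 3] = True
                if len(accepted) == k:
                    break
        if len(accepted) < k:
            raise ValueError(
                f"cannot place {k} GC plants in {length} bp; density target "
                f"{gc_density_target} infeasible at this length"
            )
        acc = np.array(accepted)
        arr[acc] = ord("G")
        arr[acc + 1] = ord("C")

    return arr.tobytes().decode("ascii")


def _draw_length(rng, mean: float, sigma: float, floor: int) -> int:
    mu = np.log(mean) - sigma**2 / 2.0  # arithmetic mean of lognormal == mean
    return max(int(round(rng.lognormal(mu, sigma))), floor)


def _draw_counts(rng, category: str) -> tuple[int, int]:
    """Study counts (n_essential, n_total) in the style of an OGEE record."""
    n_total = int(rng.integers(4, 19))
    if category == "essential":
        n_essential = n_total - int(rng.binomial(n_total, 0.05))
        n_essential = max(n_essential, 1)
    elif category == "nonessential":
        n_essential = int(rng.binomial(n_total, 0.02))
    else:  # conditional: genuine disagreement
        p = rng.uniform(0.15, 0.85)
        n_essential = int(np.clip(rng.binomial(n_total, p), 1, n_total - 1))
    return n_essential, n_total


def generate_corpus(
    config: CorpusConfig,
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Generate labeled GeneRecords plus the gene-label table.

    Deterministic given ``config.seed``.  Raises ``ValueError`` listing
    all violations when the config breaks a planted-structure invariant.
    """
    violations = config.validate()
    if violations:
        raise ValueError("invalid corpus config: " + "; ".join(violations))
    rng = np.random.default_rng(config.seed)
    genes: list[GeneRecord] = []
    rows = []
    prefixes = {"essential": "ESS", "conditional": "CND", "nonessential": "NON"}
    for category, params in config.classes().items():
        floor = max(config.min_intron_len, len(params.motif) + 8)
        for i in range(params.n_genes):
            gid = f"{prefixes[category]}{i:05d}"
            tid = f"{gid}.t1"
            n_introns = 1 + int(rng.poisson(params.intron_count_mean - 1.0))
            introns = []
            for ordinal in range(1, n_introns + 1):
                first = ordinal == 1
                L = _draw_length(
                    rng,
                    params.first_len_mean if first else params.later_len_mean,
                    params.len_dispersion,
                    floor,
                )
                seq = synthesize_intron(
                    L,
                    params.gc_density_first if first else params.gc_density_later,
                    params.base_gc,
                    unusual_5p=bool(rng.random() < params.p_unusual_5p),
                    unusual_3p=bool(rng.random() < params.p_unusual_3p),
                    motif=params.motif,
                    motif_rate=params.motif_insert_rate,
                    rng=rng,
                )
                introns.append(IntronRecord(gid, tid, ordinal, seq))
            n_ess, n_tot = _draw_counts(rng, category)
            label = assign_label(n_ess, n_tot, category)
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    strand="+" if rng.random() < 0.5 else "-",
                    introns=introns,
                    label=label,
                    essential_fraction=n_ess / n_tot,
                )
            )
            rows.append(
                {
                    "gene_id": gid,
                    "n_essential": n_ess,
                    "n_total": n_tot,
                    "category": category,
                }
            )
    return genes, pd.DataFrame(rows)


def _wrap_fasta(fh, seq: str, width: int = 80) -> None:
    for k in range(0, len(seq), width):
        fh.write(seq[k : k + width])
        fh.write("\n")


def emit_corpus(
    genes: list[GeneRecord],
    labels: pd.DataFrame,
    out_dir: str | Path,
    exon_len: int = 150,
    flank_len: int = 50,
    seed: int = 0,
) -> dict[str, Path]:
    """Write genome FASTA + GFF3 + label TSV realizing the corpus.

    Each gene is placed on its own contig: random flanks around a
    transcript of ``n_introns + 1`` exons interleaved with the gene's
    introns.  Minus-strand genes are written reverse-complemented on the
    contig so extraction must strand-correct to recover the planted
    sequences.  Every fifth gene also gets a decoy transcript covering
    only the first exon, exercising the longest-CDS transcript rule.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    fasta = out_dir / "genome.fa"
    gff = out_dir / "annotation.gff3"
    labels_path = out_dir / "labels.tsv"
    with open(fasta, "w") as ffh, open(gff, "w") as gfh:
        gfh.write("##gff-version 3\n")
        for gi, gene in enumerate(genes):
            contig = f"ctg_{gene.gene_id}"
            pieces = []  # transcript-orientation pieces: (kind, seq)
            for k, intr in enumerate(gene.introns):
                pieces.append(("exon", _random_seq(rng, exon_len)))
                pieces.append(("intron", intr.sequence))
            pieces.append(("exon", _random_seq(rng, exon_len)))
            tx = "".join(s for _, s in pieces)
            genomic = tx if gene.strand == "+" else str(Seq(tx).reverse_complement())
            contig_seq = (
                _random_seq(rng, flank_len) + genomic + _random_seq(rng, flank_len)
            )
            ffh.write(f">{contig}\n")
            _wrap_fasta(ffh, contig_seq)

            # transcript-orientation offsets -> genomic 1-based coordinates
            T = len(tx)
            exon_coords = []
            off = 0
            for kind, s in pieces:
                t0, t1 = off, off + len(s)  # 0-based half-open in tx orientation
                off = t1
                if kind != "exon":
                    continue
                if gene.strand == "+":
                    g0, g1 = flank_len + t0, flank_len + t1
                else:
                    g0, g1 = flank_len + (T - t1), flank_len + (T - t0)
                exon_coords.append((g0 + 1, g1))  # GFF 1-based inclusive
            exon_coords.sort()
            gene_start, gene_end = exon_coords[0][0], exon_coords[-1][1]
            tid = gene.introns[0].transcript_id if gene.introns else f"{gene.gene_id}.t1"
            gfh.write(
                f"{contig}\tsim\tgene\t{gene_start}\t{gene_end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            gfh.write(
                f"{contig}\tsim\tmRNA\t{gene_start}\t{gene_end}\t.\t"
                f"{gene.strand}\t.\tID={tid};Parent={gene.gene_id}\n"
            )
            for k, (s, e) in enumerate(exon_coords):
                gfh.write(
                    f"{contig}\tsim\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={tid}.exon{k};Parent={tid}\n"
                )
                gfh.write(
                    f"{contig}\tsim\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                    f"ID={tid}.cds{k};Parent={tid}\n"
                )
            if gi % 5 == 0 and len(exon_coords) >= 2:
                # decoy transcript: first exon only (shorter CDS, must lose)
                dtid = f"{gene.gene_id}.t2"
                # first exon in transcript orientation
                s, e = exon_coords[0] if gene.strand == "+" else exon_coords[-1]
                gfh.write(
                    f"{contig}\tsim\tmRNA\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={dtid};Parent={gene.gene_id}\n"
                )
                gfh.write(
                    f"{contig}\tsim\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={dtid}.exon0;Parent={dtid}\n"
                )
                gfh.write(
                    f"{contig}\tsim\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                    f"ID={dtid}.cds0;Parent={dtid}\n"
                )
    labels.to_csv(labels_path, sep="\t", index=False)
    return {"fasta": fasta, "gff": gff, "labels": labels_path}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
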