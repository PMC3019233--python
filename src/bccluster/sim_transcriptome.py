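"""Synthetic transcriptomes, pyrosequencing-style reads, and mock assemblies.

The simulator emits *post-assembly* state directly -- padded ACE
contigs, read placements, and ground-truth tables -- so that every
downstream stage (broken-read graph, BCC classification, variant
calling, filtering) can be exercised without an external assembler.

Gene categories and the assembly behaviour they emulate:

``allelic_pair``
    two alleles diverged at per-base SNP/indel rates; the assembler
    yields one contig per allele, and reads spanning the (synthetic)
    break point are split across both contigs.
``allelic_triple``
    as above plus a chimeric third contig (5' of allele 1 joined to 3'
    of allele 2 -- a common assembler artifact), giving a three-node
    BCC whose pairwise relations are all allelic.
``paralog_triple``
    a family of three recent duplicates at a configurable identity band
    (substitution divergence), fragmenting into a three-contig BCC whose
    relations are all duplicated.
``cassette``
    a cassette-exon gene: isoform A = E1-E2-E3, isoform B = E1-E3.  The
    assembler yields one contig per exon; junction-spanning reads from
    either isoform become broken reads, producing the classic
    three-contig triangle whose members share no sequence similarity.

Reads have truncated-normal lengths; in homopolymer-error mode a read
may gain or lose one base adjacent to a run of >= 3 identical bases, the
dominant pyrosequencing error.  All randomness flows from a single
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly_io import Assembly, PaddedContig, ReadPlacement, write_ace, write_fasta
from .variant_pipeline import MsaMatrix

__all__ = [
    "SimConfig",
    "PlantedVariant",
    "GeneTruth",
    "SimRead",
    "simulate_genes",
    "simulate_reads",
    "simulate_assembly",
    "simulate",
    "simulate_msa",
    "evaluate",
    "reads_table",
    "truth_tables",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Alignment maps (CIGAR-style edit scripts)
#
# A map from sequence A to sequence B is a list of (op, length) with
# 'M' consuming both, 'I' consuming A only (A-specific base), and 'D'
# consuming B only (B-specific base).
# ---------------------------------------------------------------------------

def _cigar_lengths(cigar: list[tuple[str, int]]) -> tuple[int, int]:
    a = sum(n for op, n in cigar if op in "MI")
    b = sum(n for op, n in cigar if op in "MD")
    return a, b


def _push(out: list[tuple[str, int]], op: str, n: int) -> None:
    if n <= 0:
        return
    if out and out[-1][0] == op:
        out[-1] = (op, out[-1][1] + n)
    else:
        out.append((op, n))


def _invert(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    swap = {"M": "M", "I": "D", "D": "I"}
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        _push(out, swap[op], n)
    return out


def _slice_src(
    cigar: list[tuple[str, int]], s0: int, s1: int
) -> tuple[int, list[tuple[str, int]]]:
    """Restrict an A->B map to A positions [s0, s1).

    Returns (B offset of the slice, sub-map).  D runs at the slice
    boundaries (B-only bases outside the A window) are trimmed.
    """
    out: list[tuple[str, int]] = []
    apos = bpos = 0
    b_start = None
    for op, n in cigar:
        if op == "D":
            if s0 < apos < s1 or (apos == s0 and out):
                _push(out, "D", n)
            bpos += n
            continue
        # op consumes A
        lo, hi = max(apos, s0), min(apos + n, s1)
        if lo < hi:
            if b_start is None:
                b_start = bpos + (lo - apos if op == "M" else 0)
            _push(out, op, hi - lo)
        apos += n
        if op == "M":
            bpos += n
        if apos >= s1 and lo >= hi:
            break
    if b_start is None:
        b_start = bpos
    # trim trailing D
    while out and out[-1][0] == "D":
        out.pop()
    return b_start, out


def _slice_tgt(
    cigar: list[tuple[str, int]], t0: int, t1: int
) -> tuple[int, list[tuple[str, int]]]:
    a0, sub = _slice_src(_invert(cigar), t0, t1)
    return a0, _invert(sub)


def _compose(
    ab: list[tuple[str, int]], bc: list[tuple[str, int]]
) -> list[tuple[str, int]]:
    """Compose A->B with B->C into A->C.  Requires len(B) to agree."""
    ab_len_b = _cigar_lengths(ab)[1]
    bc_len_b = _cigar_lengths(bc)[0]
    if ab_len_b != bc_len_b:
        raise ValueError(f"map composition mismatch: {ab_len_b} vs {bc_len_b}")
    out: list[tuple[str, int]] = []
    ai, an = 0, 0
    bi, bn = 0, 0

    def next_a():
        nonlocal ai, an
        while ai < len(ab) and an >= ab[ai][1]:
            ai += 1
            an = 0
        return ab[ai][0] if ai < len(ab) else None

    def next_b():
        nonlocal bi, bn
        while bi < len(bc) and bn >= bc[bi][1]:
            bi += 1
            bn = 0
        return bc[bi][0] if bi < len(bc) else None

    while True:
        oa, ob = next_a(), next_b()
        if oa is None and ob is None:
            break
        if oa == "I":
            _push(out, "I", 1)
            an += 1
            continue
        if ob == "D":
            _push(out, "D", 1)
            bn += 1
            continue
        if oa is None or ob is None:
            raise ValueError("inconsistent maps in composition")
        # oa in (M, D) consumes B; ob in (M, I) consumes B
        if oa == "M" and ob == "M":
            _push(out, "M", 1)
        elif oa == "M" and ob == "I":
            _push(out, "I", 1)
        elif oa == "D" and ob == "M":
            _push(out, "D", 1)
        # oa == 'D' and ob == 'I': B-only base dropped in both -> nothing
        an += 1
        bn += 1
    return out


# ---------------------------------------------------------------------------
# Configuration and truth types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_genes: int = 50
    allele_snp_rate: float = 0.0057
    allele_indel_rate: float = 0.002
    dup_fraction: float = 0.2
    dup_identity_range: tuple[float, float] = (0.85, 0.95)
    isoform_fraction: float = 0.2
    allelic_triple_fraction: float = 0.2
    exon_length_range: tuple[int, int] = (150, 500)
    read_length_mean: float = 440.0
    read_length_sd: float = 60.0
    homopolymer_error_rate: float = 0.0
    coverage_mean: float = 20.0
    collapse_alleles: bool = False
    reverse_fraction: float = 0.5
    min_part_length: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("allele_snp_rate", "allele_indel_rate", "dup_fraction",
                     "isoform_fraction", "allelic_triple_fraction",
                     "homopolymer_error_rate", "reverse_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dup_fraction + self.isoform_fraction + self.allelic_triple_fraction > 1:
            raise ValueError("category fractions exceed 1")
        if self.dup_identity_range[0] > self.dup_identity_range[1]:
            raise ValueError("dup_identity_range must be ordered")
        if self.exon_length_range[0] > self.exon_length_range[1]:
            raise ValueError("exon_length_range must be ordered")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass(frozen=True)
class PlantedVariant:
    kind: str  # snp | insertion | deletion
    position: int  # 0-based on the reference source (call coordinates)
    ref: str
    alt: str


@dataclass
class GeneTruth:
    gene_id: str
    category: str
    sources: dict[str, str]  # source name -> sequence
    contig_plan: list[tuple[str, str, tuple[int, int]]]  # (contig_id, source, window)
    contig_seqs: dict[str, str]
    maps: dict[tuple[str, str], tuple[tuple[int, int], int, list[tuple[str, int]]]]
    # (source, contig) -> (source window, contig start, cigar)
    boundaries: dict[str, list[int]]  # source -> break points (source coords)
    pair_routing: list[tuple[str, str]]  # cyclic routes for split parts
    home_contig: dict[str, str]  # source -> contig for unsplit reads
    variants: list[PlantedVariant] = field(default_factory=list)
    expected_relations: list[tuple[str, str, str]] = field(default_factory=list)
    expected_bcc_verdict: str | None = None
    duplicate_partner: str | None = None


@dataclass
class SimRead:
    read_id: str
    sequence: str  # as sequenced (reverse-complemented for reverse strand)
    gene_id: str
    source: str
    start: int  # 0-based on the source sequence
    length: int
    strand: str  # forward | reverse
    cigar: list[tuple[str, int]]  # read -> source window (consensus orientation)
    hp_errors: list[tuple[str, int]] = field(default_factory=list)  # (kind, source pos)

    @property
    def oriented(self) -> str:
        """Read sequence in source (consensus) orientation."""
        return _revcomp(self.sequence) if self.strand == "reverse" else self.sequence


# ---------------------------------------------------------------------------
# Sequence mutation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _substitute(rng: np.random.Generator, base: str) -> str:
    # transition-biased: 2/3 transitions, 1/6 each transversion
    if rng.random() < 2 / 3:
        return _TRANSITION[base]
    tvs = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
    return tvs[rng.integers(len(tvs))]


def _run_length_at(seq: str, i: int) -> int:
    b = seq[i]
    j = i
    while j > 0 and seq[j - 1] == b:
        j -= 1
    k = i
    while k + 1 < len(seq) and seq[k + 1] == b:
        k += 1
    return k - j + 1


def _in_hp_context(seq: str, i: int, min_run: int = 3) -> bool:
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(seq) and _run_length_at(seq, j) >= min_run:
            return True
    return False


def _mutate_alleles(
    seq: str,
    rng: np.random.Generator,
    snp_rate: float,
    indel_rate: float,
) -> tuple[str, list[PlantedVariant], list[tuple[str, int]]]:
    """Derive a second allele; returns (mutant, variants, cigar src->mutant).

    Indel variants are only planted outside homopolymer context so that
    genuine allelic indels are separable from pyrosequencing errors.
    """
    out: list[str] = []
    cigar: list[tuple[str, int]] = []
    variants: list[PlantedVariant] = []
    for i, b in enumerate(seq):
        r = rng.random()
        if r < indel_rate:
            if i > 0 and not _in_hp_context(seq, i):
                if rng.random() < 0.5:  # deletion in the mutant
                    variants.append(PlantedVariant("deletion", i, b, "-"))
                    _push(cigar, "I", 1)
                    continue
                # inserted base must differ from both neighbours so it
                # cannot extend a run into homopolymer context
                choices = [x for x in "ACGT" if x != seq[i - 1] and x != b]
                ins = choices[rng.integers(len(choices))]
                out.append(ins)
                _push(cigar, "D", 1)
                variants.append(PlantedVariant("insertion", i - 1, "-", ins))
        elif r < indel_rate + snp_rate:
            alt = _substitute(rng, b)
            out.append(alt)
            _push(cigar, "M", 1)
            variants.append(PlantedVariant("snp", i, b, alt))
            continue
        out.append(b)
        _push(cigar, "M", 1)
    return "".join(out), variants, cigar


def _mutate_subs(
    seq: str, rng: np.random.Generator, rate: float
) -> str:
    """Substitute an exact count of round(rate * L) distinct positions."""
    chars = list(seq)
    k = round(rate * len(chars))
    for i in rng.choice(len(chars), size=k, replace=False):
        chars[int(i)] = _substitute(rng, chars[int(i)])
    return "".join(chars)


def _chimera(
    a1: str, a2: str, cigar12: list[tuple[str, int]], m: int
) -> tuple[str, list[tuple[str, int]], list[tuple[str, int]]]:
    """Join a1[:m] to the a2 region aligned beyond m.

    Returns (chimera, map a1->chimera, map a2->chimera) built in one
    replay of the a1->a2 alignment.
    """
    out: list[str] = []
    c1: list[tuple[str, int]] = []
    c2: list[tuple[str, int]] = []
    p1 = p2 = 0
    for op, n in cigar12:
        for _ in range(n):
            if op == "M":
                out.append(a1[p1] if p1 < m else a2[p2])
                _push(c1, "M", 1)
                _push(c2, "M", 1)
                p1 += 1
                p2 += 1
            elif op == "I":  # a1-only base
                if p1 < m:
                    out.append(a1[p1])
                    _push(c1, "M", 1)
                    _push(c2, "D", 1)
                else:
                    _push(c1, "I", 1)
                p1 += 1
            else:  # 'D': a2-only base
                if p1 >= m:
                    out.append(a2[p2])
                    _push(c1, "D", 1)
                    _push(c2, "M", 1)
                else:
                    _push(c2, "I", 1)
                p2 += 1
    return "".join(out), c1, c2


# ---------------------------------------------------------------------------
# Gene simulation
# ---------------------------------------------------------------------------

def simulate_genes(config: SimConfig) -> list[GeneTruth]:
    """Generate ground-truth genes with planted relations and variants."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_iso = round(n * config.isoform_fraction)
    n_dup = round(n * config.dup_fraction)
    n_tri = round(n * config.allelic_triple_fraction)
    categories = (
        ["cassette"] * n_iso
        + ["paralog_triple"] * n_dup
        + ["allelic_triple"] * n_tri
    )
    categories += ["allelic_pair"] * (n - len(categories))
    categories = list(np.array(categories)[rng.permutation(n)]) if n else []

    genes: list[GeneTruth] = []
    for gi, category in enumerate(categories):
        gid = f"g{gi:04d}"
        if category == "cassette":
            genes.append(_make_cassette(gid, rng, config))
        elif category == "paralog_triple":
            genes.append(_make_paralogs(gid, rng, config))
        elif category == "allelic_triple":
            genes.append(_make_allelic(gid, rng, config, triple=True))
        else:
            genes.append(_make_allelic(gid, rng, config, triple=False))
    return genes


def _transcript_length(rng: np.random.Generator, config: SimConfig, n_exons: int = 2) -> int:
    lo, hi = config.exon_length_range
    return int(sum(rng.integers(lo, hi + 1) for _ in range(n_exons)))


def _make_allelic(
    gid: str, rng: np.random.Generator, config: SimConfig, triple: bool
) -> GeneTruth:
    a1 = _random_seq(rng, _transcript_length(rng, config))
    a2, variants, cig12 = _mutate_alleles(
        a1, rng, config.allele_snp_rate, config.allele_indel_rate
    )
    m = len(a1) // 2
    m2 = _aligned_pos(cig12, m)  # a2 coordinate aligned to a1 position m
    c1, c2, c3 = f"{gid}c1", f"{gid}c2", f"{gid}c3"
    ident = [("M", len(a1))]
    ident2 = [("M", len(a2))]
    sources = {"a1": a1, "a2": a2}
    if config.collapse_alleles and not triple:
        maps = {
            ("a1", c1): ((0, len(a1)), 0, ident),
            ("a2", c1): ((0, len(a2)), 0, _invert(cig12)),
        }
        return GeneTruth(
            gene_id=gid,
            category="allelic_pair",
            sources=sources,
            contig_plan=[(c1, "a1", (0, len(a1)))],
            contig_seqs={c1: a1},
            maps=maps,
            boundaries={"a1": [], "a2": []},
            pair_routing=[],
            home_contig={"a1": c1, "a2": c1},
            variants=variants,
            expected_relations=[],
            expected_bcc_verdict=None,
        )
    maps = {
        ("a1", c1): ((0, len(a1)), 0, ident),
        ("a2", c1): ((0, len(a2)), 0, _invert(cig12)),
        ("a1", c2): ((0, len(a1)), 0, cig12),
        ("a2", c2): ((0, len(a2)), 0, ident2),
    }
    if not triple:
        return GeneTruth(
            gene_id=gid,
            category="allelic_pair",
            sources=sources,
            contig_plan=[(c1, "a1", (0, len(a1))), (c2, "a2", (0, len(a2)))],
            contig_seqs={c1: a1, c2: a2},
            maps=maps,
            boundaries={"a1": [m], "a2": [m2]},
            pair_routing=[(c1, c2)],
            home_contig={"a1": c1, "a2": c2},
            variants=variants,
            expected_relations=[(c1, c2, "allelic")],
            expected_bcc_verdict=None,
        )
    chim, map1, map2 = _chimera(a1, a2, cig12, m)
    maps[("a1", c3)] = ((0, len(a1)), 0, map1)
    maps[("a2", c3)] = ((0, len(a2)), 0, map2)
    return GeneTruth(
        gene_id=gid,
        category="allelic_triple",
        sources=sources,
        contig_plan=[
            (c1, "a1", (0, len(a1))),
            (c2, "a2", (0, len(a2))),
            (c3, "a1", (0, len(chim))),
        ],
        contig_seqs={c1: a1, c2: a2, c3: chim},
        maps=maps,
        boundaries={"a1": [m], "a2": [m2]},
        pair_routing=[(c1, c2), (c2, c3), (c1, c3)],
        home_contig={"a1": c1, "a2": c2},
        variants=variants,
        expected_relations=[
            (c1, c2, "allelic"),
            (c1, c3, "allelic"),
            (c2, c3, "allelic"),
        ],
        expected_bcc_verdict="allelic",
    )


def _aligned_pos(cigar: list[tuple[str, int]], apos: int) -> int:
    """B coordinate aligned to A position ``apos`` in an A->B map."""
    a = b = 0
    for op, n in cigar:
        if op == "M":
            if a + n > apos:
                return b + (apos - a)
            a += n
            b += n
        elif op == "I":
            if a + n > apos:
                return b
            a += n
        else:
            b += n
    return b


def _make_paralogs(gid: str, rng: np.random.Generator, config: SimConfig) -> GeneTruth:
    base = _random_seq(rng, _transcript_length(rng, config))
    lo, hi = config.dup_identity_range
    seqs = {"p1": base}
    for k in (2, 3):
        ident = rng.uniform(lo, hi)
        seqs[f"p{k}"] = _mutate_subs(base, rng, 1.0 - ident)
    cids = {s: f"{gid}c{i+1}" for i, s in enumerate(["p1", "p2", "p3"])}
    L = len(base)
    maps = {
        (s, cids[t]): ((0, L), 0, [("M", L)])
        for s in seqs
        for t in seqs
    }
    m = L // 2
    order = ["p1", "p2", "p3"]
    return GeneTruth(
        gene_id=gid,
        category="paralog_triple",
        sources=seqs,
        contig_plan=[(cids[s], s, (0, L)) for s in order],
        contig_seqs={cids[s]: seqs[s] for s in order},
        maps=maps,
        boundaries={s: [m] for s in order},
        pair_routing=[(cids["p1"], cids["p2"]), (cids["p2"], cids["p3"]),
                      (cids["p3"], cids["p1"])],
        home_contig={s: cids[s] for s in order},
        variants=[],
        expected_relations=[
            (cids["p1"], cids["p2"], "duplicated"),
            (cids["p1"], cids["p3"], "duplicated"),
            (cids["p2"], cids["p3"], "duplicated"),
        ],
        expected_bcc_verdict="duplicated",
        duplicate_partner=cids["p2"],
    )


def _make_cassette(gid: str, rng: np.random.Generator, config: SimConfig) -> GeneTruth:
    lo, hi = config.exon_length_range
    e1, e2, e3 = (
        _random_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(3)
    )
    iso_a = e1 + e2 + e3
    iso_b = e1 + e3
    l1, l2, l3 = len(e1), len(e2), len(e3)
    c1, c2, c3 = f"{gid}c1", f"{gid}c2", f"{gid}c3"
    maps = {
        ("isoA", c1): ((0, l1), 0, [("M", l1)]),
        ("isoA", c2): ((l1, l1 + l2), 0, [("M", l2)]),
        ("isoA", c3): ((l1 + l2, l1 + l2 + l3), 0, [("M", l3)]),
        ("isoB", c1): ((0, l1), 0, [("M", l1)]),
        ("isoB", c3): ((l1, l1 + l3), 0, [("M", l3)]),
    }
    return GeneTruth(
        gene_id=gid,
        category="cassette",
        sources={"isoA": iso_a, "isoB": iso_b},
        contig_plan=[(c1, "isoA", (0, l1)), (c2, "isoA", (l1, l1 + l2)),
                     (c3, "isoA", (l1 + l2, l1 + l2 + l3))],
        contig_seqs={c1: e1, c2: e2, c3: e3},
        maps=maps,
        boundaries={"isoA": [l1, l1 + l2], "isoB": [l1]},
        pair_routing=[],
        home_contig={},
        variants=[],
        expected_relations=[
            (c1, c2, "alt_splice"),
            (c1, c3, "alt_splice"),
            (c2, c3, "alt_splice"),
        ],
        expected_bcc_verdict="alternative_splicing",
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(truth: list[GeneTruth], config: SimConfig) -> list[SimRead]:
    """Sample reads from every source sequence of every gene.

    Per-source read numbers are Poisson with mean coverage_mean * L /
    read_length_mean; lengths are truncated normal (floor 50 nt, capped
    at the source length).  In homopolymer-error mode each read position
    adjacent to a run of >= 3 identical bases gains or loses one base
    with probability ``homopolymer_error_rate``.
    """
    if not truth:
        raise ValueError("no genes to sample reads from")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    reads: list[SimRead] = []
    if config.coverage_mean <= 0:
        import warnings

        warnings.warn("coverage_mean is 0; no reads simulated", stacklevel=2)
        return reads
    serial = 0
    for gene in truth:
        for source, seq in sorted(gene.sources.items()):
            L = len(seq)
            n_reads = int(rng.poisson(config.coverage_mean * L / config.read_length_mean))
            n_reads = max(n_reads, 2)
            for _ in range(n_reads):
                length = int(
                    np.clip(
                        rng.normal(config.read_length_mean, config.read_length_sd),
                        50,
                        L,
                    )
                )
                start = int(rng.integers(0, L - length + 1))
                frag = seq[start : start + length]
                frag, cigar, errors = _apply_hp_errors(
                    frag, rng, config.homopolymer_error_rate, start
                )
                strand = "reverse" if rng.random() < config.reverse_fraction else "forward"
                rid = f"R{serial:06d}"
                serial += 1
                reads.append(
                    SimRead(
                        read_id=rid,
                        sequence=_revcomp(frag) if strand == "reverse" else frag,
                        gene_id=gene.gene_id,
                        source=source,
                        start=start,
                        length=len(frag),
                        strand=strand,
                        cigar=cigar,
                        hp_errors=errors,
                    )
                )
    return reads


def _apply_hp_errors(
    frag: str, rng: np.random.Generator, rate: float, source_start: int
) -> tuple[str, list[tuple[str, int]], list[tuple[str, int]]]:
    """Inject homopolymer over/under-calls; returns (read, cigar read->source, errors)."""
    n = len(frag)
    if rate <= 0.0:
        return frag, [("M", n)], []
    out: list[str] = []
    cigar: list[tuple[str, int]] = []
    errors: list[tuple[str, int]] = []
    for i, b in enumerate(frag):
        if _run_length_at(frag, i) >= 3 and rng.random() < rate:
            if rng.random() < 0.5:  # over-call: duplicate the base
                out.append(b)
                out.append(b)
                _push(cigar, "M", 1)
                _push(cigar, "I", 1)
                errors.append(("insertion", source_start + i))
            else:  # under-call: drop the base
                _push(cigar, "D", 1)
                errors.append(("deletion", source_start + i))
            continue
        out.append(b)
        _push(cigar, "M", 1)
    return "".join(out), cigar, errors


def reads_table(reads: list[SimRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "gene_id": [r.gene_id for r in reads],
            "source": [r.source for r in reads],
            "start": [r.start for r in reads],
            "length": [r.length for r in reads],
            "strand": [r.strand for r in reads],
            "n_hp_errors": [len(r.hp_errors) for r in reads],
        }
    )


# ---------------------------------------------------------------------------
# Mock assembly
# ---------------------------------------------------------------------------

def simulate_assembly(
    truth: list[GeneTruth], reads: list[SimRead], config: SimConfig
) -> Assembly:
    """Place reads on the planned contigs, splitting boundary-spanning reads.

    A read overlapping a planned break point is split into suffixed
    parts (``<name>.<from>-<to>``, 1-based read coordinates); consecutive
    parts of triangle genes are routed to different contigs in rotation,
    which is what turns them into broken reads.
    """
    by_gene = {g.gene_id: g for g in truth}
    placements: dict[str, list[dict]] = {g_cid: [] for g in truth for g_cid in g.contig_seqs}
    route_state: dict[str, int] = {}
    for read in reads:
        gene = by_gene.get(read.gene_id)
        if gene is None:
            raise KeyError(f"read {read.read_id} has no gene {read.gene_id}")
        _place_read(read, gene, config, placements, route_state)
    contigs = [
        _build_ace_contig(cid, gene.contig_seqs[cid], placements[cid])
        for gene in truth
        for cid, _, _ in gene.contig_plan
    ]
    return Assembly(contigs=contigs, source="simulated")


def _place_read(
    read: SimRead,
    gene: GeneTruth,
    config: SimConfig,
    placements: dict[str, list[dict]],
    route_state: dict[str, int],
) -> None:
    s0, s1 = read.start, read.start + read.length
    cuts = [b for b in gene.boundaries.get(read.source, []) if s0 < b < s1]
    oriented = read.oriented
    if not cuts:
        cid = _covering_contig(gene, read.source, s0, s1)
        if cid is None:
            return
        _add_part(placements[cid], read, read.read_id, 0, read.length, cid, gene)
        return
    # split at the cuts
    edges = [s0] + cuts + [s1]
    parts = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    if gene.category == "cassette":
        targets = [_covering_contig(gene, read.source, a, b) for a, b in parts]
    else:
        # route the two halves along the gene's contig-pair rotation
        idx = route_state.get(gene.gene_id, 0)
        route_state[gene.gene_id] = idx + 1
        pair = gene.pair_routing[idx % len(gene.pair_routing)]
        if read.source in gene.home_contig and gene.home_contig[read.source] in pair:
            first = gene.home_contig[read.source]
            second = pair[1] if pair[0] == first else pair[0]
            pair = (first, second)
        targets = [pair[0], pair[1]]
    for (a, b), cid in zip(parts, targets):
        if cid is None or b - a < config.min_part_length:
            continue
        # read-local coordinates of the part, via the read->source map
        r0, _ = _slice_tgt(read.cigar, a - s0, b - s0)
        r1 = r0 + _cigar_lengths(_slice_tgt(read.cigar, a - s0, b - s0)[1])[0]
        part_id = f"{read.read_id}.{r0 + 1}-{r1}"
        _add_part(placements[cid], read, part_id, a - s0, b - s0, cid, gene)


def _covering_contig(gene: GeneTruth, source: str, a: int, b: int) -> str | None:
    for cid, _, _ in gene.contig_plan:
        entry = gene.maps.get((source, cid))
        if entry is None:
            continue
        (w0, w1), _, _ = entry
        if w0 <= a and b <= w1:
            return cid
    return None


def _add_part(
    bucket: list[dict],
    read: SimRead,
    part_id: str,
    src_a: int,
    src_b: int,
    cid: str,
    gene: GeneTruth,
) -> None:
    """Project read window [src_a, src_b) (read-map coords) onto the contig."""
    entry = gene.maps[(read.source, cid)]
    (w0, w1), cstart, cigar_sc = entry
    abs_a, abs_b = read.start + src_a, read.start + src_b
    if not (w0 <= abs_a and abs_b <= w1):
        return
    # read part -> source window
    r0, rc = _slice_tgt(read.cigar, src_a, src_b)
    part_seq = read.oriented[r0 : r0 + _cigar_lengths(rc)[0]]
    # source window -> contig
    t0, sc = _slice_src(cigar_sc, abs_a - w0, abs_b - w0)
    # source span consumed by sc may be trimmed relative to rc's target span
    src_span_sc = _cigar_lengths(sc)[0]
    src_span_rc = _cigar_lengths(rc)[1]
    if src_span_sc != src_span_rc:
        # a boundary-adjacent indel made the two slices disagree on the
        # source span; skip this part (rare, and harmless to the truth)
        return
    full = _compose(rc, sc)
    bucket.append(
        {
            "read_id": part_id,
            "strand": read.strand,
            "seq": part_seq,
            "cstart": cstart + t0,
            "cigar": full,
        }
    )


def _build_ace_contig(
    contig_id: str, consensus: str, raw_placements: list[dict]
) -> PaddedContig:
    """Assemble gapped placements + a shared padded consensus from edit scripts."""
    L = len(consensus)
    ins_at_by_read: list[dict[int, int]] = []
    base_op_by_read: list[dict[int, str]] = []
    for p in raw_placements:
        ins_at: dict[int, int] = {}
        base_op: dict[int, str] = {}
        tpos = p["cstart"]
        for op, n in p["cigar"]:
            if op == "I":
                ins_at[tpos] = ins_at.get(tpos, 0) + n
            elif op == "M":
                for _ in range(n):
                    base_op[tpos] = "M"
                    tpos += 1
            else:
                for _ in range(n):
                    base_op[tpos] = "D"
                    tpos += 1
        ins_at_by_read.append(ins_at)
        base_op_by_read.append(base_op)

    pads = [0] * (L + 1)
    for ins_at in ins_at_by_read:
        for pos, k in ins_at.items():
            pads[pos] = max(pads[pos], k)

    padded_chars: list[str] = []
    padded_pos_of_base = [0] * (L + 1)  # padded index of base p (or end)
    idx = 0
    for p in range(L):
        idx += pads[p]
        padded_pos_of_base[p] = idx
        padded_chars.append("*" * pads[p] + consensus[p])
        idx += 1
    padded_pos_of_base[L] = idx
    padded_consensus = "".join(padded_chars) + "*" * pads[L]

    out: list[ReadPlacement] = []
    for p, ins_at, base_op in zip(raw_placements, ins_at_by_read, base_op_by_read):
        if not base_op and not ins_at:
            continue
        cstart = p["cstart"]
        cend = max(base_op) + 1 if base_op else cstart
        seq = p["seq"]
        ri = 0
        chunks: list[str] = []
        first_ins = ins_at.get(cstart, 0)
        if first_ins:
            padded_start = padded_pos_of_base[cstart] - pads[cstart]
            chunks.append(seq[ri : ri + first_ins])
            ri += first_ins
            chunks.append("*" * (pads[cstart] - first_ins))
        else:
            padded_start = padded_pos_of_base[cstart]
        for pos in range(cstart, cend):
            if pos != cstart:
                k = ins_at.get(pos, 0)
                chunks.append(seq[ri : ri + k])
                ri += k
                chunks.append("*" * (pads[pos] - k))
            if base_op[pos] == "M":
                chunks.append(seq[ri])
                ri += 1
            else:
                chunks.append("*")
        k = ins_at.get(cend, 0)
        if k and cend != cstart:
            chunks.append(seq[ri : ri + k])
            ri += k
        gapped = "".join(chunks)
        out.append(
            ReadPlacement(
                read_id=p["read_id"],
                base_name=p["read_id"].split(".")[0],
                strand=p["strand"],
                padded_start=padded_start + 1,
                gapped_read=gapped,
                clip_range=(1, len(gapped)),
            )
        )
    out.sort(key=lambda pl: (pl.padded_start, pl.read_id))
    return PaddedContig(
        contig_id=contig_id, padded_consensus=padded_consensus, placements=out
    )


# ---------------------------------------------------------------------------
# End-to-end convenience, truth tables, evaluation
# ---------------------------------------------------------------------------

def simulate(config: SimConfig, outdir: str | Path | None = None):
    """Run genes -> reads -> assembly; optionally write ACE/FASTA/truth TSVs."""
    genes = simulate_genes(config)
    reads = simulate_reads(genes, config) if genes else []
    assembly = simulate_assembly(genes, reads, config) if genes else Assembly([], "simulated")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ace(assembly, outdir / "assembly.ace")
        write_fasta(((r.read_id, r.sequence) for r in reads), outdir / "reads.fasta")
        reads_table(reads).to_csv(outdir / "reads.tsv", sep="\t", index=False)
        for name, table in truth_tables(genes).items():
            table.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
    return genes, reads, assembly


def truth_tables(genes: list[GeneTruth]) -> dict[str, pd.DataFrame]:
    contig_rows, rel_rows, var_rows = [], [], []
    for g in genes:
        for cid, source, window in g.contig_plan:
            contig_rows.append(
                {
                    "contig_id": cid,
                    "gene_id": g.gene_id,
                    "category": g.category,
                    "length": len(g.contig_seqs[cid]),
                }
            )
        for a, b, verdict in g.expected_relations:
            rel_rows.append(
                {"gene_id": g.gene_id, "contig_a": a, "contig_b": b, "verdict": verdict}
            )
        ref_contig = g.contig_plan[0][0]
        for v in g.variants:
            var_rows.append(
                {
                    "gene_id": g.gene_id,
                    "contig_id": ref_contig,
                    "position": v.position,
                    "kind": v.kind,
                    "ref": v.ref,
                    "alt": v.alt,
                }
            )
    return {
        "contigs": pd.DataFrame(contig_rows),
        "relations": pd.DataFrame(rel_rows),
        "variants": pd.DataFrame(var_rows),
    }


def evaluate(predictions: dict, truth: dict) -> dict:
    """Confusion counts, sensitivity and FDR per task.

    ``predictions`` / ``truth`` may contain:
      * ``bcc_verdicts``: mapping frozenset(nodes) -> verdict
      * ``variants``: set of (contig_id, position, kind)
    Sensitivity = TP / (TP + FN); FDR = FP / (TP + FP) (0 without positives).
    """
    out: dict[str, dict] = {}
    if "bcc_verdicts" in truth:
        pred = predictions.get("bcc_verdicts", {})
        tru = truth["bcc_verdicts"]
        tp = sum(1 for k, v in pred.items() if tru.get(k) == v)
        fp = len(pred) - tp
        fn = sum(1 for k in tru if k not in pred or pred[k] != tru[k])
        out["bcc_verdicts"] = _metrics(tp, fp, fn)
    if "variants" in truth:
        pred_v = set(predictions.get("variants", set()))
        tru_v = set(truth["variants"])
        tp = len(pred_v & tru_v)
        out["variants"] = _metrics(tp, len(pred_v - tru_v), len(tru_v - pred_v))
    if not out:
        raise ValueError("no shared task between predictions and truth")
    return out


def _metrics(tp: int, fp: int, fn: int) -> dict:
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "fdr": fp / (tp + fp) if tp + fp else 0.0,
    }


# ---------------------------------------------------------------------------
# Direct MSA simulation (caller calibration)
# ---------------------------------------------------------------------------

def simulate_msa(
    n_sites: int,
    coverage: int,
    n_variant_sites: int,
    minor_fraction: tuple[float, float] = (0.2, 0.5),
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[MsaMatrix, set[int]]:
    """A pooled-sample MSA with planted biallelic SNP columns.

    Variant columns carry a minor-allele *read* fraction drawn uniformly
    from ``minor_fraction`` (the exact number of minor-allele reads is
    planted, so the stated fraction is what the caller actually sees);
    every read base is then miscalled to a random other base with
    probability ``error_rate``.  Returns the matrix and the set of
    planted positions.
    """
    rng = np.random.default_rng(seed)
    consensus = _random_seq(rng, n_sites)
    variant_pos = set(
        int(i) for i in rng.choice(n_sites, size=n_variant_sites, replace=False)
    )
    msa = MsaMatrix(contig_id="sim", consensus=consensus)
    read_ids = [f"r{i}" for i in range(coverage)]
    for p in range(n_sites):
        ref = consensus[p]
        bases = {rid: ref for rid in read_ids}
        if p in variant_pos:
            alt = _substitute(rng, ref)
            f = rng.uniform(*minor_fraction)
            n_minor = max(1, round(f * coverage))
            for idx in rng.choice(coverage, size=n_minor, replace=False):
                bases[read_ids[int(idx)]] = alt
        obs = {}
        for rid, base in bases.items():
            if rng.random() < error_rate:
                others = [b for b in "ACGT" if b != base]
                base = others[rng.integers(3)]
            obs[rid] = base
        msa.columns[(p, 0)] = obs
    return msa, variant_pos
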