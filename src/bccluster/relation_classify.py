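"""Classify contig pairs and BCCs as allelic / duplicated / alternatively spliced.

Contigs joined by broken reads fall into three biological classes that
separate by sequence similarity: divergent alleles of one gene are
nearly identical over their shared span, recent gene duplicates retain
partial similarity, and alternatively spliced exons may share none.

The decision cascade, applied to the best local alignment of each pair
(both strands tried):

1. *allelic* -- at least ``min_block`` (50) aligned columns at
   ``min_ident`` (95) percent identity, and at each end of the alignment
   either only one sequence has unaligned residue (a single-stranded
   overhang, any length) or both unaligned tails are at most
   ``max_flank`` (10) nt;
2. otherwise *duplicated* -- alignment E-value below ``e_cutoff`` (1e-5);
3. otherwise *alt_splice*.

Allelic pairs are merged into a single consensus; a whole BCC is
verdicted from its pair relations after allelic merging.  The module
also hosts the similarity-driven assembly clean-up (singleton-to-contig
merging and redundant-singleton removal) and best-hit clustering against
a homology database ("major clusters").
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "AlignScoring",
    "KarlinAltschul",
    "ClassifyConfig",
    "LocalAlignment",
    "PairRelation",
    "BCCClassification",
    "HitRecord",
    "HitCluster",
    "local_align",
    "evalue",
    "classify_pair",
    "classify_bcc",
    "merge_allelic",
    "merge_redundant",
    "cluster_best_hits",
    "write_classification_tsv",
]


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring: a gap of length k costs gap_open + k * gap_extend."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 5.0
    gap_extend: float = 2.0


@dataclass(frozen=True)
class KarlinAltschul:
    """Ungapped Karlin-Altschul parameters for E = K * m * n * exp(-lambda * S)."""

    K: float = 0.46
    lam: float = 1.28

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("Karlin-Altschul K and lambda must be positive")


@dataclass(frozen=True)
class ClassifyConfig:
    min_block: int = 50
    min_ident: float = 95.0
    max_flank: int = 10
    e_cutoff: float = 1e-5
    scoring: AlignScoring = AlignScoring()
    karlin: KarlinAltschul = KarlinAltschul()
    both_strands: bool = True


@dataclass
class LocalAlignment:
    score: float
    aligned_cols: int
    identities: int
    identity_pct: float
    a_range: tuple[int, int]  # 0-based half-open on a
    b_range: tuple[int, int]  # 0-based half-open on b (aligned orientation)
    e_value: float
    strand: str = "forward"  # strand of b relative to a
    columns: list[tuple[str, str]] = field(default_factory=list, repr=False)


@dataclass
class PairRelation:
    contig_a: str
    contig_b: str
    verdict: str  # allelic | duplicated | alt_splice
    alignment: LocalAlignment | None
    flank_a_left: int = 0
    flank_a_right: int = 0
    flank_b_left: int = 0
    flank_b_right: int = 0


@dataclass
class BCCClassification:
    bcc_id: str
    merged_groups: list[set[str]]
    verdict: str  # allelic | duplicated | alternative_splicing | mixed
    pair_relations: list[PairRelation]


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    group_id: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")


@dataclass
class HitCluster:
    group_id: str
    members: set[str]
    major: bool


# ---------------------------------------------------------------------------
# Alignment and E-values
# ---------------------------------------------------------------------------

def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    a.extend_gap_score = -scoring.gap_extend
    return a


def local_align(
    a: str,
    b: str,
    scoring: AlignScoring = AlignScoring(),
    karlin: KarlinAltschul = KarlinAltschul(),
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two nucleotide sequences.

    Identity is counted over *all* aligned columns including gap columns.
    The E-value uses the ungapped Karlin-Altschul formula over search
    space m*n.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(scoring)
    aln = aligner.align(a.upper(), b.upper())[0]
    sa, sb = str(aln[0]), str(aln[1])
    cols = [(x, y) for x, y in zip(sa, sb)]
    identities = sum(1 for x, y in cols if x == y and x != "-")
    n_cols = len(cols)
    blocks = aln.aligned
    a_range = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
    b_range = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
    return LocalAlignment(
        score=float(aln.score),
        aligned_cols=n_cols,
        identities=identities,
        identity_pct=100.0 * identities / n_cols if n_cols else 0.0,
        a_range=a_range,
        b_range=b_range,
        e_value=evalue(float(aln.score), len(a), len(b), karlin),
        columns=cols,
    )


def evalue(score: float, m: int, n: int, params: KarlinAltschul = KarlinAltschul()) -> float:
    """Expected number of chance local alignments scoring >= ``score``.

    Ungapped Karlin-Altschul form E = K * m * n * exp(-lambda * S) over a
    search space of m * n.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.K * m * n * math.exp(-params.lam * score)


def _best_alignment(a: str, b: str, config: ClassifyConfig) -> LocalAlignment:
    fwd = local_align(a, b, config.scoring, config.karlin)
    if not config.both_strands:
        return fwd
    rev = local_align(a, str(Seq(b).reverse_complement()), config.scoring, config.karlin)
    if rev.score > fwd.score:
        rev.strand = "reverse"
        return rev
    return fwd


# ---------------------------------------------------------------------------
# Pair and BCC classification
# ---------------------------------------------------------------------------

def classify_pair(
    a: str,
    b: str,
    config: ClassifyConfig = ClassifyConfig(),
    id_a: str = "a",
    id_b: str = "b",
) -> PairRelation:
    """Classify one contig pair as allelic / duplicated / alt_splice."""
    aln = _best_alignment(a, b, config)
    fa_l, fa_r = aln.a_range[0], len(a) - aln.a_range[1]
    fb_l, fb_r = aln.b_range[0], len(b) - aln.b_range[1]

    def end_ok(ta: int, tb: int) -> bool:
        # single-stranded overhang of any length, or both tails short
        return min(ta, tb) == 0 or max(ta, tb) <= config.max_flank

    allelic = (
        aln.aligned_cols >= config.min_block
        and aln.identity_pct >= config.min_ident
        and end_ok(fa_l, fb_l)
        and end_ok(fa_r, fb_r)
    )
    if allelic:
        verdict = "allelic"
    elif aln.e_value < config.e_cutoff:
        verdict = "duplicated"
    else:
        verdict = "alt_splice"
    return PairRelation(
        contig_a=id_a,
        contig_b=id_b,
        verdict=verdict,
        alignment=aln,
        flank_a_left=fa_l,
        flank_a_right=fa_r,
        flank_b_left=fb_l,
        flank_b_right=fb_r,
    )


def classify_bcc(
    bcc: set[str] | Sequence[str],
    sequences: Mapping[str, str],
    config: ClassifyConfig = ClassifyConfig(),
    bcc_id: str = "bcc",
) -> BCCClassification:
    """Verdict a whole BCC from its pairwise relations.

    Allelic pairs are unioned into merged groups first (union-find);
    the BCC verdict is then taken over the remaining inter-group pairs:
    all alt_splice -> alternative_splicing; any duplicated -> duplicated;
    a single merged group -> allelic; anything else -> mixed.
    """
    members = sorted(bcc)
    for m in members:
        if m not in sequences:
            raise KeyError(f"no sequence for contig {m}")
    parent = {m: m for m in members}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    relations = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            rel = classify_pair(sequences[a], sequences[b], config, id_a=a, id_b=b)
            relations.append(rel)
            if rel.verdict == "allelic":
                parent[find(a)] = find(b)

    groups: dict[str, set[str]] = {}
    for m in members:
        groups.setdefault(find(m), set()).add(m)
    merged_groups = sorted(groups.values(), key=lambda g: sorted(g)[0])

    if len(merged_groups) == 1:
        verdict = "allelic"
    else:
        inter = [
            r.verdict
            for r in relations
            if find(r.contig_a) != find(r.contig_b)
        ]
        if inter and all(v == "alt_splice" for v in inter):
            verdict = "alternative_splicing"
        elif any(v == "duplicated" for v in inter):
            verdict = "duplicated"
        else:
            verdict = "mixed"
    return BCCClassification(
        bcc_id=bcc_id,
        merged_groups=merged_groups,
        verdict=verdict,
        pair_relations=relations,
    )


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_allelic(
    a: str,
    b: str,
    alignment: LocalAlignment,
    coverage_a: int,
    coverage_b: int,
    id_a: str = "a",
    id_b: str = "b",
) -> str:
    """Merge an allelic contig pair into one consensus sequence.

    Matched columns keep the base; mismatch and gap columns take the
    higher-coverage contig's state (ties go to the lexicographically
    smaller contig id); unaligned overhangs are appended on both ends.
    """
    if alignment is None or not alignment.columns:
        raise ValueError("merge_allelic requires the pair's local alignment")
    b_oriented = (
        str(Seq(b).reverse_complement()) if alignment.strand == "reverse" else b
    )
    a_wins = coverage_a > coverage_b or (coverage_a == coverage_b and id_a <= id_b)

    pa_l, pa_r = alignment.a_range[0], len(a) - alignment.a_range[1]
    pb_l, pb_r = alignment.b_range[0], len(b_oriented) - alignment.b_range[1]

    def pick_overhang(tail_a: str, tail_b: str) -> str:
        if tail_a and tail_b:
            return tail_a if a_wins else tail_b
        return tail_a or tail_b

    left = pick_overhang(a[:pa_l], b_oriented[:pb_l])
    right = pick_overhang(a[alignment.a_range[1]:], b_oriented[alignment.b_range[1]:])

    core = []
    for ca, cb in alignment.columns:
        if ca == cb:
            if ca != "-":
                core.append(ca)
        else:
            chosen = ca if a_wins else cb
            if chosen != "-":
                core.append(chosen)
    return left + "".join(core) + right


def merge_redundant(
    contigs: Sequence[tuple[str, str]],
    singletons: Sequence[tuple[str, str]],
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict]:
    """Fold redundant singletons into contigs and deduplicate singletons.

    Three passes: (1) merge each singleton into a contig when their best
    local alignment has >= min_ident percent identity and the singleton
    has <= max_flank unaligned bases at each end; (2) deduplicate the
    remaining singletons inter se under the same criterion (the shorter
    of a redundant pair is discarded); (3) re-run the singleton-to-contig
    merge on the survivors.  Returns (contigs, remaining singletons,
    report of counts per pass).
    """

    def absorbed(query: str, target: str) -> bool:
        aln = _best_alignment(query, target, config)
        if aln.identity_pct < config.min_ident or aln.aligned_cols < config.min_block:
            return False
        left, right = aln.a_range[0], len(query) - aln.a_range[1]
        return left <= config.max_flank and right <= config.max_flank

    def contig_pass(pool: list[tuple[str, str]]) -> tuple[list[tuple[str, str]], int]:
        kept, merged = [], 0
        for sid, seq in pool:
            if any(absorbed(seq, cseq) for _, cseq in contigs):
                merged += 1
            else:
                kept.append((sid, seq))
        return kept, merged

    contigs = list(contigs)
    remaining, n_pass1 = contig_pass(list(singletons))

    # dedup inter se: longest-first retention
    remaining.sort(key=lambda r: (-len(r[1]), r[0]))
    retained: list[tuple[str, str]] = []
    n_dedup = 0
    for sid, seq in remaining:
        if any(absorbed(seq, rseq) for _, rseq in retained):
            n_dedup += 1
        else:
            retained.append((sid, seq))
    retained.sort(key=lambda r: r[0])

    final, n_pass3 = contig_pass(retained)
    report = {
        "singletons_merged_into_contigs": n_pass1,
        "redundant_singletons_removed": n_dedup,
        "singletons_merged_second_pass": n_pass3,
    }
    return contigs, final, report


# ---------------------------------------------------------------------------
# Best-hit clustering
# ---------------------------------------------------------------------------

def cluster_best_hits(
    hits: Sequence[HitRecord], e_cutoff: float = 1e-5
) -> list[HitCluster]:
    """Cluster queries by shared hits to homology groups.

    Hits at or above ``e_cutoff`` are discarded.  Each query's *best*
    hit (lowest E-value, bit-score then subject id as tie-breaks)
    assigns it a group; a cluster collects every query with *any*
    passing hit to that group, and is flagged *major* when all members'
    best hits point to it.
    """
    passing = [h for h in hits if h.e_value < e_cutoff]
    by_query: dict[str, list[HitRecord]] = {}
    for h in passing:
        by_query.setdefault(h.query_id, []).append(h)
    best_group = {
        q: min(hs, key=lambda h: (h.e_value, -h.bit_score, h.subject_id)).group_id
        for q, hs in by_query.items()
    }
    members_any: dict[str, set[str]] = {}
    for h in passing:
        members_any.setdefault(h.group_id, set()).add(h.query_id)
    clusters = []
    for group_id in sorted(members_any):
        members = members_any[group_id]
        major = all(best_group[q] == group_id for q in members)
        clusters.append(HitCluster(group_id=group_id, members=members, major=major))
    return clusters


def write_classification_tsv(
    classifications: Sequence[BCCClassification], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["bcc_id", "n_members", "members", "verdict", "merged_groups"])
        for c in classifications:
            members = sorted({m for g in c.merged_groups for m in g})
            w.writerow([
                c.bcc_id,
                len(members),
                ",".join(members),
                c.verdict,
                ";".join(",".join(sorted(g)) for g in c.merged_groups),
            ])
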