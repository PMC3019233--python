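"""Column-wise re-alignment, pooled variant calling, filtering and summaries.

Pyrosequencing's dominant error mode is an over- or under-call of the
length of a homopolymer run, which the assembler renders as a gap in the
read-versus-consensus alignment.  The pipeline therefore (i) extracts
pairwise alignments from the assembly, (ii) scrubs gap columns that sit
inside homopolymer context, and (iii) stacks the cleaned alignments into
a column-keyed multiple alignment from which variants are called.

The caller is a two-hypothesis Bayesian model per column.  With k1 reads
of the majority allele, k2 of the runner-up and ko others, sequencing
error rate eps and a site prior pi for polymorphism:

    L0 (monomorphic)  = (1-eps)^k1 * (eps/3)^(k2+ko)
    L1 (biallelic)    = B(k1+1, k2+1) * (1-eps)^(k1+k2) * (eps/3)^ko
                      = k1! k2! / (k1+k2+1)! * ...
    P(variant | data) = pi * L1 / (pi * L1 + (1-pi) * L0)

L1 integrates the unknown pooled allele frequency over a uniform Beta
prior.  The reported probability feeds the downstream filter (defaults:
coverage in [5, 100], probability >= 0.9, indels in homopolymer context
dropped, SNPs in homopolymer context kept).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .assembly_io import (
    MASKED,
    Assembly,
    PaddedContig,
    PairwiseAlignment,
    extract_pairwise_alignments,
)

__all__ = [
    "MsaMatrix",
    "VariantCall",
    "FilterConfig",
    "FilterReport",
    "remove_homopolymer_gaps",
    "build_msa",
    "realign_contig",
    "call_variants",
    "variant_probability",
    "filter_variants",
    "tabulate_changes",
    "summarize_density",
    "write_vcf",
    "homopolymer_positions",
]

_BASES = ("A", "C", "G", "T")
_SYMBOLS = ("A", "C", "G", "T", "-")


@dataclass
class MsaMatrix:
    """Column-keyed multiple alignment for one contig.

    Keys are ``(position, rank)`` with 0-based unpadded consensus
    ``position``; rank 0 is the consensus column itself, rank >= 1 the
    r-th insertion column after that position.  Observations map read id
    to a symbol in A/C/G/T/N/'-'.
    """

    contig_id: str
    columns: dict[tuple[int, int], dict[str, str]] = field(default_factory=dict)
    consensus: str = ""

    def coverage(self, key: tuple[int, int]) -> int:
        return len(self.columns.get(key, {}))

    def sorted_keys(self) -> list[tuple[int, int]]:
        return sorted(self.columns)

    def ref_symbol(self, key: tuple[int, int]) -> str:
        pos, rank = key
        if rank > 0 or pos < 0 or pos >= len(self.consensus):
            return "-"
        return self.consensus[pos]


@dataclass
class VariantCall:
    contig_id: str
    position: int  # 0-based unpadded consensus
    kind: str  # snp | insertion | deletion
    ref_allele: str
    alt_allele: str
    counts: dict[str, int]
    coverage: int
    probability: float
    homopolymer: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")
        if self.coverage != sum(self.counts.values()):
            raise ValueError("coverage must equal the sum of allele counts")


@dataclass(frozen=True)
class FilterConfig:
    min_coverage: int = 5
    max_coverage: int = 100
    min_probability: float = 0.9
    drop_homopolymer_indels: bool = True
    homopolymer_min_run: int = 3

    def __post_init__(self) -> None:
        if self.min_coverage > self.max_coverage:
            raise ValueError("min_coverage exceeds max_coverage")


@dataclass
class FilterReport:
    counts: dict[str, int]
    rejected: list[tuple[VariantCall, str]]


# ---------------------------------------------------------------------------
# Homopolymer-gap scrubbing
# ---------------------------------------------------------------------------

def remove_homopolymer_gaps(
    aln: PairwiseAlignment, min_run: int = 3
) -> tuple[PairwiseAlignment, list[int]]:
    """Scrub gap columns lying in homopolymer context from an alignment.

    A gap column whose opposite base sits in a run of at least
    ``min_run`` identical bases (on the ungapped opposite side) is a
    candidate pyrosequencing homopolymer error.  Insertion columns
    (consensus-side ``*``) are deleted outright; deletion columns
    (read-side ``*``) are masked to ``.`` so the consensus coordinate
    walk stays intact.  Returns the cleaned alignment and the indices
    of affected columns (in the original column numbering).
    """
    cols = aln.columns
    removed: list[int] = []
    # Map each column to its index in the ungapped string of each side.
    out: list[tuple[str, str]] = []
    for i, (c, r) in enumerate(cols):
        gap_on_cons = c == "*"
        gap_on_read = r == "*"
        if gap_on_cons == gap_on_read:  # base/base column (or none; none dropped upstream)
            out.append((c, r))
            continue
        opposite = r if gap_on_cons else c
        side = 1 if gap_on_cons else 0  # which side's ungapped context to scan
        run = _run_around(cols, i, side, opposite)
        if run >= min_run:
            removed.append(i)
            if gap_on_read:
                out.append((c, MASKED))
            # insertion columns vanish entirely
        else:
            out.append((c, r))
    return (
        PairwiseAlignment(
            contig_id=aln.contig_id,
            read_id=aln.read_id,
            columns=out,
            consensus_anchor=aln.consensus_anchor,
        ),
        removed,
    )


def _run_around(
    cols: Sequence[tuple[str, str]], idx: int, side: int, base: str
) -> int:
    """Length of the run of ``base`` on ``side`` adjacent to column idx.

    Counts contiguous columns (skipping gaps on that side) left and
    right of ``idx`` whose character equals ``base``; the opposite base
    itself counts once.
    """
    run = 1
    for step in (-1, 1):
        j = idx + step
        while 0 <= j < len(cols):
            ch = cols[j][side]
            if ch == "*":
                j += step
                continue
            if ch == base:
                run += 1
                j += step
            else:
                break
    return run


# ---------------------------------------------------------------------------
# MSA construction
# ---------------------------------------------------------------------------

def build_msa(
    alignments: Sequence[PairwiseAlignment], consensus: str | None = None
) -> MsaMatrix:
    """Stack pairwise alignments of one contig into a column-keyed MSA.

    Insertion columns are keyed ``(pos, rank)`` where ``pos`` is the
    consensus position the insertion follows; reads that span an
    insertion locus without carrying the insertion are recorded there as
    '-', so insertion columns see the full spanning coverage.
    """
    if not alignments:
        return MsaMatrix(contig_id="", consensus=consensus or "")
    contig_ids = {a.contig_id for a in alignments}
    if len(contig_ids) > 1:
        raise ValueError(f"alignments from multiple contigs: {sorted(contig_ids)}")
    contig_id = alignments[0].contig_id

    msa = MsaMatrix(contig_id=contig_id, consensus=consensus or "")
    spans: dict[str, tuple[int, int]] = {}  # read -> covered consensus [lo, hi) 0-based
    for aln in alignments:
        pos = aln.consensus_anchor - 1  # 0-based position of next consensus base
        first = pos
        rank = 0
        for c, r in aln.columns:
            if c == "*":
                rank += 1
                key = (pos - 1, rank)
                if r not in ("N", MASKED):
                    msa.columns.setdefault(key, {})[aln.read_id] = r if r != "*" else "-"
            else:
                rank = 0
                key = (pos, 0)
                if r == "*":
                    msa.columns.setdefault(key, {})[aln.read_id] = "-"
                elif r not in ("N", MASKED):
                    msa.columns.setdefault(key, {})[aln.read_id] = r
                pos += 1
        spans[aln.read_id] = (first, pos)

    # spanning reads observe '-' at insertion columns they do not carry
    for (pos, rank), obs in msa.columns.items():
        if rank == 0:
            continue
        for read_id, (lo, hi) in spans.items():
            if read_id not in obs and lo <= pos and pos + 1 < hi:
                obs[read_id] = "-"

    if consensus is None:
        # partial reconstruction from majority where covered
        length = max((p for p, r in msa.columns if r == 0), default=-1) + 1
        chars = ["N"] * length
        for (p, r), obs in msa.columns.items():
            if r == 0 and obs:
                vals = [v for v in obs.values() if v in _BASES]
                if vals:
                    chars[p] = max(set(vals), key=vals.count)
        msa.consensus = "".join(chars)
    return msa


def realign_contig(
    contig: PaddedContig, min_run: int = 3
) -> MsaMatrix:
    """Pairwise extraction + homopolymer-gap scrubbing + MSA for one contig."""
    alns = extract_pairwise_alignments(Assembly(contigs=[contig]))
    cleaned = [remove_homopolymer_gaps(a, min_run=min_run)[0] for a in alns]
    return build_msa(cleaned, consensus=contig.unpadded_consensus)


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------

def variant_probability(
    k1: int, k2: int, ko: int = 0, error_rate: float = 0.01, prior: float = 0.005
) -> float:
    """Posterior probability that a column is a real biallelic variant.

    Computed in log space; see the module docstring for the model.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    log_e3 = math.log(error_rate / 3.0)
    log_1e = math.log1p(-error_rate)
    log_l0 = k1 * log_1e + (k2 + ko) * log_e3
    log_beta = math.lgamma(k1 + 1) + math.lgamma(k2 + 1) - math.lgamma(k1 + k2 + 2)
    log_l1 = log_beta + (k1 + k2) * log_1e + ko * log_e3
    a = math.log(prior) + log_l1
    b = math.log1p(-prior) + log_l0
    m = max(a, b)
    return math.exp(a - m) / (math.exp(a - m) + math.exp(b - m))


def homopolymer_positions(consensus: str, min_run: int = 3) -> set[int]:
    """0-based positions inside or adjacent (distance 1) to a run >= min_run."""
    out: set[int] = set()
    i = 0
    n = len(consensus)
    while i < n:
        j = i
        while j < n and consensus[j] == consensus[i]:
            j += 1
        if j - i >= min_run:
            out.update(range(max(0, i - 1), min(n, j + 1)))
        i = j
    return out


def call_variants(
    msa: MsaMatrix,
    error_rate: float = 0.01,
    prior: float = 0.005,
    homopolymer_min_run: int = 3,
) -> list[VariantCall]:
    """Call SNPs and indels from a column-keyed MSA.

    A call is emitted for every column whose runner-up allele has at
    least one supporting read; the posterior probability is attached and
    thresholding is left to :func:`filter_variants`.  Runs of adjacent
    single-base deletion calls are merged into one deletion call (the
    probability of the merged call is the maximum over its columns).
    """
    hp = homopolymer_positions(msa.consensus, homopolymer_min_run)
    calls: list[VariantCall] = []
    for key in msa.sorted_keys():
        pos, rank = key
        obs = msa.columns[key]
        counts = {s: 0 for s in _SYMBOLS}
        for sym in obs.values():
            if sym in counts:
                counts[sym] += 1
        coverage = sum(counts.values())
        if coverage == 0:
            continue
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        (a1, k1), (a2, k2) = ordered[0], ordered[1]
        if k2 == 0:
            continue
        ko = coverage - k1 - k2
        prob = variant_probability(k1, k2, ko, error_rate, prior)
        ref = msa.ref_symbol(key)
        if rank > 0:
            kind = "insertion"
            alt = a1 if a1 != "-" else a2
            ref_allele, alt_allele = "-", alt
        elif "-" in (a1, a2):
            kind = "deletion"
            ref_allele, alt_allele = ref, "-"
        else:
            kind = "snp"
            alt = a1 if a1 != ref else a2
            ref_allele, alt_allele = ref, alt
        calls.append(
            VariantCall(
                contig_id=msa.contig_id,
                position=pos,
                kind=kind,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                counts={a: c for a, c in counts.items()},
                coverage=coverage,
                probability=prob,
                homopolymer=pos in hp,
            )
        )
    return _merge_adjacent_deletions(calls)


def _merge_adjacent_deletions(calls: list[VariantCall]) -> list[VariantCall]:
    out: list[VariantCall] = []
    for call in calls:
        prev = out[-1] if out else None
        if (
            prev is not None
            and call.kind == "deletion"
            and prev.kind == "deletion"
            and prev.contig_id == call.contig_id
            and call.position == prev.position + len(prev.ref_allele)
        ):
            prev.ref_allele += call.ref_allele
            prev.probability = max(prev.probability, call.probability)
            prev.homopolymer = prev.homopolymer or call.homopolymer
        else:
            out.append(call)
    return out


def filter_variants(
    calls: Sequence[VariantCall], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantCall], FilterReport]:
    """Apply the coverage / probability / homopolymer-indel filters.

    Each rejected call is attributed to the first failing rule in the
    order: coverage too low, coverage too high, probability too low,
    homopolymer indel.  SNPs in homopolymer context are kept.
    """
    kept: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []
    counts = {
        "coverage_low": 0,
        "coverage_high": 0,
        "low_probability": 0,
        "homopolymer_indel": 0,
    }
    for call in calls:
        if call.coverage < config.min_coverage:
            reason = "coverage_low"
        elif call.coverage > config.max_coverage:
            reason = "coverage_high"
        elif call.probability < config.min_probability:
            reason = "low_probability"
        elif (
            config.drop_homopolymer_indels
            and call.kind in ("insertion", "deletion")
            and call.homopolymer
        ):
            reason = "homopolymer_indel"
        else:
            kept.append(call)
            continue
        counts[reason] += 1
        rejected.append((call, reason))
    return kept, FilterReport(counts=counts, rejected=rejected)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def tabulate_changes(calls: Sequence[VariantCall]) -> dict:
    """Substitution spectrum, per-base indel counts, and ts/tv totals."""
    matrix = pd.DataFrame(0, index=list(_BASES), columns=list(_BASES))
    ins_counts = {b: 0 for b in _BASES}
    del_counts = {b: 0 for b in _BASES}
    transitions = transversions = 0
    for call in calls:
        if call.kind == "snp":
            ref, alt = call.ref_allele, call.alt_allele
            if ref in _BASES and alt in _BASES:
                matrix.loc[ref, alt] += 1
                if (ref, alt) in _TRANSITIONS:
                    transitions += 1
                else:
                    transversions += 1
        elif call.kind == "insertion":
            for b in call.alt_allele:
                if b in _BASES:
                    ins_counts[b] += 1
        elif call.kind == "deletion":
            for b in call.ref_allele:
                if b in _BASES:
                    del_counts[b] += 1
    return {
        "substitutions": matrix,
        "insertion_bases": ins_counts,
        "deletion_bases": del_counts,
        "transitions": transitions,
        "transversions": transversions,
    }


def summarize_density(
    calls: Sequence[VariantCall],
    contigs: Mapping[str, tuple[int, int]],
) -> tuple[pd.DataFrame, dict]:
    """Per-contig and global variant densities.

    ``contigs`` maps contig id to (unpadded length, read count).  The
    global SNP frequency is total SNPs over total bp and the reported
    spacing is round(1 / frequency) (None when there are no calls).
    """
    for cid, (length, _) in contigs.items():
        if length <= 0:
            raise ValueError(f"non-positive length for contig {cid}")
    n_snp = {cid: 0 for cid in contigs}
    n_indel = {cid: 0 for cid in contigs}
    for call in calls:
        if call.contig_id not in contigs:
            raise KeyError(f"call on unknown contig {call.contig_id}")
        if call.kind == "snp":
            n_snp[call.contig_id] += 1
        else:
            n_indel[call.contig_id] += 1
    rows = []
    for cid in sorted(contigs):
        length, n_reads = contigs[cid]
        rows.append(
            {
                "contig": cid,
                "length": length,
                "n_reads": n_reads,
                "n_snp": n_snp[cid],
                "n_indel": n_indel[cid],
                "snp_per_bp": n_snp[cid] / length,
                "indel_per_bp": n_indel[cid] / length,
            }
        )
    table = pd.DataFrame(rows)
    total_bp = sum(length for length, _ in contigs.values())
    snp_freq = sum(n_snp.values()) / total_bp if total_bp else 0.0
    indel_freq = sum(n_indel.values()) / total_bp if total_bp else 0.0
    summary = {
        "snp_per_bp": snp_freq,
        "indel_per_bp": indel_freq,
        "snp_spacing_bp": round(1.0 / snp_freq) if snp_freq > 0 else None,
        "indel_spacing_bp": round(1.0 / indel_freq) if indel_freq > 0 else None,
    }
    return table, summary


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
{contigs}##INFO=<ID=DP,Number=1,Type=Integer,Description="Read coverage at the site">
##INFO=<ID=PR,Number=1,Type=Float,Description="Posterior probability of the variant">
##INFO=<ID=HP,Number=0,Type=Flag,Description="Site in homopolymer context">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    contigs: Mapping[str, str],
) -> None:
    """Write calls as minimal VCF 4.2.

    ``contigs`` maps contig id to its unpadded consensus, used to anchor
    indels on the preceding reference base (VCF left-anchoring).
    """
    for call in calls:
        if call.contig_id not in contigs:
            raise KeyError(f"call on unknown contig {call.contig_id}")
    contig_lines = "".join(
        f"##contig=<ID={cid},length={len(seq)}>\n" for cid, seq in sorted(contigs.items())
    )
    lines = [_VCF_HEADER.format(contigs=contig_lines)]
    for call in sorted(calls, key=lambda c: (c.contig_id, c.position)):
        cons = contigs[call.contig_id]
        p = call.position
        if call.kind == "snp":
            pos1, ref, alt = p + 1, call.ref_allele, call.alt_allele
        elif call.kind == "deletion":
            if p >= 1:
                anchor = cons[p - 1]
                pos1, ref, alt = p, anchor + call.ref_allele, anchor
            else:  # deletion at contig start: anchor on the following base
                nxt = cons[p + len(call.ref_allele)]
                pos1, ref, alt = 1, call.ref_allele + nxt, nxt
        else:  # insertion after position p
            anchor = cons[p] if 0 <= p < len(cons) else "N"
            pos1, ref, alt = p + 1, anchor, anchor + call.alt_allele
        info = f"DP={call.coverage};PR={call.probability:.6g}"
        if call.homopolymer:
            info += ";HP"
        lines.append(
            f"{call.contig_id}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n"
        )
    Path(path).write_text("".join(lines))


def write_density_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_spectrum_tsv(spectrum: dict, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["ref", "alt", "count"])
        mat = spectrum["substitutions"]
        for ref in mat.index:
            for alt in mat.columns:
                if ref != alt:
                    w.writerow([ref, alt, int(mat.loc[ref, alt])])
        for b, c in spectrum["insertion_bases"].items():
            w.writerow(["-", b, c])
        for b, c in spectrum["deletion_bases"].items():
            w.writerow([b, "-", c])
        w.writerow(["transitions", "", spectrum["transitions"]])
        w.writerow(["transversions", "", spectrum["transversions"]])
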