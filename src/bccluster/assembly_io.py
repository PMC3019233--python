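"""ACE / FASTA input-output and per-read pairwise alignment extraction.

An ACE file records, per contig, a padded consensus (with ``*`` pad
characters marking columns where at least one read carries an insertion)
and the gapped placement of every read against that consensus.  This
module parses ACE into light dataclasses, writes them back out, recovers
base read names from assembler split-read identifiers, and turns each
read placement into an explicit column-by-column pairwise alignment
against the (unpadded) consensus -- the raw material for both the
broken-read graph and the variant-calling pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Sequencing import Ace as _Ace

__all__ = [
    "AceParseError",
    "AceConsistencyError",
    "ReadPlacement",
    "PaddedContig",
    "Assembly",
    "PairwiseAlignment",
    "DEFAULT_NAME_PATTERN",
    "read_ace",
    "write_ace",
    "read_fasta",
    "write_fasta",
    "base_read_name",
    "extract_pairwise_alignments",
]

#: Strips assembler split-read suffixes of the form ``.<int>-<int>``
#: (sub-range style, e.g. ``READ12.103-455``) or ``_part<int>``.  The
#: original assembler's convention is not universal, so this is always
#: overridable wherever a name pattern is accepted.
DEFAULT_NAME_PATTERN = r"^(.+?)(?:\.\d+-\d+|_part\d+)$"

#: Symbol used in pairwise-alignment columns for a read observation that
#: has been masked (e.g. a homopolymeric gap scrubbed before re-alignment).
MASKED = "."

_GAPPED_ALPHABET = set("ACGTNacgtn*")


class AceParseError(ValueError):
    """Malformed ACE syntax (reported with a line number)."""


class AceConsistencyError(ValueError):
    """Internally inconsistent ACE content (e.g. AF without a matching RD)."""


@dataclass
class ReadPlacement:
    """One read's gapped placement on a padded contig consensus.

    ``gapped_read`` is stored in the orientation in which it aligns to
    the consensus (the ACE convention: reverse-strand reads appear
    already reverse-complemented), with ``*`` pads.  ``clip_range`` is
    the 1-based inclusive quality-clip interval on the gapped read.
    """

    read_id: str
    base_name: str
    strand: str  # "forward" | "reverse"
    padded_start: int  # 1-based on the padded consensus
    gapped_read: str
    clip_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r} for read {self.read_id}")
        lo, hi = self.clip_range
        if not (1 <= lo <= hi <= len(self.gapped_read)):
            raise ValueError(
                f"clip range {self.clip_range} outside read {self.read_id} "
                f"of length {len(self.gapped_read)}"
            )
        bad = set(self.gapped_read) - _GAPPED_ALPHABET
        if bad:
            raise ValueError(f"illegal characters {bad} in read {self.read_id}")


@dataclass
class PaddedContig:
    contig_id: str
    padded_consensus: str
    placements: list[ReadPlacement] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.placements)

    @property
    def unpadded_consensus(self) -> str:
        return self.padded_consensus.replace("*", "")

    @property
    def padded_length(self) -> int:
        return len(self.padded_consensus)

    @property
    def unpadded_length(self) -> int:
        return len(self.padded_consensus) - self.padded_consensus.count("*")


@dataclass
class Assembly:
    contigs: list[PaddedContig]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate contig ids in assembly")

    @property
    def n_reads(self) -> int:
        return sum(c.n_reads for c in self.contigs)

    def contig(self, contig_id: str) -> PaddedContig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass
class PairwiseAlignment:
    """Column list of (consensus_char, read_char) for one read placement.

    ``*`` marks a gap on either side; ``.`` on the read side marks a
    masked observation (still consumes a consensus base, contributes no
    evidence).  ``consensus_anchor`` is the 1-based *unpadded* consensus
    position of the first column.
    """

    contig_id: str
    read_id: str
    columns: list[tuple[str, str]]
    consensus_anchor: int

    def consensus_fragment(self) -> str:
        return "".join(c for c, _ in self.columns if c != "*")

    def read_fragment(self) -> str:
        return "".join(r for _, r in self.columns if r not in ("*", MASKED))


# ---------------------------------------------------------------------------
# ACE reading / writing
# ---------------------------------------------------------------------------

def read_ace(path: str | Path) -> Assembly:
    """Parse a consed-dialect ACE file into an :class:`Assembly`.

    The AS header counts are validated against the parsed content; an AF
    line without a matching RD entry raises :class:`AceConsistencyError`.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        m = re.match(r"^AS\s+(\d+)\s+(\d+)\s*$", first)
        if not m:
            raise AceParseError(f"{path}:1: expected 'AS <contigs> <reads>' header")
        n_contigs, n_reads = int(m.group(1)), int(m.group(2))

    if n_contigs == 0:
        return Assembly(contigs=[], source=str(path))

    with open(path) as fh:
        record = _Ace.read(fh)

    contigs: list[PaddedContig] = []
    for co in record.contigs:
        af_by_name = {af.name: af for af in co.af}
        rd_names = {r.rd.name for r in co.reads}
        missing = set(af_by_name) - rd_names
        if missing:
            raise AceConsistencyError(
                f"contig {co.name}: AF lines without RD entries: {sorted(missing)}"
            )
        placements = []
        for r in co.reads:
            af = af_by_name.get(r.rd.name)
            if af is None:
                raise AceConsistencyError(
                    f"contig {co.name}: RD {r.rd.name} has no AF line"
                )
            seq = r.rd.sequence
            if r.qa is not None and r.qa.qual_clipping_start > 0:
                clip = (r.qa.qual_clipping_start, r.qa.qual_clipping_end)
            else:
                clip = (1, len(seq))
            placements.append(
                ReadPlacement(
                    read_id=r.rd.name,
                    base_name=base_read_name(r.rd.name, DEFAULT_NAME_PATTERN),
                    strand="reverse" if af.coru == "C" else "forward",
                    padded_start=af.padded_start,
                    gapped_read=seq,
                    clip_range=clip,
                )
            )
        contigs.append(
            PaddedContig(
                contig_id=co.name,
                padded_consensus=co.sequence,
                placements=placements,
            )
        )

    assembly = Assembly(contigs=contigs, source=str(path))
    if len(contigs) != n_contigs:
        raise AceConsistencyError(
            f"AS header declares {n_contigs} contigs but file has {len(contigs)}"
        )
    if assembly.n_reads != n_reads:
        raise AceConsistencyError(
            f"AS header declares {n_reads} reads but file has {assembly.n_reads}"
        )
    return assembly


_DS_LINE = "DS CHROMAT_FILE: {name} PHD_FILE: {name}.phd.1 TIME: Thu Jan 1 00:00:00 1970"


def write_ace(assembly: Assembly, path: str | Path) -> None:
    """Write an :class:`Assembly` as a consed-dialect ACE file.

    Flat base qualities (BQ 30) are emitted for every contig since the
    in-memory model carries none.
    """
    ids = [c.contig_id for c in assembly.contigs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate contig ids")
    lines: list[str] = [f"AS {len(assembly.contigs)} {assembly.n_reads}", ""]
    for contig in assembly.contigs:
        lines.append(
            f"CO {contig.contig_id} {contig.padded_length} {contig.n_reads} 0 U"
        )
        lines.extend(_wrap(contig.padded_consensus, 60))
        lines.append("")
        lines.append("BQ")
        lines.extend(_wrap_values(["30"] * contig.unpadded_length, 30))
        lines.append("")
        for p in contig.placements:
            coru = "C" if p.strand == "reverse" else "U"
            lines.append(f"AF {p.read_id} {coru} {p.padded_start}")
        lines.append("")
        for p in contig.placements:
            lines.append(f"RD {p.read_id} {len(p.gapped_read)} 0 0")
            lines.extend(_wrap(p.gapped_read, 60))
            lines.append("")
            lo, hi = p.clip_range
            lines.append(f"QA {lo} {hi} {lo} {hi}")
            lines.append(_DS_LINE.format(name=p.read_id))
            lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def _wrap(s: str, width: int) -> list[str]:
    return [s[i : i + width] for i in range(0, len(s), width)] or [""]


def _wrap_values(vals: Sequence[str], per_line: int) -> list[str]:
    return [
        " ".join(vals[i : i + per_line]) for i in range(0, len(vals), per_line)
    ] or [""]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into ``(id, sequence)`` tuples."""
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: sequence line before first FASTA header")
            break
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Read names
# ---------------------------------------------------------------------------

def base_read_name(read_id: str, pattern: str = DEFAULT_NAME_PATTERN) -> str:
    """Recover the base (pre-split) read name from a split-read identifier.

    ``pattern`` must contain one capture group holding the base name.  A
    non-matching ``read_id`` is returned unchanged (the read was not
    split, or the assembler used a different suffix dialect).
    """
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid read-name pattern {pattern!r}: {exc}") from exc
    if rx.groups < 1:
        raise ValueError(f"read-name pattern {pattern!r} has no capture group")
    m = rx.match(read_id)
    return m.group(1) if m else read_id


# ---------------------------------------------------------------------------
# Pairwise alignment extraction
# ---------------------------------------------------------------------------

def extract_pairwise_alignments(assembly: Assembly) -> list[PairwiseAlignment]:
    """One pairwise alignment per (contig, read) placement.

    Only the quality-clipped region of each read is used.  Columns where
    both sides are pads carry no information and are dropped.  Because
    ACE stores reads in consensus orientation, no re-orientation is
    needed here; the strand flag is metadata only.
    """
    out = []
    for contig in assembly.contigs:
        cons = contig.padded_consensus
        # unpadded position (1-based) of each padded index's base
        unpadded_at = []
        u = 0
        for ch in cons:
            if ch != "*":
                u += 1
            unpadded_at.append(u)
        for p in contig.placements:
            lo, hi = p.clip_range
            start = p.padded_start - 1 + (lo - 1)  # 0-based on padded consensus
            segment = p.gapped_read[lo - 1 : hi]
            if start < 0 or start + len(segment) > len(cons):
                raise ValueError(
                    f"read {p.read_id} extends beyond consensus of {contig.contig_id}"
                )
            columns = []
            for i, rch in enumerate(segment):
                cch = cons[start + i]
                if cch == "*" and rch == "*":
                    continue
                columns.append((cch.upper(), rch.upper()))
            if not columns:
                continue
            # anchor: unpadded position of the first non-pad consensus char
            # at/after the start; for a leading insertion column this is the
            # position the insertion precedes.
            anchor = unpadded_at[start] if cons[start] != "*" else unpadded_at[start] + 1
            out.append(
                PairwiseAlignment(
                    contig_id=contig.contig_id,
                    read_id=p.read_id,
                    columns=columns,
                    consensus_anchor=anchor,
                )
            )
    return out
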