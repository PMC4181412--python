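"""Extended-pileup, VCF and Newick input/output.

All genomic coordinates handled by this package are 1-based and inclusive
(:data:`COORDINATE_BASE`).  The extended pileup is a TSV with one row per
genomic site::

    chrom  pos  ref  calls

where ``calls`` is a comma-separated list of per-read base calls, each
encoded as ``base:quality:strand:read_position:read_start`` (strand is
``+``/``-``; ``read_position`` is the 1-based offset of the call within its
read; ``read_start`` is the genomic start coordinate of the carrying read).
Standard mpileup does not retain read position or read start per call,
which the error filters downstream require, hence the bespoke column.
``N`` calls are parsed and round-tripped but ignored by every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

#: Coordinate convention used by every module in this package.
COORDINATE_BASE = 1

NUCLEOTIDES = ("A", "C", "G", "T", "N")

PILEUP_HEADER = ["chrom", "pos", "ref", "calls"]


class PileupFormatError(ValueError):
    """Raised for malformed or mis-ordered extended-pileup input."""


@dataclass(frozen=True)
class BaseCall:
    """One aligned base call at a genomic site."""

    base: str
    quality: int
    strand: str  # "+" or "-"
    read_position: int  # 1-based offset within the read
    read_start: int  # genomic start coordinate of the carrying read

    def __post_init__(self) -> None:
        if self.base not in NUCLEOTIDES:
            raise ValueError(f"invalid base {self.base!r}")
        if not 0 <= self.quality <= 60:
            raise ValueError(f"quality {self.quality} outside [0, 60]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.read_position < 1:
            raise ValueError("read_position is 1-based and must be >= 1")

    @property
    def error_probability(self) -> float:
        """Phred-implied miscall probability ``10**(-Q/10)``."""
        return 10.0 ** (-0.1 * self.quality)


class PileupColumn:
    """All base calls observed at one genomic site.

    Calls are stored as parallel numpy arrays for speed; :attr:`calls`
    materialises :class:`BaseCall` records on demand.
    """

    __slots__ = ("chrom", "pos", "ref_base", "bases", "quals", "forward",
                 "read_positions", "read_starts")

    def __init__(self, chrom: str, pos: int, ref_base: str,
                 bases: np.ndarray, quals: np.ndarray, forward: np.ndarray,
                 read_positions: np.ndarray, read_starts: np.ndarray) -> None:
        self.chrom = chrom
        self.pos = int(pos)
        self.ref_base = ref_base
        self.bases = np.asarray(bases, dtype="U1")
        self.quals = np.asarray(quals, dtype=np.int64)
        self.forward = np.asarray(forward, dtype=bool)
        self.read_positions = np.asarray(read_positions, dtype=np.int64)
        self.read_starts = np.asarray(read_starts, dtype=np.int64)

    @classmethod
    def from_calls(cls, chrom: str, pos: int, ref_base: str,
                   calls: Iterable[BaseCall]) -> "PileupColumn":
        calls = list(calls)
        return cls(
            chrom, pos, ref_base,
            np.array([c.base for c in calls], dtype="U1"),
            np.array([c.quality for c in calls], dtype=np.int64),
            np.array([c.strand == "+" for c in calls], dtype=bool),
            np.array([c.read_position for c in calls], dtype=np.int64),
            np.array([c.read_start for c in calls], dtype=np.int64),
        )

    @property
    def calls(self) -> list[BaseCall]:
        return [
            BaseCall(b, int(q), "+" if f else "-", int(rp), int(rs))
            for b, q, f, rp, rs in zip(self.bases, self.quals, self.forward,
                                       self.read_positions, self.read_starts)
        ]

    @property
    def coverage(self) -> int:
        """Total number of base calls n (``N`` calls excluded)."""
        return int(np.sum(self.bases != "N"))

    def variant_count(self, alt_base: str) -> int:
        """Number of calls r supporting ``alt_base``."""
        return int(np.sum(self.bases == alt_base))

    def alternate_bases(self) -> list[str]:
        """Non-reference, non-N bases observed at this site."""
        seen = set(self.bases.tolist()) - {self.ref_base, "N"}
        return sorted(seen)

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PileupColumn):
            return NotImplemented
        return (self.chrom == other.chrom and self.pos == other.pos
                and self.ref_base == other.ref_base
                and np.array_equal(self.bases, other.bases)
                and np.array_equal(self.quals, other.quals)
                and np.array_equal(self.forward, other.forward)
                and np.array_equal(self.read_positions, other.read_positions)
                and np.array_equal(self.read_starts, other.read_starts))

    def __repr__(self) -> str:
        return (f"PileupColumn({self.chrom}:{self.pos} ref={self.ref_base} "
                f"n={len(self)})")


def _open(path, mode: str) -> IO[str]:
    if hasattr(path, "read") or hasattr(path, "write"):
        return path
    return open(path, mode)


def read_pileup(path) -> list[PileupColumn]:
    """Read an extended pileup TSV.

    Columns are returned in ascending (chrom, pos) order; the file must
    already be sorted that way.  Raises :class:`PileupFormatError` naming
    the offending line for malformed rows or non-monotone positions.
    """
    handle = _open(path, "r")
    close = handle is not path
    columns: list[PileupColumn] = []
    try:
        header = handle.readline()
        if header.strip() and header.split("\t")[0].strip() != "chrom":
            raise PileupFormatError("line 1: missing extended-pileup header")
        last_key: tuple[str, int] | None = None
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise PileupFormatError(
                    f"line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}")
            chrom, pos_s, ref, calls_s = parts
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise PileupFormatError(
                    f"line {lineno}: bad position {pos_s!r}") from exc
            key = (chrom, pos)
            if last_key is not None and key <= last_key and chrom == last_key[0]:
                raise PileupFormatError(
                    f"line {lineno}: positions not strictly increasing "
                    f"({last_key} then {key})")
            last_key = key
            calls = []
            if calls_s:
                for item in calls_s.split(","):
                    bits = item.split(":")
                    if len(bits) != 5:
                        raise PileupFormatError(
                            f"line {lineno}: bad call record {item!r}")
                    try:
                        calls.append(BaseCall(bits[0], int(bits[1]), bits[2],
                                              int(bits[3]), int(bits[4])))
                    except ValueError as exc:
                        raise PileupFormatError(
                            f"line {lineno}: bad call record {item!r}: {exc}"
                        ) from exc
            columns.append(PileupColumn.from_calls(chrom, pos, ref, calls))
    finally:
        if close:
            handle.close()
    return columns


def write_pileup(columns: Sequence[PileupColumn], path) -> None:
    """Write columns as an extended pileup TSV (inverse of read_pileup)."""
    handle = _open(path, "w")
    close = handle is not path
    try:
        handle.write("\t".join(PILEUP_HEADER) + "\n")
        for col in columns:
            records = ",".join(
                f"{b}:{q}:{'+' if f else '-'}:{rp}:{rs}"
                for b, q, f, rp, rs in zip(col.bases, col.quals, col.forward,
                                           col.read_positions, col.read_starts)
            )
            handle.write(f"{col.chrom}\t{col.pos}\t{col.ref_base}\t{records}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# VCF output

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=clonaltree
##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency r/n">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage n at the site">
##INFO=<ID=RC,Number=1,Type=Integer,Description="Variant base call count r">
##INFO=<ID=CILO,Number=1,Type=Float,Description="95% Clopper-Pearson lower bound">
##INFO=<ID=CIHI,Number=1,Type=Float,Description="95% Clopper-Pearson upper bound">
##INFO=<ID=PCF,Number=1,Type=Float,Description="Bonferroni-adjusted Chernoff P, forward calls">
##INFO=<ID=PCR,Number=1,Type=Float,Description="Bonferroni-adjusted Chernoff P, reverse calls">
##INFO=<ID=PFF,Number=1,Type=Float,Description="Bonferroni-adjusted flanking binomial P, forward calls">
##INFO=<ID=PFR,Number=1,Type=Float,Description="Bonferroni-adjusted flanking binomial P, reverse calls">
##INFO=<ID=RS,Number=1,Type=Integer,Description="Distinct read-start positions among variant calls">
##INFO=<ID=CAT,Number=1,Type=String,Description="Annotation category">
"""


def write_vcf(mutations, path) -> None:
    """Write called somatic mutations as VCF v4.2 text.

    Positions are 1-based as in VCF.  The INFO column carries the variant
    frequency, the four Bonferroni-adjusted P values, the confidence
    interval and the distinct read-start count, so calls round-trip through
    any VCF reader.
    """
    mutations = list(mutations)
    handle = _open(path, "w")
    close = handle is not path
    try:
        handle.write(_VCF_HEADER)
        for chrom in sorted({m.chrom for m in mutations}):
            handle.write(f"##contig=<ID={chrom}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m in sorted(mutations, key=lambda m: (m.chrom, m.pos)):
            info = (f"AF={m.frequency:.6g};DP={m.n};RC={m.r}"
                    f";CILO={m.ci_low:.6g};CIHI={m.ci_high:.6g}"
                    f";PCF={m.adjusted_p[0]:.6g};PCR={m.adjusted_p[1]:.6g}"
                    f";PFF={m.adjusted_p[2]:.6g};PFR={m.adjusted_p[3]:.6g}"
                    f";RS={m.distinct_read_starts};CAT={m.category}")
            handle.write(f"{m.chrom}\t{m.pos}\t.\t{m.ref_base}\t{m.alt_base}"
                         f"\t.\tPASS\t{info}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Newick output

class TreeStructureError(ValueError):
    """Raised when a tree is not a full binary tree."""


def newick_string(tree) -> str:
    """Render a proliferation tree as Newick.

    Internal nodes are labelled ``L<leafcount>_M<mutations>`` where the
    mutation count is the number of mutations assigned to that node (0 if
    unassigned); leaves are labelled ``L1``.  Raises
    :class:`TreeStructureError` if any node has exactly one child.
    """

    def render(node) -> str:
        kids = node.children
        if len(kids) == 0:
            return "L1"
        if len(kids) != 2:
            raise TreeStructureError(
                f"node with leaf count {node.leaf_count} has {len(kids)} "
                "children; proliferation trees are full binary trees")
        label = f"L{node.leaf_count}_M{node.assigned_mutation_count}"
        return f"({render(kids[0])},{render(kids[1])}){label}"

    return render(tree.root) + ";"


def write_newick(tree, path) -> None:
    """Write one proliferation tree to ``path`` in Newick format."""
    handle = _open(path, "w")
    close = handle is not path
    try:
        handle.write(newick_string(tree) + "\n")
    finally:
        if close:
            handle.close()
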