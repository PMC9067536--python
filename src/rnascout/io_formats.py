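"""Readers/writers for every on-disk format the pipeline touches.

Coordinate convention: 0-based half-open everywhere, including BED output
(BED's native convention). Sequences are stored as DNA (T); U appears only
in rendered Stockholm files and is mapped back to T on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its schema or an invariant."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STRANDS = ("+", "-", ".")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise FormatError("contig id must be nonempty")
        if len(self.sequence) < 1:
            raise FormatError(f"contig {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id!r}"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def to_1based_closed(self) -> tuple[str, int, int]:
        return (self.contig_id, self.start + 1, self.end)

    @staticmethod
    def from_1based_closed(contig_id: str, first: int, last: int, **kw) -> "Interval":
        return Interval(contig_id, first - 1, last, **kw)


@dataclass(frozen=True)
class GeneAnnotation:
    interval: Interval
    gene_name: str
    operon_id: str
    subtype: str = ""

    def __post_init__(self):
        if not self.gene_name:
            raise FormatError("gene_name must be nonempty")


@dataclass(frozen=True)
class CrisprArray:
    array_id: str
    repeat_intervals: tuple[Interval, ...]
    spacer_intervals: tuple[Interval, ...]
    consensus_repeat: str
    subtype: str = ""
    subtype_probability: float | None = None

    def __post_init__(self):
        reps, spcs = self.repeat_intervals, self.spacer_intervals
        if len(reps) != len(spcs) + 1:
            raise FormatError(
                f"array {self.array_id!r}: {len(reps)} repeats need "
                f"{len(reps) - 1} spacers, got {len(spcs)}"
            )
        # repeats and spacers must alternate R,S,R,...,R without overlap
        prev_end = -1
        for i, iv in enumerate(self.interleaved()):
            if iv.start < prev_end:
                raise FormatError(
                    f"array {self.array_id!r}: repeat/spacer intervals overlap "
                    f"or are out of order at element {i}"
                )
            prev_end = iv.end
        if self.subtype_probability is not None and not (
            0.0 <= self.subtype_probability <= 1.0
        ):
            raise FormatError(
                f"array {self.array_id!r}: subtype_probability outside [0, 1]"
            )

    def interleaved(self) -> list[Interval]:
        out: list[Interval] = []
        for i, r in enumerate(self.repeat_intervals):
            out.append(r)
            if i < len(self.spacer_intervals):
                out.append(self.spacer_intervals[i])
        return out

    @property
    def contig_id(self) -> str:
        return self.repeat_intervals[0].contig_id

    @property
    def span(self) -> Interval:
        return Interval(
            self.contig_id,
            self.repeat_intervals[0].start,
            self.repeat_intervals[-1].end,
            label=self.array_id,
        )


def check_balanced(ss: str) -> None:
    """Validate that a dot-bracket string balances and nests."""
    depth = 0
    for k, ch in enumerate(ss):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at column {k} in SS_cons")
        elif ch not in ".-_,:~":
            raise FormatError(f"unexpected SS_cons character {ch!r} at column {k}")
    if depth != 0:
        raise FormatError(f"unbalanced SS_cons: {depth} unclosed '('")


def pairs_from_dotbracket(ss: str) -> list[tuple[int, int]]:
    """Base-pair list (i, j), i < j, from a nested dot-bracket string."""
    check_balanced(ss)
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, ch in enumerate(ss):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            pairs.append((stack.pop(), k))
    return sorted(pairs)


def dotbracket_from_pairs(pairs: Iterable[tuple[int, int]], length: int) -> str:
    ss = ["."] * length
    for i, j in pairs:
        ss[i], ss[j] = "(", ")"
    out = "".join(ss)
    check_balanced(out)
    return out


@dataclass
class StockholmAlignment:
    """A multiple alignment with a consensus structure line.

    Rows are stored as DNA over {A,C,G,T,N,-}; files render U.
    """

    names: list[str]
    rows: list[str]
    ss_cons: str = ""
    gf: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise FormatError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate sequence names in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise FormatError("alignment rows have unequal lengths")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]
        for r in self.rows:
            bad = set(r) - set("ACGTN-")
            if bad:
                raise FormatError(f"unexpected alignment characters {sorted(bad)}")
        if self.ss_cons:
            if self.rows and len(self.ss_cons) != len(self.rows[0]):
                raise FormatError("SS_cons length differs from alignment width")
            check_balanced(self.ss_cons)

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def pairs(self) -> list[tuple[int, int]]:
        return pairs_from_dotbracket(self.ss_cons) if self.ss_cons else []


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read FASTA; sequences uppercased, U mapped to T, order preserved."""
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(ContigRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Annotation tables (CRISPRCasTyper-style, tab-separated)
# ---------------------------------------------------------------------------

GENE_COLUMNS = ("contig", "start", "end", "strand", "gene_name", "operon_id", "subtype")
ARRAY_COLUMNS = (
    "contig",
    "array_id",
    "repeat_starts",
    "repeat_ends",
    "spacer_starts",
    "spacer_ends",
    "consensus_repeat",
    "subtype",
    "subtype_probability",
)


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {what} {text!r} is not an integer") from exc


def _split_table(path: str | Path, columns: Sequence[str]):
    with open(path) as fh:
        lines = fh.read().splitlines()
    out = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields == list(columns):
            continue  # header
        if len(fields) != len(columns):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(columns)} fields, got {len(fields)}"
            )
        out.append((lineno, dict(zip(columns, fields))))
    return out


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    for lineno, row in _split_table(path, GENE_COLUMNS):
        start = _parse_int(row["start"], "start", lineno)
        end = _parse_int(row["end"], "end", lineno)
        if start >= end:
            raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
        if row["strand"] not in STRANDS:
            raise FormatError(
                f"{path}: line {lineno}: unknown strand symbol {row['strand']!r}"
            )
        genes.append(
            GeneAnnotation(
                Interval(row["contig"], start, end, row["strand"], row["gene_name"]),
                gene_name=row["gene_name"],
                operon_id=row["operon_id"],
                subtype=row["subtype"],
            )
        )
    return genes


def write_genes(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{g.gene_name}\t{g.operon_id}\t{g.subtype}\n"
            )


def _parse_coord_list(text: str, what: str, lineno: int) -> list[int]:
    if not text:
        return []
    return [_parse_int(t, what, lineno) for t in text.split(",")]


def read_arrays(path: str | Path) -> list[CrisprArray]:
    arrays: list[CrisprArray] = []
    for lineno, row in _split_table(path, ARRAY_COLUMNS):
        rs = _parse_coord_list(row["repeat_starts"], "repeat start", lineno)
        re_ = _parse_coord_list(row["repeat_ends"], "repeat end", lineno)
        ss = _parse_coord_list(row["spacer_starts"], "spacer start", lineno)
        se = _parse_coord_list(row["spacer_ends"], "spacer end", lineno)
        if len(rs) != len(re_) or len(ss) != len(se):
            raise FormatError(f"{path}: line {lineno}: start/end list lengths differ")
        try:
            reps = tuple(
                Interval(row["contig"], a, b, "+", "repeat") for a, b in zip(rs, re_)
            )
            spcs = tuple(
                Interval(row["contig"], a, b, "+", "spacer") for a, b in zip(ss, se)
            )
            prob = (
                float(row["subtype_probability"])
                if row["subtype_probability"] not in ("", ".", "NA")
                else None
            )
            arrays.append(
                CrisprArray(
                    array_id=row["array_id"],
                    repeat_intervals=reps,
                    spacer_intervals=spcs,
                    consensus_repeat=row["consensus_repeat"].upper().replace("U", "T"),
                    subtype=row["subtype"] if row["subtype"] != "." else "",
                    subtype_probability=prob,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return arrays


def write_arrays(arrays: Iterable[CrisprArray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ARRAY_COLUMNS) + "\n")
        for a in arrays:
            prob = "" if a.subtype_probability is None else f"{a.subtype_probability:.4g}"
            fh.write(
                "\t".join(
                    [
                        a.contig_id,
                        a.array_id,
                        ",".join(str(iv.start) for iv in a.repeat_intervals),
                        ",".join(str(iv.end) for iv in a.repeat_intervals),
                        ",".join(str(iv.start) for iv in a.spacer_intervals),
                        ",".join(str(iv.end) for iv in a.spacer_intervals),
                        a.consensus_repeat,
                        a.subtype,
                        prob,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED fields")
            start = _parse_int(fields[1], "start", lineno)
            end = _parse_int(fields[2], "end", lineno)
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                )
            out.append(Interval(fields[0], start, end, strand, name))
    return out


def write_bed(
    intervals: Iterable[Interval],
    path: str | Path,
    scores: Iterable[float] | None = None,
) -> None:
    ivs = list(intervals)
    sc = list(scores) if scores is not None else [0.0] * len(ivs)
    with open(path, "w") as fh:
        for iv, s in zip(ivs, sc):
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t"
                f"{s:g}\t{iv.strand}\n"
            )


def read_annotation_tables(
    genes_path: str | Path,
    arrays_path: str | Path,
    known_path: str | Path | None = None,
) -> tuple[list[GeneAnnotation], list[CrisprArray], list[Interval]]:
    """Load the CRISPRCasTyper-style gene/array tables plus optional known-structure BED."""
    genes = read_genes(genes_path)
    arrays = read_arrays(arrays_path)
    known = read_bed(known_path) if known_path is not None else []
    return genes, arrays, known


# ---------------------------------------------------------------------------
# Stockholm 1.0
# ---------------------------------------------------------------------------


def write_stockholm(
    alignment: StockholmAlignment,
    path: str | Path,
    pair_stats: Iterable | None = None,
) -> None:
    """Write Stockholm 1.0 with #=GC SS_cons; significant pairs as #=GF lines."""
    if alignment.ss_cons:
        check_balanced(alignment.ss_cons)
    pad = max([len(n) for n in alignment.names] + [len("#=GC SS_cons")]) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for key in sorted(alignment.gf):
            fh.write(f"#=GF {key} {alignment.gf[key]}\n")
        if pair_stats is not None:
            for ps in pair_stats:
                i, j = ps.columns
                fh.write(
                    f"#=GF COVARYING_PAIR {i} {j} MIp={ps.mip:.4f} E={ps.e_value:.4g}\n"
                )
        for name, row in zip(alignment.names, alignment.rows):
            fh.write(f"{name.ljust(pad)}{row.replace('T', 'U')}\n")
        if alignment.ss_cons:
            fh.write(f"{'#=GC SS_cons'.ljust(pad)}{alignment.ss_cons}\n")
        fh.write("//\n")


def read_stockholm(path: str | Path) -> StockholmAlignment:
    names: list[str] = []
    rows: dict[str, str] = {}
    ss_cons = ""
    gf: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line == "//" or line.startswith("# STOCKHOLM"):
                continue
            if line.startswith("#=GC SS_cons"):
                ss_cons += line.split(None, 2)[2]
            elif line.startswith("#=GF"):
                parts = line.split(None, 2)
                if len(parts) == 3:
                    key, val = parts[1], parts[2]
                    if key != "COVARYING_PAIR":
                        gf[key] = gf.get(key, "") + val
            elif not line.startswith("#"):
                m = re.match(r"(\S+)\s+(\S+)$", line)
                if not m:
                    raise FormatError(f"{path}: malformed alignment line {line!r}")
                name, chunk = m.groups()
                if name not in rows:
                    names.append(name)
                    rows[name] = ""
                rows[name] += chunk
    return StockholmAlignment(
        names=names, rows=[rows[n] for n in names], ss_cons=ss_cons, gf=gf
    )


# ---------------------------------------------------------------------------
# Hit table (tab-separated; schema shared with the homology module)
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "query_region",
    "q_start",
    "q_end",
    "subject_region",
    "s_start",
    "s_end",
    "strand",
    "identity_pct",
    "aln_len",
    "raw_score",
    "bit_score",
    "e_value",
)


def write_hits(hits: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_region}\t{h.q_start}\t{h.q_end}\t{h.subject_region}\t"
                f"{h.s_start}\t{h.s_end}\t{h.strand}\t{h.identity_pct:.2f}\t"
                f"{h.aln_len}\t{h.raw_score}\t{h.bit_score:.2f}\t{h.e_value:.3g}\n"
            )


def read_hits(path: str | Path):
    """Read a hit table back as a list of plain dicts (typed columns)."""
    out = []
    for lineno, row in _split_table(path, HIT_COLUMNS):
        out.append(
            {
                "query_region": row["query_region"],
                "q_start": _parse_int(row["q_start"], "q_start", lineno),
                "q_end": _parse_int(row["q_end"], "q_end", lineno),
                "subject_region": row["subject_region"],
                "s_start": _parse_int(row["s_start"], "s_start", lineno),
                "s_end": _parse_int(row["s_end"], "s_end", lineno),
                "strand": row["strand"],
                "identity_pct": float(row["identity_pct"]),
                "aln_len": _parse_int(row["aln_len"], "aln_len", lineno),
                "raw_score": _parse_int(row["raw_score"], "raw_score", lineno),
                "bit_score": float(row["bit_score"]),
                "e_value": float(row["e_value"]),
            }
        )
    return out
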