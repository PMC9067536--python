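"""Turn contigs plus locus annotations into merged, extracted search regions.

The slop/merge/getfasta step: each Cas-operon or CRISPR-array locus is
extended by a fixed flank on both sides, overlapping or touching extensions
on one contig are merged, and the merged interval's sequence is extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ContigRecord, CrisprArray, FormatError, GeneAnnotation, Interval


@dataclass(frozen=True)
class Region:
    """An extracted genomic window; the universe searched for motifs."""

    region_id: str
    interval: Interval
    sequence: str
    member_loci: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.sequence) != len(self.interval):
            raise FormatError(
                f"region {self.region_id}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self.interval)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def to_genome(self, local_start: int, local_end: int) -> Interval:
        """Map a region-local half-open interval onto the contig."""
        return Interval(
            self.interval.contig_id,
            self.interval.start + local_start,
            self.interval.start + local_end,
        )


def filter_contigs(contigs: list[ContigRecord], min_length: int = 3000) -> list[ContigRecord]:
    """Keep contigs strictly longer than min_length (default 3 kb)."""
    return [c for c in contigs if len(c) > min_length]


def loci_from_annotations(
    genes: list[GeneAnnotation], arrays: list[CrisprArray]
) -> list[Interval]:
    """Operon spans (union of each operon's genes) plus array spans."""
    by_operon: dict[str, list[Interval]] = {}
    for g in genes:
        by_operon.setdefault(g.operon_id, []).append(g.interval)
    loci: list[Interval] = []
    for operon_id, ivs in sorted(by_operon.items()):
        contig = {iv.contig_id for iv in ivs}
        if len(contig) != 1:
            raise FormatError(f"operon {operon_id} spans multiple contigs")
        loci.append(
            Interval(
                contig.pop(),
                min(iv.start for iv in ivs),
                max(iv.end for iv in ivs),
                "+",
                operon_id,
            )
        )
    for a in arrays:
        sp = a.span
        loci.append(Interval(sp.contig_id, sp.start, sp.end, "+", a.array_id))
    return loci


def prepare_regions(
    contigs: list[ContigRecord],
    loci: list[Interval],
    flank: int = 500,
) -> list[Region]:
    """Extend loci by `flank`, clip to contig bounds, merge, extract sequence.

    Touching extended intervals (end == start) merge, matching the default
    merge distance of 0.
    """
    seq_of = {c.id: c.sequence for c in contigs}
    per_contig: dict[str, list[Interval]] = {}
    for iv in loci:
        if iv.contig_id not in seq_of:
            raise FormatError(f"locus {iv.label!r} on unknown contig {iv.contig_id!r}")
        clen = len(seq_of[iv.contig_id])
        if iv.end > clen:
            raise FormatError(
                f"locus {iv.label!r} extends past the end of contig {iv.contig_id!r}"
            )
        per_contig.setdefault(iv.contig_id, []).append(iv)

    regions: list[Region] = []
    for contig_id in sorted(per_contig):
        clen = len(seq_of[contig_id])
        extended = sorted(
            (max(0, iv.start - flank), min(clen, iv.end + flank), iv.label)
            for iv in per_contig[contig_id]
        )
        cur_start, cur_end, members = extended[0][0], extended[0][1], [extended[0][2]]
        merged: list[tuple[int, int, list[str]]] = []
        for s, e, lab in extended[1:]:
            if s <= cur_end:  # overlap or touch
                cur_end = max(cur_end, e)
                members.append(lab)
            else:
                merged.append((cur_start, cur_end, members))
                cur_start, cur_end, members = s, e, [lab]
        merged.append((cur_start, cur_end, members))
        for s, e, mem in merged:
            rid = f"{contig_id}:{s}-{e}"
            regions.append(
                Region(
                    region_id=rid,
                    interval=Interval(contig_id, s, e, "+", rid),
                    sequence=seq_of[contig_id][s:e],
                    member_loci=tuple(m for m in mem if m),
                )
            )
    return regions


def write_regions(regions: list[Region], bed_path, fasta_path) -> None:
    from .io_formats import write_bed, write_fasta

    write_bed(
        [
            Interval(r.interval.contig_id, r.interval.start, r.interval.end, "+", r.region_id)
            for r in regions
        ],
        bed_path,
    )
    write_fasta([ContigRecord(r.region_id, r.sequence) for r in regions], fasta_path)
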