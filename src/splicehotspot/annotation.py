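"""Gene-model container and splice-site bookkeeping.

Internally every interval is 0-based half-open and every splice site is a
*boundary* coordinate: position ``p`` sits between genomic bases ``p-1`` and
``p``.  A donor (5'ss) is the exon/intron boundary at the transcript-3' end of
an exon, an acceptor (3'ss) the boundary at its transcript-5' end.  GTF/GFF3
input (1-based closed) is converted on read; output written back as GTF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils


@dataclass(frozen=True)
class Exon:
    """One exon, 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceSite:
    """A donor or acceptor boundary.

    ``pos`` is the exon/intron boundary coordinate (between bases pos-1 and
    pos).  On the + strand a donor boundary equals the exon ``end`` and an
    acceptor boundary the exon ``start``; roles swap on the - strand.
    """

    chrom: str
    pos: int
    side: str  # "donor" | "acceptor"
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("negative site position")
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"bad side {self.side!r}")


@dataclass(frozen=True)
class Junction:
    """An exon-exon junction, stored as its intron [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("intron length must be >= 1")

    @property
    def donor_boundary(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_boundary(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)

    def sorted_exons(self) -> list[Exon]:
        return sorted(self.exons, key=lambda e: e.start)

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic [start, end) intervals between consecutive exons."""
        ex = self.sorted_exons()
        out = []
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
            if b.start > a.end:  # abutting exons yield no intron
                out.append((a.end, b.start))
        return out

    def junctions(self) -> list[Junction]:
        return [
            Junction(self.chrom, s, e, self.strand) for s, e in self.introns()
        ]

    def splice_sites(self) -> list[SpliceSite]:
        out = []
        for s, e in self.introns():
            if self.strand == "+":
                out.append(SpliceSite(self.chrom, s, "donor", "+"))
                out.append(SpliceSite(self.chrom, e, "acceptor", "+"))
            else:
                out.append(SpliceSite(self.chrom, e, "donor", "-"))
                out.append(SpliceSite(self.chrom, s, "acceptor", "-"))
        return out


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())

    @property
    def length(self) -> int:
        return self.end - self.start


class Annotation:
    """All gene models plus derived splice-site indexes."""

    def __init__(self, genes: dict[str, Gene]):
        self.genes = genes
        self.transcripts: dict[str, Transcript] = {}
        for g in genes.values():
            self.transcripts.update(g.transcripts)
        self._site_set: set[SpliceSite] | None = None
        self._flank_introns: dict[SpliceSite, set[tuple[int, int]]] | None = None

    def splice_sites(self) -> list[SpliceSite]:
        """Unique annotated splice sites in (chrom, pos, side) order."""
        return sorted(
            self.site_set(), key=lambda s: (s.chrom, s.pos, s.side, s.strand)
        )

    def site_set(self) -> set[SpliceSite]:
        if self._site_set is None:
            self._site_set = {
                s for t in self.transcripts.values() for s in t.splice_sites()
            }
        return self._site_set

    def flanking_introns(self, site: SpliceSite) -> set[tuple[int, int]]:
        """Annotated introns adjacent to ``site`` on its own side.

        For a donor these are the introns it opens; for an acceptor, the
        introns it closes.  The union over isoforms is taken.
        """
        if self._flank_introns is None:
            idx: dict[SpliceSite, set[tuple[int, int]]] = {}
            for t in self.transcripts.values():
                for s, e in t.introns():
                    if t.strand == "+":
                        d = SpliceSite(t.chrom, s, "donor", "+")
                        a = SpliceSite(t.chrom, e, "acceptor", "+")
                    else:
                        d = SpliceSite(t.chrom, e, "donor", "-")
                        a = SpliceSite(t.chrom, s, "acceptor", "-")
                    idx.setdefault(d, set()).add((s, e))
                    idx.setdefault(a, set()).add((s, e))
            self._flank_introns = idx
        return self._flank_introns.get(site, set())

    def annotated_boundaries(self) -> dict[str, set[tuple[int, str]]]:
        """Per chrom, the set of (boundary position, side) pairs."""
        out: dict[str, set[tuple[int, str]]] = {}
        for s in self.site_set():
            out.setdefault(s.chrom, set()).add((s.pos, s.side))
        return out

    def junction_set(self) -> set[Junction]:
        return {
            j for t in self.transcripts.values() for j in t.junctions()
        }

    def n_sites(self) -> int:
        return len(self.site_set())


def _as_gene_dict(transcripts: list[Transcript]) -> dict[str, Gene]:
    genes: dict[str, Gene] = {}
    for t in transcripts:
        g = genes.setdefault(t.gene_id, Gene(t.gene_id, t.chrom, t.strand))
        g.transcripts[t.transcript_id] = t
    return genes


def read_annotation(path: str | Path) -> Annotation:
    """Load a GTF or GFF3 file into an :class:`Annotation`.

    Coordinates are converted from 1-based closed to 0-based half-open.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, Transcript] = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes.get("transcript_id", [None])[0]
        gid = f.attributes.get("gene_id", [None])[0]
        if tid is None:  # GFF3 dialect: Parent=transcript:<id>
            parents = f.attributes.get("Parent", [])
            tid = parents[0].split(":")[-1] if parents else None
        if tid is None:
            raise ValueError(f"exon without transcript id at {f.seqid}:{f.start}")
        if gid is None:
            gid = tid
        t = transcripts.setdefault(
            tid, Transcript(tid, gid, f.seqid, f.strand)
        )
        t.exons.append(Exon(f.seqid, f.start - 1, f.end, f.strand))
    if not transcripts:
        raise ValueError(f"no exon features found in {path}")
    return Annotation(_as_gene_dict(list(transcripts.values())))


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write the annotation as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            attrs = f'gene_id "{gid}";'
            fh.write(
                "\t".join(
                    [g.chrom, "splicehotspot", "gene", str(g.start + 1),
                     str(g.end), ".", g.strand, ".", attrs]
                ) + "\n"
            )
            for tid in sorted(g.transcripts):
                t = g.transcripts[tid]
                tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                fh.write(
                    "\t".join(
                        [t.chrom, "splicehotspot", "transcript",
                         str(t.start + 1), str(t.end), ".", t.strand, ".",
                         tattrs]
                    ) + "\n"
                )
                for i, e in enumerate(t.sorted_exons(), 1):
                    eattrs = tattrs + f' exon_number "{i}";'
                    fh.write(
                        "\t".join(
                            [e.chrom, "splicehotspot", "exon", str(e.start + 1),
                             str(e.end), ".", e.strand, ".", eattrs]
                        ) + "\n"
                    )
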