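"""Readers and writers for the on-disk formats the pipeline exchanges.

Junction tables are held as pandas DataFrames with columns
``chrom, start, end, strand, count, sample_id`` where [start, end) is the
0-based half-open intron.  Two input dialects are supported: STAR's
``SJ.out.tab`` (1-based closed intron coordinates) and BED12 junction files
(block-anchored, 0-based).  FASTA is written plainly and read through
pyfaidx; VCF is written as minimal VCFv4.2 text and read through cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "count", "sample_id"]

_STAR_STRAND = {0: ".", 1: "+", 2: "-"}


def junction_frame(rows: list[tuple], sample_id: str = "sample") -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count"])
    df["sample_id"] = sample_id
    return df[JUNCTION_COLUMNS]


def read_star_sj(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a STAR SJ.out.tab file; unique-mapping read counts are used."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "first", "last", "strand_code", "motif",
               "annotated", "unique", "multi", "overhang"],
        dtype={"chrom": str},
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["first"] - 1,  # 1-based first intron base -> 0-based
            "end": df["last"],         # 1-based last intron base -> half-open
            "strand": df["strand_code"].map(_STAR_STRAND),
            "count": df["unique"],
        }
    )
    out["sample_id"] = sample_id if sample_id is not None else path.stem
    return out[JUNCTION_COLUMNS]


def write_star_sj(df: pd.DataFrame, path: str | Path) -> None:
    code = {"+": 1, "-": 2, ".": 0}
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start + 1}\t{r.end}\t{code[r.strand]}"
                f"\t0\t1\t{r.count}\t0\t50\n"
            )


def read_bed12_junctions(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a BED12 junction file (two blocks per record, score = reads)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start = f[0], int(f[1])
            score, strand = int(f[4]), f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != 2:
                raise ValueError(f"junction BED12 record needs 2 blocks: {line!r}")
            intron_start = chrom_start + starts[0] + sizes[0]
            intron_end = chrom_start + starts[1]
            rows.append((chrom, intron_start, intron_end, strand, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count"])
    df["sample_id"] = sample_id if sample_id is not None else path.stem
    return df[JUNCTION_COLUMNS]


def read_junction_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction TSV missing columns: {sorted(missing)}")
    return df[JUNCTION_COLUMNS]


def write_junction_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_vcf(variants: pd.DataFrame, path: str | Path,
              contigs: dict[str, int] | None = None) -> None:
    """Write a minimal VCFv4.2 file.

    ``variants`` needs columns chrom, pos (0-based), ref, alt; an optional
    ``id`` column is carried through.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=splicehotspot\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in variants.itertuples(index=False):
            vid = getattr(r, "id", ".")
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{vid}\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF into a frame with 0-based ``pos``; one row per ALT allele."""
    import cyvcf2

    rows = []
    for rec in cyvcf2.VCF(str(path)):
        for alt in rec.ALT:
            rows.append((rec.CHROM, rec.POS - 1, rec.REF, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """Read BED6 or narrowPeak binding peaks.

    The name column is expected to carry ``<rbp>`` or ``<rbp>_<cell_line>``;
    a missing cell-line suffix yields cell_line = "pooled".
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "."
            if "_" in name:
                rbp, cell = name.rsplit("_", 1)
            else:
                rbp, cell = name, "pooled"
            rows.append((rbp, cell, chrom, start, end, strand))
    return pd.DataFrame(
        rows, columns=["rbp_id", "cell_line", "chrom", "start", "end", "strand"]
    )


def write_bed_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in peaks.itertuples(index=False):
            name = f"{r.rbp_id}_{r.cell_line}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")
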