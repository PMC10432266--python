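"""File-format plumbing: FASTA, GFF3, BLAST tabular, TIFF and result tables.

FASTA goes through Biopython's SeqIO; TIFF stacks through tifffile; the
tabular formats (GFF3's nine columns, BLAST outfmt-6, spot/cell tables)
through pandas.  Gene labels are read from the first matching GFF3 attribute
key among a configurable list (default ``label``, ``Name``, ``product``,
``gene``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cells import CellMask, CellQuant
from .mining import AnnotatedContig, GeneFeature, HomologyHit, RegulatoryLocus
from .spots import ImageStack, SpotFit

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]
DEFAULT_LABEL_KEYS = ("label", "Name", "product", "gene")

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# --- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --- GFF3 ------------------------------------------------------------------

def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    label_keys: Sequence[str] = DEFAULT_LABEL_KEYS,
) -> dict[str, AnnotatedContig]:
    """Parse GFF3 features into AnnotatedContigs.

    Contig lengths come from ``sequences``, from ``contig_lengths``, from
    ``##sequence-region`` pragmas, or fall back to the rightmost feature end.
    """
    lines = Path(path).read_text().splitlines()
    region_lengths: dict[str, int] = {}
    rows = []
    for line in lines:
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                region_lengths[parts[1]] = int(parts[3])
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line ({len(fields)} columns): {line[:80]}")
        rows.append(fields)
    df = pd.DataFrame(rows, columns=GFF_COLUMNS)
    contigs: dict[str, AnnotatedContig] = {}
    for seqid, sub in df.groupby("seqid", sort=True):
        features = []
        for _, r in sub.iterrows():
            attrs = _parse_attributes(r["attributes"])
            label = next((attrs[k] for k in label_keys if k in attrs), "other")
            features.append(
                GeneFeature(
                    contig_id=seqid,
                    start=int(r["start"]),
                    end=int(r["end"]),
                    strand=r["strand"],
                    label=label,
                    source="annotation",
                    attrs=attrs,
                )
            )
        seq = sequences.get(seqid) if sequences else None
        if seq is not None:
            length = len(seq)
        elif contig_lengths and seqid in contig_lengths:
            length = contig_lengths[seqid]
        elif seqid in region_lengths:
            length = region_lengths[seqid]
        else:
            length = max(f.end for f in features)
        contigs[seqid] = AnnotatedContig(id=seqid, length=length, features=features, sequence=seq)
    return contigs


def write_gff3(contigs: Iterable[AnnotatedContig], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in contigs:
            fh.write(f"##sequence-region {c.id} 1 {c.length}\n")
        for c in contigs:
            for f in sorted(c.features, key=lambda f: (f.start, f.end)):
                attrs = dict(f.attrs)
                attrs.setdefault("label", f.label)
                attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
                fh.write(
                    f"{c.id}\tpolyphage\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attr_str}\n"
                )


# --- homology hits ---------------------------------------------------------

def read_blast_tabular(
    path: str | Path, query_lengths: Mapping[str, int] | None = None
) -> list[HomologyHit]:
    """Read 12-column BLAST outfmt-6 (or 13-column with a trailing qcovs).

    With the 12-column layout, query coverage is computed from the aligned
    query span, which requires ``query_lengths``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 13:
        df.columns = BLAST6_COLUMNS + ["qcovs"]
    elif df.shape[1] == 12:
        df.columns = BLAST6_COLUMNS
        if query_lengths is None:
            raise ValueError(
                "12-column BLAST tabular input needs query_lengths to derive coverage"
            )
        df["qcovs"] = (
            (df["qend"] - df["qstart"]).abs() + 1
        ) / df["qseqid"].map(query_lengths) * 100.0
    else:
        raise ValueError(f"expected 12 or 13 columns, got {df.shape[1]}")
    hits = []
    for _, r in df.iterrows():
        s, e = int(r["sstart"]), int(r["send"])
        strand = "+" if s <= e else "-"
        hits.append(
            HomologyHit(
                query_id=str(r["qseqid"]),
                subject_contig=str(r["sseqid"]),
                percent_identity=float(r["pident"]),
                query_coverage=float(r["qcovs"]),
                evalue=float(r["evalue"]),
                subject_start=min(s, e),
                subject_end=max(s, e),
                subject_strand=strand,
            )
        )
    return hits


# --- loci / spots / cells tables -------------------------------------------

def loci_to_table(loci: Iterable[RegulatoryLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": l.contig_id,
                "telN_start": l.telN.start,
                "telN_end": l.telN.end,
                "telN_strand": l.telN.strand,
                "repA_start": l.repA.start,
                "repA_end": l.repA.end,
                "repA_strand": l.repA.strand,
                "gap_bp": l.gap_bp,
                "context": l.context,
            }
            for l in loci
        ]
    )


def spots_to_table(spots: Iterable[SpotFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": s.channel,
                "x": s.center[0],
                "y": s.center[1],
                "z": s.center[2],
                "sigma_x": s.sigma[0],
                "sigma_y": s.sigma[1],
                "sigma_z": s.sigma[2],
                "amplitude": s.amplitude,
                "background": s.background,
                "integrated_intensity": s.integrated_intensity,
                "residual": s.residual,
                "multi": s.multi,
            }
            for s in spots
        ]
    )


def spots_from_table(df: pd.DataFrame) -> list[SpotFit]:
    return [
        SpotFit(
            center=(r.x, r.y, r.z),
            sigma=(r.sigma_x, r.sigma_y, r.sigma_z),
            amplitude=r.amplitude,
            background=r.background,
            integrated_intensity=r.integrated_intensity,
            residual=r.residual,
            multi=bool(r.multi),
            channel=str(r.channel),
        )
        for r in df.itertuples()
    ]


def cells_to_table(quants: Iterable[CellQuant]) -> pd.DataFrame:
    rows = []
    for q in quants:
        row: dict = {"cell_id": q.cell_id, "quadrant": q.quadrant}
        for ch, v in q.total_intensity.items():
            row[f"total_{ch}"] = v
            row[f"pseudovalue_{ch}"] = q.pseudovalue_applied.get(ch, False)
        rows.append(row)
    return pd.DataFrame(rows)


# --- TIFF ------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(
        str(path),
        stack.voxels.astype(np.float32),
        photometric="minisblack",
        metadata={
            "channel": stack.channel,
            "voxel_size_xy": stack.voxel_size_xy,
            "z_step": stack.z_step,
        },
    )


def read_stack(
    path: str | Path, channel: str = "", voxel_size_xy: float = 0.11, z_step: float = 1.0
) -> ImageStack:
    voxels = np.asarray(tifffile.imread(str(path)), dtype=float)
    if voxels.ndim == 2:
        voxels = voxels[None]
    return ImageStack(
        voxels=np.clip(voxels, 0, None), channel=channel,
        voxel_size_xy=voxel_size_xy, z_step=z_step,
    )


def write_label_mask(mask: CellMask, path: str | Path) -> None:
    tifffile.imwrite(str(path), mask.label_image.astype(np.uint16))


def read_label_mask(path: str | Path, excluded_labels: Iterable[int] = ()) -> CellMask:
    return CellMask(
        label_image=np.asarray(tifffile.imread(str(path))).astype(np.int32),
        excluded_labels=frozenset(excluded_labels),
    )


def write_json_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
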