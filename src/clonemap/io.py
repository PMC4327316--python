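"""Readers and writers for the run artifacts.

Plain-text interchange only: FASTA for design pools, FASTQ (Phred+33) for
reads, TSV for coordinate/truth/mapping tables, PNG or TIFF (16-bit
grayscale) for chip images.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import DesignPool, ReadSet

__all__ = [
    "write_designs_fasta", "read_designs_fasta",
    "write_reads_fastq", "read_reads_fastq",
    "write_pixel_table", "read_pixel_table",
    "write_refs", "read_refs",
    "write_image", "read_image",
]


def write_designs_fasta(pool: DesignPool, path) -> None:
    records = [SeqRecord(Seq(seq), id=did, description="")
               for did, seq in zip(pool.ids, pool.sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_designs_fasta(path) -> DesignPool:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return DesignPool(ids=tuple(r.id for r in records),
                      sequences=tuple(str(r.seq).upper() for r in records))


def write_reads_fastq(reads: pd.DataFrame, path) -> None:
    """Write read_id/sequence/quality columns as Phred+33 FASTQ."""
    records = []
    for rec in reads.itertuples(index=False):
        sr = SeqRecord(Seq(rec.sequence), id=rec.read_id, description="")
        sr.letter_annotations["phred_quality"] = [ord(c) - 33 for c in rec.quality]
        records.append(sr)
    SeqIO.write(records, str(path), "fastq")


def read_reads_fastq(path) -> pd.DataFrame:
    rows = []
    for r in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"])
        rows.append((r.id, str(r.seq).upper(), qual))
    return pd.DataFrame(rows, columns=["read_id", "sequence", "quality"])


def write_pixel_table(reads: pd.DataFrame, path) -> None:
    reads[["read_id", "x_px", "y_px"]].to_csv(path, sep="\t", index=False,
                                              float_format="%.4f")


def read_pixel_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"read_id", "x_px", "y_px"} - set(df.columns)
    if missing:
        raise ValueError(f"pixel table missing columns: {sorted(missing)}")
    return df


def write_refs(refs: pd.DataFrame, path) -> None:
    """Reference-bead table: read_id, x_px, y_px, well_id."""
    refs[["read_id", "x_px", "y_px", "well_id"]].to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def read_refs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"read_id", "x_px", "y_px", "well_id"} - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    return df


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image)
    else:
        iio.imwrite(str(path), image)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(str(path))
    return iio.imread(str(path))
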