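"""Sex-chromosome-complement-aware reference masking.

Builds the two references an XX/XY-informed alignment needs: for samples
without a Y chromosome the whole Y record is hard-masked with Ns (so
homologous X-Y reads cannot mis-map to Y); for samples with a Y only the
Y pseudoautosomal regions are masked (they are duplicated verbatim on
the X PARs). Sequence lengths are always preserved and masking is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter

__all__ = ["MaskInterval", "read_par_bed", "mask_reference"]


@dataclass(frozen=True)
class MaskInterval:
    """1-based inclusive interval on a chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid interval {self.chromosome}:{self.start}-{self.end}")


def read_par_bed(path) -> list[MaskInterval]:
    """Read PAR intervals from BED (0-based half-open on disk) into
    1-based inclusive coordinates."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        comment="#",
    )
    return [
        MaskInterval(str(r.chrom), int(r.start) + 1, int(r.end))
        for r in bed.itertuples()
    ]


def _detect_line_width(path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.startswith(">") or not line.strip():
                continue
            return len(line.rstrip("\n"))
    return 60


def mask_reference(
    fasta_in,
    fasta_out,
    mode: Literal["whole_y", "y_pars"],
    y_chrom_name: str = "chrY",
    par_intervals: Sequence[MaskInterval] = (),
    line_width: int | None = None,
) -> pd.DataFrame:
    """Hard-mask a reference FASTA and return a per-record masking report.

    ``whole_y`` replaces every base of the Y record with 'N'; ``y_pars``
    masks exactly the PAR intervals that fall on ``y_chrom_name``. All
    other records pass through byte-identical (case preserved); masked
    bases are uppercase 'N'. ``line_width`` defaults to the input's wrap
    (or 60 when it cannot be detected).

    Report columns: record, length, masked_bases.
    """
    if mode not in ("whole_y", "y_pars"):
        raise ValueError(f"unknown mode {mode!r}")
    records = list(SeqIO.parse(str(fasta_in), "fasta"))
    names = {r.id for r in records}
    if mode == "whole_y" and y_chrom_name not in names:
        raise ValueError(f"reference has no record {y_chrom_name!r} to mask")
    y_pars = [iv for iv in par_intervals if iv.chromosome == y_chrom_name]
    if mode == "y_pars" and y_pars and y_chrom_name not in names:
        raise ValueError(f"PAR intervals given for missing record {y_chrom_name!r}")
    report = []
    for rec in records:
        masked = 0
        if rec.id == y_chrom_name:
            seq = str(rec.seq)
            if mode == "whole_y":
                masked = len(seq)
                seq = "N" * len(seq)
            else:
                chars = list(seq)
                for iv in y_pars:
                    if iv.end > len(seq):
                        raise ValueError(
                            f"interval {iv.chromosome}:{iv.start}-{iv.end} "
                            f"outside chromosome of length {len(seq)}"
                        )
                    for i in range(iv.start - 1, iv.end):
                        if chars[i] != "N":
                            masked += 1
                        chars[i] = "N"
                seq = "".join(chars)
            rec.seq = Seq(seq)
        report.append(
            {"record": rec.id, "length": len(rec.seq), "masked_bases": masked}
        )
    width = line_width or _detect_line_width(fasta_in)
    with open(fasta_out, "w") as fh:
        writer = FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return pd.DataFrame(report).set_index("record")
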