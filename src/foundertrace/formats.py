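"""Thin readers/writers for the standard formats the pipeline touches.

VCF support is deliberately minimal: the GT field of one named sample on
biallelic rows; everything else is skipped with a counted warning — the
pipeline needs genotype codes only.  BED export is 0-based half-open;
all in-memory coordinates stay 1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genmap import PhysicalInterval
from .roh import AutozygousSegment, Call, MarkerGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf_genotypes",
    "write_vcf_genotypes",
    "write_bed",
    "read_bed",
    "read_fasta",
    "write_fasta",
]

_GT_TO_CALL = {
    (0, 0): Call.HOM_REF,
    (0, 1): Call.HET,
    (1, 0): Call.HET,
    (1, 1): Call.HOM_ALT,
}


def read_vcf_genotypes(path, sample: str | None = None,
                       chromosome: str | None = None) -> MarkerGenotypes:
    """Read one sample's biallelic GT calls from a (plain-text) VCF.

    Multi-allelic rows, rows off the requested chromosome, and rows with
    unparseable GT are skipped with a counted warning.  With ``sample``
    omitted the VCF must contain exactly one sample; with ``chromosome``
    omitted the VCF must cover exactly one.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise ValueError(
                    f"VCF has {len(samples)} samples; name one of {samples}"
                )
            sample = samples[0]
        elif sample not in samples:
            raise ValueError(f"sample {sample!r} not in VCF (has {samples})")

        positions: list[int] = []
        calls: list[int] = []
        chroms_seen: set[str] = set()
        skipped = 0
        for rec in vcf:
            if chromosome is not None and rec.chrom != chromosome:
                skipped += 1
                continue
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            chroms_seen.add(rec.chrom)
            gt = rec.samples[sample].get("GT")
            if gt is None or len(gt) != 2:
                skipped += 1
                continue
            if None in gt:
                call = Call.MISSING
            else:
                call = _GT_TO_CALL.get(tuple(gt))
                if call is None:
                    skipped += 1
                    continue
            positions.append(rec.pos)  # pysam .pos is 1-based
            calls.append(int(call))
    if skipped:
        logger.warning("%s: skipped %d VCF records", path, skipped)
    if chromosome is None:
        if len(chroms_seen) != 1:
            raise ValueError(
                f"VCF covers {sorted(chroms_seen)}; pass chromosome= to pick one"
            )
        chromosome = chroms_seen.pop()
    return MarkerGenotypes(
        chromosome=chromosome,
        positions=np.asarray(positions, dtype=np.int64),
        calls=np.asarray(calls, dtype=np.int8),
        sample_id=sample,
    )


_CALL_TO_GT = {
    int(Call.HOM_REF): "0/0",
    int(Call.HET): "0/1",
    int(Call.HOM_ALT): "1/1",
    int(Call.MISSING): "./.",
}


def write_vcf_genotypes(g: MarkerGenotypes, path) -> None:
    """Write a minimal single-sample VCF (GT only; placeholder alleles)."""
    contig_len = int(g.positions[-1]) + 1 if g.n_markers else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=foundertrace-simulate\n")
        fh.write(f"##contig=<ID={g.chromosome},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{g.sample_id}\n"
        )
        for pos, call in zip(g.positions, g.calls):
            fh.write(
                f"{g.chromosome}\t{pos}\t.\tA\tC\t.\tPASS\t.\tGT\t"
                f"{_CALL_TO_GT[int(call)]}\n"
            )


def write_bed(intervals: Iterable[PhysicalInterval | AutozygousSegment],
              path, names: Sequence[str] | None = None) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = (
                names[i] if names is not None
                else getattr(iv, "sample_id", ".")
            )
            fh.write(f"{iv.chromosome}\t{iv.start_bp - 1}\t{iv.end_bp}\t{name}\n")


def read_bed(path) -> list[PhysicalInterval]:
    """Read BED intervals back to 1-based inclusive coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(
                PhysicalInterval(fields[0], int(fields[1]) + 1, int(fields[2]))
            )
    return out


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )
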