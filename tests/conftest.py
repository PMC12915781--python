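"""Shared fixtures and small file-writing helpers for the test suite."""

import numpy as np
import pytest

from tamscan.windows import GenomeIndex


def write_fasta(path, records: dict[str, str], width: int = 60):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def write_bed(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


write_bedgraph = write_bed


def write_vcf(path, rows, index: GenomeIndex):
    """rows: (chrom, pos, ref, alt)"""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in index.names:
            fh.write(f"##contig=<ID={chrom},length={index.lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence():
    def _make(length, seed=0, gc=0.4):
        r = np.random.default_rng(seed)
        return "".join(r.choice(list("ACGT"), size=length,
                                p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))
    return _make
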