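import textwrap

import pytest

from zfscan import synthetic_data
from zfscan.io_formats import read_gff3


@pytest.fixture(scope="session")
def default_spec():
    return synthetic_data.default_spec(17)


@pytest.fixture(scope="session")
def proteome(default_spec):
    return synthetic_data.generate_proteome(default_spec)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text, name="seqs.faa"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text))
        return path

    return _write


SIMPLE_GFF = """\
##gff-version 3
chr1\tsrc\tgene\t1000\t3000\t.\t+\t.\tID=gA
chr1\tsrc\tmRNA\t1000\t3000\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\tsrc\texon\t1000\t1500\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
chr1\tsrc\texon\t2000\t3000\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1
chr1\tsrc\tCDS\t1000\t1500\t.\t+\t0\tID=gA.t1.c1;Parent=gA.t1
chr1\tsrc\tCDS\t2000\t3000\t.\t+\t0\tID=gA.t1.c2;Parent=gA.t1
chr1\tsrc\tgene\t5000\t6000\t.\t-\t.\tID=gB
chr1\tsrc\tmRNA\t5000\t6000\t.\t-\t.\tID=gB.t1;Parent=gB
chr1\tsrc\texon\t5000\t6000\t.\t-\t.\tID=gB.t1.e1;Parent=gB.t1
chr1\tsrc\tCDS\t5000\t6000\t.\t-\t0\tID=gB.t1.c1;Parent=gB.t1
chr1\tsrc\tmRNA\t5000\t5800\t.\t-\t.\tID=gB.t2;Parent=gB
chr1\tsrc\texon\t5000\t5800\t.\t-\t.\tID=gB.t2.e1;Parent=gB.t2
chr1\tsrc\tCDS\t5000\t5800\t.\t-\t0\tID=gB.t2.c1;Parent=gB.t2
"""


@pytest.fixture
def simple_genes(tmp_path):
    path = tmp_path / "simple.gff3"
    path.write_text(SIMPLE_GFF)
    return read_gff3(path)
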