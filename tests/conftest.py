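import numpy as np
import pytest

from haploscan.io_formats import GeneticMap, HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(alleles, bp=None, cm=None, chrom="1"):
    H = np.asarray(alleles, dtype=np.uint8)
    n = H.shape[1]
    if bp is None:
        bp = (np.arange(n) + 1) * 100
    if cm is None:
        cm = np.arange(n, dtype=float) * 0.01
    return HaplotypeMatrix(H, bp, positions_cm=cm, chrom=chrom)


def random_matrix(rng, k, n, p=0.5):
    H = (rng.random((k, n)) < p).astype(np.uint8)
    return make_matrix(H)


@pytest.fixture
def tiny_map():
    return GeneticMap(
        chrom=np.array(["1", "1"], dtype=object),
        ids=np.array(["a", "b"], dtype=object),
        positions_cm=np.array([0.0, 1.0]),
        positions_bp=np.array([100, 200]),
    )


def write_vcf(path, lines, samples=("s0", "s1", "s2")):
    """Write a minimal VCF with the given record lines."""
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    path.write_text(header + "".join(line + "\n" for line in lines))
    return str(path)
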