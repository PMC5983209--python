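import pytest
from hypothesis import settings

from trapscreen.annotation import GeneModel

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def plus_gene() -> GeneModel:
    """A '+' strand gene with two exons flanking an intron."""
    return GeneModel(
        "GENE_P", "GENE_P", "chr1", 1000, 5000, "+",
        exons=((1000, 1500), (4000, 5000)),
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel(
        "GENE_M", "GENE_M", "chr1", 8000, 12000, "-",
        exons=((8000, 8600), (11000, 12000)),
    )


@pytest.fixture
def toy_genes(plus_gene, minus_gene) -> list[GeneModel]:
    return [plus_gene, minus_gene]


@pytest.fixture
def gtf_file(tmp_path):
    """GTF (1-based inclusive) describing the same two genes as `toy_genes`."""
    lines = [
        'chr1\ttest\tgene\t1001\t5000\t.\t+\t.\tgene_id "GENE_P"; gene_name "GENE_P";',
        'chr1\ttest\texon\t1001\t1500\t.\t+\t.\tgene_id "GENE_P";',
        'chr1\ttest\texon\t4001\t5000\t.\t+\t.\tgene_id "GENE_P";',
        'chr1\ttest\tgene\t8001\t12000\t.\t-\t.\tgene_id "GENE_M"; gene_name "GENE_M";',
        'chr1\ttest\texon\t8001\t8600\t.\t-\t.\tgene_id "GENE_M";',
        'chr1\ttest\texon\t11001\t12000\t.\t-\t.\tgene_id "GENE_M";',
    ]
    path = tmp_path / "genes.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def bed12_file(tmp_path):
    """BED12 equivalent of `gtf_file` (0-based half-open, block-encoded exons)."""
    lines = [
        "chr1\t1000\t5000\tGENE_P\t0\t+\t1000\t5000\t0\t2\t500,1000\t0,3000",
        "chr1\t8000\t12000\tGENE_M\t0\t-\t8000\t12000\t0\t2\t600,1000\t0,3000",
    ]
    path = tmp_path / "genes.bed"
    path.write_text("\n".join(lines) + "\n")
    return path
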