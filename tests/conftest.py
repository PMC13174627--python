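import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_gff(tmp_path_factory):
    """Two genes; GENEA has two transcripts sharing exon 1; 3 exons total 180 nt."""
    lines = [
        "##gff-version 3",
        # GENEA: GFF 101..600 -> internal [100, 600); exons 101..160, 201..260, 301..360
        "chr1\ttest\tgene\t101\t600\t.\t+\t.\tID=gene-GENEA;Name=GENEA;gene=GENEA",
        "chr1\ttest\tmRNA\t101\t600\t.\t+\t.\tID=rna-A1;Parent=gene-GENEA;gene=GENEA",
        "chr1\ttest\texon\t101\t160\t.\t+\t.\tID=exon-A1-1;Parent=rna-A1;gene=GENEA",
        "chr1\ttest\texon\t201\t260\t.\t+\t.\tID=exon-A1-2;Parent=rna-A1;gene=GENEA",
        "chr1\ttest\tmRNA\t101\t600\t.\t+\t.\tID=rna-A2;Parent=gene-GENEA;gene=GENEA",
        "chr1\ttest\texon\t101\t160\t.\t+\t.\tID=exon-A2-1;Parent=rna-A2;gene=GENEA",
        "chr1\ttest\texon\t301\t360\t.\t+\t.\tID=exon-A2-3;Parent=rna-A2;gene=GENEA",
        # GENEB on chr2, minus strand
        "chr2\ttest\tgene\t1001\t1400\t.\t-\t.\tID=gene-GENEB;Name=GENEB;gene=GENEB",
        "chr2\ttest\texon\t1001\t1100\t.\t-\t.\tID=exon-B-1;Parent=gene-GENEB;gene=GENEB",
    ]
    path = tmp_path_factory.mktemp("gff") / "toy.gff3"
    path.write_text("\n".join(lines) + "\n")
    return path
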