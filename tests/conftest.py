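import pytest

from lnckaryotype.synthetic_data import Hotspot, SimConfig, simulate


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One mid-sized synthetic bundle shared across the suite."""
    cfg = SimConfig(
        seed=11,
        lnc_per_chrom=80,
        pcg_per_chrom=50,
        variant_count=6000,
        hotspots=(Hotspot("chr1", 3, 30),),
    )
    out = tmp_path_factory.mktemp("sim_bundle")
    return simulate(cfg, out)


TOY_GTF = """\
chr1\ttoy\tgene\t101\t200\t.\t+\t.\tgene_id "G1"; gene_type "lncRNA"; gene_name "LINC00001";
chr1\ttoy\ttranscript\t101\t200\t.\t+\t.\tgene_id "G1"; gene_type "lncRNA"; transcript_id "T1";
chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "G1"; gene_type "lncRNA"; transcript_id "T1"; exon_number 1;
"""


@pytest.fixture
def toy_gtf(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(TOY_GTF)
    return p
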