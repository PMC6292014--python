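import warnings

import pytest

from omicsfunnel.pipeline import PipelineConfig, run_pipeline
from omicsfunnel.synthdata import SimulationConfig, emit_cohort

TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=10>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Population MAF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
10\t135186806\trs10466126\tT\tC\t.\tPASS\tGENE=ECHS1;MAF=0.324\tGT:GQ:DP\t1/1:99:40\t0/1:80:30\t./.:.:.
10\t200\t.\tA\tG,T\t.\tPASS\tGENE=DBT\tGT:GQ:DP\t1/2:50:20\t0|1:60:25\t2/2:70:33
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The default synthetic cohort (seed 0) with its truth manifest."""
    out = tmp_path_factory.mktemp("cohort0")
    config = SimulationConfig()
    manifest, truth = emit_cohort(config, out)
    return config, manifest, truth


def pipeline_config_from(manifest) -> PipelineConfig:
    return PipelineConfig(
        discovery_vcfs=manifest["discovery_vcfs"],
        verification_vcf=manifest["verification_vcf"],
        replication_vcf=manifest["replication_vcf"],
        sample_sheet=manifest["sample_sheet"],
        de_table=manifest["de_table"],
        gmt=manifest["gmt"],
    )


@pytest.fixture(scope="session")
def default_bundle(default_cohort):
    _config, manifest, _truth = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(pipeline_config_from(manifest))
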