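from pathlib import Path

import pytest

from organoscore import SimulationConfig, simulate_cohort

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Effect class">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##contig=<ID=7>
##contig=<ID=12>
##contig=<ID=17>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path: Path, records: list[str]) -> Path:
    """Write a minimal annotated VCF from tab-joined record lines."""
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in records))
    return path


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 12-organoid cohort small enough for fast per-test simulation."""
    return SimulationConfig(
        n_organoids=12, n_bsc=2, n_low_concordance=1, n_post_treatment=0,
        n_lost_followup=0, n_palliative=5, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under default study conditions."""
    return simulate_cohort(seed=11)
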