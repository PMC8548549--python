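import pytest

import panelgauge as pg

TOY_MAF = """\
#version 2.4
Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tVariant_Type
TP53\tTCGA-AB-1234-01A-11D\tMissense_Mutation\tSNP
TP53\tTCGA-AB-1234-01A-11D\tSilent\tSNP
KRAS\tTCGA-AB-1234-01A-11D\tIntron\tSNP
EGFR\tTCGA-CD-5678-01A-11D\tRNA\tSNP
BRAF\tTCGA-CD-5678-01A-11D\tNonsense_Mutation\tSNP
"""

TOY_CCDS = """\
#chromosome\tnc_accession\tgene\tgene_id\tccds_id\tccds_status\tcds_strand\tcds_from\tcds_to\tcds_locations\tmatch_type
1\tNC_1\tTP53\t1\tCCDS1.1\tPublic\t+\t100\t399\t[100-199, 300-399]\tIdentical
1\tNC_1\tKRAS\t2\tCCDS2.1\tPublic\t+\t1000\t1999\t[1000-1999]\tIdentical
1\tNC_1\tEGFR\t3\tCCDS3.1\tPublic\t+\t5000\t7999\t[5000-7999]\tIdentical
"""


@pytest.fixture()
def toy_maf(tmp_path):
    path = tmp_path / "toy.maf"
    path.write_text(TOY_MAF)
    return path


@pytest.fixture()
def toy_ccds(tmp_path):
    path = tmp_path / "toy.ccds.txt"
    path.write_text(TOY_CCDS)
    return path


@pytest.fixture(scope="session")
def small_universe():
    """100-gene synthetic universe (~0.3 Mb) shared across tests."""
    return pg.generate_universe(100, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_universe):
    """300-patient cohort on the small universe, with its truth table."""
    spec = pg.CohortSpec(n_patients=300, seed=7)
    records, truth = pg.generate_cohort(spec, small_universe)
    return records, truth


@pytest.fixture(scope="session")
def sim_universe():
    """500-gene universe used by the simulation-scale tests."""
    return pg.generate_universe(500, seed=21)


@pytest.fixture(scope="session")
def sim_cohort(sim_universe):
    """1000-patient cohort on the 500-gene universe."""
    spec = pg.CohortSpec(n_patients=1000, seed=22)
    records, truth = pg.generate_cohort(spec, sim_universe)
    return records, truth
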