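import math

import pytest
from hypothesis import settings

from mrinfer import case_study
from mrinfer.sumstats import HarmonizedSnp, SnpAssociation

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def snp(rsid="rs1", ea="G", oa="A", beta=0.1, se=0.05, eaf=math.nan,
        p=math.nan, n=math.nan, chrom=""):
    return SnpAssociation(rsid=rsid, effect_allele=ea, other_allele=oa,
                          beta=beta, se=se, eaf=eaf, pvalue=p, n=n,
                          chromosome=chrom)


def hsnp(rsid="rs1", bx=0.1, sx=0.01, by=0.02, sy=0.05, eaf=math.nan,
         ea="G", oa="A"):
    return HarmonizedSnp(rsid=rsid, effect_allele=ea, other_allele=oa,
                         beta_exposure=bx, se_exposure=sx, beta_outcome=by,
                         se_outcome=sy, eaf=eaf)


@pytest.fixture(scope="session")
def calcium_fixture():
    return case_study.build_fixture()


@pytest.fixture(scope="session")
def overall_snps(calcium_fixture):
    return calcium_fixture["overall"][0]


@pytest.fixture(scope="session")
def advanced_snps(calcium_fixture):
    return calcium_fixture["advanced"][0]
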