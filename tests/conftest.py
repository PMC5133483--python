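import logging

import numpy as np
import pandas as pd
import pytest

import fameqtl as fq

logging.disable(logging.INFO)  # keep test output quiet


def three_generation_pedigree() -> fq.Pedigree:
    """A 12-member, 3-generation pedigree used as the kinship fixture.

    Grandparents gp1 x gp2 have two children p1, p2.  p1 marries m1 (three
    children c1..c3); p2 marries m2 (three children c4..c6).  Contains
    parent-offspring, full-sib, avuncular, grandparent-grandchild and
    first-cousin pairs.
    """
    rows = [
        ("FAM", "gp1", None, None, 1), ("FAM", "gp2", None, None, 2),
        ("FAM", "m1", None, None, 2), ("FAM", "m2", None, None, 2),
        ("FAM", "p1", "gp1", "gp2", 1), ("FAM", "p2", "gp1", "gp2", 1),
        ("FAM", "c1", "p1", "m1", 1), ("FAM", "c2", "p1", "m1", 2),
        ("FAM", "c3", "p1", "m1", 1), ("FAM", "c4", "p2", "m2", 2),
        ("FAM", "c5", "p2", "m2", 1), ("FAM", "c6", "p2", "m2", 2),
    ]
    return fq.Pedigree(pd.DataFrame(
        rows, columns=["family", "individual", "father", "mother", "sex"]))


@pytest.fixture(scope="session")
def ped12() -> fq.Pedigree:
    return three_generation_pedigree()


@pytest.fixture(scope="session")
def kin12(ped12) -> fq.KinshipMatrix:
    return fq.kinship_from_pedigree(ped12)


@pytest.fixture(scope="session")
def small_study():
    """A small planted study shared by pipeline tests (40 probes, 300 samples)."""
    from fameqtl.synthetic_data import _make_study, ExpressionParams

    return _make_study(97, 50, 4, 600,
                       ExpressionParams(n_probes=40, causal_fraction=0.2,
                                        snp_var_frac=0.2, h2_dist=(0.6, 0.9)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/1\t1/1
1\t300\trs3\tG\tA,C\t.\t.\t.\tGT\t0/0\t0/1\t0/2
1\t400\trs4\tT\tC\t.\t.\t.\tGT\t0/0\t0/0\t0/1
"""


@pytest.fixture()
def vcf_file(tmp_path):
    p = tmp_path / "fixture.vcf"
    p.write_text(VCF_FIXTURE)
    return p


@pytest.fixture()
def trio_ped_file(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text("F1 dad 0 0 1 -9\nF1 mom 0 0 2 -9\nF1 kid dad mom 1 -9\n")
    return p
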