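import textwrap

import pytest
from hypothesis import settings

from mescore import msa_io

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

TOY_STOCKHOLM = textwrap.dedent(
    """\
    # STOCKHOLM 1.0
    #=GF ID TOYFAM
    KIN1_HUMAN/10-16   ACDEF-GH
    KIN2_HUMAN/5-12    ACDEFGGH
    KIN1_MOUSE/1-8     ACDEYGGH
    KIN1_YEAST/21-27   AC-EYGGH
    //
    """
)


@pytest.fixture
def toy_stockholm(tmp_path):
    path = tmp_path / "toy.sto"
    path.write_text(TOY_STOCKHOLM)
    return path


@pytest.fixture
def toy_alignment(toy_stockholm):
    return msa_io.read_alignment(toy_stockholm, "stockholm", family_id="TOYFAM")


VEP_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=1>
    ##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: Allele|Consequence|SwissProt|Protein_position">
    ##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    1\t100\t.\tA\tG\t.\t.\tCSQ=G|missense_variant|KIN1|11
    1\t200\t.\tC\tT\t.\t.\tCSQ=T|missense_variant|KIN1|12;CLNSIG=Pathogenic
    1\t300\t.\tG\tA\t.\t.\tCSQ=A|synonymous_variant|KIN1|13
    1\t400\t.\tT\tC\t.\t.\tCSQ=C|missense_variant||14
    1\t500\t.\tG\tC\t.\t.\tCSQ=C|missense_variant|KIN2|8-9
    """
)


@pytest.fixture
def vep_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VEP_VCF)
    return path
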