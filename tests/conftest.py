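"""Shared fixtures: a small hand-crafted cohort whose path through the
filtration cascade is fully known, plus helpers to write the text inputs."""

from pathlib import Path

import pytest

from founderscan.cohort import Individual, Pedigree


VCF_5VAR = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=VAF,Number=A,Type=Float,Description="Allelic fraction">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA1\tA2\tB1\tK1\tK2
chr1\t1500\t.\tG\tA\t.\tPASS\t.\tGT:VAF\t0/1:0.5000\t0/1:0.4500\t0/0:.\t0/0:.\t0/0:.
chr1\t1510\t.\tC\tT\t.\tPASS\t.\tGT:VAF\t0/0:.\t0/0:.\t0/1:0.5000\t0/0:.\t0/0:.
chr1\t1520\t.\tA\tG\t.\tPASS\t.\tGT:VAF\t0/1:0.5000\t0/0:.\t0/0:.\t0/0:.\t0/0:.
chr1\t1530\t.\tG\tC\t.\tPASS\t.\tGT:VAF\t0/1:0.1000\t0/0:.\t0/0:.\t0/0:.\t0/0:.
chr2\t99\t.\tT\tC\t.\tPASS\t.\tGT:VAF\t0/0:.\t0/0:.\t0/0:.\t0/1:0.5000\t0/0:.
"""

ANN_5VAR = """\
chrom\tpos\tref\talt\tgene\tconsequence\tregulatory_sources\tgnomad_af
chr1\t1500\tG\tA\tPANG\tnonsynonymous\t\t0.001
chr1\t1510\tC\tT\tPANG\tnonsynonymous\t\t0.05
chr1\t1520\tA\tG\tPANG\tsynonymous\t\t0.001
chr1\t1530\tG\tC\tPANG\tnonsynonymous\t\t0.001
chr2\t99\tT\tC\tOFFPANEL\tnonsynonymous\t\t0.001
"""

PED_5VAR = """\
FA\tA1\t0\t0\t1\t2
FA\tA2\t0\t0\t2\t2
FB\tB1\t0\t0\t1\t2
CK1\tK1\t0\t0\t0\t1
CK2\tK2\t0\t0\t0\t1
"""

COHORT_5VAR = """\
sample_id\tcohort\tis_index
A1\tcase\t1
A2\tcase\t0
B1\tcase\t1
K1\tcontrol\t0
K2\tcontrol\t0
"""

PANEL_5VAR = "chr1\t1000\t2000\tPANG\n"

SV_5VAR = """\
sample_id\tchrom\tstart\tend\tsv_type
A1\tchr1\t900\t1100\tDEL
B1\tchr1\t2000\t2100\tDUP
"""


@pytest.fixture()
def cohort_dir(tmp_path: Path) -> Path:
    """Five-variant fixture: exactly one variant survives the cascade."""
    (tmp_path / "cohort.vcf").write_text(VCF_5VAR)
    (tmp_path / "annotations.tsv").write_text(ANN_5VAR)
    (tmp_path / "cohort.ped").write_text(PED_5VAR)
    (tmp_path / "cohort_labels.tsv").write_text(COHORT_5VAR)
    (tmp_path / "panel.bed").write_text(PANEL_5VAR)
    (tmp_path / "svs.tsv").write_text(SV_5VAR)
    return tmp_path


def trio_pedigree() -> Pedigree:
    """Case trio (child index, both parents) plus two controls."""
    people = [
        Individual("child", "T1", father_id="dad", mother_id="mom",
                   affected=True, cohort="case", is_index=True),
        Individual("mom", "T1", sex="female", cohort="case"),
        Individual("dad", "T1", sex="male", cohort="case"),
        Individual("c1", "C1", cohort="control"),
        Individual("c2", "C2", cohort="control"),
    ]
    return Pedigree({p.sample_id: p for p in people})


@pytest.fixture()
def trio_ped() -> Pedigree:
    return trio_pedigree()
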