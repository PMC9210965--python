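import pytest

PFAM_SCAN_TEXT = """\
# pfam_scan.pl,  run at Thu Feb  4 2021
# <seq id> <alignment start> <alignment end> <envelope start> <envelope end>
# <hmm acc> <hmm name> <type> <hmm start> <hmm end> <hmm length>
# <bit score> <E-value> <significance> <clan>

WP_000001.1     10    60     8    62 PF00005.27 ABC_tran   Domain  1 60 60  50.0 1.2e-10 1 CL0023
WP_000001.1     80   120    78   122 PF00664.23 ABC_membrane Family 1 40 40  30.5 3.4e-06 1 CL0241
WP_000002.1      5    90     3    92 PF00072.24 Response_reg Domain 1 85 85  80.2 5.0e-20 1 CL0304
"""

TAXONOMY_TEXT = """\
species_id\tphylum\tclass\torder\tfamily\tgenus\tspecies
GCF_001\tProteobacteria\tGammaproteobacteria\tEnterobacterales\tEnterobacteriaceae\tEscherichia\tEscherichia coli
GCF_002\tFirmicutes\tBacilli\tBacillales\tBacillaceae\t\tBacillus subtilis
"""


@pytest.fixture
def pfam_scan_file(tmp_path):
    path = tmp_path / "GCF_001.pfam"
    path.write_text(PFAM_SCAN_TEXT)
    return path


@pytest.fixture
def taxonomy_file(tmp_path):
    path = tmp_path / "taxonomy.tsv"
    path.write_text(TAXONOMY_TEXT)
    return path


def make_hit(protein_id="p1", acc="PF00001", start=1, end=50, score=10.0, name=None):
    from domtax.io import DomainHit

    return DomainHit(
        protein_id=protein_id,
        domain_acc=acc,
        domain_name=name or acc,
        ali_start=start,
        ali_end=end,
        bit_score=score,
    )
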