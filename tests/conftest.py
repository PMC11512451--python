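import pytest

from opsinpred.seqdata import Dataset, OpsinRecord
from opsinpred.synthdata import StudyConfig, generate_study


def make_record(accession, aa_seq, lambda_max, phylum="Chordata", record_type="wt", **kw):
    defaults = dict(
        species=f"sp_{accession}",
        phylum=phylum,
        class_name="Actinopterygii",
        gene_family="Rh1",
    )
    defaults.update(kw)
    return OpsinRecord(
        accession=accession,
        aa_seq=aa_seq,
        lambda_max=lambda_max,
        record_type=record_type,
        **defaults,
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by the integration-flavoured tests."""
    return generate_study(
        StudyConfig(n_tips=60, L=120, min_minor_count=6, epistatic_trio_parents=4,
                    pair_double_parents=5),
        seed=11,
    )


@pytest.fixture
def epistasis_toy():
    """Wild type + two singles + a double with a 2 nm epistatic deviation."""
    wt = make_record("wt1", "MDACVA", 500.0)
    s1 = make_record(
        "m_d2n", "MNACVA", 514.0, record_type="mutant",
        mutation_notation="D2N", parent_accession="wt1",
    )
    s2 = make_record(
        "m_c4s", "MDASVA", 502.0, record_type="mutant",
        mutation_notation="C4S", parent_accession="wt1",
    )
    dbl = make_record(
        "m_dbl", "MNASVA", 514.0, record_type="mutant",
        mutation_notation="D2N_C4S", parent_accession="wt1",
    )
    return Dataset(records=[wt, s1, s2, dbl])
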