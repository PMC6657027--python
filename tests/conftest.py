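import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from ptmut.model import (
    MutationRecord,
    MutationSource,
    PSSM,
    PTMSite,
    ProteinRecord,
)
from ptmut.model import AMINO_ACIDS


def make_mutation(
    protein_id="P1",
    position=1,
    wt="S",
    mut="F",
    source=MutationSource.SOMATIC,
    sample="s1",
    context="LUAD",
):
    return MutationRecord(
        protein_id=protein_id,
        position=position,
        wt_residue=wt,
        mut_residue=mut,
        source=source,
        sample_id=sample,
        context_label=context,
    )


def uniform_pssm(value=0.0, half_width=7, name="flat", group=""):
    weights = {
        (off, aa): value
        for off in range(-half_width, half_width + 1)
        for aa in AMINO_ACIDS
    }
    return PSSM(kinase_name=name, kinase_group=group, half_width=half_width, weights=weights)


@pytest.fixture
def beta_catenin_like():
    """Toy protein with phosphosites at 33, 37, 41, 45 (S/S/T/S)."""
    seq = list("M" + "A" * 59)
    for pos, res in ((33, "S"), (37, "S"), (41, "T"), (45, "S")):
        seq[pos - 1] = res
    return ProteinRecord(protein_id="CTNNB1", sequence="".join(seq))


@pytest.fixture
def beta_catenin_sites(beta_catenin_like):
    return [
        PTMSite(protein_id="CTNNB1", position=pos, residue=res, ptm_type="phosphorylation")
        for pos, res in ((33, "S"), (37, "S"), (41, "T"), (45, "S"))
    ]
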