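import pytest
from hypothesis import HealthCheck, settings

from succinylome.io_formats import Proteome
from succinylome.pipeline import PipelineConfig, run_pipeline
from succinylome.synthetic_data import GeneratorConfig, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

# Worked example: an immunogen-style peptide whose succinylated lysine
# sits at protein residue 118 when the peptide occupies residues 112-126.
K118_PEPTIDE = "RNVNIFKFIIPNVVK"

_FILLER = "ACDEFGHILMNPQSTVWY"  # no K/R: filler cannot spawn stray tryptic sites


def _filler(n: int) -> str:
    return (_FILLER * (n // len(_FILLER) + 1))[:n]


@pytest.fixture(scope="session")
def k118_proteome() -> Proteome:
    seq = _filler(111) + K118_PEPTIDE + _filler(40)
    assert seq[117] == "K"  # residue 118, 1-based
    return Proteome({"LDHA_FIXTURE": seq, "DECOY": _filler(150)})


@pytest.fixture(scope="session")
def small_ds():
    cfg = GeneratorConfig(
        n_proteins=80,
        sites_per_protein=1.0,
        peptides_per_protein=4.0,
        evidence_per_peptide=2.0,
        seed=5,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def zero_noise_ds():
    cfg = GeneratorConfig(
        n_proteins=200,
        sites_per_protein=1.0,
        peptides_per_protein=4.0,
        evidence_per_peptide=2.0,
        noise_sigma=0.0,
        replicate_sigma=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_ds):
    # centering off: raw log2 ratios are then directly comparable to truth
    config = PipelineConfig(centering=False)
    return run_pipeline(
        zero_noise_ds.proteome, zero_noise_ds.all_evidence(), zero_noise_ds.annotations, config
    )
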