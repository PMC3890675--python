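import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodeval.io_alignments import MarkerAlignment, SpecimenRecord, single_marker_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_alignment(seqs: dict[str, str], marker: str = "m1") -> MarkerAlignment:
    length = len(next(iter(seqs.values())))
    return MarkerAlignment(marker_name=marker, sequences=seqs, length=length)


def make_specimens(species_of: dict[str, str]) -> list[SpecimenRecord]:
    return [
        SpecimenRecord(specimen_id=sid, species=sp) for sid, sp in species_of.items()
    ]


def dataset_from(seqs: dict[str, str], species_of: dict[str, str]):
    return single_marker_dataset(make_alignment(seqs), make_specimens(species_of))


def random_sequences(
    rng: np.random.Generator, n: int, length: int, missing_prob: float = 0.0
) -> dict[str, str]:
    alphabet = np.array(list("ACGT"))
    out = {}
    for i in range(n):
        chars = alphabet[rng.integers(0, 4, size=length)]
        if missing_prob > 0:
            mask = rng.random(length) < missing_prob
            gaps = np.array(list("N-?"))[rng.integers(0, 3, size=length)]
            chars = np.where(mask, gaps, chars)
        out[f"s{i:02d}"] = "".join(chars)
    return out


@pytest.fixture(scope="session")
def small_sim():
    """A small well-separated synthetic dataset shared across tests."""
    from barcodeval.synthetic_data import MarkerModel, SimParams, simulate_dataset

    params = SimParams(
        n_species=12,
        accessions=(1, 4),
        markers=(
            MarkerModel("mA", 600, relative_rate=1.0, kappa=2.0, dropout_prob=0.0),
            MarkerModel("mB", 400, relative_rate=0.5, kappa=3.0, dropout_prob=0.2),
        ),
        interspecific_depth=0.06,
        intraspecific_depth=0.002,
        seed=7,
    )
    return simulate_dataset(params)
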