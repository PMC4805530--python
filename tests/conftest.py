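import hypothesis
import pandas as pd
import pytest

from l1audit import gold_standard, synthetic

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Default-parameter synthetic cohort (seed 1): calls, samples, truth."""
    cfg = synthetic.SimulationConfig(seed=1)
    return synthetic.simulate_call_tables(cfg)


@pytest.fixture(scope="session")
def gold_sets(cohort):
    calls, _, _ = cohort
    return gold_standard.select_rcseq_gold(calls)


@pytest.fixture()
def tiny_call_frame():
    """Three calls across two samples of one individual."""
    return pd.DataFrame(
        {
            "sample_id": ["c1", "c1", "c2"],
            "individual_id": ["ind1"] * 3,
            "material": ["single_cell"] * 3,
            "cell_type": ["hippocampal_neuron"] * 3,
            "contig": ["chr1", "chr2", "chr1"],
            "start": [100, 200, 100],
            "end": [101, 201, 101],
            "read_count": [5, 1, 2],
            "junctions": ["both", "five_prime_only", "three_prime_only"],
            "prior_study": [True, False, True],
            "prior_rcseq_only": [False, False, False],
            "candidate_class": ["knr_call", "somatic_candidate", "knr_call"],
            "score": [None, None, None],
        }
    )
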