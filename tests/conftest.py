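import numpy as np
import pandas as pd
import pytest

import meropk as mp


@pytest.fixture(scope="session")
def model():
    """Published population estimates (final two-covariate model)."""
    return mp.default_model()


@pytest.fixture(scope="session")
def typical(model):
    """Typical-subject disposition parameters at the centering covariates."""
    return mp.typical_params(model, mp.CovariateVector(crcl=49.7, lpm=3.7))


@pytest.fixture(scope="session")
def cohort(model):
    """One simulated study cohort (30 subjects x 7 samples), fixed seed."""
    return mp.simulate_dataset(mp.CohortSpec(), model, seed=1)


def add_decoy_covariates(data: mp.PKDataset, seed: int, k: int = 3) -> mp.PKDataset:
    """Append k pure-noise subject-level covariate columns D1..Dk."""
    rng = np.random.default_rng(seed)
    df = data.df.copy()
    for j in range(1, k + 1):
        vals = {sid: rng.lognormal(0.0, 0.5) for sid in df["ID"].unique()}
        df[f"D{j}"] = df["ID"].map(vals)
    return mp.PKDataset(df)


DECOY_CANDIDATES = [("CRCL", "CL"), ("LPM", "Vc"),
                    ("D1", "CL"), ("D2", "Vc"), ("D3", "CL")]

_N_SEEDS = 20


@pytest.fixture(scope="session")
def sim_estimation_experiment(model):
    """The 20-seed simulation-estimation experiment at the study design.

    Per seed: simulate the 30x7 cohort under the published model, fit the
    final two-covariate structure (recovery), fit the reduced structure
    without the CRCL effect (for the likelihood-ratio power check) and run
    the stepwise covariate search against three pure-noise decoys.

    Session-scoped because the acceptance checks on parameter recovery,
    covariate-selection operating characteristics and likelihood-ratio power
    all read from the same runs.
    """
    from meropk.estimation import final_structure

    results = []
    for seed in range(1, _N_SEEDS + 1):
        data = mp.simulate_dataset(mp.CohortSpec(), model, seed=seed)
        full = mp.fit(data, model, compute_rse=False)
        reduced_init = {k: v for k, v in full.estimates.items() if k != "beta_CRCL_CL"}
        reduced = mp.fit(
            data, reduced_init,
            mp.ModelStructure((final_structure().effects[1],)),
            compute_rse=False,
        )
        decoy_data = add_decoy_covariates(data, seed=1000 + seed)
        final_fit, trace = mp.stepwise_covariate_search(decoy_data, DECOY_CANDIDATES, model)
        results.append(dict(seed=seed, data=data, full=full, reduced=reduced,
                            stepwise=final_fit, trace=trace))
    return results
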