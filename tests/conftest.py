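import numpy as np
import pandas as pd
import pytest

import metscreen as ms
from metscreen.simulate import ScreenParams, ScreenTruth


def make_truth(cluster_label: dict, n_metabolites: int = 4) -> ScreenTruth:
    """Minimal truth object for pair-set / annotation tests."""
    strains = sorted(cluster_label)
    mets = [f"m{j:02d}" for j in range(n_metabolites)]
    zeros = pd.DataFrame(0.0, index=strains, columns=mets)
    return ScreenTruth(
        true_concentration=zeros + 1.0,
        effect_mask=zeros.astype(bool),
        effect_size=zeros,
        dilution_factor=pd.Series(1.0, index=strains),
        batch_scale=pd.DataFrame(1.0, index=[0], columns=mets),
        cluster_label=pd.Series(cluster_label).sort_index(),
        noise_rsd=pd.Series(0.05, index=mets),
        baselines=pd.Series(1.0, index=mets),
    )


#: parameters of the planted 3-cluster recovery scenario: three functional
#: modules of sizes 10/7/5 perturbing disjoint metabolite panels with strong
#: (8 SD) effects, on an otherwise unperturbed background
RECOVERY_PARAMS = ScreenParams(
    effect_density=22 / 120,
    slow_fraction=0.0,
    noise_rsd=0.08,
    cluster_sizes=(10, 7, 5),
    cluster_signature_mode="disjoint",
    effect_size_sd=8.0,
    effect_size_sigma=0.0,
)


def recovery_screen(seed: int):
    return ms.simulate_screen(120, 12, RECOVERY_PARAMS, seed=seed)


@pytest.fixture(scope="session")
def clustered_screen():
    """One processed recovery screen shared across tests."""
    screen = recovery_screen(seed=0)
    normalized, factors = ms.quantify_and_normalize(screen, "linear")
    results = ms.ScreenProfileModel(normalized).fit(seed=0)
    return {
        "screen": screen,
        "normalized": normalized,
        "factors": factors,
        "results": results,
    }


@pytest.fixture(scope="session")
def null_screen():
    """A no-effect screen for normalization recovery tests.

    Independent per-metabolite noise and exact calibration standards: the
    recovery bounds checked against this screen (batch-mean equalization,
    false-call control) probe the normalization itself, not
    calibration-transfer error or noise correlation.
    """
    params = ScreenParams(
        effect_density=0.0, slow_fraction=0.0, noise_rsd=0.08,
        corr_blocks=(), standard_noise_rsd=0.0,
    )
    screen = ms.simulate_screen(600, 19, params, seed=42)
    normalized, factors = ms.quantify_and_normalize(screen, "linear")
    return {"screen": screen, "normalized": normalized, "factors": factors}


def dilution_recovery_factors(seed: int = 42):
    """PQN applied directly to a quantified batch-free screen; returns
    (recovered, planted) dilution factors.

    Batch-mean scaling deliberately absent: rescaling batches to a common
    mean absorbs each batch's median dilution, so absolute per-sample
    factors are only identifiable on a batch-free screen.
    """
    params = ScreenParams(
        effect_density=0.0, slow_fraction=0.0, noise_rsd=0.08,
        corr_blocks=(), standard_noise_rsd=0.0, batch_sigma=0.0,
    )
    screen = ms.simulate_screen(600, 19, params, seed=seed)
    curves = ms.calibrate_screen(
        screen.responses, screen.layout, screen.standards, "linear"
    )
    conc, _ = ms.quantify(screen.responses, curves, screen.layout, screen.standards)
    strains = conc.loc[screen.strain_samples].set_axis(
        screen.layout.loc[screen.strain_samples, "strain_id"]
    )
    _, factors = ms.pqn(strains)
    planted = (
        screen.truth.dilution_factor.loc[screen.strain_samples]
        .set_axis(factors.index)
    )
    return factors, planted
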