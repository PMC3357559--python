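"""Shared fixtures: model parameter sets and reusable simulation runs."""

import numpy as np
import pytest

from pbtk import MetabolicPathway, PartitionSet, chemicals
from pbtk.cases.coumarin import RatModel
from pbtk.physiology import TISSUES, PhysiologyProfile, TissueEntry, get_profile


@pytest.fixture(scope="session")
def adult_profile():
    return get_profile("human", "adult")


@pytest.fixture(scope="session")
def bpa_cfg():
    return chemicals.load_chemical("bpa_human")


@pytest.fixture(scope="session")
def bpa_model(adult_profile, bpa_cfg):
    """Calibrated adult BPA engine inputs."""
    return {
        "profile": adult_profile,
        "partitions": chemicals.partitions_from_config(bpa_cfg),
        "pathways": chemicals.calibrated_bpa_pathways(bpa_cfg, adult_profile),
    }


@pytest.fixture(scope="session")
def rat_model():
    """One shared rat coumarin model so batch runs reuse the metrics cache."""
    return RatModel()


@pytest.fixture(scope="session")
def one_compartment():
    """Flow-dominated configuration that collapses to one well-mixed volume.

    All partition coefficients are 1 and flows are scaled far above the
    clearance, so every compartment tracks a single concentration and
    the blood curve follows the closed-form one-compartment solution
    with V = total volume and k_e = CL/V.
    """
    bw = 70.0
    tissues = {
        "liver": TissueEntry(0.026 * bw, 0.225),
        "kidney": TissueEntry(0.004 * bw, 0.190),
        "skin": TissueEntry(0.037 * bw, 0.058),
        "fat": TissueEntry(0.190 * bw, 0.050),
        "richly_perfused": TissueEntry(0.050 * bw, 0.227),
        "slowly_perfused": TissueEntry(0.550 * bw, 0.250),
        "arterial_blood": TissueEntry(0.0257 * bw),
        "venous_blood": TissueEntry(0.0514 * bw),
    }
    profile = PhysiologyProfile("human", "adult", bw, 390.0 * 2000.0, tissues)
    clearance = 20.0  # L/h
    pathway = MetabolicPathway("linear", vmax=clearance * 1e9, km=1e9, conjugate="conj")
    partitions = PartitionSet({t: 1.0 for t in TISSUES})
    v_total = sum(e.volume_L for e in tissues.values())
    return {
        "profile": profile,
        "partitions": partitions,
        "pathways": [pathway],
        "clearance": clearance,
        "v_total": v_total,
    }


def bateman(t, dose_ug, v_total, ka, ke):
    """Closed-form one-compartment curve for first-order absorption/elimination."""
    t = np.asarray(t)
    return dose_ug * ka / (v_total * (ke - ka)) * (np.exp(-ka * t) - np.exp(-ke * t))
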