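import pytest

from methylerase import synthetic_data as sd


@pytest.fixture(scope="session")
def default_params():
    """Study-default kinetics (calibrated k_dem), deterministic seed."""
    return sd.default_params(seed=0)


@pytest.fixture(scope="session")
def cca():
    return sd.cca_condition()


@pytest.fixture()
def quiet_locus():
    """5' locus with a 0.5 log2 arrest excess over a 0.3 baseline."""
    return sd.LocusSpec(
        nucleosome_id="n1", replication_time_min=20.0, tss_distance_bp=100.0,
        induction_class="alpha", arrest_excess_log2=0.5, baseline_fraction=0.3)


def dilution_only_params(**kw):
    """No deposition, no demethylation, no noise, no synchrony dispersion:
    the only dynamics left is the replication halving."""
    base = dict(k_dem=0.0, k_dep_mid=0.0, noise_sigma_log2=0.0, sync_sd_min=0.0,
                tie_deposition_to_baseline=False, seed=0)
    base.update(kw)
    return sd.KineticParams(**base)
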