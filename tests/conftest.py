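import numpy as np
import pytest

import thyromix as tx

ZERO_DIRTY = {k: 0.0 for k in (
    "missing_value", "male_sex", "age_out_of_range",
    "duplicate_patient", "out_of_amr", "tpoab_high",
)}


def make_truth(n_per_trimester, seed=1, hypo=0.0, hyper=0.0, tpoab=0.0, dirty=None):
    return tx.default_truth_params(
        n_per_trimester=n_per_trimester,
        seed=seed,
        hypo_fraction=hypo,
        hyper_fraction=hyper,
        tpoab_pos_fraction=tpoab,
        dirty_record_rates=dirty if dirty is not None else ZERO_DIRTY,
    )


def clean_record(pid="P1", age=30, week=10, tsh=1.5, ft4=16.0, tpo=10.0, sex="female"):
    return tx.LabRecord(patient_id=pid, age=age, sex=sex, gestational_week=week,
                        tsh=tsh, ft4=ft4, tpo_ab=tpo)


@pytest.fixture(scope="session")
def healthy_tsh_50k():
    """Uncontaminated first-trimester TSH sample of 50 000 with its truth."""
    truth = make_truth((50000, 0, 0), seed=1)
    records = tx.generate_cohort(truth)
    retained, _ = tx.clean_cohort(records)
    cohort = tx.stratify(retained)
    return cohort, truth.stratum("first")


@pytest.fixture(scope="session")
def contaminated_cohort_30k():
    """First-trimester cohort of 30 000 with 5% hypo + 5% hyper contamination."""
    truth = make_truth((30000, 0, 0), seed=1, hypo=0.05, hyper=0.05)
    records = tx.generate_cohort(truth)
    retained, _ = tx.clean_cohort(records)
    cohort = tx.stratify(retained)
    return cohort, truth.stratum("first")


@pytest.fixture(scope="session")
def contaminated_tsh_fit(contaminated_cohort_30k):
    """Selected mixture fit of the contaminated TSH sample (shared: fitting
    30 000 values across candidates is the slow step)."""
    cohort, stratum = contaminated_cohort_30k
    values = cohort.values("TSH", "first")
    fit = tx.select_model(values, tx.default_spec_sets())
    return fit, values, stratum


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
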