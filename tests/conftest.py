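import numpy as np
import pytest

from initmut import cohort_io
from initmut.doubling_growth import fit_saturating_curve


@pytest.fixture(scope="session")
def table1():
    """(patient, n, mu_bar, b_printed, survival_months) for the seven patients."""
    return [
        (r["patient"], r["n_mutations"], r["avg_rate_per_day"],
         r["b_printed"], r["survival_months"])
        for r in cohort_io.COHORT_FIXTURE
    ]


@pytest.fixture(scope="session")
def cohort_records():
    df = cohort_io.cohort_frame(include_printed=False)
    return [
        cohort_io.PatientRecord(
            patient_id=row.patient,
            survival_months=row.survival_months,
            clone_time_low_yr=row.clone_time_low_yr,
            clone_time_high_yr=row.clone_time_high_yr,
            n_mutations=int(row.n_mutations),
            avg_rate=row.avg_rate_per_day,
        )
        for row in df.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def fitted_spec():
    """Saturating-curve fit to the doubling-event reconstruction."""
    return fit_saturating_curve(grid="events")
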