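import numpy as np
import pytest

import mortwear as mw


@pytest.fixture(scope="session")
def default_fit():
    """Classifier fitted on the default calibrated synthetic training set."""
    points = mw.synthetic_training_points(seed=1)
    return mw.DurationClassifier.from_points(points).fit()


@pytest.fixture(scope="session")
def separated_fit():
    """Three widely separated classes fitted from exact two-point samples.

    Class k has mean (mu, mu/10) with mu = 2, 20, 200 and within-class
    spread ~0.2 on SD and 0.02 on CV, so posteriors saturate away from the
    boundaries.
    """
    sd, cv, labels = [], [], []
    for mu, lab in ((2.0, "A"), (20.0, "B"), (200.0, "C")):
        sd += [mu - 0.2, mu + 0.2]
        cv += [mu / 10 - 0.02, mu / 10 + 0.02]
        labels += [lab, lab]
    grid = mw.GridSpec(x_min=-5, x_max=250, y_min=-0.5, y_max=25, nx=400, ny=400)
    return mw.DurationClassifier(sd, cv, labels).fit(grid=grid)


def make_records(month_days, sample_id="s", densities=None, hemisphere="north"):
    """Records with given (month, day) dates; densities default to 10+i."""
    recs = []
    for i, (m, d) in enumerate(month_days):
        dens = 10.0 + i if densities is None else densities[i]
        recs.append(
            mw.IndividualRecord(
                specimen_id=f"{sample_id}-{i}",
                sample_id=sample_id,
                species="test",
                death_month=m,
                death_day=d,
                count_area1=dens,
                count_area2=dens,
                hemisphere=hemisphere,
            )
        )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20150)
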