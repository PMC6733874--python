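import numpy as np
import pytest

from phenoscreen import phenoscore as ph
from phenoscreen import screening, synthetic_data as sd


@pytest.fixture(scope="session")
def battery():
    return sd.generate_battery()


@pytest.fixture(scope="session")
def control_pipeline():
    """36 positive candidates + 36 DMSO wells and the annealed reference."""
    controls = sd.generate_control_plates(36, 36, 0)
    reference = ph.select_reference(
        controls[:36], controls[36:], ph.AnnealConfig(subset_size=12, seed=0)
    )
    return controls, reference


@pytest.fixture(scope="session")
def screen_case(control_pipeline):
    """200-compound synthetic screen, scored and assembled into a table."""
    _, reference = control_pipeline
    profiles, library = sd.generate_screen(200, 0.1, 0.05, 4)
    scores = ph.score_profiles(profiles, reference)
    table = screening.build_screen_table(profiles, scores)
    return profiles, library, table


@pytest.fixture(scope="session")
def ec50_recovery_errors():
    """|log10(ec50_est/ec50_true)| over 100 seeded noisy 4PL datasets."""
    ladder = np.array(sd.default_dose_ladder())
    errors = []
    for s in range(100):
        rng = np.random.default_rng(s)
        ec50 = float(10 ** rng.uniform(-0.5, 1.0))
        hill = float(rng.uniform(1.0, 3.0))
        conc = np.repeat(ladder, 4)
        y = 1.0 / (1.0 + (ec50 / conc) ** hill) + rng.normal(0, 0.1, conc.size)
        fit = screening.fit_dose_response(conc, y)
        errors.append(abs(np.log10(fit.ec50_uM / ec50)))
    return np.array(errors)
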