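import numpy as np
import pytest

from hydrochem.chemistry import ION_METADATA, WaterSample, from_meq
from hydrochem.synthetic import default_config, generate


def make_sample(sample_id="S1", ph=7.0, tds=300.0, **ions):
    """WaterSample with unspecified ions at 0 mg/L."""
    base = dict(k=0.0, na=0.0, ca=0.0, mg=0.0, cl=0.0, so4=0.0, hco3=0.0, no3=0.0)
    base.update(ions)
    return WaterSample(sample_id=sample_id, ph=ph, tds=tds, **base)


def sample_from_meq(sample_id="S1", ph=7.0, tds=300.0, **meq):
    """WaterSample built from meq/L targets (converted to mg/L)."""
    ions = {ion: float(from_meq(v, ion)) for ion, v in meq.items()}
    return make_sample(sample_id=sample_id, ph=ph, tds=tds, **ions)


@pytest.fixture
def balanced_sample():
    """A charge-balanced HCO3–Ca type water."""
    return sample_from_meq(ca=2.0, mg=0.5, na=1.0, k=0.1, hco3=2.4, cl=0.8, so4=0.3, no3=0.1)


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default-condition synthetic survey (n=300) reused across tests."""
    return generate(default_config(n=300, seed=777))


@pytest.fixture(scope="session")
def random_samples():
    """1,000 random strictly-positive samples for oracle comparisons."""
    rng = np.random.default_rng(2024)
    out = []
    for i in range(1000):
        conc = rng.lognormal(mean=2.0, sigma=1.0, size=9)
        out.append(
            WaterSample(
                sample_id=f"R{i}",
                ph=float(rng.uniform(5.0, 9.5)),
                tds=float(rng.uniform(20, 1500)),
                k=conc[0], na=conc[1], ca=conc[2], mg=conc[3],
                cl=conc[4], so4=conc[5], hco3=conc[6], co3=conc[7], no3=conc[8],
            )
        )
    return out
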