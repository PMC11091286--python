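import numpy as np
import pytest

from mrmediate import HarmonizedInstrumentSet, HarmonizedPair, datasets


def make_iset(exposure_beta, exposure_se, outcome_beta, outcome_se):
    """Hand-set harmonized instrument set from parallel sequences."""
    pairs = [
        HarmonizedPair(
            snp_id=f"rs{i + 1}", action="kept",
            exposure_beta=float(b), exposure_se=float(sb),
            exposure_eaf=0.3, outcome_beta=float(o), outcome_se=float(so),
            outcome_eaf=0.3,
        )
        for i, (b, sb, o, so) in enumerate(
            zip(exposure_beta, exposure_se, outcome_beta, outcome_se))
    ]
    return HarmonizedInstrumentSet(pairs)


@pytest.fixture
def icp_records():
    return datasets.icp_instruments()


@pytest.fixture
def hand_iset():
    """Five instruments with unequal weights, no special structure."""
    rng = np.random.default_rng(7)
    be = rng.uniform(0.1, 0.5, 5)
    se_e = rng.uniform(0.01, 0.03, 5)
    bo = 0.25 * be + rng.normal(0, 0.01, 5)
    so = rng.uniform(0.01, 0.04, 5)
    return make_iset(be, se_e, bo, so)
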