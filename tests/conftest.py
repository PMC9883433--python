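import numpy as np
import pandas as pd
import pytest

from rdvload.cohort import CohortGenotypes
from rdvload.simulate import RelatednessSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact synthetic cohort reused by integration-style tests."""
    cfg = SimulationConfig(
        n_cases=200, n_controls=200, n_common_snps=800,
        synonymous_rate=0.2, seed=42,
        related=RelatednessSpec(1, 1, 1),
    )
    return simulate_cohort(cfg)


def make_cohort(gt, samples=None, gq=None, dp=None, ad_alt=None, variants=None):
    """Hand-build a CohortGenotypes from a dosage matrix for unit tests."""
    gt = np.asarray(gt, dtype=np.int8)
    n_var, n_samp = gt.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n_samp)]
    if variants is None:
        variants = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, n_var + 1) * 100,
                "ref": "A",
                "alt": "T",
                "qual": 1000.0,
                "qd": 20.0,
                "mq": 60.0,
                "rprs": 0.0,
                "mqrs": 0.0,
                "filter": "PASS",
            }
        )
        variants.index = [f"1:{p}:A:T" for p in variants["pos"]]
    full = np.full(gt.shape, 60, dtype=np.int16)
    return CohortGenotypes(
        samples=list(samples),
        variants=variants,
        gt=gt,
        gq=full.copy() if gq is None else np.asarray(gq, np.int16),
        dp=full.copy() if dp is None else np.asarray(dp, np.int16),
        ad_alt=(np.where(gt == 1, 30, np.where(gt == 2, 59, 0)).astype(np.int16)
                if ad_alt is None else np.asarray(ad_alt, np.int16)),
    )
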