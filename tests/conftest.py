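import math

import pytest

from nsclc_biomarkers import CohortConfig, VariantCall, generate_cohort


def make_variant(**kwargs) -> VariantCall:
    """A well-formed missense variant; fields overridable per test."""
    defaults = dict(
        sample_id="S1",
        gene="EGFR",
        chrom="7",
        pos=55191822,
        ref="T",
        alt="G",
        hgvs_p="p.L858R",
        consequence="missense",
        allele_frequency=0.3,
        depth=500,
        pop_freqs={"1kg": 0.0, "esp6500": 0.0},
        is_driver=False,
    )
    defaults.update(kwargs)
    return VariantCall(**defaults)


def quantile_oracle(values, p):
    """Brute-force empirical quantile: sort and linearly interpolate at p*(n-1)."""
    s = sorted(values)
    n = len(s)
    h = p * (n - 1)
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 300-sample cohort shared across read-only tests."""
    return generate_cohort(CohortConfig.default(n_samples=300, seed=20240917))
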