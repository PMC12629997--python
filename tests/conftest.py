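import numpy as np
import pytest

from inductr.coverage import BinnedCoverage


@pytest.fixture
def labelled_track():
    """Small track with an elevated region 'p' over a noisy host background."""
    rng = np.random.default_rng(42)
    host = rng.poisson(10, size=80).astype(float)
    phage = rng.poisson(60, size=20).astype(float)
    depths = np.concatenate([host[:40], phage, host[40:]])
    labels = np.array(["host"] * 40 + ["p"] * 20 + ["host"] * 40, dtype=object)
    return BinnedCoverage("c1", 100, 10_000, depths, labels)


def naive_zscore_ave(host_bins, phage_bins):
    """Per-bin loop reference for the average modified z-score."""
    xs = sorted(host_bins)
    med = _median(xs)
    mad = _median(sorted(abs(x - med) for x in host_bins))
    if mad == 0:
        return float("nan")
    total = 0.0
    for x in phage_bins:
        total += 0.6745 * (x - med) / mad
    return total / len(phage_bins)


def naive_cohens_d(host_bins, phage_bins):
    """Per-bin loop reference for pooled-SD Cohen's d."""
    mh = sum(host_bins) / len(host_bins)
    mp = sum(phage_bins) / len(phage_bins)
    vh = sum((x - mh) ** 2 for x in host_bins) / (len(host_bins) - 1)
    vp = sum((x - mp) ** 2 for x in phage_bins) / (len(phage_bins) - 1)
    pooled = ((vh + vp) / 2) ** 0.5
    if pooled == 0:
        return float("nan")
    return (mh - mp) / pooled


def _median(xs):
    xs = sorted(xs)
    n = len(xs)
    mid = n // 2
    return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2
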