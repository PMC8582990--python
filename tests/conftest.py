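import numpy as np
import pytest

from asriskmap.synthetic import FieldSpec, generate_wells
from asriskmap.variogram import VariogramModel


@pytest.fixture(scope="session")
def exp_model():
    """Exponential variogram typical of a log10 arsenic field: nugget 0.01,
    partial sill 0.05, range 10 km."""
    return VariogramModel("exponential", 0.01, 0.05, 10000.0)


@pytest.fixture(scope="session")
def strong_structure_spec():
    """Field with sill >> nugget so spatial interpolation has signal, and a
    high enough mean that censoring is rare."""
    vm = VariogramModel("exponential", 0.005, 0.06, 15000.0)
    return FieldSpec(vm, log_mean=0.5, extent=(0.0, 0.0, 30000.0, 20000.0), seed=0)


@pytest.fixture(scope="session")
def wells300(strong_structure_spec):
    return generate_wells(strong_structure_spec, 300)


def brute_force_semivariogram(xy, values, bin_width, max_lag, min_pairs):
    """O(n^2) pair-loop oracle for the empirical semivariogram."""
    xy = np.asarray(xy, float)
    values = np.asarray(values, float)
    n = len(xy)
    nbins = int(np.ceil(max_lag / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, int)
    dsum = np.zeros(nbins)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(xy[i] - xy[j])))
            if d <= 0 or d > max_lag:
                continue
            b = min(int(d / bin_width), nbins - 1)
            sums[b] += (values[i] - values[j]) ** 2
            counts[b] += 1
            dsum[b] += d
    keep = counts >= max(1, min_pairs)
    return dsum[keep] / counts[keep], sums[keep] / (2 * counts[keep]), counts[keep]
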