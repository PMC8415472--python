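"""Pairwise relatedness measures against independent brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
import scipy.stats

from quantphylo.properties import EncodedSequence, encode_alignment
from quantphylo.relatedness import (
    average_mutual_information,
    box_counting_dimension,
    lag_autocorrelation,
    pair_correlation,
    relatedness_table,
)
from quantphylo.simulate import FamilyConfig, evolve_family

# ---------------------------------------------------------------- oracles


def oracle_autocorrelation(x, m):
    """Direct summation of the printed formula."""
    n = len(x)
    xbar = sum(x) / n
    num = sum((x[t] - xbar) * (x[t + m] - xbar) for t in range(n - m))
    den = sum((x[t] - xbar) ** 2 for t in range(n))
    return num / den


def oracle_mi(x, y):
    """Brute-force plug-in MI from explicit joint counts (nats)."""
    n = len(x)
    jx, jy, jxy = Counter(x), Counter(y), Counter(zip(x, y))

    def h(counter):
        return -sum((c / n) * math.log(c / n) for c in counter.values())

    return h(jx) + h(jy) - h(jxy)


def oracle_boxdim(x, y, grid=10):
    """Independent re-derivation: explicit interval membership per cell."""
    lo = min(min(x), min(y))
    hi = max(max(x), max(y))
    if hi == lo:
        return 0.0
    edges = [lo + (hi - lo) * k / grid for k in range(grid + 1)]

    def bin_of(v):
        for k in range(grid - 1):
            if edges[k] <= v < edges[k + 1]:
                return k
        return grid - 1  # last bin is closed

    occupied = {(bin_of(a), bin_of(b)) for a, b in zip(x, y)}
    return math.log(len(occupied)) / math.log(grid)


# ------------------------------------------------------------- correlation


class TestCorrelation:
    def test_identity(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert pair_correlation(x, x) == 1.0

    def test_mirror_about_mean(self, rng):
        x = rng.normal(size=50)
        y = 2 * x.mean() - x
        assert pair_correlation(x, y) == pytest.approx(-1.0)

    def test_independent_near_zero(self, rng):
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        assert abs(pair_correlation(x, y)) < 0.05

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            x, y = rng.normal(size=30), rng.normal(size=30)
            assert pair_correlation(x, y) == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, rel=1e-12
            )

    def test_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pair_correlation(x, y) == pair_correlation(y, x)

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="constant"):
            pair_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLagAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        x = rng.normal(size=40)
        assert lag_autocorrelation(x, 0) == 1.0

    def test_alternating_series_approaches_minus_one(self):
        x = [1.0, -1.0] * 500
        assert lag_autocorrelation(x, 1) == pytest.approx(-1.0, abs=2e-3)

    def test_matches_direct_summation(self, rng):
        for _ in range(100):
            x = rng.normal(size=25).tolist()
            m = int(rng.integers(0, 10))
            assert lag_autocorrelation(x, m) == pytest.approx(
                oracle_autocorrelation(x, m), rel=1e-12
            )

    def test_lag_out_of_range(self):
        with pytest.raises(ValueError):
            lag_autocorrelation([1.0, 2.0], 2)


# --------------------------------------------------------------------- MI


class TestMutualInformation:
    def test_self_mi_equals_entropy(self, rng):
        x = rng.integers(0, 5, size=40).astype(float)
        counts = np.bincount(x.astype(int))
        h = scipy.stats.entropy(counts[counts > 0])
        assert average_mutual_information(x, x) == pytest.approx(h, rel=1e-12)

    def test_constant_partner_zero(self, rng):
        x = rng.integers(0, 4, size=30).astype(float)
        y = np.zeros(30)
        assert average_mutual_information(x, y) == 0.0

    def test_four_position_toy(self):
        # joint counts {(1,1):2, (1,2):1, (2,2):1}
        x = [1.0, 1.0, 1.0, 2.0]
        y = [1.0, 1.0, 2.0, 2.0]
        assert average_mutual_information(x, y) == pytest.approx(
            oracle_mi(x, y), rel=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            x = rng.integers(0, 6, size=50).tolist()
            y = rng.integers(0, 6, size=50).tolist()
            assert average_mutual_information(x, y) == pytest.approx(
                oracle_mi(x, y), rel=1e-12, abs=1e-12
            )

    def test_symmetry(self, rng):
        x = rng.integers(0, 6, size=50).astype(float)
        y = rng.integers(0, 6, size=50).astype(float)
        assert average_mutual_information(x, y) == pytest.approx(
            average_mutual_information(y, x), rel=1e-12
        )

    def test_bounded_by_marginal_entropies(self, rng):
        for _ in range(30):
            x = rng.integers(0, 8, size=60).astype(float)
            y = rng.integers(0, 8, size=60).astype(float)
            mi = average_mutual_information(x, y)
            hx = scipy.stats.entropy(np.unique(x, return_counts=True)[1])
            hy = scipy.stats.entropy(np.unique(y, return_counts=True)[1])
            assert 0 <= mi <= min(hx, hy) + 1e-12

    def test_bits_units(self):
        x = [1.0, 1.0, 2.0, 2.0]
        assert average_mutual_information(x, x, units="bits") == pytest.approx(1.0)

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            average_mutual_information([], [])


# ----------------------------------------------------------------- boxdim


class TestBoxDimension:
    def test_single_cell(self):
        # x values cluster in the first bin, y values in the last: one cell
        x = [0.0, 0.01, 0.02]
        y = [5.0, 5.01, 5.02]
        assert box_counting_dimension(x, y) == pytest.approx(0.0)

    def test_exact_diagonal_is_one(self):
        x = [k + 0.5 for k in range(10)]
        assert box_counting_dimension(x, x) == pytest.approx(1.0)

    def test_full_grid_is_two(self):
        pts = [(i + 0.5, j + 0.5) for i in range(10) for j in range(10)]
        x, y = zip(*pts)
        assert box_counting_dimension(list(x), list(y)) == pytest.approx(2.0)

    def test_zero_range_convention(self):
        with pytest.warns(UserWarning, match="zero value range"):
            assert box_counting_dimension([3.0, 3.0], [3.0, 3.0]) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            x = rng.uniform(-5, 5, size=40).tolist()
            y = rng.uniform(-5, 5, size=40).tolist()
            assert box_counting_dimension(x, y) == pytest.approx(
                oracle_boxdim(x, y), rel=1e-12
            )

    def test_symmetry(self, rng):
        x = rng.uniform(size=30)
        y = rng.uniform(size=30)
        assert box_counting_dimension(x, y) == box_counting_dimension(y, x)

    def test_self_dimension_at_most_one(self, rng):
        for _ in range(20):
            x = rng.uniform(size=50)
            d = box_counting_dimension(x, x)
            assert d <= 1.0 + 1e-12
            # log10 of the number of occupied diagonal cells
            n_cells = round(10 ** d)
            assert math.isclose(d, math.log10(n_cells), rel_tol=1e-9)

    def test_offset_averaging_stays_in_range(self, rng):
        x = rng.uniform(size=60)
        y = rng.uniform(size=60)
        d = box_counting_dimension(x, y, average_offsets=True)
        assert 0.0 <= d <= 2.0


# ------------------------------------------------------------- aggregation


class TestRelatednessTable:
    def test_identical_taxa_correlation(self, toy_alignment):
        seqs = [toy_alignment[0], toy_alignment[0].__class__("copy", toy_alignment[0].letters)]
        encoded = encode_alignment(seqs)
        table = relatedness_table(encoded, "correlation")
        mean, sd = table.cell(seqs[0].taxon, "copy")
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_three_taxa_cardinality(self, toy_alignment):
        encoded = encode_alignment(toy_alignment)
        table = relatedness_table(encoded, "ami")
        n = len(table.labels)
        assert n == 3
        upper = table.mean[np.triu_indices(n, 1)]
        assert len(upper) == 3

    def test_default_property_sets(self, toy_alignment):
        from quantphylo.properties import BOXDIM_PROPERTIES, DEFAULT_PROPERTIES, PROPERTY_NAMES

        encoded = encode_alignment(toy_alignment, PROPERTY_NAMES)
        assert relatedness_table(encoded, "correlation").properties_used == DEFAULT_PROPERTIES
        assert relatedness_table(encoded, "box_dimension").properties_used == BOXDIM_PROPERTIES

    def test_missing_entry_named(self, toy_alignment):
        encoded = encode_alignment(toy_alignment, ["volume"])
        with pytest.raises(KeyError, match="alpha.*pI_25C"):
            relatedness_table(encoded, "correlation", properties=["volume", "pI_25C"])

    def test_tsv_layout(self, toy_alignment):
        encoded = encode_alignment(toy_alignment)
        tsv = relatedness_table(encoded, "correlation").to_tsv()
        lines = tsv.strip().splitlines()
        assert len(lines) == 4
        assert "±" in lines[1]


def test_monotone_degradation():
    """Mean pair correlation is non-increasing in the number of planted
    substitutions, averaged over >= 50 simulated descendant pairs."""
    levels = [0, 5, 20, 80]
    means = []
    for n_subs in levels:
        vals = []
        for seed in range(50):
            config = FamilyConfig(
                topology=("X", "Y"),
                root_length=356,
                substitutions_per_branch={"X": 0, "Y": n_subs},
                rng_seed=seed,
            )
            aln, _ = evolve_family(config)
            encoded = encode_alignment(list(aln), ["volume"])
            vals.append(
                pair_correlation(encoded[("X", "volume")], encoded[("Y", "volume")])
            )
        means.append(np.mean(vals))
    assert means[0] == pytest.approx(1.0)
    assert all(a >= b for a, b in zip(means, means[1:]))
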