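"""5hmC estimation, M-values, systematic classification, QC and expression
filtering."""

import numpy as np
import pandas as pd
import pytest

from eqthm.preprocess import (BetaPairMatrix, QCError, classify_systematic,
                              estimate_5hmc, expression_quartiles,
                              filter_transcripts, min_samples_required,
                              qc_filter, to_m_values)
from conftest import toy_beta_pair


def _pair(bs, oxbs):
    idx = [f"p{i}" for i in range(len(bs))]
    cols = [f"S{j}" for j in range(len(bs[0]))]
    return BetaPairMatrix(bs=pd.DataFrame(bs, index=idx, columns=cols),
                          oxbs=pd.DataFrame(oxbs, index=idx, columns=cols))


class TestEstimate5hmc:
    @pytest.mark.parametrize("bs,oxbs,expected", [
        (0.50, 0.30, 0.20),   # plain subtraction
        (0.30, 0.50, 0.00),   # non-negativity clamp
        (1.00, 0.00, 1.00),
    ])
    def test_pointwise(self, bs, oxbs, expected):
        hmc = estimate_5hmc(_pair([[bs]], [[oxbs]])).hmc
        assert hmc.iloc[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_matches_scalar_loop_oracle(self, rng):
        bs = rng.uniform(0, 1, (100, 10))
        ox = rng.uniform(0, 1, (100, 10))
        hmc = estimate_5hmc(_pair(bs, ox)).hmc.to_numpy()
        for i in range(100):
            for j in range(10):
                expected = max(bs[i, j] - ox[i, j], 0.0)
                assert hmc[i, j] == expected
        assert hmc.min() >= 0 and hmc.max() <= 1

    def test_mismatched_indices_rejected(self):
        bs = pd.DataFrame([[0.5]], index=["a"], columns=["S1"])
        ox = pd.DataFrame([[0.3]], index=["b"], columns=["S1"])
        with pytest.raises(QCError):
            BetaPairMatrix(bs=bs, oxbs=ox)


class TestMValues:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert to_m_values(beta) == pytest.approx(m, abs=1e-12)

    def test_zero_stays_finite(self):
        assert np.isfinite(to_m_values(0.0))
        assert np.isfinite(to_m_values(1.0))

    def test_strictly_increasing_and_antisymmetric(self, rng):
        b = np.sort(rng.uniform(1e-5, 1 - 1e-5, 200))
        m = to_m_values(b)
        assert np.all(np.diff(m) > 0)
        np.testing.assert_allclose(to_m_values(b), -to_m_values(1 - b),
                                   atol=1e-9)


class TestClassifySystematic:
    def _hmc(self, rows):
        return pd.DataFrame(rows, index=[f"cg{i}" for i in range(len(rows))])

    def test_rule_boundary_n4(self):
        # floor(0.5 * 4) = 2 samples needed
        flags = classify_systematic(self._hmc([[0.12, 0.11, 0.05, 0.02],
                                               [0.12, 0.05, 0.05, 0.02]]))
        assert flags.tolist() == [True, False]

    def test_study_sample_count(self):
        # 227 samples -> at least 50% means 113 of them
        assert min_samples_required(227, 0.5) == 113

    def test_monotone_in_values(self, rng):
        base = rng.uniform(0, 0.3, (50, 9))
        flags = classify_systematic(pd.DataFrame(base))
        bumped = base.copy()
        bumped[rng.uniform(size=base.shape) < 0.3] += 0.2
        flags2 = classify_systematic(pd.DataFrame(np.clip(bumped, 0, 1)))
        assert not np.any(flags.to_numpy() & ~flags2.to_numpy())


class TestQCFilter:
    def test_probe_and_sample_rules(self):
        # with only 10 probes the sample rule uses a 25% cutoff so that a
        # probe can fail in 2 retained samples without tripping it
        pairs = toy_beta_pair(10, 5)
        det = pairs.detection_p.copy()
        det.loc["p3", ["S1", "S2"]] = 0.05       # fails in 2 samples -> out
        det.loc["p4", "S1"] = 0.05               # fails in 1 -> kept
        det.loc[["p1", "p2", "p5"], "S5"] = 0.05   # S5 fails 30% > 25%
        pairs = BetaPairMatrix(bs=pairs.bs, oxbs=pairs.oxbs, detection_p=det)
        out = qc_filter(pairs, crossreactive_list=["p9"], snp_list=["p10"],
                        sample_fail_frac=0.25)
        # 10 probes - 2 listed - 1 detection-failing = 7; 5 samples - 1 = 4
        assert out.bs.shape == (7, 4)
        assert "p3" not in out.cpg_ids and "p4" in out.cpg_ids
        assert "S5" not in out.sample_ids
        # p1 failed only in the removed sample, so it survives
        assert "p1" in out.cpg_ids

    def test_sample_three_percent_failure_removed(self):
        pairs = toy_beta_pair(100, 4, seed=1)
        det = pairs.detection_p.copy()
        det.loc[["p1", "p2", "p3"], "S2"] = 0.05   # 3% of probes > 2%
        pairs = BetaPairMatrix(bs=pairs.bs, oxbs=pairs.oxbs, detection_p=det)
        out = qc_filter(pairs)
        assert "S2" not in out.sample_ids

    def test_everything_removed_is_hard_error(self):
        pairs = toy_beta_pair(3, 3)
        with pytest.raises(QCError):
            qc_filter(pairs, crossreactive_list=["p1", "p2", "p3"])


class TestFilterTranscripts:
    def _counts(self, names, rows, samples=4):
        return pd.DataFrame(rows, index=names,
                            columns=[f"S{j}" for j in range(samples)])

    def test_name_substring_rule(self):
        names = ["LOC101", "ABC1", "MIR21", "C1orf99"]
        counts = self._counts(names, np.full((4, 4), 1000.0))
        table = pd.DataFrame({"gene_id": names, "chrom": "chr1"})
        out = filter_transcripts(counts, table, max_low_samples=4)
        assert list(out.index) == ["ABC1"]

    def test_cpm_boundary_is_strictly_more_than(self):
        n = 200
        base = np.full((2, n), 2000.0)
        # library size 4000 => CPM threshold 1 corresponds to count 0.004
        low = np.full(n, 2000.0)
        low[:31] = 0.0
        base[0] = low                      # low in 31 samples -> removed
        low30 = np.full(n, 2000.0)
        low30[:30] = 0.0
        base[1] = low30                    # low in 30 -> kept
        counts = self._counts(["g31", "g30"], base, samples=n)
        counts.loc["anchor"] = 2000.0      # keeps library sizes positive
        table = pd.DataFrame({"gene_id": ["g31", "g30", "anchor"],
                              "chrom": "chr1"})
        out = filter_transcripts(counts, table)
        assert "g31" not in out.index and "g30" in out.index

    def test_hand_enumerated_fixture(self):
        # 6 genes: 2 low-CPM, 1 bad name, 1 on chrX -> 2 survive
        n = 40
        rows = np.full((6, n), 500.0)
        rows[0, :] = 0.0    # CPM 0 < 1 everywhere
        rows[1, :] = 0.0
        counts = self._counts(["low1", "low2", "LOCx", "chrXgene", "keep1",
                               "keep2"], rows, samples=n)
        table = pd.DataFrame({
            "gene_id": counts.index,
            "chrom": ["chr1", "chr1", "chr1", "chrX", "chr2", "chr2"]})
        out = filter_transcripts(counts, table, max_low_samples=30)
        assert sorted(out.index) == ["keep1", "keep2"]
        # output is log2 scale
        assert float(out.max().max()) < 30


class TestExpressionQuartiles:
    def test_even_split(self):
        expr = pd.DataFrame({"S1": np.arange(8.0)},
                            index=[f"g{i}" for i in range(8)])
        q = expression_quartiles(expr)
        assert q.value_counts().tolist() == [2, 2, 2, 2]
        assert q["g0"] == "Q1" and q["g7"] == "Q4"

    def test_ties_stay_balanced_and_deterministic(self):
        expr = pd.DataFrame({"S1": np.ones(9)},
                            index=[f"g{i}" for i in range(9)])
        q1 = expression_quartiles(expr)
        q2 = expression_quartiles(expr)
        assert sorted(q1.value_counts().tolist(), reverse=True) == [3, 2, 2, 2]
        assert q1.equals(q2)

    def test_101_genes_rank_arithmetic(self, rng):
        expr = pd.DataFrame({"S1": rng.normal(size=101)},
                            index=[f"g{i:03d}" for i in range(101)])
        sizes = expression_quartiles(expr).value_counts()
        assert sizes["Q1"] == 26
        assert sizes["Q2"] == sizes["Q3"] == sizes["Q4"] == 25
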