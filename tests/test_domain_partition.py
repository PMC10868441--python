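"""PAE-based and track-based domain partitioning and classification."""

import json

import numpy as np
import pytest

from ensemblekit.domain_partition import (
    DomainPartition, PAEMatrix, classify, load_pae, mean_pae_disorder,
    partition_disorder_track, partition_pae, sweep_threshold,
)
from ensemblekit.generator import synthetic_pae


def brute_force_blocks(values, t_domain, min_size):
    """Greedy maximal low-PAE square blocks, for cross-checking."""
    n = values.shape[0]
    taken = np.zeros(n, dtype=bool)
    blocks = []
    low = values < t_domain
    for start in range(n):
        if taken[start]:
            continue
        end = start
        while (end + 1 < n and not taken[end + 1]
               and low[start:end + 2, start:end + 2].all()):
            end += 1
        if end - start + 1 >= min_size:
            blocks.append((start + 1, end + 1))
            taken[start:end + 1] = True
    return blocks


class TestLoadPAE:
    def test_symmetric_unchanged(self, tmp_path):
        m = np.array([[0.0, 4.0], [4.0, 2.0]])
        np.savetxt(tmp_path / "m.csv", m, delimiter=",")
        pae = load_pae(tmp_path / "m.csv")
        np.testing.assert_allclose(pae.values, m)

    def test_symmetrization_by_mean(self, tmp_path):
        m = np.array([[0.0, 4.0], [6.0, 0.0]])
        np.savetxt(tmp_path / "m.csv", m, delimiter=",")
        pae = load_pae(tmp_path / "m.csv")
        assert pae.values[0, 1] == pytest.approx(5.0)
        assert pae.values[1, 0] == pytest.approx(5.0)

    def test_afdb_json_dialect(self, tmp_path):
        mat = np.full((30, 30), 12.0)
        payload = [{"predicted_aligned_error": mat.tolist(),
                    "max_predicted_aligned_error": 31.75}]
        (tmp_path / "pae.json").write_text(json.dumps(payload))
        pae = load_pae(tmp_path / "pae.json")
        assert pae.n_residues == 30

    def test_non_square_rejected(self, tmp_path):
        np.savetxt(tmp_path / "m.csv", np.zeros((2, 3)), delimiter=",")
        with pytest.raises(ValueError, match="square"):
            load_pae(tmp_path / "m.csv")

    def test_above_cap_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="cap"):
            pae = PAEMatrix(np.full((3, 3), 40.0))
        assert pae.values.max() == pytest.approx(31.75)


class TestMeanPAE:
    def test_constant_matrix(self):
        pae = PAEMatrix(np.full((40, 40), 7.0))
        assert mean_pae_disorder(pae) == pytest.approx(7.0)

    def test_near_diagonal_band_excluded(self):
        n = 60
        values = np.full((n, n), 20.0)
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        values[np.abs(i - j) < 10] = 3.0
        assert mean_pae_disorder(PAEMatrix(values)) == pytest.approx(20.0)


class TestPartitionPAE:
    def test_all_low_single_domain(self):
        pae = PAEMatrix(np.full((80, 80), 5.0))
        part = partition_pae(pae)
        assert part.domains == [(1, 80)]
        assert part.protein_class == "F"

    def test_all_high_no_domains(self):
        values = np.full((80, 80), 25.0)
        np.fill_diagonal(values, 0.0)
        part = partition_pae(PAEMatrix(values))
        assert part.domains == []
        assert part.protein_class == "D"

    def test_planted_two_blocks_recovered(self):
        pae = synthetic_pae(300, [(30, 120), (160, 280)], seed=0)
        part = partition_pae(pae)
        assert len(part.domains) == 2
        for found, planted in zip(part.domains, [(30, 120), (160, 280)]):
            assert abs(found[0] - planted[0]) <= 3
            assert abs(found[1] - planted[1]) <= 3
        assert part.protein_class == "Mf"
        # cross-check against an independent greedy block finder
        blocks = brute_force_blocks(pae.values, 10.58, 25)
        assert len(blocks) == 2
        for found, ref in zip(part.domains, blocks):
            assert abs(found[0] - ref[0]) <= 3
            assert abs(found[1] - ref[1]) <= 3

    def test_planted_recovery_over_seeds(self):
        """2-4 planted blocks, sizes 30-120: exact count in >= 95% of 50
        seeded matrices, boundary error <= 3 residues."""
        exact = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            k = int(rng.integers(2, 5))
            sizes = rng.integers(30, 121, k)
            gaps = rng.integers(12, 40, k + 1)
            intervals = []
            pos = 1 + int(gaps[0])
            for sz, gap in zip(sizes, gaps[1:]):
                intervals.append((pos, pos + int(sz) - 1))
                pos += int(sz) + int(gap)
            n = pos + 10
            pae = synthetic_pae(n, intervals, seed=seed)
            part = partition_pae(pae)
            if len(part.domains) == len(intervals) and all(
                    abs(f[0] - p[0]) <= 3 and abs(f[1] - p[1]) <= 3
                    for f, p in zip(part.domains, intervals)):
                exact += 1
        assert exact >= 48  # 96%

    def test_determinism(self):
        pae = synthetic_pae(200, [(40, 100)], seed=5)
        p1 = partition_pae(pae)
        p2 = partition_pae(pae)
        assert p1.domains == p2.domains

    def test_domain_residues_monotone_in_threshold(self):
        pae = synthetic_pae(250, [(30, 100), (140, 230)], seed=9)
        grid = np.arange(8.58, 12.68, 0.5)
        totals = [partition_pae(pae, t_domain=t).domain_residues
                  for t in grid]
        assert all(b >= a for a, b in zip(totals, totals[1:]))


class TestClassify:
    def test_canonical_layouts(self):
        assert classify(DomainPartition([], 100)) == "D"
        assert classify(DomainPartition([(1, 100)], 100)) == "F"
        assert classify(DomainPartition([(1, 196)], 320)) == "Sf"
        assert classify(DomainPartition([(10, 60), (80, 140)], 150)) == "Mf"

    def test_short_terminal_segments_still_folded(self):
        # 9-residue overhangs on both sides are below the 10-residue IDR rule
        assert classify(DomainPartition([(10, 92)], 100)) == "F"
        assert classify(DomainPartition([(11, 92)], 100)) == "Sf"


class TestDisorderTrack:
    def test_all_ordered_single_domain(self):
        part = partition_disorder_track(np.zeros(60), threshold=0.15)
        assert part.domains == [(1, 60)]
        assert part.protein_class == "F"

    def test_two_runs_with_long_linker(self):
        scores = np.ones(130)
        scores[:50] = 0.0
        scores[80:130] = 0.0
        part = partition_disorder_track(scores)
        assert part.domains == [(1, 50), (81, 130)]
        assert part.protein_class == "Mf"
        assert part.linkers == [(51, 80)]

    def test_short_gap_merged(self):
        scores = np.ones(102)
        scores[:50] = 0.0
        scores[52:102] = 0.0  # 2-residue disordered gap
        part = partition_disorder_track(scores)
        assert part.domains == [(1, 102)]

    def test_chezod_convention(self):
        scores = np.full(80, 10.0)  # ordered when CheZOD >= 8
        part = partition_disorder_track(scores, threshold=8.0,
                                        ordered_when="above")
        assert part.protein_class == "F"

    def test_strict_inequality_at_threshold(self):
        # scores exactly at the threshold are NOT ordered ('below' is strict)
        part = partition_disorder_track(np.full(60, 0.15), threshold=0.15)
        assert part.domains == []


class TestSweep:
    def test_planted_blocks_stable_across_sweep(self):
        pae = synthetic_pae(300, [(30, 120), (160, 280)], seed=3)
        result = sweep_threshold(pae, np.arange(8.58, 12.68, 0.4))
        assert set(result["classes"].values()) == {"Mf"}
        assert result["stable"]
        assert result["fractions"]["Mf"] == 1.0

    def test_boundary_matrix_exposes_sensitivity(self):
        values = np.full((80, 80), 10.6)
        np.fill_diagonal(values, 0.0)
        result = sweep_threshold(PAEMatrix(values),
                                 [8.58, 10.58, 12.58])
        assert len(set(result["classes"].values())) > 1
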