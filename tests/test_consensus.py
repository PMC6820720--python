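"""Consensus consolidation, confidence classification and evaluation."""

import numpy as np
import pytest

from methylassign.assign import RunResult
from methylassign.consensus import (
    ConsensusConfig,
    EvaluationReport,
    consensus_shift,
    consolidate,
    consolidate_geminal,
    evaluate_vs_reference,
    explained_fraction,
    write_reports,
)
from methylassign.peaklists import ShiftEntry, ShiftList

from conftest import ideal_methyl


def _methyls(rng, geminal=True):
    a = ideal_methyl(1, "V", "CG1", [0, 0, 0], rng,
                     geminal="1-CG2" if geminal else None)
    b = ideal_methyl(1, "V", "CG2", [2.5, 0, 0], rng,
                     geminal="1-CG1" if geminal else None)
    c = ideal_methyl(2, "A", "CB", [6, 0, 0], rng)
    return [a, b, c]


def _run(methyls, shifts, noe=2):
    """Fabricate a RunResult with given per-methyl (C, H) shifts."""
    ids = [g.id for g in methyls]
    sc = np.array([s[0] if s else np.nan for s in shifts])
    sh = np.array([s[1] if s else np.nan for s in shifts])
    counts = np.array([noe if s else 0 for s in shifts])
    return RunResult(methyl_ids=ids, shift_c=sc, shift_h=sh,
                     noe_count=counts, anchors=np.zeros(len(ids), dtype=int),
                     mapped_noe_peaks=frozenset(), score=0.0,
                     n_measured_noe=10)


class TestConsensusShift:
    def test_identical_values(self):
        c, f = consensus_shift([23.1] * 100, 0.4)
        assert c == pytest.approx(23.1)
        assert f == 1.0

    def test_85_15_split(self):
        values = [0.85] * 85 + [1.50] * 15
        c, f = consensus_shift(values, 0.04)
        assert c == pytest.approx(0.85, abs=1e-6)
        assert f == pytest.approx(0.85)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            consensus_shift([], 0.4)

    def test_argmax_matches_dense_grid_oracle(self, rng):
        for _ in range(15):
            values = np.concatenate([
                rng.normal(22.0, 0.15, rng.integers(5, 40)),
                rng.normal(24.5, 0.2, rng.integers(5, 40)),
            ])
            tol = 0.4
            c, _ = consensus_shift(values, tol)
            grid = np.arange(values.min() - tol, values.max() + tol, tol / 400)
            ks = np.exp(-((grid[:, None] - values[None, :]) ** 2)
                        / (2 * tol ** 2)).sum(axis=1)
            kc = np.exp(-((c - values) ** 2) / (2 * tol ** 2)).sum()
            # the candidate grid has spacing tol/20, so the kernel-sum
            # height can trail the continuum optimum by at most
            # n * (tol/40)^2 / (2 tol^2) = n/3200
            assert kc >= ks.max() - len(values) / 3000.0

    def test_tie_breaks_toward_lowest_ppm(self):
        c, _ = consensus_shift([1.0, 2.0], 0.04)
        assert c == pytest.approx(1.0)


class TestConsolidateGeminal:
    def test_swap_noise_removed(self):
        # runs alternate the two slots; redistribution makes slot 1 always
        # carry the smaller 13C pair
        runs = 20
        c1 = np.array([23.0, 25.0] * (runs // 2))
        h1 = np.array([0.8, 1.1] * (runs // 2))
        c2 = np.array([25.0, 23.0] * (runs // 2))
        h2 = np.array([1.1, 0.8] * (runs // 2))
        o1c, o1h, o2c, o2h = consolidate_geminal(c1, h1, c2, h2)
        assert np.allclose(o1c, 23.0) and np.allclose(o1h, 0.8)
        assert np.allclose(o2c, 25.0) and np.allclose(o2h, 1.1)

    def test_already_ordered_is_identity(self):
        c1, h1 = np.full(5, 21.0), np.full(5, 0.7)
        c2, h2 = np.full(5, 22.5), np.full(5, 0.9)
        out = consolidate_geminal(c1, h1, c2, h2)
        assert np.allclose(out[0], c1) and np.allclose(out[2], c2)

    def test_half_assigned_run_contributes_nothing(self):
        c1 = np.array([23.0, np.nan])
        h1 = np.array([0.8, np.nan])
        c2 = np.array([25.0, 24.0])
        h2 = np.array([1.1, 1.0])
        o1c, _, o2c, _ = consolidate_geminal(c1, h1, c2, h2)
        assert np.isnan(o1c[1]) and np.isnan(o2c[1])

    def test_joint_consolidation_keeps_h_attached_to_its_c(self, rng):
        # swap-noisy runs: joint redistribution keeps each 1H with its own
        # 13C, so the slot-1 1H consensus is the partner of the slot-1 13C
        # consensus; consolidating the nuclei independently breaks this
        n = 100
        true1, true2 = (23.0, 1.05), (23.3, 0.70)  # C close, H far apart
        swap = rng.random(n) < 0.5
        c1 = np.where(swap, true2[0], true1[0])
        h1 = np.where(swap, true2[1], true1[1])
        c2 = np.where(swap, true1[0], true2[0])
        h2 = np.where(swap, true1[1], true2[1])
        o1c, o1h, o2c, o2h = consolidate_geminal(c1, h1, c2, h2)
        c_cons, _ = consensus_shift(o1c, 0.4)
        h_cons, _ = consensus_shift(o1h, 0.04)
        assert c_cons == pytest.approx(true1[0])
        assert h_cons == pytest.approx(true1[1])  # H follows its C
        # independent per-nucleus sorting would pair min-C with min-H
        h_indep = np.minimum(h1, h2)
        h_wrong, _ = consensus_shift(h_indep, 0.04)
        assert h_wrong == pytest.approx(true2[1])  # inconsistent pairing


class TestConsolidate:
    def test_unanimous_with_noe_support_is_strong(self, rng):
        methyls = _methyls(rng)
        runs = [_run(methyls, [(21.0, 0.8), (22.5, 0.95), (19.0, 1.3)])
                for _ in range(100)]
        out = consolidate([runs, runs, runs], methyls)
        assert all(a.strong for a in out)
        assert all(a.agreement == 1.0 for a in out)

    def test_unanimous_without_noes_is_weak(self, rng):
        methyls = _methyls(rng)
        runs = [_run(methyls, [(21.0, 0.8), (22.5, 0.95), (19.0, 1.3)], noe=0)
                for _ in range(100)]
        out = consolidate([runs], methyls)
        assert not any(a.strong for a in out)
        assert all(a.agreement == 1.0 for a in out)

    def test_threshold_monotonicity(self, rng):
        methyls = _methyls(rng)
        runs = []
        for k in range(100):
            # methyl 3 agrees in 85% of runs, the others in 95%
            s3 = (19.0, 1.3) if k < 85 else (17.0, 1.1)
            s1 = (21.0, 0.8) if k < 95 else (20.0, 0.9)
            runs.append(_run(methyls, [s1, (22.5, 0.95), s3]))
        strong_sets = []
        for thr in (0.8, 0.9, 0.96):
            out = consolidate([runs], methyls,
                              ConsensusConfig(threshold=thr))
            strong_sets.append({a.methyl_id for a in out if a.strong})
        assert strong_sets[0] >= strong_sets[1] >= strong_sets[2]
        assert "2-CB" in strong_sets[0] and "2-CB" not in strong_sets[1]

    def test_batch_size_mismatch_warns_but_pools(self, rng):
        methyls = _methyls(rng)
        runs = [_run(methyls, [(21.0, 0.8), (22.5, 0.95), (19.0, 1.3)])
                for _ in range(10)]
        with pytest.warns(UserWarning, match="differing run counts"):
            out = consolidate([runs, runs[:5]], methyls)
        assert len(out) == 3


class TestEvaluate:
    def _reference(self):
        return ShiftList(entries=[
            ShiftEntry(1, 21.0, 0.4, "CG1", 1),
            ShiftEntry(2, 0.80, 0.04, "QG1", 1),
            ShiftEntry(3, 22.5, 0.4, "CG2", 1),
            ShiftEntry(4, 0.95, 0.04, "QG2", 1),
            ShiftEntry(5, 19.0, 0.4, "CB", 2),
            ShiftEntry(6, 1.30, 0.04, "QB", 2),
        ])

    def test_perfect_recovery_no_errors(self, rng):
        methyls = _methyls(rng)
        runs = [_run(methyls, [(21.0, 0.8), (22.5, 0.95), (19.0, 1.3)])
                for _ in range(50)]
        out = consolidate([runs], methyls)
        rep = evaluate_vs_reference(out, self._reference(), methyls)
        assert rep.n_strong == 3 and rep.n_correct == 3
        assert rep.n_erroneous == 0 and rep.n_no_reference == 0

    def test_swapped_nongeminal_atoms_count_two_errors(self, rng):
        methyls = _methyls(rng)
        # Ala takes Val-g1's shifts and vice versa (far outside tolerance)
        runs = [_run(methyls, [(19.0, 1.3), (22.5, 0.95), (21.0, 0.8)])
                for _ in range(50)]
        out = consolidate([runs], methyls)
        rep = evaluate_vs_reference(out, self._reference(), methyls)
        assert rep.n_erroneous == 2
        assert rep.n_correct == 1

    def test_missing_reference_counts_no_reference(self, rng):
        methyls = _methyls(rng)
        ref = ShiftList(entries=[
            ShiftEntry(1, 21.0, 0.4, "CG1", 1),
            ShiftEntry(2, 0.80, 0.04, "QG1", 1),
            ShiftEntry(3, 22.5, 0.4, "CG2", 1),
            ShiftEntry(4, 0.95, 0.04, "QG2", 1),
        ])
        runs = [_run(methyls, [(21.0, 0.8), (22.5, 0.95), (19.0, 1.3)])
                for _ in range(50)]
        out = consolidate([runs], methyls)
        rep = evaluate_vs_reference(out, ref, methyls)
        assert rep.n_no_reference == 1
        assert rep.n_strong == rep.n_correct + rep.n_erroneous + rep.n_no_reference

    def test_report_counts_must_sum(self):
        with pytest.raises(ValueError):
            EvaluationReport(n_strong=3, n_correct=1, n_erroneous=1,
                             n_no_reference=0)


class TestExplainedFraction:
    def test_trivial_cases(self, rng):
        methyls = _methyls(rng)
        full = _run(methyls, [(21.0, 0.8)] * 3)
        full = RunResult(**{**full.__dict__,
                            "mapped_noe_peaks": frozenset(range(10))})
        none = _run(methyls, [(21.0, 0.8)] * 3)
        assert explained_fraction([full]) == 1.0
        assert explained_fraction([none]) == 0.0
        assert explained_fraction([full, none]) == pytest.approx(0.5)


class TestWriteReports:
    def test_files_and_tokens(self, tmp_path, rng):
        methyls = _methyls(rng)
        runs = [_run(methyls, [(21.0, 0.8), (22.5, 0.95), None])
                for _ in range(50)]
        out = consolidate([runs], methyls)
        rep = None
        write_reports(out, tmp_path,
                      peaklist_stats={"CCNOESY": (40, 38, 30.0)})
        tab = (tmp_path / "consol.tab").read_text()
        assert "strong" in tab
        assert "weak" in tab  # unassigned/weak methyls are still listed
        prot = (tmp_path / "consol.prot").read_text()
        assert "999.000" in prot  # unassigned Ala
        flya = (tmp_path / "flya.txt").read_text()
        assert "CCNOESY" in flya and "40" in flya
        # strong rows in the table match the in-memory strong count
        n_strong_rows = sum(" strong " in l for l in tab.splitlines())
        assert n_strong_rows == sum(a.strong for a in out)
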