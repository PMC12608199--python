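"""Gillespie kinetics: move set, rates, waiting times, first passage."""

import math

import numpy as np
import pytest
from scipy import stats

from hpfold._kmc_kernels import catalog_snapshot
from hpfold.core import DEFAULT_PARAMS, Conformation, HPSequence, energy
from hpfold.kmc import (
    KMCResult,
    TrappedStateError,
    apply_move,
    first_passage,
    gillespie_step,
    legal_moves,
    mean_fpt_curve,
    run_seed,
)

from conftest import SMALL_FOLDER, SMALL_FOLDER_E0


def rod(n):
    return Conformation.from_directions("R" * (n - 1))


def catalog_key(cat):
    return sorted((p.bead, p.target, p.delta_e) for p in cat.proposals)


def kernel_catalog_key(conf, seq, params=DEFAULT_PARAMS):
    k, beads, targets, des = catalog_snapshot(
        len(conf), conf.positions, seq.type_codes.astype(np.uint8), params.matrix
    )
    return sorted(
        (int(beads[i]), tuple(int(v) for v in targets[i]), int(des[i]))
        for i in range(k)
    )


class TestMoveSet:
    def test_straight_rod_has_eight_end_flips(self):
        seq = HPSequence("H" * 16)
        cat = legal_moves(rod(16), seq, temperature=2.0)
        assert len(cat.proposals) == 8
        assert all(p.kind == "end" and p.delta_e == 0 and p.rate == 1.0
                   for p in cat.proposals)
        assert cat.total_rate == pytest.approx(8.0)

    def test_u_shape_corner_flips_blocked_by_occupancy(self):
        seq = HPSequence("HHHH")
        u = Conformation(np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]))
        corners = [p for p in legal_moves(u, seq).proposals if p.kind == "corner"]
        # both interior beads have perpendicular bonds, but each diagonal
        # site is occupied by the opposite terminal bead: no corner flips
        assert corners == []

    def test_corner_flip_on_open_bend(self):
        bend = Conformation.from_directions("RRU")  # bead 2 is a corner
        seq = HPSequence("HHHH")
        corners = [p for p in legal_moves(bend, seq).proposals if p.kind == "corner"]
        assert [(p.bead, p.target) for p in corners] == [(2, (1, 1, 0))]

    def test_no_180_degree_end_flip(self):
        seq = HPSequence("H" * 5)
        cat = legal_moves(rod(5), seq)
        # bead 0's forbidden reversal site is (2,0,0)=antipode across bead 1
        assert all(p.target != (2, 0, 0) for p in cat.proposals if p.bead == 0)

    def test_occupied_targets_absent_and_moves_stay_valid(self):
        rng = np.random.default_rng(11)
        seq = HPSequence(SMALL_FOLDER)
        conf = rod(8)
        for _ in range(300):
            cat = legal_moves(conf, seq, temperature=1.5)
            occupied = {tuple(p) for p in conf.positions}
            for p in cat.proposals:
                assert p.target not in occupied
            move = cat.proposals[rng.integers(len(cat.proposals))]
            conf = apply_move(conf, move)  # Conformation validates invariants

    def test_kernel_catalog_matches_python_reference(self):
        rng = np.random.default_rng(3)
        seq = HPSequence(SMALL_FOLDER)
        conf = rod(8)
        for step in range(200):
            assert kernel_catalog_key(conf, seq) == catalog_key(
                legal_moves(conf, seq, temperature=1.0)
            )
            cat = legal_moves(conf, seq, temperature=1.0)
            conf = apply_move(conf, cat.proposals[rng.integers(len(cat.proposals))])

    def test_delta_e_agrees_with_recomputed_energy(self):
        rng = np.random.default_rng(5)
        seq = HPSequence(SMALL_FOLDER)
        conf = rod(8)
        e = energy(conf, seq)
        for _ in range(200):
            cat = legal_moves(conf, seq, temperature=1.0)
            move = cat.proposals[rng.integers(len(cat.proposals))]
            conf = apply_move(conf, move)
            e += move.delta_e
            assert e == energy(conf, seq)


class TestGillespieStep:
    def test_waiting_times_exponential_at_frozen_conformation(self):
        seq = HPSequence("H" * 16)
        cat = legal_moves(rod(16), seq, temperature=2.0)  # W_T = 8, all W=1
        rng = np.random.default_rng(42)
        waits = np.array([gillespie_step(cat, rng)[1] for _ in range(100_000)])
        # <t> = 1/W_T = 1/K for K unit-rate moves
        assert waits.mean() == pytest.approx(1 / 8, rel=0.02)
        # <-ln xi> = 1
        assert (waits * cat.total_rate).mean() == pytest.approx(1.0, rel=0.02)
        ks = stats.kstest(waits, "expon", args=(0, 1 / cat.total_rate))
        assert ks.pvalue > 1e-3

    def test_selection_frequencies_proportional_to_rates(self):
        # freeze a conformation whose catalog mixes W = 1 and W = e^(-dE/T)
        seq = HPSequence(SMALL_FOLDER)
        rng = np.random.default_rng(8)
        conf = rod(8)
        for _ in range(400):
            cat = legal_moves(conf, seq, temperature=1.0)
            if len({p.rate for p in cat.proposals}) >= 2:
                break
            conf = apply_move(conf, cat.proposals[rng.integers(len(cat.proposals))])
        rates = np.array([p.rate for p in cat.proposals])
        assert len(set(rates)) >= 2
        draws = 40_000
        idx = {p: i for i, p in enumerate(cat.proposals)}
        counts = np.zeros(len(rates))
        for _ in range(draws):
            move, _ = gillespie_step(cat, rng)
            counts[idx[move]] += 1
        expected = draws * rates / rates.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, len(rates) - 1) > 1e-3

    def test_detailed_balance_of_rates(self):
        seq = HPSequence(SMALL_FOLDER)
        rng = np.random.default_rng(13)
        conf = rod(8)
        temperature = 1.3
        checked = 0
        for _ in range(150):
            cat = legal_moves(conf, seq, temperature=temperature)
            move = cat.proposals[rng.integers(len(cat.proposals))]
            old = tuple(conf.positions[move.bead])
            nxt = apply_move(conf, move)
            rev_cat = legal_moves(nxt, seq, temperature=temperature)
            rev = [p for p in rev_cat.proposals
                   if p.bead == move.bead and p.target == old]
            assert len(rev) == 1  # every move is reversible
            assert rev[0].delta_e == -move.delta_e
            ratio = move.rate / rev[0].rate
            assert ratio == pytest.approx(
                math.exp(-move.delta_e / temperature), rel=1e-12
            )
            checked += 1
            conf = nxt
        assert checked == 150

    def test_empty_catalog_raises(self):
        seq = HPSequence("H" * 16)
        cat = legal_moves(rod(16), seq)
        empty = type(cat)(cat.conformation, (), 0.0)
        with pytest.raises(TrappedStateError):
            gillespie_step(empty, np.random.default_rng(0))


class TestFirstPassage:
    def test_zero_time_if_already_at_target(self):
        res = first_passage(SMALL_FOLDER, temperature=1.0, e0=0, seed=5)
        assert res.fpt == 0.0 and res.events == 0 and res.reached

    def test_reaches_native_and_is_deterministic(self):
        a = first_passage(SMALL_FOLDER, temperature=1.5, seed=77)
        b = first_passage(SMALL_FOLDER, temperature=1.5, seed=77)
        assert a == b == KMCResult(a.fpt, a.events, True, False, 77)
        assert a.fpt > 0 and a.events > 0
        c = first_passage(SMALL_FOLDER, temperature=1.5, seed=78)
        assert c.fpt != a.fpt

    def test_incremental_energy_bookkeeping_self_check(self):
        for seed in range(3):
            res = first_passage(
                SMALL_FOLDER, temperature=1.0, e0=SMALL_FOLDER_E0, seed=seed,
                _check_every=1000,
            )
            assert res.reached  # status -2 would raise

    def test_censoring_at_event_cap(self):
        res = first_passage(
            SMALL_FOLDER, temperature=1.0, e0=SMALL_FOLDER_E0, seed=3,
            max_events=5,
        )
        assert res.censored and not res.reached and res.events == 5

    def test_non_unique_sequence_refused(self):
        with pytest.raises(ValueError, match="unique"):
            first_passage("PPPPPPPP", temperature=1.0, seed=0)


class TestFPTCurve:
    def test_curve_statistics_and_censoring(self):
        temps = [1.0, 2.0]
        curve = mean_fpt_curve(SMALL_FOLDER, temperatures=temps, runs=30, seed=9)
        assert curve.mean_fpt.shape == (2,)
        assert np.all(np.isfinite(curve.mean_fpt))
        assert np.all(curve.n_censored == 0)
        # all runs censored -> mean absent, every run counted
        short = mean_fpt_curve(
            SMALL_FOLDER, temperatures=[1.0], runs=5, seed=9, max_events=3
        )
        assert np.isnan(short.mean_fpt[0]) and short.n_censored[0] == 5

    def test_streams_independent_of_grid_shape(self):
        # run at T=2.0 alone vs inside a grid: same per-run seeds -> same mean
        alone = mean_fpt_curve(SMALL_FOLDER, temperatures=[2.0], runs=10, seed=4)
        # temperature index differs, so means differ across positions only
        # through sampling, not systematically; check the seed derivation
        assert run_seed(4, 0, 3) != run_seed(4, 1, 3) != run_seed(5, 1, 3)
        assert np.isfinite(alone.mean_fpt[0])
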