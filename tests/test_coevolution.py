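"""Alignment handling, reweighting, pseudolikelihood fit, variant scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from varstab.coevolution import (
    GAP,
    Q,
    Alignment,
    PottsModel,
    _gauge_fix,
    build_evo_matrix,
    coverage_mask,
    encode_sequence,
    fit_potts,
    rank_normalize,
    read_alignment,
    read_model,
    score_variant,
    sequence_energy,
    sequence_weights,
    write_model,
)
from varstab.variants import AMINO_ACIDS


def _write_fasta(tmp_path, entries, name="aln.fasta"):
    p = tmp_path / name
    p.write_text("".join(f">{n}\n{s}\n" for n, s in entries))
    return p


class TestReadAlignment:
    def test_plain_fasta(self, tmp_path):
        p = _write_fasta(tmp_path, [("query", "ACD"), ("s1", "ACE"), ("s2", "A-D")])
        aln = read_alignment(p, "query")
        assert aln.sequences == ["ACD", "ACE", "A-D"]
        assert aln.column_map == (1, 2, 3)
        assert aln.query == "ACD"

    def test_a2m_lowercase_inserts_dropped(self, tmp_path):
        p = _write_fasta(tmp_path, [("query", "ACxyD"), ("s1", "AC..E")])
        # lowercase / '.' columns are per-sequence insert states
        aln = read_alignment(p, "query")
        assert aln.sequences == ["ACD", "ACE"]
        assert aln.column_map == (1, 2, 3)

    def test_query_gap_column_dropped(self, tmp_path):
        p = _write_fasta(tmp_path, [("query", "A-D"), ("s1", "ACE")])
        aln = read_alignment(p, "query")
        assert aln.sequences == ["AD", "AE"]
        assert aln.column_map == (1, 2)

    def test_missing_query(self, tmp_path):
        p = _write_fasta(tmp_path, [("s1", "ACD")])
        with pytest.raises(ValueError, match="query"):
            read_alignment(p, "nope")

    def test_ragged_rows(self, tmp_path):
        p = _write_fasta(tmp_path, [("query", "ACD"), ("s1", "AC")])
        with pytest.raises(ValueError, match="ragged"):
            read_alignment(p, "query")


def _aln(seqs, query_index=0):
    return Alignment(
        sequences=seqs,
        query_index=query_index,
        column_map=tuple(range(1, len(seqs[0]) + 1)),
    )


class TestSequenceWeights:
    def test_identical_cluster(self):
        w = sequence_weights(_aln(["AAA"] * 4))
        assert np.allclose(w, 0.25)
        assert np.isclose(w.sum(), 1.0)

    def test_all_singletons(self):
        w = sequence_weights(_aln(["AAA", "CCC", "DDD"]))
        assert np.allclose(w, 1.0)

    def test_mixed_brute_force(self):
        # identity(AAA, AAA) = 1 >= 0.8; identity(AAA, CCC) = 0
        w = sequence_weights(_aln(["AAA", "AAA", "CCC"]))
        assert np.allclose(w, [0.5, 0.5, 1.0])


class TestRankNormalize:
    def test_examples(self):
        assert np.allclose(rank_normalize([-2.0, 0.0, 5.0]), [0.25, 0.5, 0.75])
        assert np.allclose(rank_normalize([1.0, 1.0]), [0.5, 0.5])

    def test_na_preserved(self):
        out = rank_normalize([np.nan, 1.0, 2.0])
        assert np.isnan(out[0]) and np.allclose(out[1:], [1 / 3, 2 / 3])

    def test_all_na_error(self):
        with pytest.raises(ValueError):
            rank_normalize([np.nan, np.nan])

    @settings(derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30, unique=True))
    def test_monotone_transform_invariance_and_grid(self, xs):
        base = rank_normalize(xs)
        # scaling is strictly monotone and cannot collapse distinct floats here
        transformed = rank_normalize([3.0 * x for x in xs])
        assert np.allclose(base, transformed)
        n = len(xs)
        # distinct inputs: output is exactly the uniform grid {1..n}/(n+1)
        assert np.allclose(sorted(base), np.arange(1, n + 1) / (n + 1))
        assert np.all((base > 0) & (base < 1))


def _random_symmetric_model(L, rng, scale=0.5):
    h = rng.normal(0, 1, size=(L, Q))
    J = rng.normal(0, scale, size=(L, L, Q, Q))
    J = 0.5 * (J + J.transpose(1, 0, 3, 2))
    J[np.arange(L), np.arange(L)] = 0.0
    return PottsModel(h=h, J=J, lambda_h=0.0, lambda_J=0.0)


class TestSequenceEnergy:
    def test_zero_model(self):
        model = PottsModel(h=np.zeros((3, Q)), J=np.zeros((3, 3, Q, Q)),
                           lambda_h=0, lambda_J=0)
        assert sequence_energy(model, "ACD") == 0.0

    def test_field_only_hand_computed(self):
        h = np.zeros((3, Q))
        h[0, 0], h[1, 1], h[2, 2] = 1.0, 2.0, 3.0  # A, C, D
        model = PottsModel(h=h, J=np.zeros((3, 3, Q, Q)), lambda_h=0, lambda_J=0)
        assert sequence_energy(model, "ACD") == pytest.approx(-6.0)
        assert sequence_energy(model, "CCD") == pytest.approx(-5.0)

    def test_pair_model_exhaustive(self, rng):
        """2-site model: energy over all 20^2 sequences matches the Hamiltonian."""
        model = _random_symmetric_model(2, rng)
        for a in range(20):
            for b in range(20):
                seq = AMINO_ACIDS[a] + AMINO_ACIDS[b]
                direct = -(model.h[0, a] + model.h[1, b] + model.J[0, 1, a, b])
                assert sequence_energy(model, seq) == pytest.approx(direct)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            sequence_energy(_random_symmetric_model(3, rng), "ACDE")


class TestScoreVariant:
    def test_wt_to_wt_zero(self, rng):
        model = _random_symmetric_model(4, rng)
        assert score_variant(model, "ACDE", 2, "C") == 0.0

    def test_field_only_closed_form(self):
        h = np.zeros((2, Q))
        h[0, 0], h[0, 5] = 2.0, 0.5  # A and G at site 1
        model = PottsModel(h=h, J=np.zeros((2, 2, Q, Q)), lambda_h=0, lambda_J=0)
        assert score_variant(model, "AC", 1, "G") == pytest.approx(2.0 - 0.5)

    def test_fast_path_equals_full_recompute(self, rng):
        model = _random_symmetric_model(5, rng)
        wt = "ACDEF"
        e_wt = sequence_energy(model, wt)
        for mut in AMINO_ACIDS:
            if mut == wt[2]:
                continue
            full = sequence_energy(model, wt[:2] + mut + wt[3:]) - e_wt
            assert score_variant(model, wt, 3, mut) == pytest.approx(full)

    def test_gauge_invariance(self, rng):
        """Moving block means into the fields leaves every dE unchanged."""
        model = _random_symmetric_model(6, rng)
        h2, J2 = _gauge_fix(model.h, model.J)
        gauged = PottsModel(h=h2, J=J2, lambda_h=0, lambda_J=0)
        assert np.allclose(h2.sum(axis=1), 0.0)
        assert np.allclose(J2.sum(axis=2), 0.0) and np.allclose(J2.sum(axis=3), 0.0)
        wt = "ACDEFG"
        for pos in (1, 4, 6):
            for mut in "WYK":
                assert score_variant(model, wt, pos, mut) == pytest.approx(
                    score_variant(gauged, wt, pos, mut)
                )


def _field_only_oracle(counts, lam):
    """Solve the 1-column regularized problem n*(softmax(h) - f) + 2*lam*h = 0."""

    def obj(h):
        lse = np.log(np.exp(h - h.max()).sum()) + h.max()
        return -(counts * h).sum() + counts.sum() * lse + lam * (h**2).sum()

    res = minimize(obj, np.zeros(Q), method="L-BFGS-B", options={"gtol": 1e-10})
    return res.x - res.x.mean()


class TestFitPotts:
    def test_independent_columns_reduce_to_fields(self, rng):
        """With a dominant J penalty the fit matches per-column closed-form fields."""
        n, L = 400, 3
        cols = [rng.choice(list("ACDE"), size=n, p=[0.5, 0.3, 0.15, 0.05]) for _ in range(L)]
        seqs = ["".join(row) for row in zip(*cols)]
        aln = _aln(seqs)
        w = np.ones(n)
        model = fit_potts(aln, lambda_h=0.01, lambda_J=1e5, weights=w,
                          max_iter=3000, tol=1e-9)
        assert np.max(np.abs(model.J)) < 1e-3
        X = aln.to_matrix()
        for i in range(L):
            counts = np.bincount(X[:, i], minlength=Q).astype(float)
            expected = _field_only_oracle(counts, 0.01)
            assert np.allclose(model.h[i], expected, atol=1e-2)

    def test_covarying_pair_gets_largest_coupling(self, rng):
        """Two perfectly covarying columns dominate the fitted couplings."""
        n = 300
        state = rng.integers(0, 2, size=n)
        col0 = np.where(state == 0, "A", "C")
        col1 = np.where(state == 0, "D", "E")  # deterministic function of col0
        col2 = rng.choice(list("AC"), size=n)  # independent
        col3 = rng.choice(list("DE"), size=n)  # independent
        seqs = ["".join(t) for t in zip(col0, col1, col2, col3)]
        model = fit_potts(_aln(seqs), lambda_J=0.5, weights=np.ones(n), max_iter=400)
        norms = {
            (i, j): np.linalg.norm(model.J[i, j])
            for i in range(4)
            for j in range(i + 1, 4)
        }
        assert max(norms, key=norms.get) == (0, 1)

    def test_single_column(self, rng):
        seqs = ["".join(rng.choice(list("AC"))) for _ in range(50)]
        model = fit_potts(_aln(seqs), weights=np.ones(50))
        assert model.length == 1
        assert np.all(model.J == 0.0)

    def test_requires_two_distinct_sequences(self):
        with pytest.raises(ValueError):
            fit_potts(_aln(["AAA", "AAA"]))

    def test_deterministic(self, rng):
        seqs = ["".join(rng.choice(list("ACDE"), size=4)) for _ in range(60)]
        m1 = fit_potts(_aln(seqs))
        m2 = fit_potts(_aln(seqs))
        assert np.array_equal(m1.h, m2.h) and np.array_equal(m1.J, m2.J)


class TestCoverageMask:
    def test_all_gap_column_masked(self):
        aln = _aln(["AC", "A" + GAP, "A" + GAP, "A" + GAP], query_index=0)
        w = np.ones(4)
        masked = coverage_mask(aln, weights=w, min_neff_column=2, max_gap_fraction=0.5)
        assert masked == {2}

    def test_threshold_boundary_unmasked(self):
        aln = _aln(["AC", "AC", "A" + GAP, "A" + GAP])
        w = np.ones(4)
        # column 2: effective non-gap count exactly 2, gap fraction exactly 0.5
        masked = coverage_mask(aln, weights=w, min_neff_column=2, max_gap_fraction=0.5)
        assert masked == set()


def test_model_serialization_roundtrip(tmp_path, rng):
    model = _random_symmetric_model(3, rng)
    model = PottsModel(h=model.h, J=model.J, lambda_h=0.01, lambda_J=0.4,
                       column_map=(2, 5, 9))
    p = tmp_path / "model.txt"
    write_model(model, p)
    back = read_model(p)
    assert np.array_equal(back.h, model.h)
    assert np.array_equal(back.J, model.J)
    assert back.column_map == (2, 5, 9)
    assert back.lambda_J == 0.4


def test_build_evo_matrix_masking_and_ordering(rng):
    model = _random_symmetric_model(4, rng)
    model.column_map = (1, 2, 3, 4)
    evo = build_evo_matrix(model, "ACDE", masked_positions={3})
    assert all(pos != 3 for pos, _ in evo.raw)
    assert len(evo.raw) == 3 * 19
    raw = np.array([evo.raw[k] for k in sorted(evo.raw)])
    norm = np.array([evo.normalized[k] for k in sorted(evo.raw)])
    assert np.array_equal(np.argsort(raw), np.argsort(norm))
    assert np.all((norm > 0) & (norm < 1))
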