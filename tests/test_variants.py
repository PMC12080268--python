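"""Variant parsing, dE scoring, enumeration/ranking, epistasis, ddG tables."""

import numpy as np
import pandas as pd
import pytest

from evotherm.potts import PottsModel, energy, to_zero_sum_gauge
from evotherm.variants import (
    Variant,
    enumerate_and_rank,
    epistasis_decompose,
    ingest_ddg_runs,
    parse_variant,
    score_variant,
    stabilizing_only,
)

from conftest import random_model


def mutate(model, variant):
    sigma = model.focus_seq.astype(int).copy()
    for pos, _, mut in variant.substitutions:
        sigma[model.position_index(pos)] = model.alphabet.index(mut)
    return sigma


class TestVariantParsing:
    def test_single(self):
        v = parse_variant("Q289G")
        assert v.substitutions == ((289, "Q", "G"),)
        assert v.name == "Q289G"

    def test_double_sorted_by_position(self):
        v = parse_variant("Q289G/S180T")
        assert v.name == "S180T/Q289G"

    @pytest.mark.parametrize("bad", ["Q289", "289G", "Q289-", "Q289G/Q289A"])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_variant(bad)

    def test_synonymous_rejected(self):
        with pytest.raises(ValueError, match="synonymous"):
            parse_variant("Q289Q")


class TestScoreVariant:
    def test_empty_variant_scores_zero(self, rng):
        m = random_model(rng)
        assert score_variant(m, Variant(())) == 0.0

    def test_fields_only_closed_form(self, rng):
        L, q = 5, 6
        h = rng.normal(size=(L, q))
        m = PottsModel(
            h, np.zeros((L, L, q, q)), alphabet="-ACDEF",
            focus_seq=np.ones(L, dtype=np.int8),
        )
        v = Variant(((3, "A", "D"),))
        expected = h[2, m.alphabet.index("D")] - h[2, m.alphabet.index("A")]
        assert score_variant(m, v) == pytest.approx(expected)

    def test_double_matches_full_energy_difference(self, rng):
        """Incremental dE equals E(mutant) - E(wild type), 100 random trials."""
        for _ in range(100):
            m = random_model(rng, L=6, q=6, alphabet="-ACDEF")
            cols = rng.choice(6, size=2, replace=False)
            subs = []
            for c in sorted(cols):
                wt = m.alphabet[m.focus_seq[c]]
                choices = [a for a in "ACDEF" if a != wt]
                subs.append((c + 1, wt, str(rng.choice(choices))))
            v = Variant(tuple(subs))
            de = score_variant(m, v)
            full = energy(m, mutate(m, v)) - energy(m, m.focus_seq.astype(int))
            assert de == pytest.approx(full, abs=1e-9)

    def test_unmodeled_position_error_names_position(self, rng):
        m = random_model(rng, L=4, q=5)
        m.positions = np.array([1, 2, 4, 5])  # position 3 filtered out
        wt = m.alphabet[m.focus_seq[0]]
        mut = "A" if wt != "A" else "C"
        with pytest.raises(KeyError, match="3"):
            score_variant(m, Variant(((3, wt, mut),)))

    def test_wild_type_mismatch_rejected(self, rng):
        m = random_model(rng, L=4, q=5)
        wt = m.alphabet[m.focus_seq[0]]
        wrong = "C" if wt != "C" else "D"
        mut = "E" if wt != "E" else "A"
        with pytest.raises(ValueError, match="ild-type"):
            score_variant(m, Variant(((1, wrong, mut),)))

    def test_gauge_invariant(self, rng):
        m = random_model(rng)
        zs = to_zero_sum_gauge(m)
        for _ in range(10):
            c = int(rng.integers(0, m.L))
            wt = m.alphabet[m.focus_seq[c]]
            choices = [a for a in m.alphabet[1:] if a != wt]
            v = Variant(((c + 1, wt, str(rng.choice(choices))),))
            assert score_variant(m, v) == pytest.approx(
                score_variant(zs, v), abs=1e-8
            )

    def test_antisymmetric_under_role_swap(self, rng):
        """dE(wt -> mut) = -dE(mut -> wt)."""
        m = random_model(rng)
        c = 2
        wt = m.alphabet[m.focus_seq[c]]
        mut = next(a for a in m.alphabet[1:] if a != wt)
        forward = score_variant(m, Variant(((c + 1, wt, mut),)))
        swapped = PottsModel(
            m.h, m.J, alphabet=m.alphabet,
            focus_seq=np.array(
                [m.alphabet.index(mut) if i == c else s
                 for i, s in enumerate(m.focus_seq)], dtype=np.int8),
        )
        backward = score_variant(swapped, Variant(((c + 1, mut, wt),)))
        assert forward == pytest.approx(-backward, abs=1e-10)


class TestEnumerateAndRank:
    def test_matches_brute_force(self, rng):
        m = random_model(rng, L=3, q=5, alphabet="-ACDE")
        for order in ("single", "double"):
            ranked = enumerate_and_rank(m, order=order, top_k=10**6)
            brute = []
            if order == "single":
                for c in range(m.L):
                    wt = m.alphabet[m.focus_seq[c]]
                    for a in m.alphabet[1:]:
                        if a == wt:
                            continue
                        v = Variant(((c + 1, wt, a),))
                        brute.append((score_variant(m, v), v.name))
            else:
                for c1 in range(m.L):
                    for c2 in range(c1 + 1, m.L):
                        w1 = m.alphabet[m.focus_seq[c1]]
                        w2 = m.alphabet[m.focus_seq[c2]]
                        for a in m.alphabet[1:]:
                            for b in m.alphabet[1:]:
                                if a == w1 or b == w2:
                                    continue
                                v = Variant(((c1 + 1, w1, a), (c2 + 1, w2, b)))
                                brute.append((score_variant(m, v), v.name))
            brute.sort(key=lambda t: -t[0])
            assert len(ranked) == len(brute)
            for got, (de, name) in zip(ranked, brute[: len(ranked)]):
                assert got.delta_e == pytest.approx(de, abs=1e-9)

    def test_ranks_dense_and_sorted(self, rng):
        m = random_model(rng, L=4, q=5)
        ranked = enumerate_and_rank(m, "single", top_k=10)
        des = [s.delta_e for s in ranked]
        assert des == sorted(des, reverse=True)
        assert ranked[0].rank == 1
        assert all(
            b.rank in (a.rank, a.rank + 1) for a, b in zip(ranked, ranked[1:])
        )

    def test_top_k_exceeding_size_returns_all(self, rng):
        m = random_model(rng, L=3, q=4, alphabet="-ACD")
        ranked = enumerate_and_rank(m, "single", top_k=10_000)
        assert len(ranked) == 3 * 2  # L * (aa states - wt)

    def test_stable_under_input_permutation(self, rng):
        """Ranking is a total order: scoring does not depend on storage order."""
        m = random_model(rng, L=4, q=5)
        ranked1 = enumerate_and_rank(m, "double", top_k=15)
        ranked2 = enumerate_and_rank(m, "double", top_k=15)
        assert [s.variant.name for s in ranked1] == [
            s.variant.name for s in ranked2
        ]


class TestEpistasisDecompose:
    def test_zero_couplings_zero_gap(self, rng):
        L, q = 5, 6
        h = rng.normal(size=(L, q))
        m = PottsModel(h, np.zeros((L, L, q, q)), alphabet="-ACDEF",
                       focus_seq=np.ones(L, dtype=np.int8))
        rec = epistasis_decompose(m, parse_variant("A1C/A3D"))
        assert rec.coupling_gap == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_exact(self, rng):
        """dE(double) = dE_a + dE_b + coupling_gap, exactly."""
        m = random_model(rng)
        c1, c2 = 1, 4
        w1, w2 = m.alphabet[m.focus_seq[c1]], m.alphabet[m.focus_seq[c2]]
        m1 = next(a for a in m.alphabet[1:] if a != w1)
        m2 = next(a for a in m.alphabet[1:] if a != w2)
        double = Variant(((c1 + 1, w1, m1), (c2 + 1, w2, m2)))
        rec = epistasis_decompose(m, double)
        assert rec.delta_e_a + rec.delta_e_b + rec.coupling_gap == pytest.approx(
            score_variant(m, double), abs=1e-9
        )
        # gap equals the four-term coupling difference
        a_, b_ = m.alphabet.index(m1), m.alphabet.index(m2)
        wa, wb = m.focus_seq[c1], m.focus_seq[c2]
        four = (
            m.J[c1, c2, a_, b_] - m.J[c1, c2, a_, wb]
            - m.J[c1, c2, wa, b_] + m.J[c1, c2, wa, wb]
        )
        assert rec.coupling_gap == pytest.approx(four, abs=1e-9)

    def test_from_score_table(self):
        scores = {"S180T/Q289G": 4.43, "S180T": 1.26, "Q289G": 3.13}
        rec = epistasis_decompose(scores, parse_variant("S180T/Q289G"))
        assert rec.coupling_gap == pytest.approx(0.04)

    def test_missing_single_raises(self):
        with pytest.raises(KeyError, match="Q289G"):
            epistasis_decompose({"S180T/Q289G": 4.43, "S180T": 1.26},
                                parse_variant("S180T/Q289G"))


class TestIngestDdg:
    def test_degenerate_runs(self):
        rows = [("D138N", i, -5.35) for i in range(1, 6)]
        df = pd.DataFrame(rows, columns=["variant", "run_index", "ddg"])
        (score,) = ingest_ddg_runs(df)
        assert score.ddg_mean == pytest.approx(-5.35)
        assert score.ddg_sem == pytest.approx(0.0)
        assert score.rank == 1

    def test_sorted_ascending_with_sem(self):
        rows = []
        for v, mean in [("D138N", -5.35), ("E20I", -2.84), ("D138C", -4.34)]:
            for i in range(1, 6):
                rows.append((v, i, mean + 0.01 * (i - 3)))
        scores = ingest_ddg_runs(
            pd.DataFrame(rows, columns=["variant", "run_index", "ddg"])
        )
        assert [s.variant.name for s in scores] == ["D138N", "D138C", "E20I"]
        assert scores[0].ddg_mean == pytest.approx(-5.35)
        assert scores[0].ddg_sem > 0

    def test_zero_mean_excluded_by_stabilizing_filter(self):
        rows = [("A1C", 1, -1.0), ("A1C", 2, 0.0), ("A1C", 3, 1.0),
                ("A2C", 1, -0.5)]
        scores = ingest_ddg_runs(
            pd.DataFrame(rows, columns=["variant", "run_index", "ddg"])
        )
        kept = stabilizing_only(scores)
        assert [s.variant.name for s in kept] == ["A2C"]

    def test_duplicate_run_rejected(self):
        df = pd.DataFrame(
            [("A1C", 1, -1.0), ("A1C", 1, -2.0)],
            columns=["variant", "run_index", "ddg"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            ingest_ddg_runs(df)

    def test_non_numeric_rejected(self):
        df = pd.DataFrame(
            [("A1C", 1, "oops")], columns=["variant", "run_index", "ddg"]
        )
        with pytest.raises(ValueError):
            ingest_ddg_runs(df)

    def test_parses_delimited_text(self):
        text = "variant,run_index,ddg\nD138N,1,-5.35\nD138N,2,-5.35\n"
        (score,) = ingest_ddg_runs(text)
        assert score.ddg_mean == pytest.approx(-5.35)
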