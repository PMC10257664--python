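"""PSSM predictor, ensemble consensus rule, filter cascade and ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoact import mhc_binding as mb
from neoact import synthetic_fixtures as sf
from neoact.variant_peptides import PeptidePair


def make_candidate(mut_ic50, wt_ic50, tpm, vaf=0.3, peptide="KLMNPQRST",
                   vid="v1"):
    pair = PeptidePair(vid, peptide, peptide if wt_ic50 is not None else None,
                       1, len(peptide))
    return mb.NeoantigenCandidate(pair, mut_ic50, wt_ic50, tpm, vaf)


class TestPSSM:
    def test_degenerate_motif(self):
        model = mb.train_pssm(["KLMNPQRST"] * 20, 9)
        assert mb.pssm_score(model, "KLMNPQRST") == pytest.approx(1.0)
        for i in range(9):
            col = model.weights[:, i]
            assert mb.AMINO_ACIDS[int(np.argmax(col))] == "KLMNPQRST"[i]

    def test_anti_consensus_scores_zero(self):
        model = mb.train_pssm(["KLMNPQRST"] * 20, 9)
        worst = "".join(mb.AMINO_ACIDS[int(np.argmin(model.weights[:, i]))]
                        for i in range(9))
        assert mb.pssm_score(model, worst) == pytest.approx(0.0)

    def test_zero_binders_rejected(self):
        with pytest.raises(ValueError):
            mb.train_pssm([], 9)

    def test_wrong_length_rejected(self):
        model = mb.train_pssm(["KLMNPQRST"] * 20, 9)
        with pytest.raises(ValueError):
            mb.train_pssm(["KLMNPQRS"], 9)
        with pytest.raises(ValueError):
            mb.pssm_score(model, "KLMNPQRS")

    def test_anchor_columns_dominate(self):
        cfg = sf.SimConfig(seed=3, motif_anchors={2: "L", 9: "K"})
        binders = sf.gen_binder_set(cfg, "HLA-A*11:01", 100)
        model = mb.train_pssm(binders, 9)
        col_range = model.weights.max(axis=0) - model.weights.min(axis=0)
        top_two = set(np.argsort(col_range)[-2:])
        assert top_two == {1, 8}  # 0-based anchor columns
        assert mb.AMINO_ACIDS[int(np.argmax(model.weights[:, 1]))] == "L"
        assert mb.AMINO_ACIDS[int(np.argmax(model.weights[:, 8]))] == "K"

    @given(st.text(alphabet=mb.AMINO_ACIDS, min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_score_bounded(self, peptide):
        model = mb.train_pssm(["KLMNPQRST", "KAMNPQRSV"] * 5, 9)
        assert 0.0 <= mb.pssm_score(model, peptide) <= 1.0


class TestScoreToIC50:
    def test_endpoints(self):
        assert mb.score_to_ic50(1.0) == pytest.approx(1.0)
        assert mb.score_to_ic50(0.0) == pytest.approx(50000.0)
        assert mb.score_to_ic50(0.5) == pytest.approx(math.sqrt(50000.0))

    def test_domain(self):
        with pytest.raises(ValueError):
            mb.score_to_ic50(1.2)


def consensus_oracle(values):
    """Independent restatement of the consensus rule: count then min."""
    strong = [v for v in values if v < 500.0]
    return min(values) if len(strong) >= 3 else 50000.0


class TestConsensus:
    @pytest.mark.parametrize("values,expected", [
        ([100, 200, 300, 600, 700], 100),
        ([100, 600, 700, 800, 900], 50000),
        ([499, 499, 499, 50000, 50000], 499),
        ([500, 400, 450, 480, 50000], 400),  # 500 itself does not vote
    ])
    def test_examples(self, values, expected):
        assert mb.consensus_ic50(values) == expected

    def test_arity(self):
        with pytest.raises(ValueError):
            mb.consensus_ic50([100, 200, 300])

    def test_matches_oracle_on_random_tuples(self):
        rng = np.random.default_rng(5)
        for _ in range(2000):
            values = list(rng.uniform(1, 60000, size=5))
            if rng.random() < 0.3:  # force boundary values
                values[rng.integers(5)] = 500.0
            assert mb.consensus_ic50(values) == consensus_oracle(values)

    def test_output_is_min_or_sentinel(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            values = list(rng.uniform(1, 2000, size=5))
            result = mb.consensus_ic50(values)
            assert result == min(values) or result == 50000.0


class TestEnsemble:
    def test_unanimous(self):
        pair = PeptidePair("v1", "KLMNPQRST", "KLMNPQRSV", 1, 9)
        preds = [lambda p, a: 100.0] * 5
        mut, wt = mb.predict_ensemble([pair], preds, "HLA-A*11:01")
        assert mut["KLMNPQRST"].consensus_ic50 == 100.0
        assert wt["KLMNPQRSV"].consensus_ic50 == 100.0

    def test_no_wt_prediction_for_frameshift_window(self):
        pair = PeptidePair("v1", "KLMNPQRST", None, 1, 9)
        preds = [lambda p, a: 100.0] * 5
        _mut, wt = mb.predict_ensemble([pair], preds, "HLA-A*11:01")
        assert wt == {}

    def test_failing_predictor_records_sentinel(self):
        def boom(p, a):
            raise RuntimeError("predictor offline")
        pair = PeptidePair("v1", "KLMNPQRST", None, 1, 9)
        preds = [lambda p, a: 100.0] * 4 + [boom]
        mut, _ = mb.predict_ensemble([pair], preds, "A")
        assert mut["KLMNPQRST"].predictor_ic50s[-1] == 50000.0
        assert mut["KLMNPQRST"].consensus_ic50 == 100.0

    def test_exchange_tsv_round_trip(self, tmp_path):
        """Pre-computed IC50s from file give identical consensus values."""
        pair = PeptidePair("v1", "KLMNPQRST", None, 1, 9)
        values = [120.0, 90.0, 700.0, 300.0, 450.0]
        preds = [(lambda v: lambda p, a: v)(v) for v in values]
        mut, _ = mb.predict_ensemble([pair], preds, "HLA-A*11:01")

        path = tmp_path / "exchange.tsv"
        lines = ["peptide\tallele\tpredictor\tic50_nm"]
        for i, v in enumerate(values):
            lines.append(f"KLMNPQRST\tHLA-A*11:01\tp{i}\t{v}")
        path.write_text("\n".join(lines) + "\n")
        table = mb.read_exchange_tsv(path)
        external = mb.exchange_predictions(table)
        assert (external["KLMNPQRST"].consensus_ic50
                == mut["KLMNPQRST"].consensus_ic50)

    def test_exchange_tsv_requires_five_predictors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("peptide\tallele\tpredictor\tic50_nm\n"
                        "KLMNPQRST\tA\tp1\t100\n")
        with pytest.raises(ValueError):
            mb.read_exchange_tsv(path)


class TestFilterCascade:
    @pytest.mark.parametrize("mut,wt,tpm,expected", [
        (300, 250, 5, {mb.FAIL_WT_COMPARISON}),
        (450, 600, 0.9, {mb.FAIL_EXPRESSION}),
        (450, 600, 2, set()),
        (500, 600, 2, set()),            # 500 is not > 500
        (600, 250, 0.5, {mb.FAIL_AFFINITY, mb.FAIL_WT_COMPARISON,
                         mb.FAIL_EXPRESSION}),  # all flags evaluated
    ])
    def test_flags(self, mut, wt, tpm, expected):
        [c] = mb.apply_filters([make_candidate(mut, wt, tpm)])
        assert c.filter_flags == frozenset(expected)

    def test_wt_comparison_skipped_without_partner(self):
        [c] = mb.apply_filters([make_candidate(400, None, 5)])
        assert c.filter_flags == frozenset()

    def test_monotone_under_tightening(self):
        rng = np.random.default_rng(8)
        cands = [make_candidate(float(rng.uniform(1, 2000)),
                                float(rng.uniform(1, 2000)),
                                float(rng.uniform(0, 10)),
                                peptide=f"PEP{i:04d}AA", vid=f"v{i}")
                 for i in range(200)]

        def n_retained(affinity, tpm_min):
            return sum(1 for c in mb.apply_filters(cands, affinity, tpm_min)
                       if not c.filter_flags)

        base = n_retained(500, 1.0)
        assert n_retained(250, 1.0) <= base   # stricter affinity
        assert n_retained(500, 2.0) <= base   # stricter expression


class TestRanking:
    def test_sorted_by_ic50(self):
        cands = mb.apply_filters([
            make_candidate(50, 600, 5, peptide="AAAAAAAAA", vid="a"),
            make_candidate(10, 600, 5, peptide="CCCCCCCCC", vid="b"),
            make_candidate(400, 600, 5, peptide="DDDDDDDDD", vid="c"),
        ])
        ranked = mb.rank_candidates(cands)
        assert [c.mut_ic50 for c in ranked] == [10, 50, 400]
        assert [c.rank for c in ranked] == [1, 2, 3]

    def test_tie_broken_by_vaf(self):
        cands = mb.apply_filters([
            make_candidate(100, 600, 5, vaf=0.1, peptide="AAAAAAAAA", vid="a"),
            make_candidate(100, 600, 5, vaf=0.3, peptide="CCCCCCCCC", vid="b"),
        ])
        ranked = mb.rank_candidates(cands)
        assert [c.vaf for c in ranked] == [0.3, 0.1]

    def test_top_n_truncates(self):
        cands = mb.apply_filters([
            make_candidate(float(i + 1), None, 5, peptide=f"PEP{i:04d}AA",
                           vid=f"v{i}") for i in range(30)])
        assert len(mb.rank_candidates(cands, top_n=20)) == 20

    def test_duplicate_peptides_keep_lowest_ic50(self):
        cands = mb.apply_filters([
            make_candidate(200, None, 5, peptide="AAAAAAAAA", vid="a"),
            make_candidate(100, None, 5, peptide="AAAAAAAAA", vid="b"),
        ])
        ranked = mb.rank_candidates(cands)
        assert len(ranked) == 1 and ranked[0].mut_ic50 == 100

    def test_ranked_tsv_deterministic(self, tmp_path):
        cands = mb.apply_filters([
            make_candidate(123.45678, 600.0, 5.5, peptide=f"PEP{i:04d}AA",
                           vid=f"v{i}") for i in range(10)])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        mb.write_ranked_tsv(mb.rank_candidates(cands), p1)
        mb.write_ranked_tsv(mb.rank_candidates(list(cands)), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert "123.4568" in p1.read_text()  # 4-decimal floats


class TestMotifRecovery:
    def test_motif_peptides_outscore_random(self, sim_config, pssm_ensemble):
        """Peptides from the training motif get lower consensus IC50 than
        uniform-random peptides (rank separation of the two samples)."""
        from scipy.stats import mannwhitneyu

        binders = sf.gen_binder_set(sim_config, "HLA-A*11:01", 50)
        decoys = sf.gen_random_peptides(sim_config, 50, label="test-decoys")

        def consensus(pep):
            return mb.consensus_ic50([p(pep, "HLA-A*11:01")
                                      for p in pssm_ensemble])

        binder_scores = [consensus(p) for p in binders]
        decoy_scores = [consensus(p) for p in decoys]
        assert np.median(binder_scores) < np.median(decoy_scores)
        stat = mannwhitneyu(binder_scores, decoy_scores, alternative="less")
        assert stat.pvalue < 1e-6
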