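"""Rule-based candidate screen: scoring, selection, upstream expansion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from regcycle.netfilter import (
    score_criteria,
    select_candidates,
    upstream_expand,
)
from regcycle.synth import HUB_IDS, FixtureSpec, generate_network_fixture


def edges(*rows):
    return pd.DataFrame(rows, columns=["source", "target", "sign", "layer",
                                       "evidence"])


def e(src, dst, sign, layer="direct", ev="experimental"):
    return (src, dst, sign, layer, ev)


class TestScoring:
    def test_triple_satisfier(self):
        df = edges(e("AMPK", "CDC37", "activation"),
                   e("CDC37", "ULK1", "activation"),
                   e("CDC37", "MTOR", "inhibition"))
        scores = score_criteria(df, HUB_IDS)
        assert len(scores) == 1
        s = scores[0]
        assert s.protein == "CDC37" and s.count == 3
        assert s.induced_by_ampk and s.activates_ulk1 and s.inhibits_mtor

    def test_wrong_signs_score_zero(self):
        df = edges(e("AMPK", "X", "inhibition"),
                   e("X", "ULK1", "inhibition"),
                   e("X", "MTOR", "activation"))
        (s,) = score_criteria(df, HUB_IDS)
        assert s.count == 0

    def test_empty_table(self):
        df = edges()
        with pytest.raises(ValueError):
            score_criteria(df, HUB_IDS)

    def test_missing_hub_key(self):
        df = edges(e("AMPK", "X", "activation"))
        with pytest.raises(KeyError):
            score_criteria(df, {"ampk": "AMPK", "ulk1": "ULK1"})

    def test_hubs_not_candidates(self):
        df = edges(e("AMPK", "ULK1", "activation"),
                   e("AMPK", "X", "activation"))
        assert [s.protein for s in score_criteria(df, HUB_IDS)] == ["X"]

    def test_experimental_beats_conflicting_predicted(self):
        # predicted activation overruled by experimental inhibition
        df = edges(e("AMPK", "X", "activation", ev="predicted"),
                   e("AMPK", "X", "inhibition", ev="experimental"))
        (s,) = score_criteria(df, HUB_IDS)
        assert not s.induced_by_ampk
        # but an experimental record of the required sign always counts
        df2 = edges(e("AMPK", "X", "activation", ev="experimental"),
                    e("AMPK", "X", "inhibition", ev="experimental"))
        (s2,) = score_criteria(df2, HUB_IDS)
        assert s2.induced_by_ampk
        assert s2.evidence["induced_by_ampk"] == "experimental"

    def test_predicted_only_counts_and_is_flagged(self):
        df = edges(e("X", "ULK1", "activation", ev="predicted"))
        (s,) = score_criteria(df, HUB_IDS)
        assert s.activates_ulk1
        assert s.evidence["activates_ulk1"] == "predicted"

    @given(st.integers(0, 500))
    def test_invariant_to_order_and_duplication(self, seed):
        df, _ = generate_network_fixture(FixtureSpec(
            n_proteins=40, n_triple=1, n_double=3, n_single=2,
            decoy_edges=30, seed=seed))
        base = {(s.protein, s.count)
                for s in score_criteria(df, HUB_IDS)}
        rng = np.random.default_rng(seed)
        shuffled = df.sample(frac=1.0, random_state=int(rng.integers(1e6)))
        doubled = pd.concat([shuffled, df.iloc[: len(df) // 2]])
        again = {(s.protein, s.count)
                 for s in score_criteria(doubled, HUB_IDS)}
        assert base == again


class TestSelection:
    def test_nested_supersets(self, network_fixture):
        df, _ = network_fixture
        scores = score_criteria(df, HUB_IDS)
        sel = {m: {s.protein for s in select_candidates(scores, m)}
               for m in (1, 2, 3)}
        assert sel[3] <= sel[2] <= sel[1]

    def test_planted_recovery(self, network_fixture):
        df, truth = network_fixture
        scores = score_criteria(df, HUB_IDS)
        assert sorted(s.protein for s in select_candidates(scores, 3)) \
            == truth.triple
        assert sorted(s.protein for s in select_candidates(scores, 2)) \
            == truth.candidates(2)

    def test_sorted_by_count_then_name(self, network_fixture):
        df, _ = network_fixture
        sel = select_candidates(score_criteria(df, HUB_IDS), 1)
        keys = [(-s.count, s.protein) for s in sel]
        assert keys == sorted(keys)

    def test_min_count_validated(self):
        with pytest.raises(ValueError):
            select_candidates([], 0)


class TestUpstreamExpansion:
    def test_activator_of_activator_kept_inhibitor_dropped(self):
        df = edges(e("X", "ULK1", "activation"),
                   e("X", "MTOR", "inhibition"),
                   e("U1", "X", "activation", layer="additional"),
                   e("U2", "X", "inhibition", layer="additional"))
        cands = select_candidates(score_criteria(df, HUB_IDS), 2)
        kept, report = upstream_expand(df, cands)
        pairs = set(zip(kept.source, kept.target))
        assert ("U1", "X") in pairs
        assert ("U2", "X") not in pairs
        assert report.sign_inconsistent == 1

    def test_unsigned_edge_dropped_and_counted(self):
        df = edges(e("X", "ULK1", "activation"),
                   e("AMPK", "X", "activation"),
                   e("U", "X", "unknown", layer="additional"))
        cands = select_candidates(score_criteria(df, HUB_IDS), 2)
        kept, report = upstream_expand(df, cands)
        assert report.unsigned == 1
        assert "U" not in set(kept.source)

    def test_output_is_subgraph_and_idempotent(self, network_fixture):
        df, _ = network_fixture
        cands = select_candidates(score_criteria(df, HUB_IDS), 2)
        once, _ = upstream_expand(df, cands)
        merged = df.merge(once, how="inner")
        assert len(merged) == len(once)          # subgraph of the input
        twice, rep2 = upstream_expand(once, cands)
        assert twice.reset_index(drop=True).equals(
            once.reset_index(drop=True))
        assert rep2.sign_inconsistent == 0 and rep2.unsigned == 0

    def test_planted_sign_inconsistent_edges_all_dropped(self,
                                                         network_fixture):
        df, truth = network_fixture
        cands = select_candidates(score_criteria(df, HUB_IDS), 1)
        kept, _ = upstream_expand(df, cands)
        pairs = set(zip(kept.source, kept.target))
        assert not pairs & set(truth.upstream_dropped)
        cand_set = {c.protein for c in cands}
        expected_kept = {p for p in truth.upstream_kept
                         if p[1] in cand_set}
        assert expected_kept <= pairs

    def test_literal_activator_only_rule(self):
        # Y inhibits mTOR but does not touch ULK1: under the literal rule
        # its upstream edges are not filtered
        df = edges(e("AMPK", "Y", "activation"),
                   e("Y", "MTOR", "inhibition"),
                   e("U", "Y", "inhibition", layer="additional"))
        cands = select_candidates(score_criteria(df, HUB_IDS), 2)
        strict, _ = upstream_expand(df, cands, activator_rule_only=False)
        literal, _ = upstream_expand(df, cands, activator_rule_only=True)
        assert ("U", "Y") not in set(zip(strict.source, strict.target))
        assert ("U", "Y") in set(zip(literal.source, literal.target))
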