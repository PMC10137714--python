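"""Nine-type decision table, merging/naming, and landscape summaries."""

import itertools

import pytest

from tsrnakit.align import CollapsedRead, FragmentAlignment
from tsrnakit.classify import (NINE_TYPES, TsRNAType, classify_fragment,
                               merge_and_name, summarize_landscape)


def _aln(space, start, end):
    return FragmentAlignment("r", "g", space, start, end, 0, 1.0)


def classify(model, space, start, end):
    return classify_fragment(_aln(space, start, end), model)


class TestDecisionTable:
    @pytest.mark.parametrize("space,start,end,expected", [
        # 5' series: ends in D-loop, between D-loop and anticodon stem,
        # in the stem
        ("mature", 1, 18, TsRNAType.TRF_5A),
        ("mature", 1, 21, TsRNAType.TRF_5A),
        ("mature", 1, 24, TsRNAType.TRF_5B),
        ("mature", 1, 28, TsRNAType.TRF_5C),
        ("mature", 2, 31, TsRNAType.TRF_5C),
        # halves: anticodon-loop cleavage, 30-36 nt
        ("mature", 1, 32, TsRNAType.TIRNA_5),
        ("mature", 1, 34, TsRNAType.TIRNA_5),
        ("mature", 3, 32, TsRNAType.TIRNA_5),  # the 30-nt half
        ("mature", 1, 36, TsRNAType.TIRNA_5),
        ("mature", 35, 76, TsRNAType.TIRNA_3),
        ("mature", 32, 76, TsRNAType.TIRNA_3),
        # 3' series: CCA-terminated 18-mer and 22-mer
        ("mature", 59, 76, TsRNAType.TRF_3A),
        ("mature", 55, 76, TsRNAType.TRF_3B),
        # precursor trailer
        ("precursor", 77, 92, TsRNAType.TRF_1),
        ("precursor", 78, 92, TsRNAType.TRF_1),
        # interior
        ("mature", 10, 40, TsRNAType.I_TRF),
        # 5'-anchored but longer than a half: falls to the interior bucket
        ("mature", 1, 37, TsRNAType.I_TRF),
        ("mature", 1, 38, TsRNAType.I_TRF),
    ])
    def test_examples(self, canonical, space, start, end, expected):
        assert classify(canonical, space, start, end) is expected

    def test_five_prime_rule_precedence_near_full_length(self, canonical):
        # both anchors hold; judged by the 5' rule
        label = classify(canonical, "mature", 1, 75)
        assert label is TsRNAType.I_TRF  # 75 nt exceeds the half window

    def test_out_of_bounds_rejected(self, canonical):
        with pytest.raises(ValueError):
            classify(canonical, "mature", 0, 20)
        with pytest.raises(ValueError):
            classify(canonical, "mature", 50, 80)

    def test_exhaustive_and_disjoint_on_canonical(self, canonical):
        """Every 15-45-nt fragment gets exactly one label; all nine occur."""
        seen = set()
        for start, end in itertools.combinations_with_replacement(
                range(1, 77), 2):
            if 15 <= end - start + 1 <= 45:
                seen.add(classify(canonical, "mature", start, end))
        plen = 76 + len(canonical.trailer_seq)
        for start in range(77, plen + 1):
            for end in range(start + 14, plen + 1):
                if end - start + 1 <= 45:
                    seen.add(classify(canonical, "precursor", start, end))
        assert seen == set(NINE_TYPES)

    def test_tirna5_length_bounds_match_definition(self, canonical):
        """5' halves ending in the anticodon loop span exactly 30-36 nt."""
        lengths = []
        for start in range(1, 4):
            for end in range(32, 39):
                if classify(canonical, "mature", start, end) \
                        is TsRNAType.TIRNA_5:
                    lengths.append(end - start + 1)
        assert min(lengths) == 30
        assert max(lengths) == 36


class TestMergeAndName:
    def test_shared_sequence_merges_parents(self, small_models):
        donors = [m for m in small_models
                  if m.amino_acid == small_models[0].amino_acid][:1]
        m = donors[0]
        twin = m.__class__(**{**m.__dict__, "gene_id": "twin-1"})
        seq = m.mature_seq[:30]
        reads = [CollapsedRead("r1", seq, {"S1": 10})]
        alns = [FragmentAlignment("r1", m.gene_id, "mature", 1, 30, 0, 0.5),
                FragmentAlignment("r1", "twin-1", "mature", 1, 30, 0, 0.5)]
        records = merge_and_name(reads, alns, [m, twin])
        assert len(records) == 1
        rec = records[0]
        assert rec.parents == (m.gene_id, "twin-1")
        assert rec.name.endswith("-001")
        assert rec.name.startswith(f"tRF-{m.amino_acid}-{m.anticodon}")

    def test_serials_follow_count_order(self, small_models):
        m = small_models[0]
        reads = [CollapsedRead("r1", m.mature_seq[:20], {"S1": 10}),
                 CollapsedRead("r2", m.mature_seq[:18], {"S1": 100})]
        alns = [FragmentAlignment("r1", m.gene_id, "mature", 1, 20, 0, 1.0),
                FragmentAlignment("r2", m.gene_id, "mature", 1, 18, 0, 1.0)]
        records = {r.sequence: r.name for r in merge_and_name(reads, alns, [m])}
        assert records[m.mature_seq[:18]].endswith("-001")
        assert records[m.mature_seq[:20]].endswith("-002")

    def test_type_tie_breaks_lexicographically_and_flags(self, small_models):
        m = small_models[0]
        other = m.__class__(**{**m.__dict__, "gene_id": "zz-1"})
        reads = [CollapsedRead("r1", m.mature_seq[:30], {"S1": 1})]
        # fabricate conflicting placements of equal weight
        alns = [FragmentAlignment("r1", m.gene_id, "mature", 1, 30, 0, 0.5),
                FragmentAlignment("r1", "zz-1", "mature", 10, 39, 0, 0.5)]
        rec = merge_and_name(reads, alns, [m, other])[0]
        assert "ambiguous_type" in rec.flags
        assert rec.type is min(
            (TsRNAType.TRF_5C, TsRNAType.I_TRF), key=lambda t: t.value)

    def test_mixed_origin_counts_as_cytosolic(self, small_models):
        m = small_models[0]
        mito = m.__class__(**{**m.__dict__, "gene_id": "mt-1",
                              "origin": "mitochondrial"})
        reads = [CollapsedRead("r1", m.mature_seq[:30], {"S1": 1})]
        alns = [FragmentAlignment("r1", m.gene_id, "mature", 1, 30, 0, 0.5),
                FragmentAlignment("r1", "mt-1", "mature", 1, 30, 0, 0.5)]
        rec = merge_and_name(reads, alns, [m, mito])[0]
        assert rec.origin == "cytosolic"
        assert "mixed_origin" in rec.flags


class TestSummaries:
    def _records(self, small_models, specs):
        reads, alns = [], []
        for i, (model, start, end, count) in enumerate(specs):
            rid = f"r{i}"
            reads.append(CollapsedRead(
                rid, model.mature_seq[start - 1:end], {"S1": count}))
            alns.append(FragmentAlignment(rid, model.gene_id, "mature",
                                          start, end, 0, 1.0))
        return merge_and_name(reads, alns, small_models)

    def test_amino_acid_portions(self, small_models):
        gly_like = small_models[0]
        other = next(m for m in small_models
                     if m.amino_acid != gly_like.amino_acid)
        records = self._records(small_models, [
            (gly_like, 1, 18, 5), (gly_like, 1, 19, 5), (gly_like, 1, 20, 5),
            (other, 1, 18, 5)])
        tables = summarize_landscape(records)
        aa = tables["per_amino_acid"]["pct_distinct"]
        assert aa[gly_like.amino_acid] == pytest.approx(75.0)
        assert aa[other.amino_acid] == pytest.approx(25.0)

    def test_single_type_composition(self, small_models):
        m = small_models[0]
        records = self._records(small_models, [(m, 1, 28, 3), (m, 2, 28, 7)])
        comp = summarize_landscape(records)["type_composition"]
        assert comp.loc["tRF-5c", "pct_distinct"] == pytest.approx(100.0)
        assert comp.drop("tRF-5c")["pct_distinct"].sum() == 0.0

    def test_portions_sum_to_100(self, small_models):
        records = self._records(
            small_models,
            [(small_models[i % len(small_models)], 1 + i % 3, 20 + i, 1 + i)
             for i in range(12)])
        tables = summarize_landscape(records)
        for name in ("type_composition", "origin_split", "space_split",
                     "per_amino_acid", "per_parent_family"):
            for col in ("pct_distinct", "pct_reads"):
                assert tables[name][col].sum() == pytest.approx(100.0)
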