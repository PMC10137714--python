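"""Read collapsing, filtering, and tRNA-space alignment."""

import numpy as np
import pytest

from tsrnakit.align import (CollapsedRead, align_to_trna, collapse_reads,
                            collapse_sequences, filter_reads)


def brute_force_placements(read, models, max_mismatch):
    """Independent oracle: test every offset of every reference by slicing."""
    hits = []
    for model in models:
        for space, ref in (("mature", model.mature_seq),
                           ("precursor", model.precursor_seq)):
            for off in range(len(ref) - len(read) + 1):
                window = ref[off:off + len(read)]
                mm = sum(1 for x, y in zip(read, window) if x != y)
                if mm <= max_mismatch:
                    end = off + len(read)
                    if space == "precursor" and end <= model.mature_end:
                        continue
                    hits.append((model.gene_id, space, off + 1, end, mm))
    if not hits:
        return []
    best = min(h[4] for h in hits)
    return sorted(h for h in hits if h[4] == best)


class TestCollapse:
    def test_fastq_counts_per_sample(self, tmp_path):
        fq = tmp_path / "s1.fastq"
        fq.write_text("".join(f"@r{i}\nACGTACGTACGTACG\n+\n{'I'*15}\n"
                              for i in range(3)))
        reads = collapse_reads({"S1": fq})
        assert len(reads) == 1
        assert reads[0].count_per_sample == {"S1": 3}

    def test_empty_file_empty_set(self, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        assert collapse_reads({"S1": fq}) == []

    def test_two_samples_share_one_record(self):
        reads = collapse_sequences({"S1": ["ACGT" * 5], "S2": ["ACGT" * 5] * 2})
        assert len(reads) == 1
        assert reads[0].count_per_sample == {"S1": 1, "S2": 2}

    def test_bad_record_names_position(self, tmp_path):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r1\nACGTXCGT\n+\nIIIIIIII\n")
        with pytest.raises(ValueError, match="#1"):
            collapse_reads({"S1": fq})


class TestFilter:
    def _read(self, seq):
        return CollapsedRead("r1", seq, {"S1": 1})

    def test_length_window(self):
        kept, report = filter_reads(
            [self._read("A" * 30), self._read("A" * 12), self._read("A" * 50)])
        assert len(kept) == 1 and len(kept[0].sequence) == 30
        assert report["too_short"] == 1 and report["too_long"] == 1

    def test_adapter_trimmed_then_kept(self):
        adapter = "TGGAATTCTCGGGTGCCAAGG"
        seq = "C" * 30 + adapter[:10]
        kept, report = filter_reads([self._read(seq)], adapter3=adapter)
        assert kept[0].sequence == "C" * 30
        assert report["adapter_trimmed"] == 1

    def test_short_adapter_overlap_not_trimmed(self):
        adapter = "TGGAATTCTCGGGTGCCAAGG"
        seq = "C" * 30 + adapter[:5]  # below the 8-nt overlap floor
        kept, _ = filter_reads([self._read(seq)], adapter3=adapter)
        assert kept[0].sequence == seq

    def test_n_filter(self):
        kept, report = filter_reads([self._read("N" + "A" * 29)])
        assert kept == [] and report["too_many_N"] == 1


class TestAlign:
    def test_prefix_read_single_hit(self, small_models):
        model = small_models[0]
        reads = [CollapsedRead("r1", model.mature_seq[:30], {"S1": 5})]
        alns, unaligned = align_to_trna(reads, [model])
        assert unaligned == []
        # the precursor placement is suppressed: one mature hit, weight 1
        assert len(alns) == 1
        a = alns[0]
        assert (a.space, a.start, a.end, a.weight) == ("mature", 1, 30, 1.0)

    def test_multimapper_weights_split(self, small_models):
        m = small_models[0]
        reads = [CollapsedRead("r1", m.mature_seq[:30], {"S1": 4})]
        alns, _ = align_to_trna(reads, [m, m.__class__(**{**m.__dict__,
                                                          "gene_id": "twin"})])
        assert len(alns) == 2
        assert all(a.weight == 0.5 for a in alns)

    def test_mismatch_respects_threshold(self, small_models):
        m = small_models[0]
        seq = "G" + m.mature_seq[1:30] if m.mature_seq[0] != "G" \
            else "C" + m.mature_seq[1:30]
        reads = [CollapsedRead("r1", seq, {"S1": 1})]
        alns0, unaligned0 = align_to_trna(reads, [m], max_mismatch=0)
        assert alns0 == [] and unaligned0 == ["r1"]
        alns1, _ = align_to_trna(reads, [m], max_mismatch=1)
        assert alns1 and alns1[0].mismatches == 1

    def test_trailer_read_is_precursor_space(self, small_models):
        m = small_models[0]
        reads = [CollapsedRead("r1", m.precursor_seq[76:92], {"S1": 1})]
        alns, _ = align_to_trna(reads, [m])
        spaces = {a.space for a in alns}
        assert "precursor" in spaces
        pre = [a for a in alns if a.space == "precursor"][0]
        assert pre.start == 77 and pre.end == 92

    @pytest.mark.parametrize("max_mismatch", [0, 1])
    def test_matches_brute_force_oracle(self, small_models, max_mismatch):
        rng = np.random.default_rng(7)
        for _ in range(60):
            model = small_models[rng.integers(len(small_models))]
            source = model.precursor_seq
            length = int(rng.integers(15, 46))
            start = int(rng.integers(0, len(source) - length + 1))
            seq = list(source[start:start + length])
            if rng.random() < 0.3:  # sprinkle a substitution
                i = int(rng.integers(length))
                seq[i] = "ACGT"[(("ACGT".index(seq[i])) + 1) % 4]
            read = CollapsedRead("r1", "".join(seq), {"S1": 1})
            alns, _ = align_to_trna([read], small_models, max_mismatch)
            got = sorted((a.gene_id, a.space, a.start, a.end, a.mismatches)
                         for a in alns)
            assert got == brute_force_placements(read.sequence, small_models,
                                                 max_mismatch)

    def test_count_conservation(self, small_models):
        rng = np.random.default_rng(8)
        seqs = []
        for _ in range(50):
            m = small_models[rng.integers(len(small_models))]
            s = int(rng.integers(0, 40))
            seqs.append(m.mature_seq[s:s + 20])
        reads = collapse_sequences({"S1": seqs})
        alns, unaligned = align_to_trna(reads, small_models)
        assert unaligned == []
        total_in = sum(r.total_count for r in reads)
        total_out = sum(a.weight * next(r for r in reads
                                        if r.read_id == a.read_id).total_count
                        for a in alns)
        assert total_out == pytest.approx(total_in)
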