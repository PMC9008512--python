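"""lncRNA cascade, ORF calling, small-RNA catalogue, feature summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernakit import txclass
from cernakit._errors import ValidationError
from cernakit.containers import TranscriptRecord

from _oracles import longest_orf_oracle


def _rec(id, class_code, length, chrom="chr1", start=1000):
    return TranscriptRecord(id=id, chrom=chrom, strand="+", start=start,
                            end=start + length - 1, class_code=class_code,
                            sequence="A" * length)


class TestCandidateFilter:
    @pytest.mark.parametrize("code,length,kept", [
        ("u", 350, True),       # intergenic, long enough
        ("=", 350, False),      # reference match is never a candidate
        ("x", 200, False),      # boundary: strictly > 200
        ("x", 201, True),
        ("i", 250, True),
        ("o", 250, True),
        ("j", 250, False),
    ])
    def test_class_code_and_length_rules(self, code, length, kept):
        out = txclass.filter_lncrna_candidates([_rec("t", code, length)])
        assert (len(out) == 1) is kept

    def test_order_preserved_and_pure_filter(self):
        recs = [_rec(f"t{i}", c, 300)
                for i, c in enumerate("u=xio")]
        out = txclass.filter_lncrna_candidates(recs)
        assert [t.id for t in out] == ["t0", "t2", "t3", "t4"]
        assert set(t.id for t in out) <= {t.id for t in recs}

    def test_missing_class_code_lists_ids(self):
        bad = TranscriptRecord(id="noclass", chrom="c", strand="+",
                               start=1, end=300)
        with pytest.raises(ValidationError, match="noclass"):
            txclass.filter_lncrna_candidates([bad])


class TestCodingPotential:
    def test_long_orf_is_coding(self):
        seq = "GCA" * 100 + "ATG" + "GCT" * 150 + "TAA" + "GCA" * 100
        res = txclass.coding_potential(seq)
        assert res.longest_orf_aa == 151 and res.label == "coding"

    def test_no_start_codon(self):
        res = txclass.coding_potential("CCC" * 100)
        assert res.longest_orf_aa == 0
        assert res.orf_coverage == 0.0
        assert res.label == "non-coding"

    def test_tiny_orf_in_long_context(self):
        seq = "C" * 117 + "ATGAAATAA" + "C" * 114
        assert len(seq) == 240
        res = txclass.coding_potential(seq)
        assert res.longest_orf_aa == 2
        assert res.orf_coverage == pytest.approx(9 / 240)
        assert res.label == "non-coding"

    def test_coverage_rule_alone_triggers_coding(self):
        # 60-aa ORF below min_orf_aa but covering most of the transcript
        seq = "ATG" + "GCT" * 60 + "TAA" + "CC"
        res = txclass.coding_potential(seq)
        assert res.longest_orf_aa == 61 < 100
        assert res.orf_coverage > 0.5
        assert res.label == "coding"

    def test_empty_sequence(self):
        with pytest.raises(ValidationError):
            txclass.coding_potential("")

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=200))
    def test_longest_orf_matches_enumeration_oracle(self, seq):
        res = txclass.coding_potential(seq)
        nt = longest_orf_oracle(seq)
        assert res.longest_orf_aa == max(0, nt // 3 - 1)


class TestClassifyTranscripts:
    def test_generator_records_round_trip(self, small_ds):
        out = txclass.classify_transcripts(small_ds.annotation)
        got = {t.id for t in out if t.biotype == "lncRNA"}
        want = {t.id for t in small_ds.annotation if t.biotype == "lncRNA"}
        assert got == want
        mrnas = {t.id for t in small_ds.annotation if t.biotype == "mRNA"}
        assert all(t.biotype == "other" for t in out if t.id in mrnas)

    def test_no_record_dropped(self, small_ds):
        out = txclass.classify_transcripts(small_ds.annotation)
        assert {t.id for t in out} == {t.id for t in small_ds.annotation}
        assert all(t.biotype in ("lncRNA", "other") for t in out)

    def test_empty_input(self):
        assert txclass.classify_transcripts([]) == []

    def test_raising_orf_threshold_grows_lncrna_set(self, small_ds):
        strict = {t.id for t in txclass.classify_transcripts(
            small_ds.annotation, min_orf_aa=50) if t.biotype == "lncRNA"}
        loose = {t.id for t in txclass.classify_transcripts(
            small_ds.annotation, min_orf_aa=200) if t.biotype == "lncRNA"}
        assert strict <= loose


class TestSmallRNACatalog:
    MATURE = {"mirA": "ACGTACGTACGTACGTACGTA", "mirB": "TTTTACGTACGTACGTACGTA"}

    def test_short_reads_discarded(self):
        out = txclass.catalog_small_rna(["ACGTACGTACGTACGTA"], self.MATURE)
        assert out == []   # 17 nt

    def test_identity_match(self):
        out = txclass.catalog_small_rna([self.MATURE["mirA"]], self.MATURE)
        assert out[0].status == "conserved"
        assert out[0].matched_mature_id == "mirA"
        assert out[0].mismatches == 0

    def test_distance_two_is_unassigned(self):
        read = "GGGTACGTACGTACGTACGTA"   # 2 mismatches vs mirA, 3 vs mirB
        out = txclass.catalog_small_rna([read], self.MATURE)
        assert out[0].status == "unassigned"
        assert out[0].matched_mature_id is None

    def test_tie_breaks_to_smallest_id(self):
        mature = {"b": "AAAAAAAAAAAAAAAAAA", "a": "AAAAAAAAAAAAAAAAAA"}
        out = txclass.catalog_small_rna(["AAAAAAAAAAAAAAAAAA"], mature)
        assert out[0].matched_mature_id == "a"

    def test_agrees_with_all_pairs_hamming_oracle(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        mature = {f"m{i:02d}": "".join(rng.choice(bases, rng.integers(18, 25)))
                  for i in range(20)}
        reads = ["".join(rng.choice(bases, rng.integers(15, 25)))
                 for _ in range(80)]
        reads += [list(mature.values())[i][:18] for i in range(10)]
        reads += [m for m in list(mature.values())[:10]]
        out = txclass.catalog_small_rna(reads, mature)
        kept = [r for r in reads if len(r) >= 18]
        assert len(out) == len(kept)
        for rec in out:
            best = None
            for mid in sorted(mature):
                m = mature[mid]
                if len(m) != rec.length:
                    continue
                d = sum(a != b for a, b in zip(rec.sequence, m))
                if d <= 1 and (best is None or d < best[0]):
                    best = (d, mid)
            if best is None:
                assert rec.status == "unassigned"
            else:
                assert (rec.mismatches, rec.matched_mature_id) == best

    def test_raising_min_len_never_grows_conserved_set(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        reads = ["".join(rng.choice(bases, rng.integers(16, 25)))
                 for _ in range(50)] + list(self.MATURE.values())
        conserved = {}
        for min_len in (18, 20, 22):
            out = txclass.catalog_small_rna(reads, self.MATURE, min_len)
            conserved[min_len] = {r.sequence for r in out
                                  if r.status == "conserved"}
        assert conserved[22] <= conserved[20] <= conserved[18]

    def test_empty_mature_and_bad_characters(self):
        with pytest.raises(ValidationError):
            txclass.catalog_small_rna(["ACGT" * 5], {})
        with pytest.raises(ValidationError):
            txclass.catalog_small_rna(["ACGTXCGTACGTACGTACGT"], self.MATURE)


class TestSummarizeFeatures:
    def _group(self, seqs, prefix):
        return [TranscriptRecord(id=f"{prefix}{i}", chrom="c", strand="+",
                                 start=1, end=len(s), class_code="u",
                                 sequence=s)
                for i, s in enumerate(seqs)]

    def test_gc_definition(self):
        assert txclass.gc_content("GGCC") == 1.0
        assert txclass.gc_content("AATT") == 0.0

    def test_identical_groups_give_null_t(self):
        seqs = ["ACGTACGTAA", "GGCCAATTGG", "ACACACACAC"]
        s = txclass.summarize_features(self._group(seqs, "l"),
                                       self._group(seqs, "m"))
        assert s["gc_t"] == pytest.approx(0.0, abs=1e-12)
        assert s["gc_p"] == pytest.approx(1.0)

    def test_separated_gc_distributions_reach_reported_precision(self):
        """Welch t on N(0.40, 0.02) vs N(0.50, 0.02), n=500 each, drives p
        below 2.22e-16; a label-permutation test agrees (no permutation
        statistic reaches the observed difference)."""
        rng = np.random.default_rng(5)
        gc_l = np.clip(rng.normal(0.40, 0.02, 500), 0, 1)
        gc_m = np.clip(rng.normal(0.50, 0.02, 500), 0, 1)

        def seqs(gcs, n=1000):
            return [("G" * round(g * n)).ljust(n, "A") for g in gcs]

        s = txclass.summarize_features(self._group(seqs(gc_l), "l"),
                                       self._group(seqs(gc_m), "m"))
        assert s["gc_p"] < 2.22e-16
        # permutation cross-check on the mean difference
        pooled = np.concatenate([gc_l, gc_m])
        obs = abs(gc_m.mean() - gc_l.mean())
        n_perm, exceed = 20_000, 0
        for chunk in range(20):
            idx = np.argsort(rng.random((n_perm // 20, 1000)), axis=1)
            perm = pooled[idx]
            diffs = np.abs(perm[:, 500:].mean(1) - perm[:, :500].mean(1))
            exceed += int((diffs >= obs).sum())
        assert exceed == 0     # p below the permutation resolution

    def test_undefined_t_for_tiny_group(self):
        s = txclass.summarize_features(self._group(["ACGT"], "l"),
                                       self._group(["AAGG", "CCTT"], "m"))
        assert s["gc_t"] is None and s["gc_p"] is None
        assert s["n_lncrna"] == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            txclass.summarize_features([], self._group(["ACGT"], "m"))
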