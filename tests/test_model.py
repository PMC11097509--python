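"""Variant identity, normalization, knowledge-base lookup, and cohort I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncoyield.io import (
    read_cohort,
    read_knowledge_base,
    read_variant_table,
    write_cohort,
    write_knowledge_base,
    write_variant_table,
)
from oncoyield.model import (
    FormatError,
    KnowledgeBase,
    VariantCall,
    VariantKey,
    infer_variant_class,
    normalize_variant,
)


def apply_variant(seq: str, key: VariantKey) -> str:
    """Brute-force edit of a 1-based reference sequence — the oracle
    that two representations denote the same genomic change."""
    i = key.pos - 1
    assert seq[i:i + len(key.ref)] == key.ref
    return seq[:i] + key.alt + seq[i + len(key.ref):]


class TestVariantKey:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(FormatError):
            VariantKey("chr7", 100, "A", "A")

    @pytest.mark.parametrize("ref,alt", [("", "A"), ("A", ""), ("AN", "A"), ("a", "T")])
    def test_non_dna_rejected(self, ref, alt):
        with pytest.raises(FormatError):
            VariantKey("chr7", 100, ref, alt)

    def test_position_must_be_positive(self):
        with pytest.raises(FormatError):
            VariantKey("chr7", 0, "A", "T")


class TestNormalization:
    def test_shared_suffix_trimmed(self):
        assert normalize_variant(VariantKey("chr7", 100, "CTT", "CT")) == VariantKey(
            "chr7", 100, "CT", "C"
        )

    def test_minimal_snv_unchanged(self):
        key = VariantKey("chr7", 100, "A", "T")
        assert normalize_variant(key) == key

    def test_shared_prefix_trimmed_with_anchor(self):
        # GCA>GC: suffix-trim gives GCA>GC? no — trim A? GCA vs GC share no suffix;
        # prefix GC shared, anchor kept
        assert normalize_variant(VariantKey("chr1", 10, "GCC", "GTC")) == VariantKey(
            "chr1", 11, "C", "T"
        )

    def test_left_alignment_through_repeat(self):
        # deletion of one A inside an A-run shifts to the run's left edge
        ref = {"chr1": "GGGAAAAAT"}
        raw = VariantKey("chr1", 7, "AA", "A")
        norm = normalize_variant(raw, ref)
        assert norm == VariantKey("chr1", 3, "GA", "G")
        assert apply_variant(ref["chr1"], raw) == apply_variant(ref["chr1"], norm)

    @settings(derandomize=True, max_examples=200)
    @given(data=st.data())
    def test_normalization_preserves_change_and_is_idempotent(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=12, max_size=30))
        pos = data.draw(st.integers(2, len(seq) - 10))
        ref_len = data.draw(st.integers(1, 6))
        ref = seq[pos - 1:pos - 1 + ref_len]
        alt = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=6))
        if ref == alt:
            alt = alt + "A" if not ref.endswith("A") or len(alt) >= 6 else alt + "C"
        if ref == alt:
            return
        raw = VariantKey("c", pos, ref, alt)
        norm = normalize_variant(raw, {"c": seq})
        assert apply_variant(seq, raw) == apply_variant(seq, norm)
        assert normalize_variant(norm, {"c": seq}) == norm


class TestVariantCall:
    def _call(self, **kw):
        base = dict(key=VariantKey("chr1", 5, "A", "T"), gene="G", vaf=0.1, depth=100)
        base.update(kw)
        return VariantCall(**base)

    def test_vaf_bounds(self):
        with pytest.raises(FormatError):
            self._call(vaf=1.2)

    def test_class_inferred_and_checked(self):
        assert self._call().variant_class == "SNV"
        with pytest.raises(FormatError):
            self._call(variant_class="InDel")

    def test_db_counts_keys_enforced(self):
        with pytest.raises(FormatError):
            self._call(db_counts={"a": 1})

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "T", "SNV"), ("AC", "TT", "MNV"), ("AC", "A", "InDel"), ("A", "ACC", "InDel")],
    )
    def test_class_inference(self, ref, alt, expected):
        assert infer_variant_class(ref, alt) == expected


class TestKnowledgeBase:
    def test_most_specific_descriptor_wins(self):
        kb = KnowledgeBase()
        kb.add("BRAF", "p.V600", "3B", "IIC")
        kb.add("BRAF", "p.V600E", "1", "IA")
        assert kb.lookup("BRAF", "p.V600E").oncokb_level == "1"
        assert kb.lookup("BRAF", "p.V600K").oncokb_level == "3B"  # positional class

    def test_unlisted_gene_not_classified(self):
        kb = KnowledgeBase()
        entry = kb.lookup("TP53", "p.R175H")
        assert (entry.oncokb_level, entry.amp_tier) == ("none", "none")

    def test_duplicate_rejected(self):
        kb = KnowledgeBase()
        kb.add("BRAF", "p.V600E", "1", "IA")
        with pytest.raises(FormatError):
            kb.add("BRAF", "p.V600E", "1", "IA")

    def test_unknown_tokens_rejected(self):
        kb = KnowledgeBase()
        with pytest.raises(FormatError):
            kb.add("BRAF", "p.V600E", "5", "IA")

    def test_kb_roundtrip(self, kb, tmp_path):
        path = tmp_path / "kb.tsv"
        write_knowledge_base(kb, path)
        again = read_knowledge_base(path)
        assert again.entries == kb.entries

    def test_fixture_kb_rows(self, kb):
        assert kb.lookup("BRAF", "p.V600E") == kb.lookup("ERBB2", "amplification")
        assert kb.lookup("BRAF", "p.V600E").oncokb_level == "1"
        assert kb.lookup("ERBB2", "amplification").amp_tier == "IA"


class TestVariantTableIO:
    def test_fixture_table_contains_reported_braf(self, cohort, tmp_path):
        tissue = cohort.get("GE01").tissue
        path = tmp_path / "ge01.tsv"
        write_variant_table(tissue.calls, path)
        calls = read_variant_table(path)
        brafs = [c for c in calls if c.gene == "BRAF"]
        assert len(brafs) == 1
        assert brafs[0].hgvs_p == "p.V600E"
        assert brafs[0].vaf == pytest.approx(0.514)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_variant_table([], path)
        assert read_variant_table(path) == []

    def test_out_of_range_vaf_is_row_addressed(self, cohort, tmp_path):
        path = tmp_path / "bad.tsv"
        write_variant_table(cohort.get("GE01").tissue.calls, path)
        text = path.read_text().replace("0.514", "1.2")
        path.write_text(text)
        with pytest.raises(FormatError, match="row 2"):
            read_variant_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("sample_id\tchrom\tpos\nX\tchr1\t5\n")
        with pytest.raises(FormatError, match="missing mandatory column"):
            read_variant_table(path)

    def test_minimal_vcf_reader(self, tmp_path):
        vcf = tmp_path / "s.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=VAF,Number=1,Type=Float,Description="VAF">\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##INFO=<ID=HGVSP,Number=1,Type=String,Description="protein">\n'
            "##contig=<ID=chr7>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr7\t140453136\t.\tA\tT\t.\tPASS\tVAF=0.514;DP=800;GENE=BRAF;HGVSP=p.V600E\n"
        )
        calls = read_variant_table(vcf)
        assert len(calls) == 1
        assert calls[0].key == VariantKey("chr7", 140453136, "A", "T")
        assert calls[0].vaf == pytest.approx(0.514)
        assert calls[0].gene == "BRAF"


def test_cohort_roundtrip(cohort, tmp_path):
    """Write-then-read of the full cohort reproduces identical records."""
    write_cohort(cohort, tmp_path / "cohort")
    again = read_cohort(tmp_path / "cohort")
    assert again == cohort
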