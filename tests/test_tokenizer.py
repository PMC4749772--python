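"""Per-step behaviour and invariants of the rule tokenizer."""

import pytest
from hypothesis import given, settings, strategies as st

from chemseg import (
    Lexicon,
    LexiconSet,
    TokenizerConfig,
    tokenize,
    tokenize_case_change_baseline,
    tokenize_whitespace_baseline,
)
from chemseg.tokenizer import (
    rule1_merge_numeric,
    rule2_merge_containers,
    rule3_merge_case,
    rule4_merge_known,
    rule5_split_plural,
    split_affixes,
    split_delimiters,
    split_whitespace,
)

from conftest import make_lexicon


def seq_of(*surfaces):
    """Build a TokenSequence of source-contiguous tokens from surfaces."""
    from chemseg.tokenizer import Token, TokenSequence

    text = "".join(surfaces)
    out, pos = [], 0
    for s in surfaces:
        out.append(Token(s, pos, pos + len(s), "d"))
        pos += len(s)
    return TokenSequence("d", text, tuple(out))


class TestSplitWhitespace:
    def test_splits_at_spaces(self):
        assert split_whitespace("tetrazolium bromide").surfaces() == [
            "tetrazolium",
            "bromide",
        ]

    def test_empty_input(self):
        assert len(split_whitespace("")) == 0

    def test_offsets_exact(self):
        seq = split_whitespace("  a  ")
        assert len(seq) == 1
        assert (seq[0].surface, seq[0].start, seq[0].end) == ("a", 2, 3)


class TestSplitAffixes:
    @pytest.mark.parametrize(
        "word,expected",
        [
            ("hyperinsulinaemia", ["hyper", "insulinaemia"]),
            ("Antiherpetic", ["Anti", "herpetic"]),
            ("water", ["water"]),
        ],
    )
    def test_examples(self, builtin_lexica, word, expected):
        seq = split_affixes(split_whitespace(word), builtin_lexica.affixes)
        assert seq.surfaces() == expected

    def test_offsets_partition_original(self, builtin_lexica):
        seq = split_affixes(split_whitespace("x hyperinsulinaemia"), builtin_lexica.affixes)
        hyper, rest = seq.tokens[1], seq.tokens[2]
        assert hyper.end == rest.start and (hyper.start, rest.end) == (2, 19)


class TestSplitDelimiters:
    def test_entity_lexicon_gate(self, cfg):
        ent = make_lexicon(["d-alpha-tocopheryl-co-poly"])
        seq = split_delimiters(split_whitespace("d-alpha-tocopheryl-co-poly"), ent, cfg)
        assert seq.surfaces() == ["d-alpha-tocopheryl-co-poly"]

    def test_case_fused_header_detaches_capital(self, cfg, empty_lexica):
        seq = split_delimiters(
            split_whitespace("CONCLUSIONGlucose"), empty_lexica.entities, cfg
        )
        assert seq.surfaces() == ["CONCLUSION", "G", "lucose"]

    def test_punctuation_each_its_own_token(self, cfg, empty_lexica):
        seq = split_delimiters(split_whitespace("125,12,12"), empty_lexica.entities, cfg)
        assert seq.surfaces() == ["125", ",", "12", ",", "12"]

    def test_no_delimiter_no_split(self, cfg, empty_lexica):
        seq = split_delimiters(split_whitespace("abc"), empty_lexica.entities, cfg)
        assert seq.surfaces() == ["abc"]

    def test_digit_runs_kept_whole(self, cfg, empty_lexica):
        seq = split_delimiters(split_whitespace("ab123cd"), empty_lexica.entities, cfg)
        assert seq.surfaces() == ["ab", "123", "cd"]

    def test_greek_letters_split_singly(self, cfg, empty_lexica):
        seq = split_delimiters(split_whitespace("αβx"), empty_lexica.entities, cfg)
        assert seq.surfaces() == ["α", "β", "x"]

    def test_gate_respects_case_policy(self, cfg):
        ent = make_lexicon(["TPGS"], policy="sensitive")
        assert split_delimiters(split_whitespace("TPGS"), ent, cfg).surfaces() == ["TPGS"]
        # lowercased form is not gated and passes through the case splitter
        assert split_delimiters(split_whitespace("TpGs"), ent, cfg).surfaces() != ["TpGs"]


class TestMergeRules:
    def test_rule1_merges_numeric_chain(self, cfg):
        seq = seq_of("125", ",", "12", ",", "12")
        assert rule1_merge_numeric(seq, cfg).surfaces() == ["125,12,12"]

    def test_rule1_merges_dash_pair(self, cfg):
        assert rule1_merge_numeric(seq_of("1", "-", "3"), cfg).surfaces() == ["1-3"]

    def test_rule1_blocked_by_non_numeric(self, cfg):
        seq = seq_of("12", ",", "ab")
        assert rule1_merge_numeric(seq, cfg).surfaces() == ["12", ",", "ab"]

    def test_rule1_requires_contiguity(self, cfg):
        seq = split_whitespace("1 - 3")  # gaps between tokens
        assert rule1_merge_numeric(seq, cfg).surfaces() == ["1", "-", "3"]

    def test_rule2_wraps_balanced_containers(self, cfg):
        assert rule2_merge_containers(seq_of("(", "1-3", ")"), cfg).surfaces() == ["(1-3)"]
        assert rule2_merge_containers(seq_of("[", "42", "]"), cfg).surfaces() == ["[42]"]

    def test_rule2_rejects_mismatched_pair(self, cfg):
        seq = seq_of("(", "1-3", "]")
        assert rule2_merge_containers(seq, cfg).surfaces() == ["(", "1-3", "]"]

    def test_rule2_ignores_alphabetic_content(self, cfg):
        seq = seq_of("(", "abc", ")")
        assert rule2_merge_containers(seq, cfg).surfaces() == ["(", "abc", ")"]

    def test_rule3_rejoins_single_capital(self):
        assert rule3_merge_case(seq_of("C", "ommon")).surfaces() == ["Common"]

    def test_rule3_needs_single_letter_left(self):
        assert rule3_merge_case(seq_of("AB", "cd")).surfaces() == ["AB", "cd"]

    def test_rule3_left_to_right_pairs(self):
        seq = seq_of("C", "ommon", "S", "ense")
        assert rule3_merge_case(seq).surfaces() == ["Common", "Sense"]

    def test_rule4_merges_known_name(self, cfg):
        chem = make_lexicon(["NaCL"], policy="insensitive")
        assert rule4_merge_known(seq_of("Na", "CL"), chem, cfg).surfaces() == ["NaCL"]

    def test_rule4_without_lexicon_no_merge(self, cfg):
        chem = make_lexicon([], policy="insensitive")
        assert rule4_merge_known(seq_of("Na", "CL"), chem, cfg).surfaces() == ["Na", "CL"]

    def test_rule4_window_of_three(self, cfg):
        chem = make_lexicon(["H2O"], policy="insensitive")
        assert rule4_merge_known(seq_of("H", "2", "O"), chem, cfg).surfaces() == ["H2O"]

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6, 7])
    def test_rule4_window_bound(self, cfg, k):
        """Known names spanning 2-5 contiguous sub-tokens merge; 6+ never do."""
        parts = [c for c in "abcdefg"[:k]]
        chem = make_lexicon(["".join(parts)], policy="insensitive")
        merged = rule4_merge_known(seq_of(*parts), chem, cfg).surfaces()
        if k <= 5:
            assert merged == ["".join(parts)]
        else:
            assert merged == parts

    def test_rule5_splits_gated_plural(self, cfg, builtin_lexica):
        seq = seq_of("salicylates")
        out = rule5_split_plural(
            seq, builtin_lexica.entities, builtin_lexica.chem_names, cfg
        )
        assert out.surfaces() == ["salicylate", "s"]

    def test_rule5_acids_example(self, cfg, builtin_lexica):
        out = rule5_split_plural(
            seq_of("Acids"), builtin_lexica.entities, builtin_lexica.chem_names, cfg
        )
        assert out.surfaces() == ["Acid", "s"]

    def test_rule5_gate_blocks_ordinary_words(self, cfg, builtin_lexica):
        out = rule5_split_plural(
            seq_of("is"), builtin_lexica.entities, builtin_lexica.chem_names, cfg
        )
        assert out.surfaces() == ["is"]


class TestFullTokenizer:
    def test_mtt_sentence_keeps_entity_parts_intact(self, builtin_lexica):
        text = "reduce 3-(4,5-dimethylthiazol-2-yl)-2,5-diphenyl tetrazolium bromide (MTT)"
        surfaces = tokenize(text, lexica=builtin_lexica).surfaces()
        for part in ("3-(4,5-dimethylthiazol-2-yl)-2,5-diphenyl", "tetrazolium", "bromide"):
            assert part in surfaces

    def test_empty_input(self, builtin_lexica):
        assert len(tokenize("", lexica=builtin_lexica)) == 0

    def test_composed_rule_examples(self, builtin_lexica):
        surfaces = tokenize("(1-3) Common Acids", lexica=builtin_lexica).surfaces()
        assert surfaces == ["(1-3)", "Common", "Acid", "s"]

    def test_determinism(self, builtin_lexica):
        text = "Antiherpetic NaCL (1-3) CONCLUSIONGlucose salicylates"
        a = tokenize(text, "d", builtin_lexica)
        b = tokenize(text, "d", builtin_lexica)
        assert a == b

    def test_rule_toggles_disable_merges(self, builtin_lexica):
        cfg_off = TokenizerConfig(rule1=False, rule2=False, rule3=False,
                                  rule4=False, rule5=False)
        assert tokenize("(1-3)", lexica=builtin_lexica, cfg=cfg_off).surfaces() == [
            "(", "1", "-", "3", ")"
        ]

    def test_whitespace_baseline_alias(self):
        seq = tokenize_whitespace_baseline("tetrazolium bromide", "d")
        assert seq.surfaces() == ["tetrazolium", "bromide"]

    def test_case_change_baseline_produces_lucose(self):
        seq = tokenize_case_change_baseline("CONCLUSIONGlucose")
        assert seq.surfaces() == ["CONCLUSIONG", "lucose"]

    def test_monotone_gating(self, cfg):
        """Adding a token's surface to the entity lexicon never increases
        the number of tokens produced from that exact text."""
        text = "d-alpha-tocopheryl-co-poly"
        without = tokenize(text, lexica=LexiconSet.empty(), cfg=cfg)
        lex = LexiconSet.empty()
        gated = LexiconSet(lex.affixes, lex.entities.add(text), lex.chem_names)
        with_gate = tokenize(text, lexica=gated, cfg=cfg)
        assert len(with_gate) <= len(without)

    @given(st.text(max_size=80))
    @settings(derandomize=True, max_examples=300)
    def test_round_trip_reconstruction(self, text):
        seq = tokenize(text, "d", LexiconSet.builtin())
        assert seq.reconstruct() == text

    @given(st.text(alphabet="aA1(). -", max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_no_merge_crosses_whitespace(self, text):
        seq = tokenize(text, "d", LexiconSet.builtin())
        for t in seq:
            assert not any(c.isspace() for c in seq.source_text[t.start:t.end])

    @given(st.text(max_size=60))
    @settings(derandomize=True, max_examples=200)
    def test_offsets_strictly_ordered(self, text):
        seq = tokenize(text, "d", LexiconSet.builtin())
        for a, b in zip(seq.tokens, seq.tokens[1:]):
            assert a.end <= b.start
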