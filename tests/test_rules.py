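import pytest

from excelsafe.rules import (
    RuleConfig,
    decide_escape,
    looks_like_date_or_time,
    match_date_time,
    number_needs_escape,
    parse_number,
)


class TestParseNumber:
    def test_riken_style(self):
        parts = parse_number("2610100E13")
        assert parts is not None
        assert parts.int_digits == "2610100"
        assert parts.exp_digits == "13"
        assert parts.mantissa_int_len == 7

    def test_single_digit_mantissa(self):
        parts = parse_number("2E4")
        assert parts is not None and parts.mantissa_int_len == 1

    @pytest.mark.parametrize(
        "text",
        ["1 A", "", "1,234", "11A9", "1/3", "abc", "+", "-", "1..2", "1e", "e4", "--2"],
    )
    def test_not_a_number(self, text):
        assert parse_number(text) is None

    @pytest.mark.parametrize(
        "text",
        ["0", "-1", "+1.5", "1.", ".5", "1e5", "+1E+05", "-0.25e-3", "00123456"],
    )
    def test_reassembly_is_lossless(self, text):
        parts = parse_number(text)
        assert parts is not None
        assert parts.reassemble() == text


class TestNumberBranch:
    def _decide(self, text, **flags):
        parts = parse_number(text)
        assert parts is not None
        return number_needs_escape(parts, RuleConfig(**flags))

    def test_leading_zero(self):
        assert self._decide("00123456").rule == "leading_zero"

    def test_sci_mantissa(self):
        assert self._decide("11E9").rule == "sci_mantissa"

    def test_single_digit_mantissa_passes(self):
        assert not self._decide("3e46").escape

    def test_long_integer(self):
        decision = self._decide("52070900777217100409406332354780")
        assert decision.rule == "long_integer"

    def test_long_integer_with_fraction(self):
        assert self._decide("123456789012.5").rule == "long_integer"

    def test_exponent_zeroes_do_not_trigger(self):
        # The leading-zero rule reads the integer mantissa portion only.
        assert not self._decide("1E05").escape

    def test_precedence_leading_zero_first(self):
        assert self._decide("0001e2").rule == "leading_zero"

    def test_flags_disable(self):
        assert not self._decide("00123456", escape_zeroes=False).escape
        assert not self._decide("11E9", escape_sci=False).escape
        assert not self._decide("1234567890123456789", escape_sci=False).escape


class TestDateTimeGrammar:
    @pytest.mark.parametrize(
        "text",
        ["SEPT7", "1/3", "MARCH1", "DEC1", "SEP15", "7-Sep", "Oct 31",
         "3/4/2017", "1-jan", "APR-1", "2017-09-07", "31/12"],
    )
    def test_date_like(self, text):
        assert looks_like_date_or_time(text) == "date_like"

    @pytest.mark.parametrize(
        "text",
        ["1 A", "12:30", "23:59", "2 P", "5A", "1:02:03", "9:05 am", "11 pm"],
    )
    def test_time_like(self, text):
        assert looks_like_date_or_time(text) == "time_like"

    @pytest.mark.parametrize(
        "text",
        ["SEPTIN7", "MARCHF8", "11A9", "SEPT", "13/45", "SEPT0", "24:00",
         "13 A", "0 A", "1B", "gene list", "SEPT 7 X"],
    )
    def test_none(self, text):
        assert looks_like_date_or_time(text) == "none"

    def test_rendering_details(self):
        m = match_date_time("SEPT7")
        assert (m.kind, m.month, m.day, m.month_abbr) == ("date_like", 9, 7, "Sep")
        m = match_date_time("2 P")
        assert (m.kind, m.hour, m.minute) == ("time_like", 14, 0)


class TestDecideEscape:
    def test_leading_plusminus(self):
        assert decide_escape("++ stain intensity").rule == "leading_plusminus"

    def test_pure_signs_pass(self):
        assert not decide_escape("++").escape

    def test_plain_symbol_passes(self):
        assert not decide_escape("TP53").escape

    def test_paranoid_escapes_text(self):
        assert decide_escape("TP53", RuleConfig(paranoid=True)).rule == "paranoid"

    def test_paranoid_skips_numbers(self):
        assert not decide_escape("123456", RuleConfig(paranoid=True)).escape

    def test_empty_passes(self):
        assert not decide_escape("").escape
        assert not decide_escape("", RuleConfig(paranoid=True)).escape

    def test_signed_numbers_are_numbers(self):
        assert not decide_escape("-1").escape
        assert not decide_escape("+1.5").escape

    def test_dates_flag_disables_both(self):
        off = RuleConfig(escape_dates=False)
        assert not decide_escape("SEPT7", off).escape
        assert not decide_escape("1 A", off).escape

    def test_precedence_in_text_branch(self):
        assert decide_escape("'=x").rule == "leading_quote"
        assert decide_escape("=+1 A").rule == "leading_equals"

    def test_number_date_exclusivity(self, vtable):
        # A field recognized as a number never reaches the date/time grammar.
        for row in vtable:
            if parse_number(row.text) is not None:
                assert decide_escape(row.text).rule not in ("date_like", "time_like")

    def test_validation_table_decisions(self, vtable):
        for row in vtable:
            config = RuleConfig(paranoid=(row.config == "paranoid"))
            decision = decide_escape(row.text, config)
            assert decision.rule == row.tag, row.text
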