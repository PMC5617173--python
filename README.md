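# excelsafe

Spreadsheet programs silently rewrite imported text: gene symbols become
dates (`SEPT7` → `7-Sep`), accessions with an embedded `E` become scientific
notation (`2610100E13` → `2.61E+19`), leading zeroes vanish (`00123456` →
`123456`), fields starting with `=` or `+`/`-` become formulas, and integers
longer than 15 digits lose their tail to floating-point precision
(`1234567890123456789` → `1234567890123450000`).

`excelsafe` protects tab-delimited files from this corruption by wrapping
every at-risk field as a formula-quoted string — `="SEPT7"` — which imports
as literal text. It also ships a conversion **oracle** that predicts exactly
what import would do to each field, so whole tables can be audited for
would-be damage.

## Command line

`escape` is the default subcommand; all three work as pipe filters
(stdin → stdout), with diagnostics on stderr:

```sh
excelsafe data.tsv escaped.tsv          # escape a file
excelsafe < data.tsv > escaped.tsv      # same, as a filter
excelsafe --paranoid data.tsv           # escape everything that is not a number
excelsafe --no-dates --no-sci --no-zeroes data.tsv   # disable rule classes
excelsafe --eol crlf data.tsv           # CRLF output line endings
excelsafe audit data.tsv report.tsv     # which fields would import corrupt?
excelsafe eol --to lf < mac.txt > unix.txt   # normalize CR / CRLF / LF
```

Escaping is idempotent: running an already-escaped file through again is a
byte-identical no-op (prior escaping is unwrapped and re-applied). CR-only
(classic Mac), CRLF, and LF inputs are all accepted.

## Library

```python
from excelsafe import process_text, predict_conversion, audit_table, RuleConfig

escaped, stats = process_text("SEPT7\t00123456\n")
# '="SEPT7"\t="00123456"\n'

predict_conversion("11E9")
# ConversionPrediction(kind='number', stored_text='11000000000', lossy=True)

audit_table([["SEPT7", "TP53"]]).corrupted
# 1
```

Modules:

| module | purpose |
|---|---|
| `excelsafe.textclean` | per-field cleanup (BOM, quotes, prior escaping, padding) to a fixpoint |
| `excelsafe.rules` | escape decisions: numeric hazards, leading `'`/`=`/sign runs, date/time grammar |
| `excelsafe.escaper` | stream a TSV through clean → decide → wrap |
| `excelsafe.oracle` | predict/audit import auto-conversion, incl. 15-digit precision loss |
| `excelsafe.eol` | CR / CRLF / LF terminator normalization |
| `excelsafe.fixtures` | bundled validation table and seeded synthetic gene tables |
| `excelsafe.cli` | `excelsafe` entry point |

Five strings — `2E4 2E6 2E12 3E2 3e46` — are predicted lossy by the oracle
but deliberately left unescaped: with a single digit before the `E` they are
indistinguishable from genuine scientific notation.

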