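#!/usr/bin/env python
"""Derive each emotion's exclusive AUs from the association table.

Prints the exclusive set Q_i for each basic emotion under the operative
union-form derivation (Q_i = S_i minus every AU used by any other emotion)
and contrasts it with the literal intersection form, which degenerates to
Q_i = S_i on this table and so distinguishes nothing. Writes both to TSV.
"""

from pathlib import Path

from aucoding import builtin_emotion_au_table, derive_exclusive_sets

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = builtin_emotion_au_table()
    union_form = derive_exclusive_sets(table)
    literal_form = derive_exclusive_sets(table, literal=True)
    lines = ["emotion\tassociation_set\texclusive_union_form\tliteral_form"]
    print("emotion      association AUs              exclusive AUs")
    for e in table.emotions:
        s = "+".join(map(str, sorted(table[e])))
        q = "+".join(map(str, sorted(union_form[e]))) or "-"
        ql = "+".join(map(str, sorted(literal_form[e]))) or "-"
        lines.append(f"{e.value}\t{s}\t{q}\t{ql}")
        print(f"{e.value:<12} {s:<28} {q}")
    degenerate = all(literal_form[e] == table[e] for e in table.emotions)
    print(f"\nliteral intersection form degenerates to Q_i = S_i: {degenerate}")
    out = RESULTS / "exclusive_sets.tsv"
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
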