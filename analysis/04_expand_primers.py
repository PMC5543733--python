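"""Expand the degenerate RT-PCR primer pair used for PLI-gamma cDNA cloning.

The forward primer carries one R (A/G), one M (A/C) and one W (A/T), so it
encodes 2 x 2 x 2 = 8 concrete oligos; the reverse carries a single R.
Writes results/primer_expansions.tsv.
"""

from pathlib import Path

import pandas as pd

from episcan.seq_io import DegeneratePrimer, expand_primer

RESULTS = Path(__file__).resolve().parents[1] / "results"

PRIMERS = [
    DegeneratePrimer(id="forward", bases="CRCTCATGTAMWTTTGTCACAA"),
    DegeneratePrimer(id="reverse", bases="TTATTCAGAAGGTGTARTTTTGG"),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for primer in PRIMERS:
        expansions = expand_primer(primer)
        print(f"{primer.id}: {primer.bases} -> degeneracy {primer.degeneracy}")
        for i, concrete in enumerate(expansions, start=1):
            rows.append({"primer_id": primer.id, "expansion": i, "sequence": concrete})
    pd.DataFrame(rows).to_csv(RESULTS / "primer_expansions.tsv", sep="\t", index=False)
    print(f"wrote {len(rows)} expansions to {RESULTS / 'primer_expansions.tsv'}")


if __name__ == "__main__":
    main()
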