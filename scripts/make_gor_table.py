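"""Regenerate the packaged synthetic GOR directional-information table.

The table is NOT a transcription of the original GOR I publication: it is a
synthetic parameterization generated deterministically from the packaged
secondary-structure propensities.  Each residue contributes, to each state,
information proportional to the log of its conformational propensity, damped
by a center-peaked kernel over neighbor offsets -8..+8:

    info(s, r, d) = round(100 * w(d) * ln(P_s(r))),   w(d) = 1 - |d| / 9

with P_H = P_alpha, P_E = P_beta, P_T = P_turn and the coil propensity
defined as the reciprocal geometric mean of the other three (so coil wins
where no structured state is favored).  Values are integers in centinats,
matching the granularity of published directional-information tables.

Run from the repository root:  python scripts/make_gor_table.py
"""

import math
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "src" / "episcan" / "data"

HEADER = """\
# name: gor-info-synthetic
# source: synthetic directional-information table generated from the packaged
# source: Chou-Fasman propensities (see scripts/make_gor_table.py); NOT a
# source: transcription of Garnier, Osguthorpe & Robson (1978)
# columns: state residue offset value  (value in centinats; offsets -8..+8)
"""


def main() -> None:
    pa, pb, pt = {}, {}, {}
    for line in (DATA / "chou_fasman.tsv").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        r = parts[0]
        pa[r], pb[r], pt[r] = map(float, parts[1:4])

    def log_propensity(state: str, r: str) -> float:
        if state == "H":
            return math.log(pa[r])
        if state == "E":
            return math.log(pb[r])
        if state == "T":
            return math.log(pt[r])
        # coil: reciprocal geometric mean of the structured propensities
        return -(math.log(pa[r]) + math.log(pb[r]) + math.log(pt[r])) / 3.0

    lines = [HEADER.rstrip()]
    for state in ("H", "E", "T", "C"):
        for r in sorted(pa):
            for d in range(-8, 9):
                w = 1.0 - abs(d) / 9.0
                v = round(100.0 * w * log_propensity(state, r))
                lines.append(f"{state}\t{r}\t{d}\t{v}")
    (DATA / "gor_info_synthetic.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote {DATA / 'gor_info_synthetic.tsv'} ({len(lines) - 1} entries)")


if __name__ == "__main__":
    main()
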