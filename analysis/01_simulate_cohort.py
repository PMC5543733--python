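"""Simulate the synthetic study cohort: 50 seeded 200-residue proteins, each
with one planted hydrophilic/turn-rich epitope-like segment (15-25 aa) and
one planted hydrophobic buried-helix segment (15 aa).

Writes results/cohort.fasta and results/cohort.truth.json.
"""

from pathlib import Path

from episcan.seq_io import write_fasta
from episcan.synthetic import default_protein_spec, generate_protein, write_ground_truth

RESULTS = Path(__file__).resolve().parents[1] / "results"
N = 50
BASE_SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    seqs, truth = [], {}
    for i in range(N):
        spec = default_protein_spec(BASE_SEED + i)
        seq, segments = generate_protein(spec)
        seqs.append(seq)
        truth[seq.id] = [
            {"kind": s.kind, "start": s.start, "end": s.end} for s in segments
        ]
    write_fasta(seqs, RESULTS / "cohort.fasta")
    write_ground_truth(truth, RESULTS / "cohort.truth.json")
    lengths = [t[0]["end"] - t[0]["start"] + 1 for t in truth.values()]
    print(f"wrote {N} sequences to {RESULTS / 'cohort.fasta'}")
    print(f"planted epitope lengths: min {min(lengths)}, max {max(lengths)}")


if __name__ == "__main__":
    main()
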