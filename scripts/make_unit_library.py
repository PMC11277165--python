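"""Regenerate the packaged structural-unit library.

The packaged library (src/coicoii/data/unit_library.synthetic.fasta) holds synthetic
exemplar sequences for the structural elements of the COI-COII intergenic
region; the annotator and the synthetic generator share it by default so the
test loop is closed. Users analyzing real data should supply their own
exemplar FASTA (ids TRNA_LEU, P, P0, P1, Q, COX2_STUB) instead.

Usage: python scripts/make_unit_library.py [--seed N] [--out PATH]
"""

import argparse
from pathlib import Path

from coicoii.sequence_io import SequenceRecord, write_fasta
from coicoii.simulate import PACKAGED_LIBRARY_SEED, make_unit_library


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=PACKAGED_LIBRARY_SEED)
    parser.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1]
        / "src/coicoii/data/unit_library.synthetic.fasta",
    )
    args = parser.parse_args()
    library = make_unit_library(args.seed)
    records = [
        SequenceRecord(sample_id=label, bases=seq, source="reference")
        for label, seq in library.units.items()
    ]
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_fasta(records, args.out)
    print(f"wrote {len(records)} units to {args.out}")


if __name__ == "__main__":
    main()
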