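"""Re-pin SHA-256 checksums of the packaged parameter tables.

Run after any deliberate edit of a data table:
    python scripts/pin_checksums.py
"""

import hashlib
import json
from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "episcan" / "data"


def main() -> None:
    pins = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(DATA.glob("*.tsv"))
    }
    (DATA / "checksums.json").write_text(json.dumps(pins, indent=2) + "\n")
    print(f"pinned {len(pins)} files in {DATA / 'checksums.json'}")


if __name__ == "__main__":
    main()
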