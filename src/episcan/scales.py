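"""Residue propensity scales: container, plain-text format, packaged registry.

Scale files are two-column TSV (residue, value) with ``#``-prefixed header
lines carrying ``name``, ``source`` (citation) and ``combine_mode`` metadata.
Every scale must be total over the 20 canonical residues.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ChecksumError, ScaleError
from .seq_io import AMINO_ACIDS

COMBINE_MODES = ("arithmetic-mean", "product-ratio", "weighted-mean")


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue numeric scale with its windowing semantics."""

    name: str
    values: dict[str, float]
    source: str = ""
    combine_mode: str = "arithmetic-mean"

    def __post_init__(self) -> None:
        if self.combine_mode not in COMBINE_MODES:
            raise ScaleError(f"scale {self.name!r}: unknown combine_mode {self.combine_mode!r}")
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        if missing:
            raise ScaleError(f"scale {self.name!r}: missing residues {missing}")
        extra = sorted(set(self.values) - set(AMINO_ACIDS))
        if extra:
            raise ScaleError(f"scale {self.name!r}: non-canonical residues {extra}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def negated(self, name: str | None = None) -> "ResidueScale":
        """Sign-inverted copy (e.g. hydropathy -> hydrophilicity orientation)."""
        return ResidueScale(
            name=name or f"neg-{self.name}",
            values={r: -v for r, v in self.values.items()},
            source=self.source,
            combine_mode=self.combine_mode,
        )


def parse_scale(text: str, path_hint: str = "<string>") -> ResidueScale:
    meta: dict[str, str] = {}
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip().lower()
                if key in ("name", "source", "combine_mode"):
                    if key == "source" and key in meta:
                        meta[key] += " " + val.strip()
                    else:
                        meta.setdefault(key, val.strip())
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ScaleError(f"{path_hint}: expected 'residue value', got {line!r}")
        res, val = parts
        try:
            values[res.upper()] = float(val)
        except ValueError:
            raise ScaleError(f"{path_hint}: non-numeric value in line {line!r}") from None
    if "name" not in meta:
        raise ScaleError(f"{path_hint}: missing '# name:' header")
    return ResidueScale(
        name=meta["name"],
        values=values,
        source=meta.get("source", ""),
        combine_mode=meta.get("combine_mode", "arithmetic-mean"),
    )


def load_scale(path: str | Path) -> ResidueScale:
    path = Path(path)
    return parse_scale(path.read_text(), path_hint=str(path))


_BUILTIN_FILES = {
    "hopp-woods": "hopp_woods.tsv",
    "kyte-doolittle": "kyte_doolittle.tsv",
    "emini-surface": "emini_surface.tsv",
    "flexibility": "flexibility.tsv",
}


def data_path(filename: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("episcan.data") / filename)


def builtin_scale(name: str) -> ResidueScale:
    """Load one of the packaged scales by registry name."""
    try:
        filename = _BUILTIN_FILES[name]
    except KeyError:
        raise ScaleError(
            f"unknown builtin scale {name!r}; available: {sorted(_BUILTIN_FILES)}"
        ) from None
    return load_scale(data_path(filename))


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def verify_data_checksums(strict: bool = True) -> dict[str, bool]:
    """Check every packaged parameter file against its pinned SHA-256.

    The pins live in ``data/checksums.json``; a mismatch means a parameter
    table was edited without re-pinning, which silently changes every
    downstream profile.  With ``strict`` a mismatch raises
    :class:`~episcan.errors.ChecksumError`.
    """
    pins = json.loads(data_path("checksums.json").read_text())
    result = {}
    for filename, expected in pins.items():
        actual = file_sha256(data_path(filename))
        result[filename] = actual == expected
        if strict and actual != expected:
            raise ChecksumError(
                f"data file {filename!r}: checksum {actual[:12]}... does not match "
                f"pinned {expected[:12]}..."
            )
    return result
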