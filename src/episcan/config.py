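"""Declarative pipeline configuration with packaged defaults.

A user config file carries the same YAML structure as the packaged defaults
(``data/default_config.yaml``) and may be partial: trees are deep-merged over
the defaults.  The config echo written to every run manifest is the complete
merged tree, which is what makes reports reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import yaml

from .epitope_select import SelectionCriteria
from .errors import CriteriaError
from .scales import data_path, verify_data_checksums


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class PipelineConfig:
    """The merged configuration tree driving prediction and conservation runs."""

    tree: dict

    @classmethod
    def default(cls) -> "PipelineConfig":
        tree = yaml.safe_load(data_path("default_config.yaml").read_text())
        return cls(tree=tree)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PipelineConfig":
        cfg = cls.default()
        if path is not None:
            user = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(user, dict):
                raise CriteriaError(f"config file {path} must be a YAML mapping")
            cfg = cls(tree=_deep_merge(cfg.tree, user))
        if cfg.tree.get("verify_checksums", True):
            verify_data_checksums(strict=True)
        return cfg

    def __getitem__(self, key: str):
        return self.tree[key]

    @property
    def seed(self) -> int:
        return int(self.tree.get("seed", 0))

    def selection_criteria(self) -> SelectionCriteria:
        sel = self.tree["selection"]
        return SelectionCriteria(
            min_length=int(sel["min_length"]),
            ai_threshold=float(sel["ai_threshold"]),
            hydrophilicity_min=float(sel["hydrophilicity_min"]),
            surface_min=float(sel["surface_min"]),
            flexibility_min=float(sel["flexibility_min"]),
            max_rigid_fraction=float(sel["max_rigid_fraction"]),
            gap_merge=int(sel["gap_merge"]),
            forbidden_regions=tuple(
                (int(s), int(e)) for s, e in sel.get("forbidden_regions") or []
            ),
        )

    def echo(self) -> dict:
        """The complete merged tree, safe to serialize into a manifest."""
        return copy.deepcopy(self.tree)
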