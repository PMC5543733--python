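"""End-to-end orchestration: profiles -> secondary structure -> antigenic
index -> candidate selection, and the conservation run.

Everything here is deterministic given (input, config); run outputs include a
manifest echoing the full merged configuration so any report can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import pandas as pd

from . import __version__
from .antigenic_index import (
    AntigenicIndexTrack,
    DiscretizedTrack,
    antigenic_index,
    discretize_profile,
    discretize_structure,
)
from .config import PipelineConfig
from .conservation import AlignmentSet, group_contrast, region_conservation
from .epitope_select import (
    EpitopeCandidate,
    candidates_to_frame,
    extract_segments,
    filter_candidates,
    rank_candidates,
)
from .errors import ScaleError, SequenceTooShortError
from .profiles import (
    Profile,
    flexibility_profile,
    profiles_to_tsv,
    surface_probability_profile,
    windowed_profile,
)
from .scales import builtin_scale
from .secstruct import (
    SecondaryStructureTrack,
    chou_fasman,
    consensus_track,
    garnier_robson,
    load_chou_fasman_params,
    load_gor_info,
)
from .seq_io import ProteinSequence, read_fasta

#: Shortest sequence the full pipeline can analyze (7-residue windows + hexapeptide).
MIN_ANALYZABLE_LENGTH = 7


@lru_cache(maxsize=1)
def _cf_params():
    return load_chou_fasman_params()


@lru_cache(maxsize=1)
def _gor_info():
    return load_gor_info()


@dataclass
class PredictionResult:
    """All per-residue tracks and candidates for one sequence."""

    sequence: ProteinSequence
    hydrophilicity: Profile
    surface: Profile
    flexibility: Profile
    cf_track: SecondaryStructureTrack
    gr_track: SecondaryStructureTrack
    consensus: SecondaryStructureTrack
    ai_track: AntigenicIndexTrack
    candidates: list[EpitopeCandidate]
    ranked: list[EpitopeCandidate]

    @property
    def top_candidate(self) -> EpitopeCandidate | None:
        return self.ranked[0] if self.ranked else None

    def report_dict(self, config_echo: dict | None = None) -> dict:
        report = {
            "sequence_id": self.sequence.id,
            "sequence_length": self.sequence.length,
            "n_candidates": len(self.candidates),
            "n_passed": len(self.ranked),
            "candidates": [c.to_dict() for c in self.candidates],
        }
        if config_echo is not None:
            report["config"] = config_echo
        return report


def compute_tracks(seq: ProteinSequence, config: PipelineConfig):
    """The five predictor tracks plus the consensus structure and the index."""
    if seq.length < MIN_ANALYZABLE_LENGTH:
        raise SequenceTooShortError(
            f"sequence {seq.id!r} has {seq.length} residues; the pipeline needs "
            f"at least {MIN_ANALYZABLE_LENGTH}"
        )
    tree = config.tree
    sc = tree["scales"]

    hydro_scale = builtin_scale(sc["hydrophilicity"]["name"])
    if hydro_scale.name == "kyte-doolittle":
        # hydropathy scale: invert so high = hydrophilic, as documented
        hydro_scale = hydro_scale.negated("kyte-doolittle-inverted")
    elif hydro_scale.combine_mode == "product-ratio":
        raise ScaleError("hydrophilicity track cannot use a product-ratio scale")
    hydro = windowed_profile(seq, hydro_scale, int(sc["hydrophilicity"]["window"]))

    surface = surface_probability_profile(
        seq, builtin_scale(sc["surface"]["name"]), anchor=sc["surface"].get("anchor", "first")
    )
    flex = flexibility_profile(
        seq,
        builtin_scale(sc["flexibility"]["name"]),
        window=int(sc["flexibility"]["window"]),
        weights=tuple(sc["flexibility"]["weights"]) if sc["flexibility"].get("weights") else None,
    )

    ss = tree["secstruct"]
    cf = chou_fasman(
        seq,
        _cf_params(),
        helix_cutoff=float(ss["helix_cutoff"]),
        strand_cutoff=float(ss["strand_cutoff"]),
        turn_cutoff=float(ss["turn_cutoff"]),
    )
    gr = garnier_robson(
        seq, _gor_info(), decision_constants=ss.get("gor_decision_constants")
    )
    cons = consensus_track(cf, gr)

    disc = tree["discretization"]
    levels = tuple(disc["levels"])
    components = {
        "hydrophilicity": discretize_profile(
            hydro, tuple(disc["hydrophilicity_thresholds"]), levels, name="hydrophilicity"
        ),
        "surface": discretize_profile(
            surface, tuple(disc["surface_thresholds"]), levels, name="surface"
        ),
        "flexibility": discretize_profile(
            flex, tuple(disc["flexibility_thresholds"]), levels, name="flexibility"
        ),
        "structure_cf": discretize_structure(cf, disc["state_scores"], name="structure_cf"),
        "structure_gr": discretize_structure(gr, disc["state_scores"], name="structure_gr"),
    }
    ai = antigenic_index(seq.id, components, tree["antigenic_index_weights"])
    return hydro, surface, flex, cf, gr, cons, ai


def predict_epitopes(
    seq: ProteinSequence, config: PipelineConfig | None = None
) -> PredictionResult:
    """Run the full selection pipeline on one sequence."""
    if config is None:
        config = PipelineConfig.default()
    hydro, surface, flex, cf, gr, cons, ai = compute_tracks(seq, config)
    criteria = config.selection_criteria()
    candidates = extract_segments(ai, hydro, seq, criteria)
    filter_candidates(candidates, cons, surface, flex, criteria)
    ranked = rank_candidates(candidates)
    return PredictionResult(
        sequence=seq,
        hydrophilicity=hydro,
        surface=surface,
        flexibility=flex,
        cf_track=cf,
        gr_track=gr,
        consensus=cons,
        ai_track=ai,
        candidates=candidates,
        ranked=ranked,
    )


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def run_predict(
    fasta: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "episcan_out",
) -> list[PredictionResult]:
    """Predict epitopes for every record of a FASTA file; write reports.

    Outputs per sequence: ``<id>.candidates.tsv``, ``<id>.tracks.tsv`` and
    ``<id>.report.json``; plus one ``manifest.json`` echoing the merged
    config, package version and seed.  Zero passed candidates is a valid
    result, not an error.
    """
    if config is None:
        config = PipelineConfig.default()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = []
    for seq in read_fasta(fasta, alphabet="protein"):
        res = predict_epitopes(seq, config)
        results.append(res)
        candidates_to_frame(res.candidates).to_csv(
            out / f"{seq.id}.candidates.tsv", sep="\t", index=False
        )
        tracks = res.ai_track.to_frame()
        tracks["cf_state"] = list(res.cf_track.states)
        tracks["gr_state"] = list(res.gr_track.states)
        tracks["consensus_state"] = list(res.consensus.states)
        tracks["hydrophilicity_raw"] = res.hydrophilicity.values
        tracks["surface_raw"] = res.surface.values
        tracks["flexibility_raw"] = res.flexibility.values
        tracks.to_csv(out / f"{seq.id}.tracks.tsv", sep="\t", index=False)
        _write_json(res.report_dict(), out / f"{seq.id}.report.json")
    manifest = {
        "tool": "episcan",
        "version": __version__,
        "command": "predict",
        "input": str(fasta),
        "seed": config.seed,
        "config": config.echo(),
        "sequences": [r.sequence.id for r in results],
    }
    _write_json(manifest, out / "manifest.json")
    return results


def run_conserve(
    aln: AlignmentSet | str | Path,
    region: tuple[int, int],
    config: PipelineConfig | None = None,
    groups_path: str | Path | None = None,
    with_group_contrast: bool = False,
    out_dir: str | Path = "episcan_out",
) -> dict:
    """Conservation report for a declared epitope window of an alignment."""
    if config is None:
        config = PipelineConfig.default()
    if not isinstance(aln, AlignmentSet):
        aln = AlignmentSet.from_fasta(aln, groups_path=groups_path)
    cons_cfg = config.tree["conservation"]
    report = region_conservation(
        aln,
        region,
        gap_policy=cons_cfg["gap_policy"],
        variable_threshold=float(cons_cfg["variable_threshold"]),
    )
    payload = {"conservation": report.to_dict()}
    if with_group_contrast:
        contrast = group_contrast(aln, region)
        payload["group_contrast"] = {
            "region": list(contrast["region"]),
            "discordant_columns": contrast["discordant_columns"],
            "group_modal": {
                str(col): modals for col, modals in contrast["group_modal"].items()
            },
        }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out / "conservation.tsv", sep="\t", index=False)
    _write_json(payload, out / "conservation.json")
    manifest = {
        "tool": "episcan",
        "version": __version__,
        "command": "conserve",
        "region": list(region),
        "seed": config.seed,
        "config": config.echo(),
    }
    _write_json(manifest, out / "manifest.json")
    return payload
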