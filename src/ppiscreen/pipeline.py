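"""End-to-end cascade orchestration with manifests and a funnel summary.

``run_pipeline`` executes the stages in protocol order — hot-spot
analysis, hypothesis construction, pharmacophore screen, docking (mock
engines unless an adapter is supplied), z-score selection, consensus
filtering, clustering — writing one manifest per stage plus a final
summary that mirrors the screening funnel (input size, pharmacophore
survivors, z-selected, consensus passes, cluster representatives).

Configuration is validated before anything runs; unknown keys are
rejected.  A single seed fans out into per-stage seeds by stable
hashing, so runs with identical configs are byte-for-byte reproducible
while stages stay statistically independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, fields
from pathlib import Path

from . import cascade, hotspot, synth
from .ligand import annotate_ligand
from .pharmacophore import build_hypothesis
from .structure import read_structure, select_residues

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the protocol's printed constants."""

    # inputs; None -> generate synthetic fixtures
    pdb_path: str | None = None
    msa_path: str | None = None
    anchor: str = "B:7-11"
    receptor: str = "A:160-206"
    essential_residues: tuple[int, ...] = (8, 10)
    # printed protocol constants
    exclusion_cutoff: float = 4.0
    feature_radius: float = 1.0
    projection_radius: float = 1.4
    min_match: int = 3
    consensus_threshold: float = 2.0
    contact_cutoff: float = 4.5
    cons_min: int = 7
    ddg_window: tuple[float, float] = (2.0, 4.0)
    similarity_threshold: float = 0.7
    # synthetic-library shape
    n_actives: int = 30
    n_decoys: int = 30
    n_true_hits: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.min_match < 1:
            raise ValueError("min_match must be >= 1")
        for name in ("exclusion_cutoff", "feature_radius", "projection_radius",
                     "consensus_threshold", "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.n_true_hits > self.n_actives:
            raise ValueError("n_true_hits cannot exceed n_actives")
        _parse_selection(self.anchor)
        _parse_selection(self.receptor)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        doc = dict(doc)
        for key in ("essential_residues", "ddg_window"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


def _parse_selection(text: str) -> tuple[str, int, int]:
    try:
        chain, rng = text.split(":")
        start, end = rng.split("-")
        return chain, int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"selection must look like 'B:7-11', got {text!r}") from exc


def stage_seed(base: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (base * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _manifest(outdir: Path, stage: str, params: dict, counts: dict, outputs: dict) -> None:
    doc = {"stage": stage, "parameters": params, "counts": counts, "outputs": {}}
    for label, path in outputs.items():
        data = Path(path).read_bytes()
        doc["outputs"][label] = {
            "path": str(path),
            "sha256": hashlib.sha256(data).hexdigest(),
        }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n"
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the cascade and return the funnel summary (also written as JSON)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.pdb_path is None:
            toy = synth.make_toy_complex(
                synth.aurora_interface_spec(seed=stage_seed(config.seed, "complex"))
            )
            structure, anchor, receptor = toy.structure, toy.anchor, toy.receptor
            pdb_file = outdir / "complex.pdb"
            pdb_file.write_text(toy.pdb_text)
        else:
            structure = read_structure(Path(config.pdb_path).read_text())
            ch, s, e = _parse_selection(config.anchor)
            anchor = select_residues(structure, ch, s, e, role="anchor")
            ch, s, e = _parse_selection(config.receptor)
            receptor = select_residues(structure, ch, s, e, role="receptor")
            pdb_file = Path(config.pdb_path)
        if config.msa_path is None:
            seq = "".join(
                {"SER": "S", "TYR": "Y", "ASP": "D", "GLY": "G", "ALA": "A", "PHE": "F"}.get(
                    structure.residue_atoms(anchor.chain_id, r)[0].residue_name, "A"
                )
                for r in anchor.residue_numbers
            )
            msa_text = synth.make_anchor_msa(seq, seed=stage_seed(config.seed, "msa"))
            (outdir / "anchor_msa.fasta").write_text(msa_text)
        else:
            msa_text = Path(config.msa_path).read_text()
        _manifest(outdir, stage, {"seed": config.seed}, {"atoms": len(structure.atoms)},
                  {"pdb": pdb_file})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- hot spots --------------------------------------------------------
    stage = "hotspot"
    try:
        profile = hotspot.conservation_profile(msa_text)
        scan = hotspot.alanine_scan(structure, anchor, config.contact_cutoff)
        res_cols = {r: i for i, r in enumerate(anchor.residue_numbers)}
        spots = hotspot.rank_hotspots(
            profile, scan, res_cols, cons_min=config.cons_min,
            ddg_window=config.ddg_window,
        )
        report = ["residue\tconservation\tddg_kJ_mol\thotspot"]
        hot = {r.residue_number for r in spots}
        for r in scan:
            cons = profile.scores[res_cols[r.residue_number]]
            ddg = "NA" if r.missing else f"{r.ddg:.3f}"
            report.append(
                f"{r.residue_name}{r.residue_number}\t{cons}\t{ddg}\t"
                f"{int(r.residue_number in hot)}"
            )
        hotspot_file = outdir / "hotspots.tsv"
        hotspot_file.write_text("\n".join(report) + "\n")
        _manifest(outdir, stage,
                  {"cons_min": config.cons_min, "ddg_window": list(config.ddg_window)},
                  {"anchor_residues": len(scan), "hotspots": len(spots)},
                  {"report": hotspot_file})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- hypothesis -------------------------------------------------------
    stage = "build-ph"
    try:
        hyp = build_hypothesis(
            structure, anchor, receptor,
            exclusion_cutoff=config.exclusion_cutoff,
            essential_residues=list(config.essential_residues),
            feature_radius=config.feature_radius,
            projection_radius=config.projection_radius,
            min_match=config.min_match,
        )
        hyp_file = outdir / "hypothesis.json"
        hyp_file.write_text(hyp.to_json() + "\n")
        _manifest(outdir, stage, {"exclusion_cutoff": config.exclusion_cutoff},
                  {"features": len(hyp.features), "points": hyp.n_points,
                   "exclusions": len(hyp.exclusions)},
                  {"hypothesis": hyp_file})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- library + pharmacophore screen ----------------------------------
    stage = "screen"
    try:
        lib = synth.make_library(
            synth.LibrarySpec(
                n_actives=config.n_actives,
                n_decoys=config.n_decoys,
                seed=stage_seed(config.seed, "library"),
            ),
            hyp,
        )
        conformers = {cid: [annotate_ligand(m)] for cid, m in lib.mols.items()}
        survivors = cascade.ph_screen(conformers, hyp)
        (outdir / "labels.tsv").write_text(lib.labels_tsv())
        _manifest(outdir, stage, {"min_match": config.min_match},
                  {"library": len(lib.mols), "survivors": len(survivors)},
                  {"labels": outdir / "labels.tsv"})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- docking (mock adapters) + z-selection + consensus ---------------
    stage = "dock"
    try:
        true_hits = set(lib.active_ids[: config.n_true_hits])
        surviving_mols = {cid: lib.mols[cid] for cid in survivors}
        poses, scores = synth.make_mock_docking(
            surviving_mols,
            synth.MockEngineSpec(seed=stage_seed(config.seed, "docking")),
            consistent_ids=true_hits,
            boosted_ids=true_hits,
        )
        _manifest(outdir, stage, {"engines": ["dovis", "vina", "moldock"]},
                  {"docked": len(poses)}, {})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "zselect"
    try:
        selected = cascade.zscore_select(scores)
        _manifest(outdir, stage, {"rule": "> mean + 2 SD"},
                  {"in": len(scores), "selected": len(selected)}, {})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "consensus"
    try:
        sel_poses = {cid: poses[cid] for cid in selected}
        results = (
            cascade.consensus_filter(sel_poses, hyp, threshold=config.consensus_threshold)
            if sel_poses
            else []
        )
        passed = sorted(r.compound_id for r in results if r.passed)
        _manifest(outdir, stage, {"threshold": config.consensus_threshold},
                  {"in": len(selected), "passed": len(passed)}, {})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "cluster"
    try:
        passed_mols = {cid: lib.mols[cid] for cid in passed}
        clusters, reps = cascade.cluster_and_pick(
            passed_mols, {cid: scores[cid] for cid in passed},
            similarity_threshold=config.similarity_threshold,
        )
        _manifest(outdir, stage, {"similarity_threshold": config.similarity_threshold},
                  {"clusters": len(set(clusters.values())), "representatives": len(reps)},
                  {})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    summary = {
        "funnel": {
            "library": len(lib.mols),
            "ph_survivors": len(survivors),
            "z_selected": len(selected),
            "consensus_passed": len(passed),
            "representatives": len(reps),
        },
        "hotspots": sorted(f"{r.residue_name}{r.residue_number}" for r in spots),
        "ph_survivor_ids": sorted(survivors),
        "z_selected_ids": selected,
        "consensus_passed_ids": passed,
        "representative_ids": reps,
        "true_hit_ids": sorted(true_hits),
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete: %s", summary["funnel"])
    return summary
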