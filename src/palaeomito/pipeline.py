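"""End-to-end orchestration: simulate → assemble → damage → contam → classify → tree.

Stages exchange plain files only (FASTA/FASTQ/TSV/JSON), so each stage is
independently runnable and debuggable.  A ``manifest.json`` in the run
directory records the seed, the normalized configuration and a SHA-256
checksum of every stage output; before a stage consumes an upstream file
it re-hashes it against the manifest, so tampered intermediates are
detected and re-running with the same configuration is byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .align import ScoringParams
from .assemble import iterative_assemble
from .contam import estimate_contamination, find_diagnostic_positions
from .damage import damage_profile, plot_profile, terminal_damage_summary, write_profile_tsv
from .errors import ConfigError, DependencyError, IntegrityError
from .fixtures import make_study_fixture
from . import io
from .phylo import classify_haplogroup, nj_tree, p_distance_matrix, read_haplogroup_tree_tsv
from .reference import CircularReference, GenomeRecord
from .simulate import DamageModel, SimulationConfig, simulate_reads

__all__ = ["STAGES", "validate_config", "demo_config", "run_pipeline"]

STAGES = ["simulate", "assemble", "damage", "contam", "classify", "tree"]

# schema: stage -> key -> (type, default, validator or None)
_SCHEMA = {
    "simulate": {
        "n_reads": (int, 4000, lambda v: v >= 1),
        "mean_fragment_length": ((int, float), 50.0, lambda v: v >= 20),
        "fragment_length_sd": ((int, float), 10.0, lambda v: v > 0),
        "contamination_fraction": ((int, float), 0.02, lambda v: 0.0 <= v <= 1.0),
        "mean_quality": ((int, float), 35.0, lambda v: 2 <= v <= 41),
        "quality_sd": ((int, float), 3.0, lambda v: v >= 0),
        "p5_max": ((int, float), 0.40, lambda v: 0.0 <= v <= 1.0),
        "p3_max": ((int, float), 0.40, lambda v: 0.0 <= v <= 1.0),
        "decay": ((int, float), 0.3, lambda v: v >= 0),
        "baseline": ((int, float), 0.001, lambda v: 0.0 <= v <= 1.0),
    },
    "assemble": {
        "min_depth": (int, 2, lambda v: v >= 1),
        "max_iterations": (int, 10, lambda v: v >= 1),
        "damage_mode": (str, "half", lambda v: v in ("off", "half", "full")),
    },
    "damage": {
        "window": (int, 25, lambda v: v >= 1),
        "plot": (bool, True, None),
    },
    "contam": {
        "threshold": ((int, float), 0.99, lambda v: 0.5 < v <= 1.0),
        "panel_size": (int, 311, lambda v: v >= 1),
        "panel_mask_rate": ((int, float), 0.005, lambda v: 0.0 <= v < 1.0),
        "confidence": ((int, float), 0.95, lambda v: 0.0 < v < 1.0),
    },
    "classify": {
        "match_fraction": ((int, float), 0.8, lambda v: 0.0 < v <= 1.0),
    },
    "tree": {
        "region": (str, "complete", lambda v: v in ("complete", "coding")),
    },
}


def demo_config() -> dict:
    """The bundled study-like demonstration configuration."""
    return {
        "seed": 17,
        "stages": {name: True for name in STAGES},
    }


def validate_config(config) -> dict:
    """Schema-check a configuration (dict, or path to YAML/JSON).

    Unknown keys are rejected; defaults are filled in; all violations are
    reported together, each with its dotted path.  A seed is mandatory
    whenever the simulate stage is enabled (reproducibility contract).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    config = copy.deepcopy(config)
    errors: List[str] = []

    allowed_top = {"seed", "stages"}
    for key in set(config) - allowed_top:
        errors.append(f"{key}: unknown key")

    stages_in = config.get("stages", {})
    if not isinstance(stages_in, dict):
        errors.append("stages: must be a mapping")
        stages_in = {}
    for key in set(stages_in) - set(STAGES):
        errors.append(f"stages.{key}: unknown stage")

    normalized_stages: Dict[str, object] = {}
    for stage in STAGES:
        block = stages_in.get(stage, False)
        if block is False or block is None:
            normalized_stages[stage] = False
            continue
        if block is True:
            block = {}
        if not isinstance(block, dict):
            errors.append(f"stages.{stage}: must be a mapping or boolean")
            continue
        schema = _SCHEMA[stage]
        for key in set(block) - set(schema):
            errors.append(f"stages.{stage}.{key}: unknown key")
        out = {}
        for key, (types, default, check) in schema.items():
            value = block.get(key, default)
            if isinstance(value, bool) and types is not bool:
                errors.append(f"stages.{stage}.{key}: expected {types}, got boolean")
                continue
            if not isinstance(value, types):
                errors.append(
                    f"stages.{stage}.{key}: expected {types}, got {type(value).__name__}"
                )
                continue
            if check is not None and not check(value):
                errors.append(f"stages.{stage}.{key}: value {value!r} out of range")
                continue
            out[key] = value
        normalized_stages[stage] = out

    seed = config.get("seed")
    if normalized_stages.get("simulate") is not False and seed is None:
        errors.append("seed: required when the simulate stage is enabled")
    if seed is not None and not isinstance(seed, int):
        errors.append(f"seed: expected integer, got {type(seed).__name__}")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(sorted(errors)))
    return {"seed": seed if seed is not None else 0, "stages": normalized_stages}


# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: dict):
        self.path = outdir / "manifest.json"
        self.outdir = outdir
        if self.path.exists():
            with open(self.path) as fh:
                self.data = json.load(fh)
        else:
            self.data = {
                "package_version": __version__,
                "seed": config["seed"],
                "config": config,
                "stages": {},
            }

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def record(self, stage: str, files: Sequence[Path]) -> None:
        self.data["stages"][stage] = {
            "outputs": {
                str(p.relative_to(self.outdir)): _sha256(p) for p in sorted(files)
            }
        }
        self.save()

    def verify_inputs(self, stage: str, files: Sequence[Path]) -> None:
        known = {}
        for block in self.data["stages"].values():
            known.update(block.get("outputs", {}))
        for p in files:
            rel = str(p.relative_to(self.outdir))
            if not p.exists():
                raise DependencyError(f"stage {stage!r}: missing upstream output {rel}")
            if rel in known and _sha256(p) != known[rel]:
                raise IntegrityError(
                    f"stage {stage!r}: checksum mismatch for {rel} "
                    "(upstream output modified since it was produced)"
                )


def _noisy_panel(
    contaminant: GenomeRecord, size: int, mask_rate: float, seed: int
) -> List[GenomeRecord]:
    """Synthetic modern panel: copies of the contaminant with random
    positions replaced by N (emulating per-genome missing data)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 311]))
    panel = []
    codes = np.frombuffer(contaminant.sequence.encode(), dtype=np.uint8)
    for i in range(size):
        seq = codes.copy()
        if mask_rate > 0:
            n_mask = rng.binomial(len(seq), mask_rate)
            idx = rng.choice(len(seq), size=n_mask, replace=False)
            seq[idx] = ord("N")
        panel.append(GenomeRecord(f"panel{i:03d}", seq.tobytes().decode()))
    return panel


def run_pipeline(config, outdir, only: Optional[Sequence[str]] = None) -> Path:
    """Execute the enabled stages in order inside ``outdir``.

    ``only`` restricts execution to a subset of stages (their upstream
    outputs must already be on disk).  Returns the run directory.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, cfg)
    manifest.save()
    seed = cfg["seed"]
    stages = cfg["stages"]
    fixture_dir = outdir / "fixture"

    def enabled(name: str) -> bool:
        return stages[name] is not False and (only is None or name in only)

    if enabled("simulate"):
        p = stages["simulate"]
        fixture = make_study_fixture(seed)
        fixture.write(fixture_dir)
        damage_model = DamageModel(p["p5_max"], p["p3_max"], p["decay"], p["baseline"])
        sim_cfg = SimulationConfig(
            n_reads=p["n_reads"],
            endogenous_genome=fixture.genome("StHe_like"),
            contaminant_genome=fixture.genome("modern_contaminant"),
            contamination_fraction=p["contamination_fraction"],
            mean_fragment_length=p["mean_fragment_length"],
            fragment_length_sd=p["fragment_length_sd"],
            mean_quality=p["mean_quality"],
            quality_sd=p["quality_sd"],
            seed=seed,
        )
        reads, truth = simulate_reads(sim_cfg, damage_model)
        io.write_fastq(reads, outdir / "reads.fastq")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest.record(
            "simulate",
            [outdir / "reads.fastq", outdir / "truth.tsv"]
            + sorted(fixture_dir.iterdir()),
        )

    if enabled("assemble"):
        p = stages["assemble"]
        inputs = [outdir / "reads.fastq", fixture_dir / "reference.fasta"]
        manifest.verify_inputs("assemble", inputs)
        reads = io.read_fastq(inputs[0])
        ref_rec = io.read_fasta(inputs[1])[0]
        ref = CircularReference(ref_rec.id, ref_rec.sequence)
        scoring = ScoringParams(damage_mode=p["damage_mode"])
        consensus, report = iterative_assemble(
            reads, ref, scoring, min_depth=p["min_depth"], max_iterations=p["max_iterations"]
        )
        io.write_fasta(
            [GenomeRecord("consensus", consensus.sequence)], outdir / "consensus.fasta"
        )
        # re-derive final molecules for downstream stages
        from .align import KmerIndex, align_read
        from .assemble import collapse_unique_molecules

        final_ref = CircularReference("consensus", consensus.sequence)
        index = KmerIndex(final_ref, scoring.k)
        alignments = [
            a for r in reads if (a := align_read(r, final_ref, scoring, index)) is not None
        ]
        molecules = collapse_unique_molecules(alignments)
        io.write_molecules_tsv(molecules, outdir / "molecules.tsv")
        with open(outdir / "assembly_report.json", "w") as fh:
            json.dump(
                {
                    "n_input_reads": report.n_input_reads,
                    "n_aligned": report.n_aligned,
                    "on_target_fraction": report.on_target_fraction,
                    "n_unique_molecules": report.n_unique_molecules,
                    "mean_coverage": report.mean_coverage,
                    "min_coverage": report.min_coverage,
                    "mean_raw_coverage": report.mean_raw_coverage,
                    "n_iterations": report.n_iterations,
                    "converged": report.converged,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        manifest.record(
            "assemble",
            [outdir / "consensus.fasta", outdir / "molecules.tsv", outdir / "assembly_report.json"],
        )

    if enabled("damage"):
        p = stages["damage"]
        inputs = [outdir / "molecules.tsv", outdir / "consensus.fasta"]
        manifest.verify_inputs("damage", inputs)
        molecules = io.read_molecules_tsv(inputs[0])
        cons = io.read_fasta(inputs[1])[0]
        profile = damage_profile(
            molecules, CircularReference(cons.id, cons.sequence), p["window"]
        )
        write_profile_tsv(profile, outdir / "damage_profile.tsv")
        outputs = [outdir / "damage_profile.tsv"]
        if p["plot"]:
            plot_profile(profile, outdir / "damage_profile.png")
            outputs.append(outdir / "damage_profile.png")
        summary = terminal_damage_summary(profile)
        with open(outdir / "damage_summary.json", "w") as fh:
            json.dump(
                {
                    "ct_5p_d1": summary.ct_5p_d1,
                    "ga_3p_d1": summary.ga_3p_d1,
                    "ct_5p_mean_d1_3": summary.ct_5p_mean_d1_3,
                    "ga_3p_mean_d1_3": summary.ga_3p_mean_d1_3,
                    "adna_consistent": summary.adna_consistent,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        outputs.append(outdir / "damage_summary.json")
        manifest.record("damage", outputs)

    if enabled("contam"):
        p = stages["contam"]
        inputs = [outdir / "molecules.tsv", outdir / "consensus.fasta", fixture_dir / "genomes.fasta"]
        manifest.verify_inputs("contam", inputs)
        molecules = io.read_molecules_tsv(inputs[0])
        cons = io.read_fasta(inputs[1])[0]
        genomes = {g.id: g for g in io.read_fasta(inputs[2])}
        panel = _noisy_panel(
            genomes["modern_contaminant"], p["panel_size"], p["panel_mask_rate"], seed
        )
        diag = find_diagnostic_positions(cons, panel, p["threshold"])
        estimate = estimate_contamination(molecules, diag, cons.length, p["confidence"])
        with open(outdir / "contamination.json", "w") as fh:
            json.dump(
                {
                    "n_diagnostic_positions": len(diag),
                    "panel_size": diag.panel_size,
                    "n_clean": estimate.n_clean,
                    "n_contaminant": estimate.n_contaminant,
                    "n_other": estimate.n_other,
                    "point": estimate.point,
                    "wilson_low": estimate.wilson_low,
                    "wilson_high": estimate.wilson_high,
                    "confidence": estimate.confidence,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        manifest.record("contam", [outdir / "contamination.json"])

    if enabled("classify"):
        p = stages["classify"]
        inputs = [
            outdir / "consensus.fasta",
            fixture_dir / "haplogroup_tree.tsv",
            fixture_dir / "hotspot_mask.tsv",
            fixture_dir / "reference.fasta",
        ]
        manifest.verify_inputs("classify", inputs)
        cons = io.read_fasta(inputs[0])[0]
        tree = read_haplogroup_tree_tsv(inputs[1])
        mask = io.read_mask_tsv(inputs[2])
        root_ref = io.read_fasta(inputs[3])[0]
        call = classify_haplogroup(
            cons, tree, root_ref, mask, match_fraction=p["match_fraction"]
        )
        with open(outdir / "classification.json", "w") as fh:
            json.dump(
                {
                    "call": call.call,
                    "path": call.path,
                    "ambiguous": call.ambiguous,
                    "ambiguous_children": call.ambiguous_children,
                    "node_support": {
                        k: list(v) for k, v in sorted(call.node_support.items())
                    },
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        manifest.record("classify", [outdir / "classification.json"])

    if enabled("tree"):
        p = stages["tree"]
        inputs = [fixture_dir / "genomes.fasta", fixture_dir / "hotspot_mask.tsv", outdir / "consensus.fasta"]
        manifest.verify_inputs("tree", inputs)
        genomes = {g.id: g for g in io.read_fasta(inputs[0])}
        mask = io.read_mask_tsv(inputs[1])
        cons = io.read_fasta(inputs[2])[0]
        taxa = [
            GenomeRecord("StHe_assembled", cons.sequence),
            genomes["NAM117_like"],
            genomes["NAM168_like"],
            genomes["L0d2c1a_like"],
            genomes["L0d2c1b_like"],
            genomes["outgroup"],
        ]
        dm = p_distance_matrix(taxa, mask, p["region"])
        newick = nj_tree(dm, outgroup="outgroup")
        io.write_newick(newick, outdir / "nj_tree.nwk")
        manifest.record("tree", [outdir / "nj_tree.nwk"])

    return outdir
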