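"""Pipeline configuration and orchestration.

A run is described by one YAML file naming the per-locus inputs, the
alignment frames to build, the diagnostic analyses to run and their seeds.
``validate_config`` checks all cross-references up front and aggregates
every problem instead of failing on the first; ``run_pipeline`` executes
the stages in analysis order (assemble -> profile -> learn -> design ->
in-silico PCR -> support), records failures per stage while letting later
independent stages proceed, and writes self-describing TSV/newick reports.
Re-running an identical config reproduces identical non-log outputs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import (
    RANKS,
    ConcatenatedAlignment,
    LabeledAlignment,
    concatenate_loci,
    read_alignment,
    write_segment_map,
)
from .assay import assay_table, design_assay, simulate_multiplex
from .phylo import bootstrap_support, group_support, write_replicates
from .profiling import information_table
from .rules import LearnerParams, learn_rules, write_rulebook

STAGES = ("profile", "learn", "design", "insilico_pcr", "support")


class ConfigError(ValueError):
    """One or more problems in a run configuration."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    loci: dict[str, dict[str, Path]]  # locus -> {"fasta": ..., "labels": ...}
    frames: dict[str, list[str]] = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    learn: dict = field(default_factory=dict)
    assay: dict = field(default_factory=dict)
    products: dict[str, Path] = field(default_factory=dict)  # locus -> fasta
    support: dict = field(default_factory=dict)
    base_dir: Path = Path(".")


def validate_config(path) -> RunConfig:
    """Parse and cross-check a YAML run config; errors are aggregated."""
    path = Path(path)
    errors: list[str] = []
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError([f"{path}: cannot read config ({exc})"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: config must be a mapping"])
    base = path.parent

    if "seed" not in raw:
        errors.append("seed: missing (seeds are mandatory wherever randomness occurs)")
    seed = int(raw.get("seed", 0))
    output_dir = Path(raw.get("output_dir", "herbdx_out"))
    if not output_dir.is_absolute():
        output_dir = base / output_dir

    loci: dict[str, dict[str, Path]] = {}
    for locus, files in (raw.get("loci") or {}).items():
        entry = {}
        for key in ("fasta", "labels"):
            if not files or key not in files:
                errors.append(f"loci.{locus}.{key}: missing")
                continue
            p = Path(files[key])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                errors.append(f"loci.{locus}.{key}: file not found ({p})")
            entry[key] = p
        loci[locus] = entry
    if not loci:
        errors.append("loci: at least one locus is required")

    frames = {}
    for name, members in (raw.get("frames") or {}).items():
        unknown = [m for m in members if m not in loci]
        if unknown:
            errors.append(f"frames.{name}: unknown locus/loci {unknown}")
        frames[name] = list(members)

    stages = list(raw.get("stages") or STAGES)
    for stage in stages:
        if stage not in STAGES:
            errors.append(f"stages: unknown stage {stage!r} (expected {STAGES})")

    learn = dict(raw.get("learn") or {})
    if "learn" in stages:
        rank = learn.get("rank")
        if rank not in RANKS:
            errors.append(f"learn.rank: {rank!r} is not one of {RANKS}")
        frame = learn.get("frame")
        if frame and frame not in frames and frame not in loci:
            errors.append(f"learn.frame: unknown frame {frame!r}")

    assay = dict(raw.get("assay") or {})
    if "design" in stages or "insilico_pcr" in stages:
        if assay.get("locus") not in loci:
            errors.append(f"assay.locus: unknown locus {assay.get('locus')!r}")
        if assay.get("group_rank") not in RANKS:
            errors.append(
                f"assay.group_rank: {assay.get('group_rank')!r} is not one of {RANKS}"
            )
        for key in ("universal_forward", "universal_reverse"):
            spec = assay.get(key) or {}
            if "start" not in spec or "length" not in spec:
                errors.append(f"assay.{key}: needs start and length")

    products: dict[str, Path] = {}
    for locus, fasta in (raw.get("products") or {}).items():
        p = Path(fasta)
        if not p.is_absolute():
            p = base / p
        if locus not in loci:
            errors.append(f"products.{locus}: unknown locus")
        if not p.exists():
            errors.append(f"products.{locus}: file not found ({p})")
        products[locus] = p

    support = dict(raw.get("support") or {})
    if "support" in stages:
        frame = support.get("frame")
        if frame and frame not in frames and frame not in loci:
            errors.append(f"support.frame: unknown frame {frame!r}")
        if support.get("method", "upgma") not in ("upgma", "mp"):
            errors.append(f"support.method: {support.get('method')!r} not in (upgma, mp)")
        for group, gdef in (support.get("groups") or {}).items():
            if "rank" not in (gdef or {}) and "taxa" not in (gdef or {}):
                errors.append(f"support.groups.{group}: needs 'rank' or explicit 'taxa'")
            if (gdef or {}).get("rank") and gdef["rank"] not in RANKS:
                errors.append(f"support.groups.{group}.rank: unknown rank {gdef['rank']!r}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        loci=loci,
        frames=frames,
        stages=stages,
        learn=learn,
        assay=assay,
        products=products,
        support=support,
        base_dir=base,
    )


@dataclass
class RunReport:
    outputs: dict[str, Path]
    stage_errors: dict[str, str]


def _build_frames(config: RunConfig) -> dict[str, LabeledAlignment]:
    alignments = {
        locus: read_alignment(files["fasta"], files["labels"], locus)
        for locus, files in config.loci.items()
    }
    frames: dict[str, LabeledAlignment] = dict(alignments)
    for name, members in config.frames.items():
        combined = concatenate_loci([alignments[m] for m in members])
        combined.locus = name
        frames[name] = combined
    return frames


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and write the report bundle."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage_errors: dict[str, str] = {}

    frames = _build_frames(config)  # assembly failure is fatal by design
    for name, aln in frames.items():
        if isinstance(aln, ConcatenatedAlignment) and aln.segments:
            seg_path = out / f"frame_{name}.segments.tsv"
            write_segment_map(aln, seg_path)
            outputs[f"segments:{name}"] = seg_path

    if "profile" in config.stages:
        try:
            table = information_table(frames)
            path = out / "information_content.tsv"
            table.to_csv(path, sep="\t", index=False)
            outputs["information_content"] = path
        except Exception as exc:  # noqa: BLE001 - recorded, later stages continue
            stage_errors["profile"] = str(exc)

    rulebook_frame = None
    if "learn" in config.stages:
        try:
            frame_name = config.learn.get("frame") or next(iter(frames))
            rulebook_frame = frames[frame_name]
            params = LearnerParams(
                max_literals=int(config.learn.get("max_literals", 5)),
                seed=config.seed,
            )
            rules = learn_rules(rulebook_frame, config.learn["rank"], params)
            path = out / "rulebook.tsv"
            write_rulebook(rules, config.learn["rank"], frame_name, path)
            outputs["rulebook"] = path
        except Exception as exc:  # noqa: BLE001
            stage_errors["learn"] = str(exc)

    assay_obj = None
    if "design" in config.stages:
        try:
            aln = frames[config.assay["locus"]]
            rank = config.assay["group_rank"]
            groups = {
                cls: [r.id for r in aln.records if r.label(rank) == cls]
                for cls in aln.classes(rank)
            }
            uf = config.assay["universal_forward"]
            ur = config.assay["universal_reverse"]
            assay_obj = design_assay(
                aln,
                groups,
                (int(uf["start"]), int(uf["length"])),
                (int(ur["start"]), int(ur["length"])),
                mismatch_budget=int(config.assay.get("mismatch_budget", 2)),
                tm_target=float(config.assay.get("tm_target", 60.0)),
                tm_window=float(config.assay.get("tm_window", 15.0)),
            )
            path = out / "assay.tsv"
            assay_table(assay_obj).to_csv(path, sep="\t", index=False)
            outputs["assay"] = path
        except Exception as exc:  # noqa: BLE001
            stage_errors["design"] = str(exc)

    if "insilico_pcr" in config.stages:
        if assay_obj is None:
            stage_errors["insilico_pcr"] = "no assay available (design stage failed or skipped)"
        else:
            try:
                locus = config.assay["locus"]
                aln = frames[locus]
                if locus in config.products:
                    from Bio import SeqIO

                    from .alignment import SequenceRecord

                    lanes = {
                        rec.id: [
                            SequenceRecord(
                                id=rec.id, residues=str(rec.seq), source="product"
                            )
                        ]
                        for rec in SeqIO.parse(str(config.products[locus]), "fasta")
                    }
                else:
                    lanes = {rec.id: [rec] for rec in aln.records}
                gel = simulate_multiplex(assay_obj, lanes)
                path = out / "virtual_gel.tsv"
                gel.to_csv(path, sep="\t", index=False)
                outputs["virtual_gel"] = path
            except Exception as exc:  # noqa: BLE001
                stage_errors["insilico_pcr"] = str(exc)

    if "support" in config.stages:
        try:
            frame_name = config.support.get("frame") or next(iter(frames))
            aln = frames[frame_name]
            method = config.support.get("method", "upgma")
            replicates = int(config.support.get("replicates", 100))
            result = bootstrap_support(
                aln,
                method=method,
                replicates=replicates,
                seed=config.seed,
                collapse_below=config.support.get("collapse_below", 50),
            )
            tree_path = out / f"{frame_name}.{method}.support.nwk"
            tree_path.write_text(result.tree.to_newick() + "\n")
            outputs["support_tree"] = tree_path
            reps_path = out / f"{frame_name}.{method}.replicates.nwk"
            write_replicates(result.replicates, reps_path)
            outputs["replicates"] = reps_path
            rows = []
            for group, gdef in (config.support.get("groups") or {}).items():
                if "taxa" in (gdef or {}):
                    taxa = list(gdef["taxa"])
                else:
                    taxa = [
                        r.id for r in aln.records if r.label(gdef["rank"]) == group
                    ]
                report = group_support(
                    result.replicates,
                    group,
                    taxa,
                    ignored=(gdef or {}).get("ignored", []),
                    method=method,
                    dataset=frame_name,
                )
                rows.append(
                    {
                        "dataset": frame_name,
                        "method": method,
                        "group": group,
                        "n_taxa": len(report.taxa),
                        "n_ignored": len(report.ignored),
                        "support": round(report.support, 1),
                        "replicates": report.n_replicates,
                    }
                )
            if rows:
                import pandas as pd

                path = out / "clade_support.tsv"
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                outputs["clade_support"] = path
        except Exception as exc:  # noqa: BLE001
            stage_errors["support"] = str(exc)

    log = out / "run_log.txt"
    log.write_text(
        "\n".join(
            [
                f"herbdx {__version__} (python {sys.version.split()[0]})",
                f"seed: {config.seed}",
                f"stages: {','.join(config.stages)}",
                f"frames: {','.join(frames)}",
                *(f"ERROR {stage}: {msg}" for stage, msg in stage_errors.items()),
            ]
        )
        + "\n"
    )
    outputs["run_log"] = log
    return RunReport(outputs=outputs, stage_errors=stage_errors)
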