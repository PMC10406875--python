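"""End-to-end orchestration: simulate -> screen -> assemble -> classify -> pcr.

A run is driven by a RunConfig (YAML-serializable); every stage writes its
outputs under the run directory and registers them, with SHA-256 checksums
and record counts, in a RunManifest (``manifest.json``). A single global seed
is fanned out to per-stage seeds through a fixed stage-name hash, so any
stage can be re-run in isolation reproducibly; two runs with the same config
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import assembly as asm
from . import classify as cls
from . import io as sio
from . import pcr as pcrmod
from . import screen as scr
from . import synthetic as syn

logger = logging.getLogger("sexmark")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Parameters for a full run; round-trips losslessly through YAML."""

    seed: int = 0
    genome: syn.GenomeModel = field(default_factory=syn.GenomeModel)
    reads: syn.ReadSimConfig = field(default_factory=syn.ReadSimConfig)
    trim: scr.TrimParams = field(default_factory=scr.TrimParams)
    screen: scr.KmerScreenParams = field(default_factory=scr.KmerScreenParams)
    assembly: asm.AssemblyParams = field(default_factory=asm.AssemblyParams)
    rescue_ratio: float = 2.0
    min_candidate_length: int = 100
    pcr: pcrmod.PcrParams = field(default_factory=pcrmod.PcrParams)
    panel: syn.PanelSpec = field(default_factory=syn.PanelSpec)
    # coordinates (start, product size) of the demonstration primer pair cut
    # from the planted MSR; primers are otherwise user inputs
    demo_primer_start: int = 1000
    demo_primer_product: int = 400
    demo_primer_length: int = 20

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls_, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        nested = {
            "genome": syn.GenomeModel,
            "reads": syn.ReadSimConfig,
            "trim": scr.TrimParams,
            "screen": scr.KmerScreenParams,
            "assembly": asm.AssemblyParams,
            "pcr": pcrmod.PcrParams,
            "panel": syn.PanelSpec,
        }
        kwargs: dict[str, Any] = {}
        valid = set(cls_.__dataclass_fields__)
        for key, value in data.items():
            if key not in valid:
                raise ValueError(f"unknown config key: {key!r}")
            if key in nested and isinstance(value, dict):
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls_(**kwargs)

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls_.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)


@dataclass
class RunManifest:
    seed: int
    parameters: dict[str, Any]
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, files: dict[str, Path], counts: dict[str, int]) -> None:
        self.stages[stage] = {
            "files": {
                key: {"path": str(path), "sha256": _sha256(path)}
                for key, path in files.items()
            },
            "counts": counts,
            "wall_seconds": round(time.monotonic() - self._stage_start, 3),
        }

    def start_stage(self) -> None:
        self._stage_start = time.monotonic()

    def write(self, path: Path) -> None:
        with open(path, "w") as handle:
            json.dump({"seed": self.seed, "parameters": self.parameters, "stages": self.stages}, handle, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def demo_primer_pair(config: RunConfig, msr: str) -> pcrmod.PrimerPair:
    """Primer pair cut from fixed coordinates of the planted MSR.

    Not a primer-design algorithm: the pair simply brackets a
    ``demo_primer_product``-sized window so the downstream PCR stage has an
    input when the user supplies none.
    """
    start = config.demo_primer_start
    plen = config.demo_primer_length
    size = config.demo_primer_product
    if start + size > len(msr):
        raise ValueError("demo primer window exceeds the MSR length")
    forward = msr[start : start + plen]
    reverse = sio.revcomp(msr[start + size - plen : start + size])
    return pcrmod.PrimerPair("demo", forward, reverse, expected_size=size)


def recovery_trial(
    seed: int,
    genome: syn.GenomeModel | None = None,
    coverage: float = 30.0,
    screen_params: scr.KmerScreenParams | None = None,
    assembly_params: asm.AssemblyParams | None = None,
    rescue_ratio: float = 2.0,
) -> dict[str, float]:
    """One in-memory simulate -> screen -> assemble -> classify trial.

    Measures how well the screen recovers the planted male-specific region
    (MSR) and whether it stays sound on the shared background. Returned keys:

    - ``n_msks``, ``false_msks``: MSK count and the number of MSKs present in
      the (circularized) female genome or absent from the male genome —
      sampling-dropout artifacts of finite pool depth.
    - ``msr_covered_fraction``: fraction of planted MSR bases contained in
      scaffolds labeled MALE_SPECIFIC or RESCUED_MALE_SPECIFIC.
    - ``autosomal_male_specific``: scaffolds that are pure substrings of the
      shared background yet labeled MALE_SPECIFIC (should be 0).
    """
    genome = genome or syn.GenomeModel()
    screen_params = screen_params or scr.KmerScreenParams()
    assembly_params = assembly_params or asm.AssemblyParams()
    model = syn.GenomeModel(**{**asdict(genome), "seed": stage_seed(seed, "genomes")})
    genomes = syn.simulate_genomes(model)
    pools = {}
    for pool, refs, weights in (
        ("male", genomes.male, genomes.male_weights),
        ("female", genomes.female, genomes.female_weights),
    ):
        cfg = syn.ReadSimConfig(coverage=coverage, seed=stage_seed(seed, f"reads:{pool}"))
        pools[pool] = syn.simulate_pool_reads(refs, cfg, weights, name_prefix=f"{pool}_")

    _, msks, candidates = scr.run_screen(pools["male"], pools["female"], screen_params)

    def _space(seqs: list[tuple[str, str]]) -> str:
        # circularized both-strand k-mer space, matching the read sampling
        parts = []
        for _, s in seqs:
            circ = s + s[: screen_params.k - 1]
            parts.extend((circ, sio.revcomp(circ)))
        return " ".join(parts)

    male_space, female_space = _space(genomes.male), _space(genomes.female)
    false_msks = sum(1 for km in msks if km in female_space or km not in male_space)

    scaffolds = asm.assemble(sio.mates(candidates), assembly_params) if candidates else []
    if scaffolds:
        profiles = cls.profile_coverage(
            sio.mates(pools["male"]), sio.mates(pools["female"]), scaffolds
        )
        reports = cls.classify_scaffolds(scaffolds, profiles, rescue_ratio)
    else:
        reports = []

    msr = genomes.male_sequence(syn.MSR_ID)
    msr_circ = msr + msr  # doubled: catches any rotation of the circular unitig
    covered = [False] * len(msr)
    background = _space(genomes.female)
    autosomal_male_specific = 0
    for report in reports:
        seq = report.scaffold.sequence
        if report.label is cls.Label.PENDING:
            continue
        hit = False
        for query in (seq, sio.revcomp(seq)):
            pos = msr_circ.find(query)
            while pos != -1:
                hit = True
                for i in range(pos, pos + len(query)):
                    covered[i % len(msr)] = True
                pos = msr_circ.find(query, pos + 1)
        if (
            not hit
            and report.label is cls.Label.MALE_SPECIFIC
            and (seq in background or sio.revcomp(seq) in background)
        ):
            autosomal_male_specific += 1
    return {
        "n_msks": len(msks),
        "false_msks": false_msks,
        "msr_covered_fraction": sum(covered) / len(msr),
        "autosomal_male_specific": autosomal_male_specific,
        "n_scaffolds": len(scaffolds),
        "candidate_pairs": len(candidates),
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute the full synthetic workflow and write all stage outputs.

    Stages: genome simulation, pooled read simulation, quality trim + k-mer
    screen, unitig assembly of MSK-bearing pairs, zero-mismatch map-back and
    depth classification, panel simulation + in-silico PCR scoring. Fails
    fast with the stage name on error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.seed, config.to_dict())
    stage = "config"
    try:
        # ---------------- simulate
        stage = "simulate"
        manifest.start_stage()
        logger.info("stage=%s simulating genomes and pools", stage)
        genome_model = syn.GenomeModel(
            **{**asdict(config.genome), "seed": stage_seed(config.seed, "genomes")}
        )
        genomes = syn.simulate_genomes(genome_model)
        sim_dir = outdir / "sim"
        sim_dir.mkdir(exist_ok=True)
        f_fa = sim_dir / "female_genome.fasta"
        m_fa = sim_dir / "male_genome.fasta"
        sio.write_fasta(f_fa, genomes.female)
        sio.write_fasta(m_fa, genomes.male)

        pools: dict[str, list[sio.ReadPair]] = {}
        pool_files: dict[str, Path] = {"female_genome": f_fa, "male_genome": m_fa}
        counts: dict[str, int] = {}
        for pool, refs, weights in (
            ("male", genomes.male, genomes.male_weights),
            ("female", genomes.female, genomes.female_weights),
        ):
            cfg = syn.ReadSimConfig(
                **{**asdict(config.reads), "seed": stage_seed(config.seed, f"reads:{pool}")}
            )
            pairs = syn.simulate_pool_reads(refs, cfg, weights, name_prefix=f"{pool}_")
            pools[pool] = pairs
            r1, r2 = sim_dir / f"{pool}_R1.fastq", sim_dir / f"{pool}_R2.fastq"
            sio.write_fastq_pairs(r1, r2, pairs)
            pool_files[f"{pool}_R1"], pool_files[f"{pool}_R2"] = r1, r2
            counts[f"{pool}_pairs"] = len(pairs)
        manifest.record(stage, pool_files, counts)

        # ---------------- screen
        stage = "screen"
        manifest.start_stage()
        logger.info("stage=%s trimming and counting k-mers", stage)
        male_trimmed = scr.quality_trim(pools["male"], config.trim)
        female_trimmed = scr.quality_trim(pools["female"], config.trim)
        table = scr.count_pool_kmers(
            list(sio.mates(male_trimmed)), list(sio.mates(female_trimmed)), config.screen
        )
        filtered, msks = scr.filter_and_select_msks(table, config.screen)
        candidates = scr.extract_candidate_read_pairs(male_trimmed, msks, config.screen)

        screen_dir = outdir / "screen"
        screen_dir.mkdir(exist_ok=True)
        table_tsv = screen_dir / "kmer_table.tsv"
        pd.DataFrame(
            [(k, m, f) for k, (m, f) in sorted(filtered.items())],
            columns=["kmer", "male_count", "female_count"],
        ).to_csv(table_tsv, sep="\t", index=False)
        msk_txt = screen_dir / "msks.txt"
        msk_txt.write_text("".join(f"{k}\n" for k in sorted(msks)))
        cand_r1, cand_r2 = screen_dir / "candidates_R1.fastq", screen_dir / "candidates_R2.fastq"
        sio.write_fastq_pairs(cand_r1, cand_r2, candidates)
        manifest.record(
            stage,
            {"kmer_table": table_tsv, "msks": msk_txt, "candidates_R1": cand_r1, "candidates_R2": cand_r2},
            {
                "male_pairs_trimmed": len(male_trimmed),
                "female_pairs_trimmed": len(female_trimmed),
                "kmers_filtered": len(filtered),
                "msks": len(msks),
                "candidate_pairs": len(candidates),
                "candidate_reads": 2 * len(candidates),
            },
        )

        # ---------------- assemble
        stage = "assemble"
        manifest.start_stage()
        logger.info("stage=%s assembling %d candidate pairs", stage, len(candidates))
        asm_dir = outdir / "assembly"
        asm_dir.mkdir(exist_ok=True)
        if candidates:
            scaffolds = asm.assemble(sio.mates(candidates), config.assembly)
        else:
            scaffolds = []
        scaffolds_fa = asm_dir / "scaffolds.fasta"
        sio.write_fasta(scaffolds_fa, [(s.id, s.sequence) for s in scaffolds])
        stats = asm.assembly_stats(scaffolds)
        stats_tsv = asm_dir / "assembly_stats.tsv"
        pd.DataFrame([stats]).to_csv(stats_tsv, sep="\t", index=False)
        manifest.record(stage, {"scaffolds": scaffolds_fa, "stats": stats_tsv}, stats)

        # ---------------- classify
        stage = "classify"
        manifest.start_stage()
        logger.info("stage=%s mapping pools back to %d scaffolds", stage, len(scaffolds))
        cls_dir = outdir / "classify"
        cls_dir.mkdir(exist_ok=True)
        if scaffolds:
            profiles = cls.profile_coverage(
                sio.mates(pools["male"]), sio.mates(pools["female"]), scaffolds
            )
            reports = cls.classify_scaffolds(scaffolds, profiles, config.rescue_ratio)
        else:
            reports = []
        report_tsv = cls_dir / "scaffold_report.tsv"
        cls.report_table(reports).to_csv(report_tsv, sep="\t", index=False)
        male_candidates = cls.filter_candidates(reports, config.min_candidate_length)
        cand_fa = cls_dir / "candidates.fasta"
        sio.write_fasta(cand_fa, [(s.id, s.sequence) for s in male_candidates])
        label_counts = {
            label.value: sum(r.label is label for r in reports) for label in cls.Label
        }
        manifest.record(
            stage,
            {"report": report_tsv, "candidates": cand_fa},
            {**label_counts, "candidates": len(male_candidates)},
        )

        # ---------------- pcr
        stage = "pcr"
        manifest.start_stage()
        logger.info("stage=%s simulating panel and scoring", stage)
        pcr_dir = outdir / "pcr"
        pcr_dir.mkdir(exist_ok=True)
        msr = genomes.male_sequence(syn.MSR_ID)
        pair = demo_primer_pair(config, msr)
        background = dict(genomes.female)[syn.AUTOSOME_ID]
        panel_spec = syn.PanelSpec(
            **{**asdict(config.panel), "seed": stage_seed(config.seed, "panel")}
        )
        templates, truth = syn.simulate_panel(msr, background, panel_spec)
        templates_fa = pcr_dir / "panel_templates.fasta"
        sio.write_fasta(
            templates_fa,
            [(f"{ind}|{seq_id}", seq) for ind, seqs in templates.items() for seq_id, seq in seqs],
        )
        calls = {
            ind: pcrmod.call_sex(seqs, pair, config.pcr) for ind, seqs in templates.items()
        }
        result = pcrmod.score_panel(calls, truth)
        panel_tsv = pcr_dir / "panel_report.tsv"
        result.rows.to_csv(panel_tsv, sep="\t", index=False)
        cont_tsv = pcr_dir / "contingency.tsv"
        result.contingency.to_csv(cont_tsv, sep="\t", index=False)
        truth_tsv = pcr_dir / "truth.tsv"
        truth.to_csv(truth_tsv, sep="\t", index=False)
        manifest.record(
            stage,
            {
                "panel_report": panel_tsv,
                "contingency": cont_tsv,
                "truth": truth_tsv,
                "panel_templates": templates_fa,
            },
            {"panel_n": result.n, "accuracy_percent_x100": int(round(result.accuracy_rate * 100))},
        )
        manifest.stages[stage]["accuracy_rate"] = result.accuracy_rate
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest.write(outdir / "manifest.json")
    return manifest
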