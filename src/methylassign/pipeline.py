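"""End-to-end assignment protocol.

prep (filter + type attribution) -> three batches of independent
optimization runs with distance cutoffs d_cut - 0.5, d_cut, d_cut + 0.5
-> consensus consolidation -> optional evaluation against a reference
shift list -> report files (consol.prot, consol.tab, flya.txt).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assign import (
    OptimizerConfig,
    RunResult,
    compile_problem,
    derive_run_shifts,
    evolve,
)
from .consensus import (
    ConsensusConfig,
    EvaluationReport,
    consolidate,
    evaluate_vs_reference,
    explained_fraction,
    write_reports,
)
from .expected import (
    EXPERIMENTS,
    GenerationConfig,
    generate_expected_geminal,
    generate_expected_hmqc,
    generate_expected_noesy,
)
from .geometry import MethylGroup, extract_methyl_groups, read_pdb
from .peaklists import PeakList, ShiftList, read_peaklist, read_sequence, read_shifts
from .prep import ResidueTyping, Tolerances, attribute_noesy_types, filter_noesy

logger = logging.getLogger("methylassign")

__all__ = ["PipelineConfig", "PipelineResult", "run_protocol_on_dataset",
           "run_full_protocol"]


@dataclass
class PipelineConfig:
    """All protocol parameters in one place (YAML-loadable)."""

    d_cut: float = 5.0
    p_noe: float = 0.1
    single_cutoff: bool = False
    filter_min_sn: float | None = None  # None: use the peak list as given
    include_geminal_noes: bool = True
    include_diagonal: bool = False
    consensus_threshold: float = 0.8
    k_alternatives: int = 3
    labeling: str = "AILV"
    tolerances: Tolerances = field(default_factory=Tolerances)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 0
    n_jobs: int = 1
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        opt = OptimizerConfig(**raw.pop("optimizer", {}))
        tol = Tolerances(**raw.pop("tolerances", {}))
        cfg = cls(**raw)
        cfg.optimizer = opt
        cfg.tolerances = tol
        return cfg

    def cutoffs(self) -> list[float]:
        if self.single_cutoff:
            return [self.d_cut]
        return [self.d_cut - 0.5, self.d_cut, self.d_cut + 0.5]


@dataclass
class PipelineResult:
    consensus: list
    run_batches: list[list[RunResult]]
    explained: float
    evaluation: EvaluationReport | None
    peaklist_stats: dict[str, tuple[int, int, float]]

    @property
    def strong(self):
        return [a for a in self.consensus if a.strong]


def _one_run(problem, opt: OptimizerConfig, seed: int) -> RunResult:
    state = evolve(problem, opt, np.random.default_rng(seed))
    return derive_run_shifts(problem, state)


def _run_batches(
    methyls: list[MethylGroup],
    hmqc: PeakList,
    noesy_lists: dict,
    geminal: PeakList | None,
    typing: ResidueTyping,
    config: PipelineConfig,
) -> tuple[list[list[RunResult]], dict]:
    opt = config.optimizer
    opt = dataclasses.replace(opt, tolerances=config.tolerances)
    exp_name = (noesy_lists and next(iter(noesy_lists.values())).experiment) or ""
    exp = EXPERIMENTS.get(exp_name.split("_")[0], EXPERIMENTS["CCNOESY"])

    batches: list[list[RunResult]] = []
    stats: dict[str, tuple[int, int, float]] = {}
    run_counter = 0
    for cutoff in config.cutoffs():
        gen = GenerationConfig(
            d_cut=cutoff,
            p_noe=config.p_noe,
            include_geminal_noes=config.include_geminal_noes,
            include_diagonal=config.include_diagonal,
        )
        expected = generate_expected_noesy(methyls, gen, exp)
        expected_gem = generate_expected_geminal(methyls) if geminal else None
        problem = compile_problem(
            methyls, expected, hmqc, noesy_lists, typing,
            tolerances=config.tolerances, expected_geminal=expected_gem,
            geminal_list=geminal, lambda_degen=opt.lambda_degen,
        )
        seeds = [config.seed + run_counter + k for k in range(opt.runs_per_cutoff)]
        run_counter += opt.runs_per_cutoff
        logger.info(
            "cutoff %.2f A: %d expected NOESY peaks, %d runs (seeds %d..%d)",
            cutoff, len(expected), len(seeds), seeds[0], seeds[-1],
        )
        if config.n_jobs > 1:
            from joblib import Parallel, delayed

            batch = Parallel(n_jobs=config.n_jobs)(
                delayed(_one_run)(problem, opt, s) for s in seeds
            )
        else:
            batch = [_one_run(problem, opt, s) for s in seeds]
        batches.append(list(batch))
        if cutoff == config.d_cut or len(config.cutoffs()) == 1:
            n_assigned = float(np.mean([np.sum(r.anchors >= 0) for r in batch]))
            stats["C13HSQC"] = (len(methyls), len(hmqc), n_assigned)
            n_mapped = float(np.mean([len(r.mapped_noe_peaks) for r in batch]))
            n_meas = sum(len(pl) for pl in noesy_lists.values())
            stats[exp.name] = (len(expected), n_meas, n_mapped)
            if geminal is not None and expected_gem is not None:
                stats["HCcCH"] = (len(expected_gem), len(geminal), float("nan"))
    return batches, stats


def _assemble(
    methyls, hmqc, noesy, geminal, typing, config, reference
) -> PipelineResult:
    if config.filter_min_sn is not None:
        before = len(noesy)
        noesy = filter_noesy(noesy, config.filter_min_sn, config.tolerances)
        logger.info("NOESY filter: %d -> %d peaks", before, len(noesy))
    noesy_lists = attribute_noesy_types(noesy, hmqc, typing, config.tolerances)
    batches, stats = _run_batches(methyls, hmqc, noesy_lists, geminal, typing,
                                  config)
    cons_cfg = ConsensusConfig(
        threshold=config.consensus_threshold,
        k_alternatives=config.k_alternatives,
        tolerances=config.tolerances,
    )
    consensus = consolidate(batches, methyls, cons_cfg)
    all_runs = [r for b in batches for r in b]
    explained = explained_fraction(all_runs)
    evaluation = None
    if reference is not None:
        evaluation = evaluate_vs_reference(
            consensus, reference, methyls, config.tolerances, explained
        )
    result = PipelineResult(
        consensus=consensus, run_batches=batches, explained=explained,
        evaluation=evaluation, peaklist_stats=stats,
    )
    if config.out_dir:
        write_reports(consensus, config.out_dir, stats, evaluation)
        _write_evaluation_tsv(result, Path(config.out_dir))
    return result


def _write_evaluation_tsv(result: PipelineResult, out: Path) -> None:
    lines = ["metric\tvalue"]
    lines.append(f"strong\t{len(result.strong)}")
    if result.evaluation is not None:
        lines.append(f"correct\t{result.evaluation.n_correct}")
        lines.append(f"erroneous\t{result.evaluation.n_erroneous}")
        lines.append(f"no_reference\t{result.evaluation.n_no_reference}")
    lines.append(f"explained_noe_fraction\t{result.explained:.4f}")
    (out / "evaluation.tsv").write_text("\n".join(lines) + "\n")


def run_protocol_on_dataset(dataset, config: PipelineConfig) -> PipelineResult:
    """Run the full protocol on an in-memory (synthetic) dataset."""
    return _assemble(
        dataset.methyls, dataset.hmqc, dataset.noesy, dataset.geminal,
        dataset.typing, config, dataset.reference_shifts(),
    )


def run_full_protocol(
    structure_path,
    sequence_path,
    hmqc_path,
    noesy_path,
    config: PipelineConfig,
    geminal_path=None,
    typing: ResidueTyping | None = None,
    reference_path=None,
    peak_format: str = "xeasy",
) -> PipelineResult:
    """File-based entry point: read inputs, validate, run, write reports.

    Input consistency (sequence vs structure residue types) is checked
    before any optimization starts.
    """
    structure = read_pdb(structure_path)
    sequence = read_sequence(sequence_path)
    methyls = extract_methyl_groups(structure, sequence, config.labeling)
    if not methyls:
        raise ValueError("no labeled methyl groups found")
    hmqc = read_peaklist(hmqc_path, peak_format)
    noesy = read_peaklist(noesy_path, peak_format)
    geminal = read_peaklist(geminal_path, peak_format) if geminal_path else None
    if typing is None:
        # no typing information: every peak may belong to any labeled type
        from .geometry import parse_labeling_scheme

        letters = frozenset(parse_labeling_scheme(config.labeling))
        typing = ResidueTyping(labels={p.id: letters for p in hmqc.peaks})
    reference = read_shifts(reference_path) if reference_path else None
    if config.out_dir:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(Path(config.out_dir) / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
        try:
            logger.info("config: %s", config)
            return _assemble(methyls, hmqc, noesy, geminal, typing, config,
                             reference)
        finally:
            logger.removeHandler(handler)
    return _assemble(methyls, hmqc, noesy, geminal, typing, config, reference)
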