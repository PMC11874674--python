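"""End-to-end orchestration: genotypes + haplotypes in, scenarios out."""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import Config
from .genodata import GenotypeTable, HaplotypeTable, split_by_clutch
from .matriline_overlay import SexedParentage, resolve_parent_sexes
from .parentage_reconstruction import ParentageSolution, min_parent_search
from .popgen_stats import AlleleFrequencies, allele_frequencies
from .scenario_report import (
    MIN_TESTABLE_SIZE,
    DatasetSummary,
    MatingScenario,
    classify_scenario,
    summarize_dataset,
)


@dataclass
class PipelineResult:
    solutions: list[ParentageSolution]
    sexed: dict[str, SexedParentage]
    scenarios: dict[str, MatingScenario]
    summary: DatasetSummary
    freqs: AlleleFrequencies


def run_pipeline(
    gt: GenotypeTable,
    ht: HaplotypeTable | None = None,
    config: Config | None = None,
    screening_counts: tuple[int, int] | None = None,
) -> PipelineResult:
    """Reconstruct every clutch, sex the parents, classify mating patterns.

    Clutches below the testable size (three embryos) are reconstructed for
    bookkeeping but never classified into a mating pattern.
    """
    cfg = config or Config()
    adults = gt.adult_ids
    if adults:
        freqs = allele_frequencies(gt, subset=adults)
    else:
        freqs = allele_frequencies(gt)

    solutions: list[ParentageSolution] = []
    sexed: dict[str, SexedParentage] = {}
    scenarios: dict[str, MatingScenario] = {}
    for clutch in split_by_clutch(gt):
        sol = min_parent_search(
            gt,
            clutch.embryo_ids,
            clutch_id=clutch.clutch_id,
            exact_cap=cfg.exact_cap,
            seed=cfg.seed,
            mismatch_budget=cfg.mismatch_budget,
            freqs=freqs,
        )
        solutions.append(sol)
        if ht is not None:
            sp = resolve_parent_sexes(sol, ht)
            sexed[clutch.clutch_id] = sp
            if clutch.size >= MIN_TESTABLE_SIZE and not sp.unsexed:
                scenarios[clutch.clutch_id] = classify_scenario(sp)
    summary = summarize_dataset(solutions, scenarios, screening_counts)
    return PipelineResult(
        solutions=solutions,
        sexed=sexed,
        scenarios=scenarios,
        summary=summary,
        freqs=freqs,
    )
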