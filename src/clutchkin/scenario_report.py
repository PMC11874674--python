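"""Mating-pattern classification and dataset-level reporting.

A sexed parentage maps onto one of five mating patterns — monogamous (1 dam,
1 sire), polyandrous (1 dam, several sires), polygynous (several dams, 1
sire), two separate monogamous pairs, or polygynandrous (several of each with
at least one shared parent) — each carrying an inference about whether the
clutch reflects a lone pair, a spawning group, or consecutive pair
intrusions.  Clutches of one or two embryos are never classified: any two
embryo genotypes can be explained by a single parent pair, so only clutches
with three or more embryos are testable for multiple parentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .matriline_overlay import SexedParentage
from .parentage_reconstruction import ParentageSolution

__all__ = [
    "MatingScenario",
    "DatasetSummary",
    "classify_scenario",
    "summarize_dataset",
    "render_report",
    "MIN_TESTABLE_SIZE",
]

MIN_TESTABLE_SIZE = 3

PATTERNS = ["monogamous", "polyandrous", "polygynous", "two_pairs", "polygynandrous"]

_INFERENCE = {
    "monogamous": "Pair spawning, or one reproducing pair within a spawning group",
    "polyandrous": "Spawning group (one female, several males)",
    "polygynous": "Spawning group (one male, several females)",
    "two_pairs": "Spawning group, or consecutive pair spawnings on the same host",
    "polygynandrous": "Spawning group with shared maternity and paternity",
}

_INTRO_SCENARIO = {
    "monogamous": 1,
    "polyandrous": 2,
    "polygynous": 3,
    "two_pairs": 4,
    "polygynandrous": 4,
}


@dataclass
class MatingScenario:
    pattern: str
    inference: str
    intro_scenario: int
    n_dams: int
    n_sires: int
    secondary_pattern: str | None = None  # carried when the sexing is ambiguous


def _pattern_of(n_dams: int, n_sires: int, any_shared: bool) -> str:
    if n_dams == 1 and n_sires == 1:
        return "monogamous"
    if n_dams == 1:
        return "polyandrous"
    if n_sires == 1:
        return "polygynous"
    return "polygynandrous" if any_shared else "two_pairs"


def classify_scenario(sp: SexedParentage) -> MatingScenario:
    """Map a sexed parentage onto a mating pattern.

    Ambiguity in the sexing (e.g. a shared parent linking same-haplotype
    groups) propagates as ``secondary_pattern`` when the recorded alternative
    implies a different pattern.
    """
    if sp.unsexed:
        raise ValueError(f"clutch {sp.clutch_id}: parentage is unsexed")
    any_shared = bool(sp.sharing)
    pattern = _pattern_of(sp.n_dams, sp.n_sires, any_shared)
    secondary = None
    for alt in sp.alternatives:
        alt_shared = bool(alt.shared_roles)
        alt_pattern = _pattern_of(alt.n_dams, alt.n_sires, alt_shared)
        if alt_pattern != pattern:
            secondary = alt_pattern
            break
    return MatingScenario(
        pattern=pattern,
        inference=_INFERENCE[pattern],
        intro_scenario=_INTRO_SCENARIO[pattern],
        n_dams=sp.n_dams,
        n_sires=sp.n_sires,
        secondary_pattern=secondary,
    )


@dataclass
class DatasetSummary:
    n_clutches: int
    n_testable: int
    pattern_counts: dict[str, int]
    n_multi_parent: int
    fraction_multi_parent: float | None
    median_testable_size: float | None
    size_range: tuple[int, int] | None
    prevalence_percent: int | None


def summarize_dataset(
    solutions: list[ParentageSolution],
    scenarios: dict[str, MatingScenario] | None = None,
    screening_counts: tuple[int, int] | None = None,
) -> DatasetSummary:
    """Dataset-level bookkeeping over per-clutch solutions.

    ``screening_counts`` is ``(n_parasitised, n_screened)`` from the field
    effort; prevalence is reported as the nearest integer percent.
    """
    if not solutions:
        raise ValueError("no solutions to summarise")
    sizes = {s.clutch_id: s.n_embryos for s in solutions}
    testable = [s for s in solutions if sizes[s.clutch_id] >= MIN_TESTABLE_SIZE]
    pattern_counts = {p: 0 for p in PATTERNS}
    if scenarios:
        for s in testable:
            sc = scenarios.get(s.clutch_id)
            if sc is not None:
                pattern_counts[sc.pattern] += 1
    n_multi = sum(1 for s in testable if s.n_parents_min >= 3)
    t_sizes = sorted(sizes[s.clutch_id] for s in testable)
    if t_sizes:
        mid = len(t_sizes) // 2
        median = (
            float(t_sizes[mid])
            if len(t_sizes) % 2
            else (t_sizes[mid - 1] + t_sizes[mid]) / 2.0
        )
        rng = (t_sizes[0], t_sizes[-1])
        frac = n_multi / len(t_sizes)
    else:
        median, rng, frac = None, None, None
    prevalence = None
    if screening_counts is not None:
        n_para, n_screen = screening_counts
        prevalence = round(100.0 * n_para / n_screen)
    return DatasetSummary(
        n_clutches=len(solutions),
        n_testable=len(testable),
        pattern_counts=pattern_counts,
        n_multi_parent=n_multi,
        fraction_multi_parent=frac,
        median_testable_size=median,
        size_range=rng,
        prevalence_percent=prevalence,
    )


def render_report(
    summary: DatasetSummary,
    solutions: list[ParentageSolution],
    sexed: dict[str, SexedParentage],
    scenarios: dict[str, MatingScenario],
    out_dir,
) -> list[Path]:
    """Write deterministic TSV + text reports; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out / "clutch_parentage.tsv"
    with open(p, "w") as fh:
        fh.write(
            "clutch_id\tn_embryos\tn_parents_min\tn_dams\tn_sires\tpattern\t"
            "secondary_pattern\texact\tn_alternates\n"
        )
        for s in sorted(solutions, key=lambda s: s.clutch_id):
            sp = sexed.get(s.clutch_id)
            sc = scenarios.get(s.clutch_id)
            fh.write(
                "\t".join(
                    [
                        s.clutch_id,
                        str(s.n_embryos),
                        str(s.n_parents_min),
                        str(sp.n_dams) if sp else "NA",
                        str(sp.n_sires) if sp else "NA",
                        sc.pattern if sc else "untestable",
                        (sc.secondary_pattern or "") if sc else "",
                        str(s.exact),
                        str(len(s.alternates)),
                    ]
                )
                + "\n"
            )
    paths.append(p)

    p = out / "embryo_assignments.tsv"
    with open(p, "w") as fh:
        fh.write("clutch_id\tembryo_id\tdam\tsire\n")
        for s in sorted(solutions, key=lambda s: s.clutch_id):
            sp = sexed.get(s.clutch_id)
            for g in s.partition.groups:
                for m in sorted(g.members):
                    dam = sp.dam_of.get(m, "NA") if sp else "NA"
                    sire = sp.sire_of.get(m, "NA") if sp else "NA"
                    fh.write(f"{s.clutch_id}\t{m}\t{dam}\t{sire}\n")
    paths.append(p)

    p = out / "pattern_summary.tsv"
    with open(p, "w") as fh:
        fh.write("pattern\tn_clutches\n")
        for pat in PATTERNS:
            fh.write(f"{pat}\t{summary.pattern_counts.get(pat, 0)}\n")
    paths.append(p)

    p = out / "summary.txt"
    lines = [
        f"clutches analysed: {summary.n_clutches}",
        f"testable clutches (>= {MIN_TESTABLE_SIZE} embryos): {summary.n_testable}",
        f"multi-parent clutches: {summary.n_multi_parent}"
        + (
            f" ({100 * summary.fraction_multi_parent:.0f}% of testable)"
            if summary.fraction_multi_parent is not None
            else " (fraction undefined: no testable clutches)"
        ),
        (
            f"median testable clutch size: {summary.median_testable_size:g} "
            f"(range {summary.size_range[0]}-{summary.size_range[1]})"
            if summary.median_testable_size is not None
            else "median testable clutch size: NA"
        ),
    ]
    if summary.prevalence_percent is not None:
        lines.append(f"parasitism prevalence: {summary.prevalence_percent}%")
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)
    return paths
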