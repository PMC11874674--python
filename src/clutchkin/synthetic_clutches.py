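"""Mendelian clutch simulator with ground truth.

Generates genotype tables, mtDNA haplotype assignments and a pedigree truth
record with the statistical structure the analysis assumes: a microsatellite
panel of 17 loci spanning 4-22 alleles with expected heterozygosities between
roughly 0.33 and 0.93, a maternal haplotype pool with diversity near 0.89, an
adult reference sample (default 81 individuals) drawn from the same
population, and clutches of 1-14 embryos produced under monogamous,
polyandrous, polygynous, two-pair or polygynandrous matings.  Optional
genotyping error applies allelic dropout, mistyping and missingness after
meiosis.  Everything is driven by one seed: identical seeds give
byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genodata import ROLE_ADULT, ROLE_EMBRYO, GenotypeTable, HaplotypeTable, make_genotype_table
from .reference import MARKER_PANEL

__all__ = [
    "LocusModel",
    "PopulationModel",
    "Mating",
    "ClutchDesign",
    "MatingDesign",
    "ErrorModel",
    "TruthRecord",
    "build_population",
    "mate",
    "generate_dataset",
    "default_panel",
    "default_mt_pool",
    "study_like_design",
    "random_clutch_design",
]


@dataclass(frozen=True)
class LocusModel:
    """One simulated locus: allele count and a frequency scheme.

    Schemes: ``equifrequent``; ``dirichlet`` (symmetric, concentration
    ``param``); ``target_He`` (one major allele plus equifrequent minors, the
    major frequency solved so that ``1 - sum p^2`` hits ``param``).
    """

    name: str
    n_alleles: int
    scheme: str = "equifrequent"
    param: float | None = None
    size_start: int = 100
    repeat: int = 2

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise ValueError(f"{self.name}: need >= 2 alleles")
        if self.scheme == "target_He":
            he_max = 1.0 - 1.0 / self.n_alleles
            if self.param is None or not (0.0 < self.param <= he_max + 1e-12):
                raise ValueError(
                    f"{self.name}: target He {self.param} infeasible for "
                    f"{self.n_alleles} alleles (max {he_max:.4f})"
                )


def _major_minor_freqs(k: int, target_sum_p2: float) -> np.ndarray:
    """One major allele at q, k-1 equifrequent minors, with sum p^2 = target.

    Closed form: q solves q^2 + (1-q)^2/(k-1) = s, taking the root >= 1/k.
    """
    a = k / (k - 1)
    b = -2.0 / (k - 1)
    c = 1.0 / (k - 1) - target_sum_p2
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(f"sum p^2 = {target_sum_p2} unreachable with k = {k}")
    q = (-b + math.sqrt(disc)) / (2 * a)
    q = min(max(q, 1.0 / k), 1.0 - 1e-9)
    p = np.full(k, (1.0 - q) / (k - 1))
    p[0] = q
    return p


@dataclass(frozen=True)
class PopulationModel:
    loci: tuple[LocusModel, ...]
    mt_labels: tuple[str, ...]
    mt_freqs: tuple[float, ...]
    n_adult_reference: int = 81

    def __post_init__(self) -> None:
        if abs(sum(self.mt_freqs) - 1.0) > 1e-9:
            raise ValueError("mt pool frequencies must sum to 1")


@dataclass
class PopulationState:
    """Realised per-locus allele sizes and frequencies, plus the mt pool."""

    allele_sizes: dict[str, np.ndarray]
    allele_freqs: dict[str, np.ndarray]
    mt_labels: tuple[str, ...]
    mt_freqs: np.ndarray

    def freq_maps(self) -> dict[str, dict[int, float]]:
        return {
            loc: {int(a): float(p) for a, p in zip(self.allele_sizes[loc], self.allele_freqs[loc])}
            for loc in self.allele_sizes
        }


def default_panel() -> tuple[LocusModel, ...]:
    """A 17-locus panel with the published allele counts and He targets."""
    loci = []
    for i, (name, _motif, _n, na, size_range, _ho, he, _p) in enumerate(MARKER_PANEL):
        he_max = 1.0 - 1.0 / na
        loci.append(
            LocusModel(
                name=name,
                n_alleles=na,
                scheme="target_He",
                param=min(he, he_max - 1e-6),
                size_start=size_range[0],
            )
        )
    return tuple(loci)


def default_mt_pool(k: int = 13, target_hd: float = 0.89):
    """A maternal haplotype pool whose diversity matches the field estimate."""
    p = _major_minor_freqs(k, 1.0 - target_hd)
    labels = tuple(f"Mt{i + 1}" for i in range(k))
    return labels, tuple(float(x) for x in p)


def default_population(n_adult_reference: int = 81) -> PopulationModel:
    labels, freqs = default_mt_pool()
    return PopulationModel(
        loci=default_panel(),
        mt_labels=labels,
        mt_freqs=freqs,
        n_adult_reference=n_adult_reference,
    )


def build_population(model: PopulationModel, rng: np.random.Generator) -> PopulationState:
    """Realise per-locus frequencies from the model's schemes."""
    sizes: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    for lm in model.loci:
        k = lm.n_alleles
        sizes[lm.name] = lm.size_start + lm.repeat * np.arange(k)
        if lm.scheme == "equifrequent":
            p = np.full(k, 1.0 / k)
        elif lm.scheme == "dirichlet":
            alpha = lm.param if lm.param is not None else 1.0
            p = rng.dirichlet(np.full(k, alpha))
        elif lm.scheme == "target_He":
            p = _major_minor_freqs(k, 1.0 - float(lm.param))
        else:
            raise ValueError(f"unknown scheme {lm.scheme!r}")
        freqs[lm.name] = p
    return PopulationState(
        allele_sizes=sizes,
        allele_freqs=freqs,
        mt_labels=model.mt_labels,
        mt_freqs=np.array(model.mt_freqs),
    )


def _draw_genotype(pop: PopulationState, rng) -> dict[str, tuple[int, int]]:
    g = {}
    for loc, sizes in pop.allele_sizes.items():
        pair = rng.choice(sizes, size=2, p=pop.allele_freqs[loc])
        g[loc] = (int(min(pair)), int(max(pair)))
    return g


# ---------------------------------------------------------------------------
# Designs


@dataclass(frozen=True)
class Mating:
    dam_id: str
    sire_id: str
    n_offspring: int

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")


@dataclass(frozen=True)
class ClutchDesign:
    clutch_id: str
    matings: tuple[Mating, ...]

    @property
    def size(self) -> int:
        return sum(m.n_offspring for m in self.matings)

    def pattern(self) -> str:
        dams = {m.dam_id for m in self.matings}
        sires = {m.sire_id for m in self.matings}
        if len(dams) == 1 and len(sires) == 1:
            return "monogamous"
        if len(dams) == 1:
            return "polyandrous"
        if len(sires) == 1:
            return "polygynous"
        # a parent appearing in >1 mating means shared parentage
        counts: dict[str, int] = {}
        for m in self.matings:
            counts[m.dam_id] = counts.get(m.dam_id, 0) + 1
            counts[m.sire_id] = counts.get(m.sire_id, 0) + 1
        any_shared = any(c > 1 for c in counts.values())
        return "polygynandrous" if any_shared else "two_pairs"


@dataclass(frozen=True)
class MatingDesign:
    clutches: tuple[ClutchDesign, ...]
    max_clutch_size: int = 14

    def __post_init__(self) -> None:
        for c in self.clutches:
            if c.size > self.max_clutch_size:
                raise ValueError(
                    f"clutch {c.clutch_id} has {c.size} embryos "
                    f"(> max {self.max_clutch_size})"
                )


@dataclass(frozen=True)
class ErrorModel:
    """Post-meiotic genotyping error rates (defaults: error-free)."""

    dropout_rate: float = 0.0
    mistype_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.dropout_rate, self.mistype_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")


@dataclass
class TruthRecord:
    parent_genotypes: dict[str, dict[str, tuple[int, int]]]
    dam_haplotypes: dict[str, str]
    parents_of: dict[str, tuple[str, str]]  # embryo -> (dam, sire)
    clutch_truth: dict[str, tuple[int, int, str]]  # clutch -> (n_dams, n_sires, pattern)


def mate(
    dam_genotype: dict[str, tuple[int, int]],
    sire_genotype: dict[str, tuple[int, int]],
    n: int,
    rng: np.random.Generator,
    error: ErrorModel | None = None,
    pop: PopulationState | None = None,
) -> list[dict[str, tuple[int, int] | None]]:
    """Mendelian offspring: one uniformly chosen allele per parent per locus.

    Errors apply after meiosis: dropout turns a heterozygote homozygous for
    the remaining allele, mistyping replaces one allele with a random other
    allele of the locus (requires ``pop``), missingness blanks the call.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    error = error or ErrorModel()
    out = []
    loci = list(dam_genotype)
    for _ in range(n):
        g: dict[str, tuple[int, int] | None] = {}
        for loc in loci:
            a = dam_genotype[loc][rng.integers(2)]
            b = sire_genotype[loc][rng.integers(2)]
            pair = (min(a, b), max(a, b))
            if error.missing_rate and rng.random() < error.missing_rate:
                g[loc] = None
                continue
            if error.dropout_rate and pair[0] != pair[1] and rng.random() < error.dropout_rate:
                keep = pair[rng.integers(2)]
                pair = (keep, keep)
            if error.mistype_rate and rng.random() < error.mistype_rate:
                if pop is None:
                    raise ValueError("mistype_rate > 0 requires the population state")
                sizes = pop.allele_sizes[loc]
                which = rng.integers(2)
                current = pair[which]
                others = sizes[sizes != current]
                if len(others):
                    new = int(rng.choice(others))
                    pair = (min(new, pair[1 - which]), max(new, pair[1 - which]))
            g[loc] = pair
        out.append(g)
    return out


def generate_dataset(
    model: PopulationModel,
    design: MatingDesign,
    error: ErrorModel | None = None,
    seed: int = 0,
    year: int = 2019,
) -> tuple[GenotypeTable, HaplotypeTable, TruthRecord]:
    """Simulate a complete dataset: adults, embryos, haplotypes, ground truth."""
    rng = np.random.default_rng(seed)
    pop = build_population(model, rng)
    error = error or ErrorModel()

    parent_ids = []
    for c in design.clutches:
        for m in c.matings:
            for pid in (m.dam_id, m.sire_id):
                if pid not in parent_ids:
                    parent_ids.append(pid)
    parent_genos = {pid: _draw_genotype(pop, rng) for pid in parent_ids}
    dams = sorted({m.dam_id for c in design.clutches for m in c.matings})
    dam_haps = {
        d: str(rng.choice(np.array(pop.mt_labels), p=pop.mt_freqs)) for d in dams
    }

    records = []
    hap_of: dict[str, str] = {}
    parents_of: dict[str, tuple[str, str]] = {}
    clutch_truth: dict[str, tuple[int, int, str]] = {}
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for c in design.clutches:
        idx = 0
        for m in c.matings:
            embryos = mate(
                parent_genos[m.dam_id],
                parent_genos[m.sire_id],
                m.n_offspring,
                rng,
                error=error,
                pop=pop,
            )
            for g in embryos:
                eid = f"{c.clutch_id}.{letters[idx]}"
                idx += 1
                records.append((eid, c.clutch_id, year, ROLE_EMBRYO, g))
                hap_of[eid] = dam_haps[m.dam_id]
                parents_of[eid] = (m.dam_id, m.sire_id)
        c_dams = {m.dam_id for m in c.matings}
        c_sires = {m.sire_id for m in c.matings}
        clutch_truth[c.clutch_id] = (len(c_dams), len(c_sires), c.pattern())

    for i in range(model.n_adult_reference):
        g = _draw_genotype(pop, rng)
        records.append((f"AD{i + 1:03d}", None, year, ROLE_ADULT, g))

    loci = [lm.name for lm in model.loci]
    gt = make_genotype_table(records, loci)

    # one short synthetic sequence per haplotype so collapsing is exercisable
    hap_labels = sorted(set(hap_of.values()) | set(pop.mt_labels))
    seqs = _haplotype_sequences(hap_labels, rng)
    ht = HaplotypeTable(
        haplotype_of=dict(sorted(hap_of.items())),
        haplotype_seqs={h: seqs[h] for h in sorted(set(hap_of.values()))},
        stripped_length=len(next(iter(seqs.values()))) if seqs else 0,
    )
    truth = TruthRecord(
        parent_genotypes=parent_genos,
        dam_haplotypes=dam_haps,
        parents_of=parents_of,
        clutch_truth=clutch_truth,
    )
    return gt, ht, truth


def _haplotype_sequences(labels, rng, length: int = 120) -> dict[str, str]:
    """Distinct synthetic control-region sequences, one per haplotype label."""
    bases = np.array(list("ACGT"))
    backbone = rng.choice(bases, size=length)
    seqs = {}
    for i, lab in enumerate(sorted(labels)):
        seq = backbone.copy()
        # give each haplotype a unique substitution fingerprint
        pos = (7 * (i + 1)) % length
        seq[pos] = bases[(int(np.where(bases == seq[pos])[0][0]) + 1 + i) % 4]
        seq[(pos + 13) % length] = bases[i % 4]
        seqs[lab] = "".join(seq)
    return seqs


# ---------------------------------------------------------------------------
# Canned designs


def study_like_design() -> MatingDesign:
    """Thirteen clutches shaped like the field collection: seven monogamous,
    one polyandrous, two of two separate pairs, two polygynous, one
    polygynandrous, with matching clutch sizes."""
    c = []
    mono = [("M01", 4), ("M02", 3), ("M03", 3), ("M04", 8), ("M05", 7), ("M06", 5), ("M07", 6)]
    for cid, size in mono:
        c.append(
            ClutchDesign(cid, (Mating(f"D.{cid}", f"S.{cid}", size),))
        )
    c.append(
        ClutchDesign(
            "PA01",
            (Mating("D.PA01", "S.PA01a", 2), Mating("D.PA01", "S.PA01b", 1)),
        )
    )
    c.append(
        ClutchDesign(
            "TP01",
            (Mating("D.TP01a", "S.TP01a", 7), Mating("D.TP01b", "S.TP01b", 7)),
        )
    )
    c.append(
        ClutchDesign(
            "TP02",
            (Mating("D.TP02a", "S.TP02a", 4), Mating("D.TP02b", "S.TP02b", 4)),
        )
    )
    c.append(
        ClutchDesign(
            "PG01",
            (Mating("D.PG01a", "S.PG01", 3), Mating("D.PG01b", "S.PG01", 2)),
        )
    )
    c.append(
        ClutchDesign(
            "PG02",
            (Mating("D.PG02a", "S.PG02", 4), Mating("D.PG02b", "S.PG02", 3)),
        )
    )
    c.append(
        ClutchDesign(
            "GN01",
            (
                Mating("D.GN01a", "S.GN01a", 2),
                Mating("D.GN01a", "S.GN01b", 1),
                Mating("D.GN01b", "S.GN01a", 2),
            ),
        )
    )
    return MatingDesign(clutches=tuple(c))


def random_clutch_design(
    rng: np.random.Generator,
    pattern: str,
    size: int,
    clutch_id: str = "C01",
) -> ClutchDesign:
    """One random clutch of a given mating pattern and embryo count."""
    def split(n, parts):
        cuts = sorted(rng.choice(np.arange(1, n), size=parts - 1, replace=False))
        sizes = np.diff([0, *cuts, n])
        return [int(s) for s in sizes]

    if pattern == "monogamous":
        matings = [Mating("D1", "S1", size)]
    elif pattern == "polyandrous":
        a, b = split(size, 2)
        matings = [Mating("D1", "S1", a), Mating("D1", "S2", b)]
    elif pattern == "polygynous":
        a, b = split(size, 2)
        matings = [Mating("D1", "S1", a), Mating("D2", "S1", b)]
    elif pattern == "two_pairs":
        a, b = split(size, 2)
        matings = [Mating("D1", "S1", a), Mating("D2", "S2", b)]
    elif pattern == "polygynandrous":
        a, b, d = split(size, 3)
        matings = [Mating("D1", "S1", a), Mating("D1", "S2", b), Mating("D2", "S1", d)]
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return ClutchDesign(clutch_id, tuple(matings))
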