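"""Marker diagnostics: allele frequencies, heterozygosities, Hardy-Weinberg
exact tests, parentage exclusion probability and haplotype diversity.

Expected heterozygosity defaults to the small-sample unbiased estimator
``(2n/(2n-1)) (1 - sum p_i^2)``; haplotype diversity uses the analogous
``(n/(n-1))`` correction.  The Hardy-Weinberg exact test conditions on the
observed allele counts: the full genotype-table space is enumerated when it is
small enough, otherwise tables are sampled i.i.d. from the exact conditional
null by random pairing of the 2n gene copies.  Exclusion probabilities follow
the classical no-sampled-parent formulations (probability that a random
non-parental pair, single candidate, or second parent is Mendelian-
incompatible with a random offspring), evaluated by exact summation over
genotype combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genodata import MISSING, GenotypeTable, HaplotypeTable

__all__ = [
    "AlleleFrequencies",
    "allele_frequencies",
    "heterozygosities",
    "hwe_exact_test",
    "HweResult",
    "exclusion_probability",
    "ExclusionResult",
    "haplotype_diversity",
    "MarkerSummary",
    "marker_summary",
]


@dataclass
class AlleleFrequencies:
    """Per-locus allele->frequency maps plus gene-copy counts."""

    freqs: dict[str, dict[int, float]]
    n_copies: dict[str, int]
    mode: str = "empirical"
    flagged_empty: list[str] = field(default_factory=list)

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def of(self, locus: str) -> dict[int, float]:
        return self.freqs[locus]

    def with_floor(self, locus: str, alleles) -> dict[int, float]:
        """Frequencies with unseen ``alleles`` floored at 1/(2n+1), renormalised."""
        base = dict(self.freqs[locus])
        n2 = self.n_copies.get(locus, 0)
        floor = 1.0 / (n2 + 1) if n2 > 0 else 1.0 / (len(base) + len(alleles) + 1)
        changed = False
        for a in alleles:
            if a not in base or base[a] <= 0.0:
                base[a] = floor
                changed = True
        if changed:
            total = sum(base.values())
            base = {a: p / total for a, p in base.items()}
        return base

    @classmethod
    def uniform_minimal(cls, universes: dict[str, list[int]]) -> "AlleleFrequencies":
        """Every observed allele gets equal weight 1/N_A (flat-frequency mode)."""
        freqs = {
            loc: {a: 1.0 / len(alleles) for a in alleles}
            for loc, alleles in universes.items()
            if alleles
        }
        return cls(freqs=freqs, n_copies={loc: 0 for loc in freqs}, mode="uniform_minimal")


def _subset_calls(gt: GenotypeTable, locus: str, subset) -> np.ndarray:
    rows = [gt.row(s) for s in subset] if subset is not None else slice(None)
    arr = gt.calls[locus][rows]
    return arr[arr[:, 0] != MISSING]


def allele_frequencies(gt: GenotypeTable, subset=None) -> AlleleFrequencies:
    """Empirical allele frequencies over non-missing calls of ``subset``."""
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("subset is empty")
    freqs: dict[str, dict[int, float]] = {}
    n_copies: dict[str, int] = {}
    flagged = []
    for locus in gt.loci:
        arr = _subset_calls(gt, locus, subset)
        if arr.size == 0:
            freqs[locus] = {}
            n_copies[locus] = 0
            flagged.append(locus)
            continue
        alleles, counts = np.unique(arr.ravel(), return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): c / total for a, c in zip(alleles, counts)}
        n_copies[locus] = int(total)
    return AlleleFrequencies(freqs=freqs, n_copies=n_copies, flagged_empty=flagged)


def heterozygosities(
    gt: GenotypeTable, subset=None, unbiased: bool = True
) -> dict[str, tuple[float, float] | None]:
    """Per-locus (Ho, He); ``None`` flags loci with fewer than two typed samples."""
    out: dict[str, tuple[float, float] | None] = {}
    for locus in gt.loci:
        arr = _subset_calls(gt, locus, list(subset) if subset is not None else None)
        n = len(arr)
        if n < 2:
            out[locus] = None
            continue
        ho = float(np.mean(arr[:, 0] != arr[:, 1]))
        _, counts = np.unique(arr.ravel(), return_counts=True)
        p = counts / counts.sum()
        he = 1.0 - float(np.sum(p * p))
        if unbiased:
            he *= (2 * n) / (2 * n - 1)
        out[locus] = (ho, he)
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


@dataclass
class HweResult:
    p_value: float
    method: str  # "enumeration" | "monte_carlo" | "monomorphic"
    n: int
    n_tables: int | None = None
    seed: int | None = None


def _genotype_counts(arr: np.ndarray) -> tuple[list[int], dict[tuple[int, int], int]]:
    alleles = sorted(int(a) for a in np.unique(arr.ravel()))
    idx = {a: i for i, a in enumerate(alleles)}
    counts: dict[tuple[int, int], int] = {}
    m = [0] * len(alleles)
    for a, b in arr:
        i, j = sorted((idx[int(a)], idx[int(b)]))
        counts[(i, j)] = counts.get((i, j), 0) + 1
        m[i] += 1
        m[j] += 1
    return m, counts


def _log_table_prob(f: dict[tuple[int, int], int], m: list[int], n: int) -> float:
    # P(table | allele counts) = n! prod(m_i!) 2^het / ((2n)! prod(f_ij!))
    het = sum(c for (i, j), c in f.items() if i != j)
    lp = math.lgamma(n + 1) - math.lgamma(2 * n + 1) + het * math.log(2)
    lp += sum(math.lgamma(mi + 1) for mi in m)
    lp -= sum(math.lgamma(c + 1) for c in f.values())
    return lp


def _enumerate_tables(m: list[int], cap: int):
    """All genotype-count tables with the given allele counts, or None if > cap.

    Row-wise recursion: within allele i's row the final cell is forced to
    absorb the row remainder exactly, so every leaf reached is a valid table
    and no branch is wasted.
    """
    k = len(m)
    results: list[dict[tuple[int, int], int]] = []

    def fill_row(i: int, j: int, rem: list[int], current: dict):
        if len(results) > cap:
            raise OverflowError
        if i == k - 1:
            # last row has only the homozygote cell (i, i)
            if rem[i] % 2 == 0:
                c = rem[i] // 2
                if c:
                    current[(i, i)] = c
                results.append(dict(current))
                current.pop((i, i), None)
            return
        if j == k - 1:
            # last cell of row i: forced to rem[i]
            c = rem[i]
            if c <= rem[j]:
                if c:
                    current[(i, j)] = c
                rem[i] -= c
                rem[j] -= c
                fill_row(i + 1, i + 1, rem, current)
                rem[i] += c
                rem[j] += c
                current.pop((i, j), None)
            return
        hi = rem[i] // 2 if i == j else min(rem[i], rem[j])
        for c in range(hi + 1):
            if c:
                current[(i, j)] = c
            if i == j:
                rem[i] -= 2 * c
            else:
                rem[i] -= c
                rem[j] -= c
            fill_row(i, j + 1, rem, current)
            if i == j:
                rem[i] += 2 * c
            else:
                rem[i] += c
                rem[j] += c
            current.pop((i, j), None)

    try:
        fill_row(0, 0, list(m), {})
    except OverflowError:
        return None
    return results


def hwe_exact_test(
    gt: GenotypeTable,
    locus: str,
    subset=None,
    mc_reps: int = 100_000,
    seed: int = 0,
    enum_cap: int = 50_000,
) -> HweResult:
    """Exact conditional test for Hardy-Weinberg proportions at one locus.

    Complete enumeration of genotype tables when their number is below
    ``enum_cap``; otherwise ``mc_reps`` i.i.d. samples from the conditional
    null obtained by randomly pairing the observed gene copies (seeded).
    """
    arr = _subset_calls(gt, locus, list(subset) if subset is not None else None)
    n = len(arr)
    if n < 5:
        raise ValueError(f"{locus}: need >=5 typed individuals, have {n}")
    m, obs = _genotype_counts(arr)
    if len(m) < 2:
        return HweResult(p_value=1.0, method="monomorphic", n=n)

    lp_obs = _log_table_prob(obs, m, n)
    # with many alleles the table space is astronomically large: go straight
    # to Monte Carlo instead of filling the enumeration cap first
    tables = _enumerate_tables(m, enum_cap) if len(m) <= 6 else None
    if tables is not None:
        tol = 1e-12
        p = sum(
            math.exp(lp)
            for lp in (_log_table_prob(t, m, n) for t in tables)
            if lp <= lp_obs + tol
        )
        return HweResult(p_value=min(p, 1.0), method="enumeration", n=n, n_tables=len(tables))

    rng = np.random.default_rng(seed)
    k = len(m)
    copies = np.repeat(np.arange(k), m)
    # constant part of the log table probability; only -sum lgamma(f_ij + 1)
    # + het*log2 varies between tables
    const = (
        math.lgamma(n + 1)
        - math.lgamma(2 * n + 1)
        + sum(math.lgamma(mi + 1) for mi in m)
    )
    lgamma_tab = np.array([math.lgamma(c + 1) for c in range(n + 1)])
    hits = 0
    chunk = 5000
    done = 0
    while done < mc_reps:
        r = min(chunk, mc_reps - done)
        perm = np.argsort(rng.random((r, 2 * n)), axis=1)
        shuffled = copies[perm]
        a = shuffled[:, 0::2]
        b = shuffled[:, 1::2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        codes = lo * k + hi
        offsets = (np.arange(r) * (k * k))[:, None]
        counts = np.bincount((codes + offsets).ravel(), minlength=r * k * k).reshape(
            r, k * k
        )
        het = (lo != hi).sum(axis=1)
        lp = const + het * math.log(2) - lgamma_tab[counts].sum(axis=1)
        hits += int(np.sum(lp <= lp_obs + 1e-9))
        done += r
    p = (hits + 1) / (mc_reps + 1)
    return HweResult(p_value=p, method="monte_carlo", n=n, seed=seed)


# ---------------------------------------------------------------------------
# Exclusion probability


@dataclass
class ExclusionResult:
    per_locus: dict[str, float]
    combined: float
    form: str


def _excl_parent_pair(p: np.ndarray) -> float:
    # P(random non-parental pair is incompatible with a random HWE offspring)
    q = 1.0 - (1.0 - p) ** 2  # genotype carries allele a
    hom = float(np.sum(p**2 * q**2))
    pp = np.outer(p, p)
    qq = np.outer(q, q)
    r2 = (2.0 * pp) ** 2  # P(genotype carries both a and b)^2, a != b
    off_diag = pp * (2.0 * qq - r2)
    np.fill_diagonal(off_diag, 0.0)
    compat = hom + float(off_diag.sum())
    return 1.0 - compat


def _excl_first_parent(p: np.ndarray) -> float:
    # single random candidate excluded as *a* parent (no partner known)
    q = 1.0 - (1.0 - p) ** 2
    hom = float(np.sum(p**2 * q))
    pp = np.outer(p, p)
    pa = p[:, None] + p[None, :]
    carry_either = 1.0 - (1.0 - pa) ** 2
    off = pp * carry_either
    np.fill_diagonal(off, 0.0)
    compat = hom + float(off.sum())
    return 1.0 - compat


def _excl_second_parent(p: np.ndarray) -> float:
    # one true parent known; candidate excluded as the other parent
    k = len(p)
    compat = 0.0
    for i in range(k):
        for j in range(i, k):
            p_mom = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            mom_set = {i, j}
            transmits = [i] if i == j else [i, j]
            w = 1.0 / len(transmits)
            for m_allele in transmits:
                for f in range(k):
                    a, b = min(m_allele, f), max(m_allele, f)
                    # feasible paternal alleles given the known mother:
                    # any offspring allele whose partner the mother carries
                    s = set()
                    if a in mom_set:
                        s.add(b)
                    if b in mom_set:
                        s.add(a)
                    ps = sum(p[x] for x in s)
                    carry = 1.0 - (1.0 - ps) ** 2
                    compat += p_mom * w * p[f] * carry
    return 1.0 - compat


def exclusion_probability(
    freqs: AlleleFrequencies, form: str = "parent_pair"
) -> ExclusionResult:
    """Per-locus and combined exclusion probability.

    Forms: ``parent_pair`` (default; no parents sampled, exclude a random
    pair), ``first_parent`` and ``second_parent``.  Combined over loci as
    ``1 - prod(1 - P_l)``.
    """
    fn = {
        "parent_pair": _excl_parent_pair,
        "first_parent": _excl_first_parent,
        "second_parent": _excl_second_parent,
    }[form]
    per_locus: dict[str, float] = {}
    for locus, fmap in freqs.freqs.items():
        if len(fmap) <= 1:
            per_locus[locus] = 0.0
            continue
        p = np.array(sorted(fmap.values(), reverse=True), dtype=float)
        p = p / p.sum()
        per_locus[locus] = max(0.0, fn(p))
    log_keep = sum(math.log1p(-min(v, 1.0 - 1e-300)) for v in per_locus.values())
    combined = 1.0 - math.exp(log_keep)
    return ExclusionResult(per_locus=per_locus, combined=combined, form=form)


# ---------------------------------------------------------------------------
# Haplotype diversity


def haplotype_diversity(ht: HaplotypeTable | dict[str, str], subset=None) -> float:
    """Nei's haplotype diversity ``(n/(n-1)) (1 - sum p_i^2)``."""
    hap_of = ht.haplotype_of if isinstance(ht, HaplotypeTable) else dict(ht)
    if subset is not None:
        hap_of = {s: hap_of[s] for s in subset}
    n = len(hap_of)
    if n < 2:
        raise ValueError(f"need >=2 samples for haplotype diversity, have {n}")
    counts = np.array(list(_tally(hap_of.values()).values()), dtype=float)
    p = counts / n
    return (n / (n - 1)) * (1.0 - float(np.sum(p * p)))


def _tally(items) -> dict:
    out: dict = {}
    for it in items:
        out[it] = out.get(it, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Panel summary


@dataclass
class MarkerSummary:
    per_locus: "object"  # pandas DataFrame: locus, n, N_A, size_range, Ho, He, P_HWE
    mean_na: float
    se_na: float
    mean_ho: float
    se_ho: float
    mean_he: float
    se_he: float
    combined_exclusion: float


def marker_summary(
    gt: GenotypeTable,
    subset=None,
    seed: int = 0,
    exclusion_form: str = "parent_pair",
) -> MarkerSummary:
    """Per-locus n, N_A, size range, Ho, He and HWE p, plus panel means/SEs
    and the combined exclusion probability (empirical frequencies)."""
    import pandas as pd

    subset = list(subset) if subset is not None else None
    het = heterozygosities(gt, subset)
    freqs = allele_frequencies(gt, subset)
    rows = []
    for locus in gt.loci:
        arr = _subset_calls(gt, locus, subset)
        n = len(arr)
        alleles = sorted({int(a) for a in arr.ravel()})
        na = len(alleles)
        hohe = het[locus]
        try:
            p_hwe = hwe_exact_test(gt, locus, subset=subset, seed=seed).p_value
        except ValueError:
            p_hwe = float("nan")
        rows.append(
            {
                "locus": locus,
                "n": n,
                "N_A": na,
                "size_range": f"{alleles[0]}-{alleles[-1]}" if alleles else "",
                "Ho": hohe[0] if hohe else float("nan"),
                "He": hohe[1] if hohe else float("nan"),
                "P_HWE": p_hwe,
            }
        )
    df = pd.DataFrame(rows)
    L = len(df)

    def mean_se(col):
        vals = df[col].to_numpy(dtype=float)
        return float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1) / math.sqrt(L))

    mean_na, se_na = mean_se("N_A")
    mean_ho, se_ho = mean_se("Ho")
    mean_he, se_he = mean_se("He")
    excl = exclusion_probability(freqs, form=exclusion_form)
    return MarkerSummary(
        per_locus=df,
        mean_na=mean_na,
        se_na=se_na,
        mean_ho=mean_ho,
        se_ho=se_ho,
        mean_he=mean_he,
        se_he=se_he,
        combined_exclusion=excl.combined,
    )
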