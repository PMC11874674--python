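"""Maximum-likelihood classification of embryo pairs into kinship classes.

Each kinship hypothesis is a triple of IBD-sharing coefficients
``k = (k0, k1, k2)``: unrelated (1,0,0), half sibs (0.5,0.5,0), full sibs
(0.25,0.5,0.25) and parent-offspring (0,1,0).  The likelihood of a dyad's
multilocus genotypes under a hypothesis is ``prod_l (k0 P0 + k1 P1 + k2 P2)``
with the standard genotype-pair probabilities given 0/1/2 alleles shared
identical by descent.  Significance of the ML label against an alternative is
assessed by a Monte-Carlo likelihood-ratio test: dyads are simulated under the
alternative at the pair's jointly typed loci, and the p-value is the fraction
of simulated likelihood ratios at least as large as the observed one.

Because both members of every dyad are embryos, parent-offspring has no
direction and PO-maximal dyads are reported as full sibs (the two hypotheses
are near-indistinguishable for progeny arrays).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .genodata import GenotypeTable
from .popgen_stats import AlleleFrequencies

__all__ = [
    "K_COEFFS",
    "DyadResult",
    "ibd_pair_probs",
    "dyad_loglik",
    "lr_test",
    "LrTestResult",
    "classify_all_dyads",
]

K_COEFFS: dict[str, tuple[float, float, float]] = {
    "UR": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}


def _geno_prob(g: tuple[int, int], p: dict[int, float]) -> float:
    a, b = g
    return p[a] * p[a] if a == b else 2.0 * p[a] * p[b]


def _u(g: tuple[int, int], x: int, p: dict[int, float]) -> float:
    """P(second allele draw completes genotype ``g`` given IBD allele ``x``)."""
    a, b = g
    if a == b:
        return p[a] if x == a else 0.0
    if x == a:
        return p[b]
    if x == b:
        return p[a]
    return 0.0


def ibd_pair_probs(
    g1: tuple[int, int], g2: tuple[int, int], locus_freqs: dict[int, float]
) -> tuple[float, float, float]:
    """(P0, P1, P2): probability of the genotype pair given 0/1/2 IBD alleles.

    Raises ``KeyError`` if an allele is absent from the frequency map; callers
    wanting a floor frequency should prepare the map with
    :meth:`AlleleFrequencies.with_floor`.
    """
    for g in (g1, g2):
        for a in g:
            if a not in locus_freqs:
                raise KeyError(f"allele {a} absent from frequency map")
    p0 = _geno_prob(g1, locus_freqs) * _geno_prob(g2, locus_freqs)
    shared = {g1[0], g1[1]} & {g2[0], g2[1]}
    p1 = sum(locus_freqs[x] * _u(g1, x, locus_freqs) * _u(g2, x, locus_freqs) for x in shared)
    p2 = _geno_prob(g1, locus_freqs) if tuple(sorted(g1)) == tuple(sorted(g2)) else 0.0
    return p0, p1, p2


def _pair_freqs(
    freqs: AlleleFrequencies, locus: str, g1, g2, floor_unseen: bool = True
) -> dict[int, float]:
    alleles = set(g1) | set(g2)
    if floor_unseen:
        return freqs.with_floor(locus, alleles)
    return freqs.of(locus)


def dyad_loglik(
    gt: GenotypeTable,
    id1: str,
    id2: str,
    hypothesis: str,
    freqs: AlleleFrequencies,
    floor_unseen: bool = True,
) -> float:
    """Multilocus log-likelihood of the dyad under one kinship hypothesis."""
    k0, k1, k2 = K_COEFFS[hypothesis]
    total = 0.0
    informative = 0
    for locus in gt.loci:
        g1 = gt.call(id1, locus)
        g2 = gt.call(id2, locus)
        if g1 is None or g2 is None:
            continue
        p = _pair_freqs(freqs, locus, g1, g2, floor_unseen)
        p0, p1, p2 = ibd_pair_probs(g1, g2, p)
        lik = k0 * p0 + k1 * p1 + k2 * p2
        # an impossible hypothesis (e.g. PO with no shared allele) gets -inf
        total += math.log(lik) if lik > 0.0 else float("-inf")
        informative += 1
    if informative == 0:
        raise ValueError(f"dyad ({id1}, {id2}): no jointly typed locus")
    return float(total)


# ---------------------------------------------------------------------------
# Vectorised simulation engine


def _locus_arrays(freq_map: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
    alleles = np.array(sorted(freq_map), dtype=int)
    probs = np.array([freq_map[a] for a in alleles], dtype=float)
    probs = probs / probs.sum()
    return alleles, probs


def _sim_dyads(rng, probs: np.ndarray, k: tuple[float, float, float], n: int):
    """Simulate n dyads at one locus under IBD coefficients k.

    Returns allele-index arrays (a1, a2, b1, b2), pairs unsorted.
    """
    m = rng.choice(3, size=n, p=np.array(k))
    k_alleles = len(probs)
    draws = rng.choice(k_alleles, size=(n, 4), p=probs)
    a1, a2, b1, b2 = draws.T.copy()
    # m=1: one shared IBD allele; m=2: both genotypes identical by descent
    share1 = m >= 1
    b1[share1] = a1[share1]
    share2 = m == 2
    b2[share2] = a2[share2]
    return a1, a2, b1, b2


def _vec_ibd_probs(a1, a2, b1, b2, p: np.ndarray):
    """Vectorised (P0, P1, P2) for allele-index arrays."""
    pa1, pa2, pb1, pb2 = p[a1], p[a2], p[b1], p[b2]
    pg1 = np.where(a1 == a2, pa1 * pa2, 2.0 * pa1 * pa2)
    pg2 = np.where(b1 == b2, pb1 * pb2, 2.0 * pb1 * pb2)
    p0 = pg1 * pg2

    lo1, hi1 = np.minimum(a1, a2), np.maximum(a1, a2)
    lo2, hi2 = np.minimum(b1, b2), np.maximum(b1, b2)
    same = (lo1 == lo2) & (hi1 == hi2)
    p2 = np.where(same, pg1, 0.0)

    def u(lo, hi, x):
        # P(completing draw) for genotype (lo, hi) and IBD allele value x
        hom = lo == hi
        return np.where(
            hom & (x == lo),
            p[lo],
            np.where(~hom & (x == lo), p[hi], np.where(~hom & (x == hi), p[lo], 0.0)),
        )

    def term(x):
        in_g2 = (x == lo2) | (x == hi2)
        return np.where(in_g2, p[x] * u(lo1, hi1, x) * u(lo2, hi2, x), 0.0)

    p1 = term(lo1) + np.where(lo1 != hi1, term(hi1), 0.0)
    return p0, p1, p2


@dataclass
class LrTestResult:
    p_value: float
    lr_observed: float
    n_sims: int
    seed: int
    warn_low_sims: bool = False


def _dyad_seed(master_seed: int, id1: str, id2: str) -> np.random.SeedSequence:
    h1 = zlib.crc32(min(id1, id2).encode())
    h2 = zlib.crc32(max(id1, id2).encode())
    return np.random.SeedSequence([int(master_seed), h1, h2])


def lr_test(
    gt: GenotypeTable,
    id1: str,
    id2: str,
    putative: str,
    alternative: str,
    freqs: AlleleFrequencies,
    n_sims: int = 10_000,
    seed: int = 0,
    floor_unseen: bool = True,
) -> LrTestResult:
    """Monte-Carlo likelihood-ratio test of ``putative`` against ``alternative``.

    Simulates ``n_sims`` dyads under the alternative hypothesis at the pair's
    jointly typed loci (population frequencies, floor applied for the pair's
    unseen alleles) and returns the fraction of simulated dyads whose
    LR(putative vs alternative) is at least the observed LR.
    """
    if putative == alternative:
        raise ValueError("putative and alternative hypotheses must differ")
    if n_sims <= 0:
        raise ValueError("n_sims must be positive")
    lr_obs = dyad_loglik(gt, id1, id2, putative, freqs, floor_unseen) - dyad_loglik(
        gt, id1, id2, alternative, freqs, floor_unseen
    )

    k_put = np.array(K_COEFFS[putative])
    k_alt = K_COEFFS[alternative]
    rng = np.random.default_rng(_dyad_seed(seed, id1, id2))
    lr_sim = np.zeros(n_sims)
    for locus in gt.loci:
        g1 = gt.call(id1, locus)
        g2 = gt.call(id2, locus)
        if g1 is None or g2 is None:
            continue
        fmap = _pair_freqs(freqs, locus, g1, g2, floor_unseen)
        _, probs = _locus_arrays(fmap)
        a1, a2, b1, b2 = _sim_dyads(rng, probs, k_alt, n_sims)
        p0, p1, p2 = _vec_ibd_probs(a1, a2, b1, b2, probs)
        lik_put = k_put[0] * p0 + k_put[1] * p1 + k_put[2] * p2
        lik_alt = k_alt[0] * p0 + k_alt[1] * p1 + k_alt[2] * p2
        with np.errstate(divide="ignore"):
            lr_sim += np.log(lik_put) - np.log(lik_alt)
    p = float(np.mean(lr_sim >= lr_obs - 1e-12))
    return LrTestResult(
        p_value=p,
        lr_observed=float(lr_obs),
        n_sims=n_sims,
        seed=seed,
        warn_low_sims=n_sims < 100,
    )


@dataclass
class DyadResult:
    id1: str
    id2: str
    clutch1: str | None
    clutch2: str | None
    logliks: dict[str, float]
    ml_label: str
    fold_po_to_fs: bool
    tie_with: str | None
    lr_tests: dict[tuple[str, str], float]
    n_sims: int
    seed: int
    error: str | None = None

    @property
    def label(self) -> str:
        return f"{self.ml_label} or {self.tie_with}" if self.tie_with else self.ml_label


def classify_all_dyads(
    gt: GenotypeTable,
    freqs: AlleleFrequencies,
    embryo_ids=None,
    within_clutch: bool = True,
    n_sims: int = 10_000,
    seed: int = 0,
    tie_alpha: float = 0.05,
    fold_po_to_fs: bool = True,
) -> list[DyadResult]:
    """ML kinship label for every embryo pair, with tie annotation.

    Pairs are within-clutch by default, or all pairs of ``embryo_ids`` when
    ``within_clutch`` is false (pooled mode).  The ML label is the hypothesis
    with maximal log-likelihood (PO folded into FS); when the LR test fails to
    reject the second-ranked hypothesis at ``tie_alpha`` the result carries a
    tie annotation ("X or Y").  Per-dyad errors are returned as flagged
    results, never raised.
    """
    ids = list(embryo_ids) if embryo_ids is not None else gt.embryo_ids
    clutch_of = {s: gt.meta.loc[s, "clutch_id"] for s in ids}
    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if within_clutch and clutch_of[a] != clutch_of[b]:
                continue
            pairs.append(tuple(sorted((a, b))))
    pairs.sort()

    results: list[DyadResult] = []
    for a, b in pairs:
        try:
            logliks = {
                hyp: dyad_loglik(gt, a, b, hyp, freqs) for hyp in K_COEFFS
            }
            order = sorted(logliks, key=logliks.get, reverse=True)
            ml = order[0]
            if fold_po_to_fs and ml == "PO":
                ml = "FS"
            ranked = [h for h in order if h != ml and not (fold_po_to_fs and h == "PO")]
            second = ranked[0] if ranked else None
            lr_ps: dict[tuple[str, str], float] = {}
            tie_with = None
            if second is not None:
                res = lr_test(gt, a, b, ml, second, freqs, n_sims=n_sims, seed=seed)
                lr_ps[(ml, second)] = res.p_value
                if res.p_value >= tie_alpha:
                    tie_with = second
            results.append(
                DyadResult(
                    id1=a,
                    id2=b,
                    clutch1=clutch_of[a],
                    clutch2=clutch_of[b],
                    logliks=logliks,
                    ml_label=ml,
                    fold_po_to_fs=fold_po_to_fs,
                    tie_with=tie_with,
                    lr_tests=lr_ps,
                    n_sims=n_sims,
                    seed=seed,
                )
            )
        except (ValueError, KeyError) as exc:
            results.append(
                DyadResult(
                    id1=a,
                    id2=b,
                    clutch1=clutch_of[a],
                    clutch2=clutch_of[b],
                    logliks={},
                    ml_label="NA",
                    fold_po_to_fs=fold_po_to_fs,
                    tie_with=None,
                    lr_tests={},
                    n_sims=n_sims,
                    seed=seed,
                    error=str(exc),
                )
            )
    return results
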