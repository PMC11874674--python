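"""Minimum-parent parsimony reconstruction of clutch sibships.

The central question: what is the smallest number of parents whose (unknown)
genotypes can explain every embryo genotype in a clutch under Mendelian
inheritance?  The search space is (i) the partition of the clutch into
full-sib groups, and (ii) the "sharing topology" assigning two abstract
parents to every group, where parents may be shared between groups (half-sib
links).  Candidate parental genotypes at a locus are built from the alleles
observed in the offspring plus one untyped "wildcard" allele per parent (a
parent may carry an allele transmitted to no sampled embryo).  Two biological
constraints shape the topology search:

* distinct full-sib groups never share *both* parents (their union would then
  itself be a full-sib group, which the partition enumeration already covers);
* the parent-group incidence graph must be two-colourable, because every
  mating involves one dam and one sire.  Without this constraint three
  parents arranged in a triangle could "explain" the single-locus clutch
  {A/A, B/B, C/C}, which no sexed parentage can realise.

For clutches up to ``exact_cap`` embryos the search is an exhaustive
branch-and-bound over full-sib partitions and sharing topologies and returns
every solution attaining the minimum; larger clutches fall back to a seeded
greedy-merge heuristic flagged ``exact=False``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .genodata import GenotypeTable
from .popgen_stats import AlleleFrequencies

__all__ = [
    "WILD",
    "SibGroup",
    "SharedParentLink",
    "SibshipPartition",
    "ParentageSolution",
    "fs_compatible",
    "shared_parent_compatible",
    "min_parent_search",
    "partition_loglik",
    "cross_clutch_scan",
]

WILD = -1  # an untyped parental allele, transmitted to no sampled offspring


# ---------------------------------------------------------------------------
# Per-locus witness machinery


def _parent_candidates(alleles) -> list[tuple[int, int]]:
    al = sorted(alleles)
    cands = [(WILD, x) for x in al]
    for i, x in enumerate(al):
        for y in al[i:]:
            cands.append((x, y))
    return cands


def _explains(p: tuple[int, int], q: tuple[int, int], off: tuple[int, int]) -> bool:
    a, b = off
    return (a in p and b in q) or (b in p and a in q)


def _locus_witnesses(offspring: list[tuple[int, int]]):
    """Set of unordered parent-genotype pairs explaining every offspring call.

    ``None`` when the locus carries no constraint (no typed offspring).
    """
    if not offspring:
        return None
    alleles = {a for g in offspring for a in g}
    cands = _parent_candidates(alleles)
    out = set()
    for i, p in enumerate(cands):
        for q in cands[i:]:
            if all(_explains(p, q, off) for off in offspring):
                out.add((p, q))
    return out


def _calls_of(gt: GenotypeTable, member_ids) -> list[dict[str, tuple[int, int] | None]]:
    return [gt.sample_calls(m) for m in member_ids]


def _group_witnesses(
    calls: list[dict[str, tuple[int, int] | None]],
    loci,
    max_drops: int = 0,
):
    """Per-locus witnesses for one putative full-sib group.

    Returns ``(witnesses, dropped)`` where ``witnesses`` maps locus to a
    witness set (or None for unconstrained loci) and ``dropped`` lists
    ``(member_index, locus)`` calls ignored under the mismatch budget; returns
    ``(None, None)`` when the group is incompatible within budget.
    """
    witnesses: dict[str, object] = {}
    dropped: list[tuple[int, str]] = []
    budget = max_drops
    for locus in loci:
        offspring = [
            (idx, calls[idx][locus]) for idx in range(len(calls)) if calls[idx][locus]
        ]
        w = _locus_witnesses([g for _, g in offspring])
        if w is not None and not w and budget > 0:
            # try restoring compatibility by ignoring up to `budget` calls
            for k in range(1, budget + 1):
                best = None
                for combo in itertools.combinations(range(len(offspring)), k):
                    keep = [g for i, (_, g) in enumerate(offspring) if i not in combo]
                    w_try = _locus_witnesses(keep)
                    if w_try:
                        best = (combo, w_try)
                        break
                if best is not None:
                    combo, w = best
                    dropped.extend((offspring[i][0], locus) for i in combo)
                    budget -= len(combo)
                    break
        if w is not None and not w:
            return None, None
        witnesses[locus] = w
    return witnesses, dropped


def fs_compatible(gt: GenotypeTable, member_ids, max_drops: int = 0):
    """Can these embryos be full sibs?  Returns ``(bool, per-locus witnesses)``.

    A witness is an unordered pair of parental genotypes (``WILD`` = an allele
    unseen in the offspring); missing calls constrain nothing, and a group of
    one embryo is always compatible.
    """
    member_ids = list(member_ids)
    calls = _calls_of(gt, member_ids)
    witnesses, _ = _group_witnesses(calls, gt.loci, max_drops=max_drops)
    return (witnesses is not None), witnesses


def _slot_genotypes(witnesses: dict[str, object], locus: str):
    """Genotypes usable for one parental slot of a group at a locus (None = free)."""
    w = witnesses[locus]
    if w is None:
        return None
    out = set()
    for p, q in w:
        out.add(p)
        out.add(q)
    return out


OTHER = -2  # a concrete allele outside every linked group's observed set


def _project(geno: tuple[int, int], allele_set) -> tuple[int, int]:
    """Quotient a concrete genotype to one group's observed-allele space."""
    a, b = (x if x in allele_set else WILD for x in geno)
    return (a, b) if a <= b else (b, a)


def _shared_options(slot_sets: list, allele_sets: list, first_only: bool = False):
    """Concrete genotypes a parent shared by several groups may carry.

    ``slot_sets[i]`` is group i's slot-genotype set at this locus (None =
    unconstrained) over its own observed alleles ``allele_sets[i]``.  A
    genotype of one group's wildcard slot may be completed by another group's
    real allele, so candidates range over the union allele space plus one
    ``OTHER`` symbol and are checked group-wise after projection.  Returns
    None when no group constrains the locus; with ``first_only`` stops at the
    first feasible genotype (feasibility probe).
    """
    constrained = [(s, a) for s, a in zip(slot_sets, allele_sets) if s is not None]
    if not constrained:
        return None
    union: set[int] = set()
    for _, a in constrained:
        union |= a
    space = sorted(union) + [OTHER]
    out = set()
    for i, x in enumerate(space):
        for y in space[i:]:
            if x == OTHER and y == OTHER:
                continue
            ok = True
            for s, a in constrained:
                xa = x if x in a else WILD
                ya = y if y in a else WILD
                pr = (xa, ya) if xa <= ya else (ya, xa)
                if pr not in s:
                    ok = False
                    break
            if ok:
                out.add((x, y) if x <= y else (y, x))
                if first_only:
                    return out
    return out


def _slot_alleles(slots) -> set[int]:
    return {a for g in slots for a in g if a != WILD} if slots else set()


def shared_parent_compatible(gt: GenotypeTable, group_a, group_b, max_drops: int = 0):
    """Can the two full-sib groups share exactly one parent?

    Returns ``(bool, witness)`` where the witness maps each locus to one
    genotype the shared parent may carry (consistent with both groups'
    witness parent pairs; ``WILD`` marks an allele unseen in both groups).
    """
    ok_a, wa = fs_compatible(gt, group_a, max_drops)
    ok_b, wb = fs_compatible(gt, group_b, max_drops)
    if not (ok_a and ok_b):
        raise ValueError("both groups must be FS-compatible")
    witness: dict[str, tuple[int, int] | None] = {}
    for locus in gt.loci:
        sa = _slot_genotypes(wa, locus)
        sb = _slot_genotypes(wb, locus)
        options = _shared_options([sa, sb], [_slot_alleles(sa), _slot_alleles(sb)])
        if options is None:
            witness[locus] = None
            continue
        if not options:
            return False, None
        g = sorted(options)[0]
        witness[locus] = tuple(WILD if x == OTHER else x for x in g)
    return True, witness


# ---------------------------------------------------------------------------
# Topology search (parents per full-sib group)


def _is_bipartite(n_parents: int, edges: list[tuple[int, int]]) -> bool:
    color = [-1] * n_parents
    adj: list[list[int]] = [[] for _ in range(n_parents)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    for s in range(n_parents):
        if color[s] != -1:
            continue
        color[s] = 0
        stack = [s]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if color[v] == -1:
                    color[v] = 1 - color[u]
                    stack.append(v)
                elif color[v] == color[u]:
                    return False
    return True


def _csp_solve(assignment, witness_list, loci):
    """Exact per-locus genotype assignment for all parents, or None.

    ``assignment[g] = (p, q)`` parent indices per group.  Parent genotypes are
    concrete (union allele space plus ``OTHER``); each group constraint checks
    the pair after projection to the group's own observed alleles.  Returns
    ``{locus: {parent: genotype}}`` for constrained loci.
    """
    groups_of: dict[int, list[int]] = {}
    for gi, (p, q) in enumerate(assignment):
        groups_of.setdefault(p, []).append(gi)
        groups_of.setdefault(q, []).append(gi)

    solution: dict[str, dict[int, tuple[int, int]]] = {}
    for locus in loci:
        slot = [_slot_genotypes(w, locus) for w in witness_list]
        alle = [_slot_alleles(s) for s in slot]
        wit = [w[locus] for w in witness_list]
        constrained_parents = [
            par
            for par in groups_of
            if any(slot[gi] is not None for gi in groups_of[par])
        ]
        if not constrained_parents:
            continue
        domains: dict[int, list] = {}
        infeasible = False
        for par in constrained_parents:
            gis = groups_of[par]
            opts = _shared_options([slot[gi] for gi in gis], [alle[gi] for gi in gis])
            if not opts:
                infeasible = True
                break
            domains[par] = sorted(opts)
        if infeasible:
            return None
        order = sorted(domains, key=lambda par: len(domains[par]))
        chosen: dict[int, tuple[int, int]] = {}

        def consistent(par) -> bool:
            for gi in groups_of[par]:
                if wit[gi] is None:
                    continue
                p, q = assignment[gi]
                if p in chosen and q in chosen:
                    pa = _project(chosen[p], alle[gi])
                    pb = _project(chosen[q], alle[gi])
                    if tuple(sorted((pa, pb))) not in wit[gi]:
                        return False
            return True

        def backtrack(i: int) -> bool:
            if i == len(order):
                return True
            par = order[i]
            for g in domains[par]:
                chosen[par] = g
                if consistent(par) and backtrack(i + 1):
                    return True
                del chosen[par]
            return False

        if not backtrack(0):
            return None
        solution[locus] = {
            par: tuple(WILD if x == OTHER else x for x in g)
            for par, g in chosen.items()
        }
    return solution


class _TopologyCollector:
    """Branch-and-bound over parent-sharing topologies for fixed FS groups.

    Parents are sets of attached groups; attaching a group is pruned when no
    concrete genotype (union allele space + OTHER) satisfies all attached
    groups at some locus.  The full coupled check (mates included) runs once
    per complete assignment via :func:`_csp_solve`.
    """

    def __init__(self, witness_list, loci, best: int, keys=None, share_cache=None):
        self.wit = witness_list
        self.loci = loci
        self.G = len(witness_list)
        self.best = best
        self.solutions: list[tuple[list[tuple[int, int]], dict]] = []
        self.slot = {
            loc: [_slot_genotypes(w, loc) for w in witness_list] for loc in loci
        }
        self.alle = {
            loc: [_slot_alleles(s) for s in self.slot[loc]] for loc in loci
        }
        # cache keys identify groups by content, so results carry across the
        # many partitions sharing the same full-sib groups
        self.keys = keys if keys is not None else list(range(self.G))
        self._share_cache = share_cache if share_cache is not None else {}

    def run(self):
        self._dfs(0, [], [])
        return self.best, self.solutions

    def _can_share(self, group_idxs: list[int]) -> bool:
        key = tuple(sorted(self.keys[gi] for gi in group_idxs))
        cached = self._share_cache.get(key)
        if cached is not None:
            return cached
        self._share_cache[key] = out = self._can_share_uncached(group_idxs)
        return out

    def _can_share_uncached(self, group_idxs: list[int]) -> bool:
        for loc in self.loci:
            slots = [self.slot[loc][gi] for gi in group_idxs]
            if sum(s is not None for s in slots) < 2:
                continue
            opts = _shared_options(
                slots, [self.alle[loc][gi] for gi in group_idxs], first_only=True
            )
            if opts is not None and not opts:
                return False
        return True

    def _dfs(self, gi: int, assignment: list, parents: list[list[int]]):
        if len(parents) > self.best:
            return
        if gi == self.G:
            n_par = len(parents)
            if n_par > self.best:
                return
            if not _is_bipartite(n_par, list(assignment)):
                return
            csp = _csp_solve(assignment, self.wit, self.loci)
            if csp is None:
                return
            if n_par < self.best:
                self.best = n_par
                self.solutions = []
            self.solutions.append((list(assignment), csp))
            return
        used_pairs = {tuple(sorted(e)) for e in assignment}
        n_par = len(parents)
        # (1) reuse two existing parents
        for p in range(n_par):
            if not self._can_share(parents[p] + [gi]):
                continue
            for q in range(p + 1, n_par):
                if (p, q) in used_pairs:
                    continue
                if not self._can_share(parents[q] + [gi]):
                    continue
                assignment.append((p, q))
                if _is_bipartite(n_par, list(assignment)):
                    parents[p].append(gi)
                    parents[q].append(gi)
                    self._dfs(gi + 1, assignment, parents)
                    parents[p].pop()
                    parents[q].pop()
                assignment.pop()
        # (2) one existing parent + one new
        if n_par + 1 <= self.best:
            for p in range(n_par):
                if not self._can_share(parents[p] + [gi]):
                    continue
                parents[p].append(gi)
                parents.append([gi])
                assignment.append((p, n_par))
                self._dfs(gi + 1, assignment, parents)
                assignment.pop()
                parents.pop()
                parents[p].pop()
        # (3) two new parents
        if n_par + 2 <= self.best:
            parents.append([gi])
            parents.append([gi])
            assignment.append((n_par, n_par + 1))
            self._dfs(gi + 1, assignment, parents)
            assignment.pop()
            parents.pop()
            parents.pop()


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class SibGroup:
    members: tuple[str, ...]
    witnesses: dict[str, object] | None = None


@dataclass
class SharedParentLink:
    group_a: int
    group_b: int
    parent: str
    witness: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class SibshipPartition:
    groups: list[SibGroup]
    shared_parent_links: list[SharedParentLink]
    score: float | None = None


@dataclass
class ParentageSolution:
    clutch_id: str
    partition: SibshipPartition
    n_parents_min: int
    parent_ids: list[str]
    parents_of: dict[str, tuple[str, str]]  # embryo -> (parentX, parentY)
    group_parents: list[tuple[str, str]]  # per group
    alternates: list["ParentageSolution"] = field(default_factory=list)
    exact: bool = True
    mismatches_used: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_embryos(self) -> int:
        return sum(len(g.members) for g in self.partition.groups)


# ---------------------------------------------------------------------------
# Partition enumeration + search


def _greedy_partitions(order, gt, budget, rng=None, restarts: int = 8):
    """Candidate partitions from greedy full-sib merging (heuristic seed)."""
    ids = list(order)
    partitions = []
    orders = [sorted(ids)]
    if rng is not None:
        for _ in range(restarts):
            perm = list(ids)
            rng.shuffle(perm)
            orders.append(perm)
    memo: dict[frozenset, bool] = {}

    def compat(members) -> bool:
        key = frozenset(members)
        if key not in memo:
            memo[key] = fs_compatible(gt, sorted(members), budget)[0]
        return memo[key]

    seen = set()
    for perm in orders:
        groups: list[list[str]] = []
        for e in perm:
            placed = False
            for g in groups:
                if compat(g + [e]):
                    g.append(e)
                    placed = True
                    break
            if not placed:
                groups.append([e])
        key = frozenset(frozenset(g) for g in groups)
        if key not in seen:
            seen.add(key)
            partitions.append([sorted(g) for g in groups])
    return partitions


def _solution_from(clutch_id, groups, witness_list, assignment, csp, exact, dropped):
    order: list[int] = []
    for p, q in assignment:
        for par in (p, q):
            if par not in order:
                order.append(par)
    name_of = {par: f"P{i + 1}" for i, par in enumerate(order)}
    group_parents = [
        tuple(sorted((name_of[p], name_of[q]))) for p, q in assignment
    ]
    parents_of = {}
    for gi, members in enumerate(groups):
        for m in members:
            parents_of[m] = group_parents[gi]
    groups_out = [
        SibGroup(members=tuple(members), witnesses=witness_list[gi])
        for gi, members in enumerate(groups)
    ]
    # shared-parent links
    groups_of_parent: dict[int, list[int]] = {}
    for gi, (p, q) in enumerate(assignment):
        groups_of_parent.setdefault(p, []).append(gi)
        groups_of_parent.setdefault(q, []).append(gi)
    links = []
    for par, gis in groups_of_parent.items():
        if len(gis) < 2:
            continue
        wit = {
            loc: chosen[par]
            for loc, chosen in csp.items()
            if par in chosen
        }
        for a, b in itertools.combinations(gis, 2):
            links.append(
                SharedParentLink(group_a=a, group_b=b, parent=name_of[par], witness=wit)
            )
    partition = SibshipPartition(groups=groups_out, shared_parent_links=links)
    return ParentageSolution(
        clutch_id=clutch_id,
        partition=partition,
        n_parents_min=len(order),
        parent_ids=[name_of[p] for p in order],
        parents_of=parents_of,
        group_parents=group_parents,
        alternates=[],
        exact=exact,
        mismatches_used=dropped or [],
    )


def _canonical_key(groups, assignment):
    named = {}
    counter = itertools.count(1)
    key = []
    for gi, members in enumerate(groups):
        p, q = assignment[gi]
        for par in (p, q):
            if par not in named:
                named[par] = next(counter)
        key.append((tuple(members), tuple(sorted((named[p], named[q])))))
    return tuple(sorted(key))


def min_parent_search(
    gt: GenotypeTable,
    embryo_ids,
    clutch_id: str = "",
    exact_cap: int = 12,
    seed: int = 0,
    mismatch_budget: int = 0,
    freqs: AlleleFrequencies | None = None,
    score_mode: str = "uniform_minimal",
) -> ParentageSolution:
    """Minimum number of parents compatible with a clutch's embryo genotypes.

    Exhaustive over full-sib partitions and parent-sharing topologies for
    clutches up to ``exact_cap`` embryos (all minimal solutions are returned:
    the highest-scoring under :func:`partition_loglik` when ``freqs`` is given,
    otherwise the one with fewest full-sib groups, is primary and the rest are
    ``alternates``); larger clutches use a seeded greedy heuristic flagged
    ``exact=False``.
    """
    ids = sorted(embryo_ids)
    if not ids:
        raise ValueError("clutch has no genotyped embryos")
    loci = gt.loci
    memo_w: dict[frozenset, object] = {}
    memo_d: dict[frozenset, object] = {}

    def witnesses_of(members):
        key = frozenset(members)
        if key not in memo_w:
            w, d = _group_witnesses(
                [gt.sample_calls(m) for m in sorted(members)], loci, mismatch_budget
            )
            memo_w[key], memo_d[key] = w, d
        return memo_w[key]

    def dropped_of(groups):
        out = []
        for g in groups:
            d = memo_d.get(frozenset(g)) or []
            out.extend((sorted(g)[idx], loc) for idx, loc in d)
        return out

    exact = len(ids) <= exact_cap
    best = 2 * len(ids) + 1
    found: list[tuple[list, list, list, dict]] = []  # groups, witnesses, assignment, csp

    seen_partitions: set = set()
    share_cache: dict = {}
    _gid: dict[frozenset, int] = {}

    def group_id(members) -> int:
        key = frozenset(members)
        if key not in _gid:
            _gid[key] = len(_gid)
        return _gid[key]

    def consider(groups):
        nonlocal best, found
        pkey = frozenset(frozenset(g) for g in groups)
        if pkey in seen_partitions:
            return
        seen_partitions.add(pkey)
        if len(groups) > max((best * best) // 4, 1):
            return
        wit_list = [witnesses_of(g) for g in groups]
        if any(w is None for w in wit_list):
            return
        keys = [group_id(g) for g in groups]
        coll = _TopologyCollector(wit_list, loci, best, keys=keys, share_cache=share_cache)
        n_par, sols = coll.run()
        for assignment, csp in sols:
            if n_par < best:
                best = n_par
                found = []
            found.append((list(map(sorted, groups)), wit_list, assignment, csp))

    if exact:
        # quick upper bound from greedy merging
        for groups in _greedy_partitions(ids, gt, mismatch_budget):
            consider(groups)
        # exhaustive restricted-growth enumeration with FS pruning
        def rec(i: int, groups: list[list[str]]):
            if len(groups) > max((best * best) // 4, 1):
                return
            if i == len(ids):
                consider([list(g) for g in groups])
                return
            e = ids[i]
            for g in groups:
                g.append(e)
                if witnesses_of(g) is not None:
                    rec(i + 1, groups)
                g.pop()
            groups.append([e])
            rec(i + 1, groups)
            groups.pop()

        rec(0, [])
    else:
        rng = np.random.default_rng(seed)
        for groups in _greedy_partitions(ids, gt, mismatch_budget, rng=rng):
            consider(groups)
            # local search: try merging group pairs
            improved = True
            current = [list(g) for g in groups]
            while improved:
                improved = False
                for a, b in itertools.combinations(range(len(current)), 2):
                    merged = sorted(current[a] + current[b])
                    if witnesses_of(merged) is not None:
                        trial = [
                            g for i, g in enumerate(current) if i not in (a, b)
                        ] + [merged]
                        consider(trial)
                        current = trial
                        improved = True
                        break

    if not found:
        raise ValueError(f"no Mendelian-consistent parentage found for {clutch_id or ids}")

    # dedupe and order deterministically
    uniq = {}
    for groups, wit_list, assignment, csp in found:
        uniq[_canonical_key(groups, assignment)] = (groups, wit_list, assignment, csp)
    ordered = [uniq[k] for k in sorted(uniq)]
    solutions = [
        _solution_from(clutch_id, g, w, a, c, exact, dropped_of(g))
        for g, w, a, c in ordered
    ]
    if freqs is not None and len(solutions) > 1:
        for sol in solutions:
            sol.partition.score = partition_loglik(gt, sol, freqs, mode=score_mode)
        solutions.sort(
            key=lambda sol: (-sol.partition.score, len(sol.partition.groups))
        )
    else:
        solutions.sort(key=lambda sol: len(sol.partition.groups))
    primary = solutions[0]
    primary.alternates = solutions[1:]
    return primary


# ---------------------------------------------------------------------------
# Partition likelihood scoring


def _other_mass(fmap: dict[int, float], present) -> float:
    return max(0.0, 1.0 - sum(fmap.get(a, 0.0) for a in present))


def partition_loglik(
    gt: GenotypeTable,
    solution: ParentageSolution,
    freqs: AlleleFrequencies,
    mode: str = "uniform_minimal",
) -> float:
    """Log-likelihood of a sibship partition with its sharing topology.

    Sums, per locus and per connected family cluster, over all parental
    genotype assignments: HWE genotype priors times Mendelian offspring
    probabilities, with shared parents collapsing to a single genotype.
    ``uniform_minimal`` gives every observed allele weight ``1/N_A`` (the flat
    pseudo-frequency convention that discourages inferring allele sharing
    between parents); ``empirical`` uses the supplied frequencies with a floor
    for unseen alleles.  Returns ``-inf`` for an impossible configuration.
    """
    groups = [list(g.members) for g in solution.partition.groups]
    assignment = []
    pid_index = {pid: i for i, pid in enumerate(solution.parent_ids)}
    for pair in solution.group_parents:
        assignment.append((pid_index[pair[0]], pid_index[pair[1]]))

    # connected components of the parent graph
    n_par = len(solution.parent_ids)
    comp = list(range(n_par))

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for p, q in assignment:
        comp[find(p)] = find(q)
    comps: dict[int, list[int]] = {}
    for gi, (p, q) in enumerate(assignment):
        comps.setdefault(find(p), []).append(gi)

    OTHER = -2
    total = 0.0
    for locus in gt.loci:
        if mode == "uniform_minimal":
            na = len(freqs.of(locus)) or 1
            base = {a: 1.0 / na for a in freqs.of(locus)}
        else:
            base = freqs.of(locus)
        for group_idxs in comps.values():
            parents: list[int] = []
            for gi in group_idxs:
                for par in assignment[gi]:
                    if par not in parents:
                        parents.append(par)
            offspring: dict[int, list[tuple[int, int]]] = {}
            present: set[int] = set()
            for gi in group_idxs:
                cl = [
                    gt.call(m, locus)
                    for m in groups[gi]
                    if gt.call(m, locus) is not None
                ]
                offspring[gi] = cl
                present.update(a for g in cl for a in g)
            if not present:
                continue
            if mode == "uniform_minimal":
                na = len(freqs.of(locus)) or len(present)
                pmap = {a: 1.0 / na for a in present}
                pmap[OTHER] = max(0.0, (na - len(present)) / na)
            else:
                fmap = freqs.with_floor(locus, present)
                pmap = {a: fmap[a] for a in present}
                pmap[OTHER] = _other_mass(fmap, present)
            alleles = sorted(present) + ([OTHER] if pmap[OTHER] > 0 else [])
            genos = [
                (alleles[i], alleles[j])
                for i in range(len(alleles))
                for j in range(i, len(alleles))
            ]

            def prior(g):
                a, b = g
                return pmap[a] ** 2 if a == b else 2 * pmap[a] * pmap[b]

            def transmit(g, a):
                return (int(g[0] == a) + int(g[1] == a)) / 2.0

            def off_prob(g1, g2, off):
                a, b = off
                if a == b:
                    return transmit(g1, a) * transmit(g2, a)
                return transmit(g1, a) * transmit(g2, b) + transmit(g1, b) * transmit(
                    g2, a
                )

            # order parents so each one closes a family as early as possible,
            # letting zero offspring probabilities prune the enumeration
            par_order: list[int] = []
            for gi in group_idxs:
                for par in assignment[gi]:
                    if par not in par_order:
                        par_order.append(par)
            closes: dict[int, list[int]] = {par: [] for par in par_order}
            for gi in group_idxs:
                p, q = assignment[gi]
                later = p if par_order.index(p) >= par_order.index(q) else q
                closes[later].append(gi)
            chosen: dict[int, tuple[int, int]] = {}

            def branch(i: int) -> float:
                if i == len(par_order):
                    return 1.0
                par = par_order[i]
                acc = 0.0
                for g in genos:
                    chosen[par] = g
                    w = prior(g)
                    for gi in closes[par]:
                        p, q = assignment[gi]
                        for off in offspring[gi]:
                            w *= off_prob(chosen[p], chosen[q], off)
                            if w == 0.0:
                                break
                        if w == 0.0:
                            break
                    if w > 0.0:
                        acc += w * branch(i + 1)
                    del chosen[par]
                return acc

            s = branch(0)
            if s <= 0.0:
                return float("-inf")
            total += math.log(s)
    return total


# ---------------------------------------------------------------------------
# Cross-clutch scan


def cross_clutch_scan(
    gt: GenotypeTable,
    freqs: AlleleFrequencies,
    n_sims: int = 1000,
    seed: int = 0,
    by_year: bool = True,
):
    """Flag cross-clutch dyads whose ML kinship is FS or HS (pooled by year)."""
    from .dyadic_kinship import classify_all_dyads

    embryos = gt.embryo_ids
    pools: dict[object, list[str]] = {}
    for e in embryos:
        key = gt.meta.loc[e, "year"] if by_year else "all"
        pools.setdefault(key, []).append(e)
    flagged = []
    for key in sorted(pools, key=str):
        pool = pools[key]
        if len(pool) < 2:
            continue
        results = classify_all_dyads(
            gt, freqs, embryo_ids=pool, within_clutch=False, n_sims=n_sims, seed=seed
        )
        for r in results:
            if r.clutch1 != r.clutch2 and r.ml_label in ("FS", "HS"):
                flagged.append(r)
    return flagged
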