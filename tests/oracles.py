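"""Independent brute-force oracles for the parsimony reconstruction.

Deliberately naive: direct enumeration of parental genotypes over the
observed alleles plus one fresh (unobserved) allele per parent, set
partitions enumerated explicitly, parent pairs assigned exhaustively.  Kept
separate from the package's witness-based search so the two can disagree.
"""

import itertools

FRESH = -1000  # base id for fresh (unobserved) parental alleles


def set_partitions(items):
    """All set partitions of a list (each partition a list of lists)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _two_colourable(n_parents, edges):
    colour = {}
    adj = {p: [] for p in range(n_parents)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    for s in range(n_parents):
        if s in colour:
            continue
        colour[s] = 0
        stack = [s]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in colour:
                    colour[v] = 1 - colour[u]
                    stack.append(v)
                elif colour[v] == colour[u]:
                    return False
    return True


def _locus_feasible(groups_calls, assignment, n_parents, locus):
    """Does a joint parental genotype assignment exist at one locus?"""
    observed = set()
    offspring_per_group = []
    for calls in groups_calls:
        offs = [c[locus] for c in calls if c.get(locus) is not None]
        offspring_per_group.append(offs)
        for a, b in offs:
            observed.update((a, b))
    constrained = [g for g, offs in enumerate(offspring_per_group) if offs]
    if not constrained:
        return True
    parents_used = sorted({p for g in constrained for p in assignment[g]})
    genos = {}
    for p in parents_used:
        alleles = sorted(observed) + [FRESH - p]  # one fresh allele per parent
        genos[p] = [
            (alleles[i], alleles[j])
            for i in range(len(alleles))
            for j in range(i, len(alleles))
        ]

    def ok_group(g, chosen):
        p, q = assignment[g]
        gp, gq = chosen[p], chosen[q]
        for a, b in offspring_per_group[g]:
            if not ((a in gp and b in gq) or (b in gp and a in gq)):
                return False
        return True

    def backtrack(i, chosen):
        if i == len(parents_used):
            return True
        p = parents_used[i]
        for geno in genos[p]:
            chosen[p] = geno
            good = True
            for g in constrained:
                u, v = assignment[g]
                if u in chosen and v in chosen and not ok_group(g, chosen):
                    good = False
                    break
            if good and backtrack(i + 1, chosen):
                return True
            del chosen[p]
        return False

    return backtrack(0, {})


def brute_fs_compatible(calls, loci):
    """Naive full-sib check: one parent pair explains every embryo."""
    return all(
        _locus_feasible([calls], {0: (0, 1)}, 2, locus) for locus in loci
    )


def brute_min_parents(calls, loci, cap=8):
    """Exhaustive minimum parent count for a clutch (None if above cap).

    ``calls``: one dict per embryo mapping locus -> pair or None.  Iterates
    candidate parent counts from 2 upward; for each, tries every set
    partition into groups, every assignment of distinct parent pairs to
    groups, requires a two-colourable parent graph, and checks per-locus
    genotype feasibility by direct enumeration.
    """
    n = len(calls)
    partitions = [p for p in set_partitions(list(range(n)))]
    for n_par in range(2, min(2 * n, cap) + 1):
        pairs = list(itertools.combinations(range(n_par), 2))
        for part in partitions:
            g_count = len(part)
            if g_count > len(pairs):
                continue
            groups_calls = [[calls[i] for i in grp] for grp in part]
            for combo in itertools.permutations(pairs, g_count):
                # every parent must actually be used
                used = {p for pr in combo for p in pr}
                if len(used) != n_par:
                    continue
                assignment = dict(enumerate(combo))
                if not _two_colourable(n_par, combo):
                    continue
                if all(
                    _locus_feasible(groups_calls, assignment, n_par, locus)
                    for locus in loci
                ):
                    return n_par
    return None
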