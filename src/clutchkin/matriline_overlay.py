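"""Resolve dams versus sires by overlaying mtDNA matrilines on a parentage
solution.

Microsatellites alone cannot tell which reconstructed parent is the dam: the
mitochondrial haplotype, inherited maternally, can.  Every full-sib group
shares one dam, so all its members must carry her haplotype; half-sib groups
with *different* haplotypes must have different mothers and share a father.
Sexing a solution is a proper two-colouring of the parent graph (vertices =
reconstructed parents, one edge per full-sib group) constrained so that a dam
of several groups sees a single haplotype across them.  When more than one
valid sexing exists, the one with fewer dams is preferred (two dams sharing a
haplotype requires an extra coincidence) and the alternatives are retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .genodata import HaplotypeTable
from .parentage_reconstruction import ParentageSolution

__all__ = ["SexedParentage", "resolve_parent_sexes", "matriline_lower_bound"]


@dataclass
class SexingAlternative:
    n_dams: int
    n_sires: int
    dams: tuple[str, ...]
    sires: tuple[str, ...]
    shared_roles: tuple[tuple[str, str], ...]  # (parent id, "dam"/"sire")


@dataclass
class SexedParentage:
    clutch_id: str
    n_dams: int
    n_sires: int
    dam_of: dict[str, str]  # embryo -> dam label
    sire_of: dict[str, str]
    sharing: list[tuple[str, str]]  # (shared parent id, role)
    ambiguous: bool
    alternatives: list[SexingAlternative] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    haplotype_coverage: float = 1.0
    unsexed: bool = False

    @property
    def n_parents(self) -> int:
        return self.n_dams + self.n_sires


def matriline_lower_bound(embryo_ids, ht: HaplotypeTable) -> int:
    """Distinct mtDNA haplotypes among the clutch's embryos (lower bound on dams)."""
    haps = {ht.haplotype_of[e] for e in embryo_ids if e in ht.haplotype_of}
    return len(haps)


def _group_haplotype(members, ht: HaplotypeTable):
    haps = sorted({ht.haplotype_of[m] for m in members if m in ht.haplotype_of})
    return haps


def resolve_parent_sexes(
    solution: ParentageSolution, ht: HaplotypeTable | None
) -> SexedParentage:
    """Assign dam/sire roles to the parents of a clutch solution.

    Haplotype identity constrains only parents shared between groups; a
    full-sib group spanning two haplotypes is recorded as a conflict (the data
    contradict the sibship), never silently repaired.  With no haplotypes at
    all the output is unsexed-ambiguous: counts are still reported from an
    arbitrary orientation, flagged ``unsexed``.
    """
    groups = [list(g.members) for g in solution.partition.groups]
    parent_ids = solution.parent_ids
    pidx = {p: i for i, p in enumerate(parent_ids)}
    edges = [
        (pidx[a], pidx[b]) for a, b in solution.group_parents
    ]  # one edge per group
    n_par = len(parent_ids)

    conflicts: list[str] = []
    group_hap: list[str | None] = []
    n_typed = 0
    all_embryos = [m for g in groups for m in g]
    if ht is not None:
        n_typed = sum(1 for e in all_embryos if e in ht.haplotype_of)
    for gi, members in enumerate(groups):
        haps = _group_haplotype(members, ht) if ht is not None else []
        if len(haps) > 1:
            conflicts.append(
                f"full-sib group {tuple(members)} spans haplotypes {haps}"
            )
            group_hap.append(None)
        else:
            group_hap.append(haps[0] if haps else None)

    coverage = n_typed / len(all_embryos) if all_embryos else 0.0
    unsexed = ht is None or n_typed == 0

    # connected components of the parent graph
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n_par)]
    for gi, (u, v) in enumerate(edges):
        adj[u].append((v, gi))
        adj[v].append((u, gi))
    comp_of = [-1] * n_par
    comps: list[list[int]] = []
    for s in range(n_par):
        if comp_of[s] != -1:
            continue
        cid = len(comps)
        stack, members = [s], []
        comp_of[s] = cid
        while stack:
            u = stack.pop()
            members.append(u)
            for v, _ in adj[u]:
                if comp_of[v] == -1:
                    comp_of[v] = cid
                    stack.append(v)
        comps.append(members)

    def colorings(component: list[int]):
        """Both proper 2-colourings of one component (may yield 1 if symmetric)."""
        out = []
        root = min(component)
        for root_color in (0, 1):
            color = {root: root_color}
            stack = [root]
            ok = True
            while stack and ok:
                u = stack.pop()
                for v, _ in adj[u]:
                    if v not in color:
                        color[v] = 1 - color[u]
                        stack.append(v)
                    elif color[v] == color[u]:
                        ok = False
                        break
            if ok and len(color) == len(component):
                out.append(color)
        return out

    per_comp = [colorings(c) for c in comps]
    if any(not c for c in per_comp):
        # non-bipartite parent graph: cannot be sexed at all
        return SexedParentage(
            clutch_id=solution.clutch_id,
            n_dams=0,
            n_sires=0,
            dam_of={},
            sire_of={},
            sharing=[],
            ambiguous=True,
            conflicts=conflicts + ["parent graph is not two-colourable"],
            haplotype_coverage=coverage,
            unsexed=True,
        )

    def valid(color: dict[int, int]) -> bool:
        # a dam's groups must agree on their (known) haplotype
        for par in color:
            if color[par] != 0:
                continue
            haps = {
                group_hap[gi]
                for u, gi in _incident(par)
                if group_hap[gi] is not None
            }
            if len(haps) > 1:
                return False
        return True

    def _incident(par):
        return [(v, gi) for v, gi in adj[par]] or []

    # parents with no groups cannot occur (every parent has >=1 group)
    candidates = []
    for combo in itertools.product(*per_comp):
        color: dict[int, int] = {}
        for c in combo:
            color.update(c)
        if valid(color):
            candidates.append(color)
    if not candidates:
        # haplotype constraints unsatisfiable (conflicted data): report the
        # conflict and keep one proper orientation so bookkeeping still works
        conflicts.append("no dam/sire orientation satisfies the haplotypes")
        color = {}
        for c in next(itertools.product(*per_comp)):
            color.update(c)
        candidates = [color]

    shared_parents = [
        par for par in range(n_par) if sum(1 for _ in adj[par]) >= 2
    ]

    def signature(color):
        dams = tuple(sorted(parent_ids[p] for p in color if color[p] == 0))
        sires = tuple(sorted(parent_ids[p] for p in color if color[p] == 1))
        roles = tuple(
            sorted(
                (parent_ids[p], "dam" if color[p] == 0 else "sire")
                for p in shared_parents
            )
        )
        return len(dams), len(sires), roles, dams, sires

    sigs = {}
    for color in candidates:
        sig = signature(color)
        sigs.setdefault(sig[:3], (sig, color))
    ordered = sorted(sigs.values(), key=lambda sc: (sc[0][0], sc[0][2]))
    (n_dams, n_sires, roles, dams, sires), best_color = ordered[0]

    dam_of, sire_of = {}, {}
    for gi, members in enumerate(groups):
        u, v = edges[gi]
        dam = parent_ids[u] if best_color[u] == 0 else parent_ids[v]
        sire = parent_ids[v] if best_color[v] == 1 else parent_ids[u]
        for m in members:
            dam_of[m] = dam
            sire_of[m] = sire

    alternatives = [
        SexingAlternative(
            n_dams=s[0], n_sires=s[1], dams=s[3], sires=s[4], shared_roles=s[2]
        )
        for (s, _) in ordered[1:]
    ]
    ambiguous = unsexed or len(ordered) > 1
    return SexedParentage(
        clutch_id=solution.clutch_id,
        n_dams=n_dams,
        n_sires=n_sires,
        dam_of=dam_of,
        sire_of=sire_of,
        sharing=[(parent_ids[p], "dam" if best_color[p] == 0 else "sire") for p in shared_parents],
        ambiguous=ambiguous,
        alternatives=alternatives,
        conflicts=conflicts,
        haplotype_coverage=coverage,
        unsexed=unsexed,
    )
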