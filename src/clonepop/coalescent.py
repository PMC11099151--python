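"""Structured sequentially-Markov coalescent with per-population recombination.

Partial clonality enters the genealogical process in exactly one place: a
lineage currently residing in population ``p`` recombines at rate
``rho_site * sigma(p)`` per base pair per generation, because crossovers only
happen in the rare sexual generations.  No pre-installed coalescent engine
exposes deme-specific recombination rates, so the process is simulated here
directly:

1. The genealogy at the left end of the chromosome is drawn from the
   structured coalescent on the pure-split species tree (no migration), with
   pairwise coalescence rate ``1/(2N_p)`` inside each population.
2. Moving rightwards, the distance to the next recombination breakpoint is
   exponential with rate equal to the recombination-weighted total branch
   "length" of the current marginal tree (each branch segment weighted by the
   sigma of the population it resides in at that time).
3. At a breakpoint a branch-time point is chosen proportionally to that same
   weight, the lineage above it is detached (its former parent node is
   spliced out), and the floating lineage re-coalesces with the remaining
   tree under the structured rates (SMC approximation).
4. Mutations are laid on each marginal tree at rate ``mu`` per site per
   generation under the infinite-sites model; the ancestral state is known.

Because there is no migration, the population a branch occupies at time ``t``
is a deterministic function of the populations of the samples below it and
the split schedule, which keeps the bookkeeping exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import DemographicModel, PopEpoch

__all__ = ["simulate_haplotypes", "HaplotypeSim"]


@dataclass
class HaplotypeSim:
    """Result of one chromosome simulation.

    haplotypes is (n_haploids, n_sites) uint8 with 1 = derived allele.
    """

    positions: np.ndarray            # 0-based bp, sorted, unique
    haplotypes: np.ndarray
    sample_pops: list
    n_trees: int = 1
    breakpoints: list = field(default_factory=list)  # (bp position, population of event)


class _Demes:
    """Split-schedule helper: where is a lineage of given origin at time t?"""

    def __init__(self, epochs: dict):
        self.epochs = epochs
        self.boundaries = sorted({e.end for e in epochs.values() if math.isfinite(e.end)})

    def pop_at(self, origin: str, t: float) -> PopEpoch:
        e = self.epochs[origin]
        while t >= e.end:
            e = self.epochs[e.parent]
        return e

    def segments(self, origin: str, t0: float, t1: float):
        """Yield (a, b, PopEpoch) cutting [t0, t1) at population merges."""
        t = t0
        while t < t1:
            e = self.pop_at(origin, t)
            b = min(t1, e.end)
            yield t, b, e
            t = b


class _Tree:
    """Mutable binary genealogy with parent/children pointers.

    Nodes are indices into parallel lists; spliced-out nodes are left in
    place but marked dead.  `origin[v]` is the population in which the
    lineage immediately above node v starts (its sample population for
    leaves, the population of the coalescence event otherwise).
    """

    def __init__(self, n_leaves: int, sample_pops: list):
        self.n_leaves = n_leaves
        self.time = [0.0] * n_leaves
        self.parent = [-1] * n_leaves
        self.children = [None] * n_leaves
        self.origin = list(sample_pops)
        self.alive = [True] * n_leaves
        self.root = -1

    def new_node(self, t: float, c1: int, c2: int, origin: str) -> int:
        v = len(self.time)
        self.time.append(t)
        self.parent.append(-1)
        self.children.append([c1, c2])
        self.origin.append(origin)
        self.alive.append(True)
        self.parent[c1] = v
        self.parent[c2] = v
        return v

    def leaves_below(self, v: int) -> list:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < self.n_leaves:
                out.append(u)
            else:
                stack.extend(self.children[u])
        return out

    def branches(self):
        """All (node, t_low, t_high) branches of the tree rooted at self.root.

        The root lineage is included with t_high = inf.
        """
        out, stack = [], [self.root]
        while stack:
            u = stack.pop()
            p = self.parent[u]
            hi = self.time[p] if p >= 0 else math.inf
            out.append((u, self.time[u], hi))
            if u >= self.n_leaves:
                stack.extend(self.children[u])
        return out


def _initial_tree(demes: _Demes, sample_pops: list, rng) -> _Tree:
    tree = _Tree(len(sample_pops), sample_pops)
    lineages: dict = {}
    for v, p in enumerate(sample_pops):
        lineages.setdefault(p, []).append(v)
    merges = sorted(
        (e.end, e.name, e.parent) for e in demes.epochs.values() if math.isfinite(e.end)
    )
    mi = 0
    t = 0.0
    total = len(sample_pops)
    while total > 1:
        rates = []
        for pname, lin in lineages.items():
            k = len(lin)
            if k >= 2:
                rates.append((pname, k * (k - 1) / 2.0 / (2.0 * demes.epochs[pname].size)))
        lam = sum(r for _, r in rates)
        t_next = merges[mi][0] if mi < len(merges) else math.inf
        if lam > 0:
            dt = rng.exponential(1.0 / lam)
        else:
            dt = math.inf
        if t + dt < t_next:
            t += dt
            u = rng.uniform(0.0, lam)
            acc = 0.0
            for pname, r in rates:
                acc += r
                if u <= acc:
                    break
            lin = lineages[pname]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[i], lin[j]
            v = tree.new_node(t, a, b, pname)
            lineages[pname] = [x for x in lin if x not in (a, b)] + [v]
            total -= 1
        else:
            t = t_next
            _, child, parent = merges[mi]
            mi += 1
            if child in lineages:
                lineages.setdefault(parent, []).extend(lineages.pop(child))
    for pname, lin in lineages.items():
        if lin:
            tree.root = lin[0]
    return tree


def _branch_weight(tree: _Tree, demes: _Demes, v: int, rho_site: float):
    """Recombination weight of the branch above v, per bp; with its segments."""
    p = tree.parent[v]
    if p < 0:
        return 0.0, []
    segs = []
    w = 0.0
    for a, b, e in demes.segments(tree.origin[v], tree.time[v], tree.time[p]):
        sw = rho_site * e.sigma * (b - a)
        segs.append((a, b, e, sw))
        w += sw
    return w, segs


def _recoalesce(tree: _Tree, demes: _Demes, v: int, t_r: float, rng):
    """Detach the lineage above v at time t_r and re-coalesce it (SMC step).

    Returns the population in which the breakpoint occurred (for logging).
    """
    p = tree.parent[v]
    bp_pop = demes.pop_at(tree.origin[v], t_r).name
    # splice out p
    g = tree.parent[p]
    sib = tree.children[p][0] if tree.children[p][1] == v else tree.children[p][1]
    tree.alive[p] = False
    tree.parent[sib] = g
    if g >= 0:
        cs = tree.children[g]
        cs[cs.index(p)] = sib
    else:
        tree.root = sib
    tree.parent[v] = -1

    branches = tree.branches()
    grid = sorted(
        {tl for _, tl, _ in branches if tl > t_r}
        | {b for b in demes.boundaries if b > t_r}
    )
    grid.append(math.inf)
    t = t_r
    origin_v = tree.origin[v]
    for t_hi in grid:
        pop = demes.pop_at(origin_v, t)
        cand = [
            u for u, tl, th in branches
            if tl <= t and t < th and demes.pop_at(tree.origin[u], t).name == pop.name
        ]
        k = len(cand)
        if k > 0:
            rate = k / (2.0 * pop.size)
            dt = rng.exponential(1.0 / rate)
            if t + dt < t_hi:
                t_star = t + dt
                u = cand[int(rng.integers(k))]
                gp = tree.parent[u]
                c = tree.new_node(t_star, v, u, pop.name)
                tree.parent[c] = gp
                if gp >= 0:
                    cs = tree.children[gp]
                    cs[cs.index(u)] = c
                else:
                    tree.root = c
                return bp_pop
        t = t_hi
    raise AssertionError("floating lineage failed to re-coalesce")  # pragma: no cover


def simulate_haplotypes(
    model: DemographicModel,
    samples_per_pop: dict,
    L: int,
    rng: np.random.Generator,
) -> HaplotypeSim:
    """Simulate haploid genomes of length L bp for the given diploid samples.

    samples_per_pop maps population name -> number of DIPLOID individuals;
    two haplotypes per individual are simulated and later paired.
    """
    demes = _Demes(model.epochs())
    sample_pops = []
    for pop in sorted(samples_per_pop):
        sample_pops.extend([pop] * (2 * samples_per_pop[pop]))
    m = len(sample_pops)
    if m < 2:
        raise ValueError("need at least one diploid sample")
    mu = model.mu_site
    rho = model.rho_site

    tree = _initial_tree(demes, sample_pops, rng)
    muts: dict = {}   # position -> boolean derived vector
    breakpoints = []
    x = 0.0
    n_trees = 1
    while x < L:
        weights = []
        segsets = []
        nodes = []
        total_w = 0.0
        for u, tl, th in tree.branches():
            if not math.isfinite(th):
                continue
            w, segs = _branch_weight(tree, demes, u, rho)
            if w > 0:
                nodes.append(u)
                weights.append(w)
                segsets.append(segs)
                total_w += w
        span = rng.exponential(1.0 / total_w) if total_w > 0 else math.inf
        x_next = min(L, x + span)
        # mutations on the current tree over [x, x_next)
        tot_len = sum(
            th - tl for _, tl, th in tree.branches() if math.isfinite(th)
        )
        n_mut = rng.poisson(mu * tot_len * (x_next - x))
        if n_mut:
            branch_list = [(u, tl, th) for u, tl, th in tree.branches() if math.isfinite(th)]
            lens = np.array([th - tl for _, tl, th in branch_list])
            picks = rng.choice(len(branch_list), size=n_mut, p=lens / lens.sum())
            posns = rng.integers(int(x), int(x_next), size=n_mut) if int(x_next) > int(x) else []
            for bi, pos in zip(picks, posns):
                pos = int(pos)
                if pos in muts:
                    continue  # infinite sites on the integer grid: drop collisions
                vec = np.zeros(m, dtype=np.uint8)
                vec[tree.leaves_below(branch_list[bi][0])] = 1
                muts[pos] = vec
        if x_next >= L:
            break
        x = x_next
        # recombination event: choose branch then time point within it
        u = rng.uniform(0.0, total_w)
        acc = 0.0
        for i, w in enumerate(weights):
            acc += w
            if u <= acc:
                break
        r = rng.uniform(0.0, weights[i])
        acc2 = 0.0
        for a, b, e, sw in segsets[i]:
            acc2 += sw
            if r <= acc2:
                frac = 1.0 - (acc2 - r) / sw if sw > 0 else 0.5
                t_r = a + frac * (b - a)
                break
        bp_pop = _recoalesce(tree, demes, nodes[i], t_r, rng)
        breakpoints.append((x, bp_pop))
        n_trees += 1

    if muts:
        positions = np.array(sorted(muts), dtype=np.int64)
        hap = np.stack([muts[p] for p in positions], axis=1)
    else:
        positions = np.zeros(0, dtype=np.int64)
        hap = np.zeros((m, 0), dtype=np.uint8)
    return HaplotypeSim(
        positions=positions,
        haplotypes=hap,
        sample_pops=sample_pops,
        n_trees=n_trees,
        breakpoints=breakpoints,
    )
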