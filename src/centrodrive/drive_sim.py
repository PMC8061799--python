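"""Forward simulation of neutral mutation accumulation on a sweeping,
non-recombining haplotype.

The model is a haploid Wright-Fisher population of chromosomes founded by a
small bottleneck (default 20 chromosomes) that grows by 10% per generation to
a census cap.  Each offspring copies a uniformly chosen parent and gains
Poisson(mu * L) new mutations at uniform positions over a finite sequence of L
sites (repeat hits flip the site back: symmetric two-state mutation; at
mu*L ~ 2.6e-3 collisions are negligible).  Every generation a
without-replacement sample of chromosomes is scored for segregating sites,
and the run stops when the sample first shows at least ``stop_S`` of them —
mirroring how the observed variant count on a swept haplotype maps back to an
age.

Chromosomes are stored as references into a mutation-event tree (one node per
mutation), so memory scales with the total number of mutation events rather
than population size times sequence length.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_ROOT = 0  # ancestral, mutation-free chromosome state


@dataclass
class SimConfig:
    founder_n: int = 20          # founding chromosomes
    growth: float = 1.10         # per-generation growth factor
    n_max: int = 50_000          # chromosome census cap
    L: int = 256_867             # assayed positions
    mu: float = 1.0e-8           # per-site per-generation mutation rate
    sample_n: int = 13           # chromosomes scored per generation
    stop_S: int = 9              # segregating sites triggering the stop
    max_gen: int = 50_000        # censoring guard
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.founder_n < 2:
            raise ValueError("founder_n >= 2 required")
        if self.growth <= 1:
            raise ValueError("growth factor must exceed 1")
        if self.n_max < self.founder_n:
            raise ValueError("n_max >= founder_n required")
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.sample_n > self.founder_n:
            raise ValueError("sample_n <= founder_n required")


@dataclass
class SimResult:
    stop_generation: int | None    # None = censored at max_gen
    s_trajectory: list[int]
    pop_sizes: list[int]
    seed: int | None
    sumx_trajectory: list[int] = field(default_factory=list)

    @property
    def censored(self) -> bool:
        return self.stop_generation is None


def population_size_at(cfg: SimConfig, t: int) -> int:
    """Census at generation t: min(round(founder_n * growth^t), n_max)."""
    raw = cfg.founder_n * cfg.growth**t
    return min(int(math.floor(raw + 0.5)), cfg.n_max)


def generations_of_growth(
    founder_n: int = 20, growth: float = 1.10, n_max: int = 50_000
) -> int:
    """Complete growth generations before the census cap truncates growth.

    The founding stock of ``founder_n`` chromosomes is carried by
    ``founder_n / 2`` diploid individuals; compounding the individual census
    at ``growth`` per generation, this returns the number of full (uncapped)
    growth generations before the census first reaches ``n_max``, i.e.
    max{t : (founder_n / 2) * growth^t < n_max}.
    """
    if founder_n < 2 or growth <= 1 or n_max <= founder_n:
        raise ValueError("invalid growth parameters")
    ratio = 2.0 * n_max / founder_n
    t = int(math.floor(math.log(ratio) / math.log(growth)))
    # guard against float edges
    while (founder_n / 2.0) * growth ** (t + 1) < n_max:
        t += 1
    while t > 0 and (founder_n / 2.0) * growth**t >= n_max:
        t -= 1
    return t


def _sample_without_replacement(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    if k >= n:
        return np.arange(n)
    picked: set[int] = set()
    while len(picked) < k:
        for v in rng.integers(0, n, size=k - len(picked)):
            picked.add(int(v))
    return np.fromiter(picked, dtype=np.int64)


def _segregating_sites(
    sample_nodes: np.ndarray, parent: list[int], position: list[int]
) -> tuple[int, int]:
    """Segregating sites and summed derived counts in a chromosome sample.

    A site carries the derived state on a chromosome iff it was hit an odd
    number of times along that chromosome's mutation lineage (symmetric
    flips); the site segregates iff some but not all sampled chromosomes
    carry it.  Returns (S, sum of derived counts over segregating sites).
    """
    k = len(sample_nodes)
    carrier: Counter = Counter()
    for node in sample_nodes:
        hits: Counter = Counter()
        nd = int(node)
        while nd != _ROOT:
            hits[position[nd]] += 1
            nd = parent[nd]
        for pos_, c in hits.items():
            if c % 2 == 1:
                carrier[pos_] += 1
    seg = [c for c in carrier.values() if 0 < c < k]
    return len(seg), sum(seg)


def simulate_drive_haplotype(cfg: SimConfig) -> SimResult:
    """Run one replicate; deterministic given ``cfg.seed``.

    Stops at the first generation whose sample shows >= ``stop_S``
    segregating sites; returns a censored result after ``max_gen``
    generations otherwise (always, when mu = 0).
    """
    rng = np.random.default_rng(cfg.seed)
    mu_L = cfg.mu * cfg.L
    parent: list[int] = [-1]      # node 0 is the mutation-free root
    position: list[int] = [-1]
    pop = np.zeros(cfg.founder_n, dtype=np.int64)
    s_traj: list[int] = []
    sumx_traj: list[int] = []
    pop_sizes: list[int] = []
    for t in range(1, cfg.max_gen + 1):
        n_t = population_size_at(cfg, t)
        pop = pop[rng.integers(0, len(pop), size=n_t)]
        n_events = rng.poisson(mu_L * n_t)
        if n_events:
            hit_who = rng.integers(0, n_t, size=n_events)
            hit_where = rng.integers(0, cfg.L, size=n_events)
            for who, where in zip(hit_who, hit_where):
                parent.append(int(pop[who]))
                position.append(int(where))
                pop[who] = len(parent) - 1
        pop_sizes.append(n_t)
        sample = pop[_sample_without_replacement(rng, n_t, cfg.sample_n)]
        s, sum_x = _segregating_sites(sample, parent, position)
        s_traj.append(s)
        sumx_traj.append(sum_x)
        if s >= cfg.stop_S:
            return SimResult(
                stop_generation=t, s_trajectory=s_traj,
                pop_sizes=pop_sizes, seed=cfg.seed, sumx_trajectory=sumx_traj,
            )
    return SimResult(
        stop_generation=None, s_trajectory=s_traj,
        pop_sizes=pop_sizes, seed=cfg.seed, sumx_trajectory=sumx_traj,
    )


def star_expected_stop(stop_S: int, sample_n: int, mu: float, L: int) -> float:
    """Analytic stopping-time approximation under a star genealogy.

    With sampled lineages accumulating mutations independently at rate
    mu * L per generation, the expected generation at which the sample first
    shows ``stop_S`` segregating sites is stop_S / (sample_n * mu * L).
    """
    if stop_S <= 0 or sample_n <= 0 or mu <= 0 or L <= 0:
        raise ValueError("all arguments must be positive")
    return stop_S / (sample_n * mu * L)


def run_simulation_grid(
    mu_values,
    n_max_values,
    reps: int,
    seed: int | None = None,
    base_config: SimConfig | None = None,
) -> pd.DataFrame:
    """Replicated stopping-generation table over a mu x n_max grid.

    Replicate seeds are spawned deterministically from the master seed, so
    the full table is reproducible and individual cells can be re-run in
    isolation.
    """
    base = base_config or SimConfig()
    mu_values = list(np.atleast_1d(mu_values))
    n_max_values = list(np.atleast_1d(n_max_values))
    cells = [(float(m), int(nm)) for m in mu_values for nm in n_max_values]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cells) * max(reps, 0))
    rows = []
    k = 0
    for mu, n_max in cells:
        for rep in range(reps):
            cfg = replace(base, mu=mu, n_max=n_max, seed=None)
            cfg.seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            res = simulate_drive_haplotype(cfg)
            rows.append(
                dict(
                    rep=rep, mu=mu, n_max=n_max,
                    stop_generation=res.stop_generation,
                    censored=res.censored,
                )
            )
    return pd.DataFrame(
        rows, columns=["rep", "mu", "n_max", "stop_generation", "censored"]
    )
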