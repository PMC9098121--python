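"""Continuous-time stochastic simulation of a limited RNAPII pool.

Model: a fixed total number of polymerases is shared by a mix of short
(5 kb), medium (63 kb) and long (100 kb) genes.  Transcription initiation
on each gene is attempted as a Poisson process whose rate is proportional
to the current number of free polymerases (rate = c * free_pool per gene
copy); an attempt succeeds only if the promoter is clear (the previously
initiated polymerase is at least one footprint downstream).  Engaged
polymerases elongate deterministically at constant speed and are recycled
to the free pool on termination.

Heat shock is modelled as the instantaneous introduction of a premature
termination site at a fixed distance (10 kb) into every gene: polymerases
upstream of it terminate there, polymerases already past it run on to the
normal gene end, so the region between the premature site and the gene end
empties after one transit time.  Because termination now comes early, the
free pool grows and the mean time between initiation events drops below
its baseline — the re-initiation speed-up a limited pool produces.

The initiation constant c is calibrated so that the baseline mean
inter-initiation interval per gene is 2.5 s.
"""

from __future__ import annotations

import heapq
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SimConfig:
    """Configuration of the limited-pool simulation.

    ``gene_classes`` maps gene length (bp) to copy number.  Speed is in
    kb/min (default 2, the measured control elongation rate regime);
    ``footprint`` is the minimum promoter headway in bp.
    """

    gene_classes: tuple[tuple[int, int], ...] = ((5_000, 2), (63_000, 2), (100_000, 2))
    pool_size: int = 10_000
    elongation_speed_kb_min: float = 2.0
    footprint: int = 50
    initiation_constant: float | None = None   # per s per free polymerase per gene
    premature_tts: int = 10_000
    t_switch: float | None = None              # s; None = no heat shock
    horizon: float = 6_000.0                   # s
    seed: int = 0
    check_invariants: bool = True

    def __post_init__(self):
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.elongation_speed_kb_min <= 0:
            raise ValueError("elongation speed must be > 0")
        if self.premature_tts >= max(l for l, _ in self.gene_classes) and self.t_switch is not None:
            raise ValueError("premature_tts must lie within the longest gene class")

    @property
    def speed_bp_s(self) -> float:
        return self.elongation_speed_kb_min * 1000.0 / 60.0

    @property
    def gene_lengths(self) -> list[int]:
        return [l for l, n in self.gene_classes for _ in range(n)]


@dataclass
class SimResult:
    """One realisation: per-polymerase records and summary counters."""

    config: SimConfig
    # parallel arrays, one entry per successful initiation
    gene_index: np.ndarray
    t_init: np.ndarray
    t_term: np.ndarray
    n_attempts: int
    n_blocked: int
    final_free: int
    gene_lengths: list[int] = field(default_factory=list)

    def engaged_at(self, t: float) -> np.ndarray:
        """Indices of polymerases engaged at time t."""
        return np.flatnonzero((self.t_init <= t) & (t < self.t_term))

    def positions_at(self, t: float):
        """(gene_index, position bp) of engaged polymerases at time t."""
        idx = self.engaged_at(t)
        pos = (t - self.t_init[idx]) * self.config.speed_bp_s
        return self.gene_index[idx], pos

    def free_pool_at(self, t: float) -> int:
        return self.config.pool_size - len(self.engaged_at(t))

    def initiation_times(self, gene: int) -> np.ndarray:
        return np.sort(self.t_init[self.gene_index == gene])


def run_simulation(config: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Event-driven realisation of the limited-pool model.

    Polymerase number is conserved (free + engaged = pool) and checked at
    every event when ``config.check_invariants`` is set.
    """
    if config.initiation_constant is None:
        raise ValueError("initiation_constant must be set (run calibration first)")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    c = config.initiation_constant
    speed = config.speed_bp_s
    dead = config.footprint / speed
    lengths = config.gene_lengths
    n_genes = len(lengths)
    pool = config.pool_size

    def eff_term(t_start: float, length: int) -> float:
        """Termination time for a polymerase initiated at t_start."""
        if config.t_switch is not None and t_start >= config.t_switch and config.premature_tts < length:
            return t_start + config.premature_tts / speed
        return t_start + length / speed

    t = 0.0
    free = pool
    last_success = [-np.inf] * n_genes
    term_heap: list[tuple[float, int]] = []
    gi_log, ti_log, tt_log = [], [], []
    n_attempts = n_blocked = 0
    switch_done = config.t_switch is None

    def draw_attempt(now: float) -> float:
        rate = c * free * n_genes
        if rate <= 0:
            return np.inf
        return now + rng.exponential(1.0 / rate)

    next_attempt = draw_attempt(t)
    while True:
        t_term = term_heap[0][0] if term_heap else np.inf
        t_next = min(next_attempt, t_term)
        if not switch_done and config.t_switch <= t_next:
            # introduce the premature site: truncate upstream polymerases
            t = config.t_switch
            switch_done = True
            new_heap = []
            for k in range(len(tt_log)):
                if tt_log[k] <= t:
                    continue
                pos = (t - ti_log[k]) * speed
                if pos < config.premature_tts < lengths[gi_log[k]]:
                    tt_log[k] = ti_log[k] + config.premature_tts / speed
                new_heap.append((tt_log[k], k))
            heapq.heapify(new_heap)
            term_heap = new_heap
            next_attempt = draw_attempt(t)  # memoryless redraw
            continue
        if t_next > config.horizon or not np.isfinite(t_next):
            break
        if next_attempt <= t_term:
            t = next_attempt
            n_attempts += 1
            g = int(rng.integers(n_genes))
            if free >= 1 and (t - last_success[g]) >= dead:
                free -= 1
                last_success[g] = t
                k = len(ti_log)
                gi_log.append(g)
                ti_log.append(t)
                tt_log.append(eff_term(t, lengths[g]))
                heapq.heappush(term_heap, (tt_log[k], k))
            else:
                n_blocked += 1
            next_attempt = draw_attempt(t)
        else:
            t, _k = heapq.heappop(term_heap)
            free += 1
            next_attempt = draw_attempt(t)
        if config.check_invariants and free + len(term_heap) != pool:
            raise AssertionError(
                f"conservation violated at t={t}: free={free}, engaged={len(term_heap)}"
            )

    return SimResult(
        config=config,
        gene_index=np.array(gi_log, dtype=int),
        t_init=np.array(ti_log, float),
        t_term=np.array(tt_log, float),
        n_attempts=n_attempts,
        n_blocked=n_blocked,
        final_free=free,
        gene_lengths=lengths,
    )


def mean_interinitiation(result: SimResult, t_lo: float, t_hi: float) -> float:
    """Mean interval between successive initiation events per gene within
    [t_lo, t_hi], pooled over genes."""
    intervals = []
    for g in range(len(result.gene_lengths)):
        times = result.initiation_times(g)
        lo = bisect_left(times, t_lo)
        hi = bisect_right(times, t_hi)
        if hi - lo >= 2:
            intervals.append(np.diff(times[lo:hi]))
    if not intervals:
        return np.nan
    return float(np.mean(np.concatenate(intervals)))


def predicted_initiation_constant(config: SimConfig, target_interval: float = 2.5) -> float:
    """Closed-form calibration from the equilibrium fixed point.

    Successful initiations per gene form a dead-time-thinned Poisson
    process: mean interval = footprint/speed + 1/(c * F).  The engaged
    count follows from the throughput and transit times (Little's law),
    E = sum_g T_g / target, so F = pool - E and
    c = 1 / ((target - dead_time) * F).
    """
    dead = config.footprint / config.speed_bp_s
    if dead >= target_interval:
        raise ValueError("promoter headway alone exceeds the target interval")
    transit = sum(l / config.speed_bp_s for l in config.gene_lengths)
    engaged = transit / target_interval
    free = config.pool_size - engaged
    if free <= 0:
        raise ValueError(
            f"pool exhausted: equilibrium needs ~{engaged:.0f} engaged polymerases, "
            f"pool is {config.pool_size}; increase pool_size"
        )
    return 1.0 / ((target_interval - dead) * free)


def calibrate_initiation_constant(
    config: SimConfig,
    target_interval: float = 2.5,
    rel_tol: float = 0.01,
    n_runs: int = 3,
    burn_in: float | None = None,
    measure: float = 1500.0,
    max_iter: int = 20,
) -> float:
    """Bisection on c so the simulated baseline mean inter-initiation
    interval equals ``target_interval`` (s) within ``rel_tol``.

    Runs the model without the premature-termination switch; the
    measurement window starts after the longest transit time (plus margin)
    so the pool has equilibrated.
    """
    if burn_in is None:
        burn_in = max(config.gene_lengths) / config.speed_bp_s * 1.2
    base = SimConfig(**{**config.__dict__,
                        "t_switch": None, "horizon": burn_in + measure})

    def simulated_interval(c: float, tag: int) -> float:
        vals = []
        for r in range(n_runs):
            cfg = SimConfig(**{**base.__dict__, "initiation_constant": c})
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 7_001, tag, r])
            )
            res = run_simulation(cfg, rng)
            vals.append(mean_interinitiation(res, burn_in, burn_in + measure))
        return float(np.nanmean(vals))

    c0 = predicted_initiation_constant(config, target_interval)
    lo, hi = c0 / 4, c0 * 4
    # interval is decreasing in c: bracket the target
    for it in range(max_iter):
        mid = np.sqrt(lo * hi)
        val = simulated_interval(mid, it)
        if abs(val - target_interval) <= rel_tol * target_interval:
            return mid
        if val > target_interval:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


@dataclass
class DensityTrajectory:
    """Run-averaged polymerase density per gene class over time."""

    time_grid: np.ndarray
    bin_edges_bp: np.ndarray
    density: dict[int, np.ndarray]   # gene length -> (n_times, n_bins) mean count
    free_pool: np.ndarray            # (n_times,) mean free pool over runs
    n_runs: int


def summarize_density(
    results: list[SimResult],
    time_grid: np.ndarray,
    bin_size_bp: int = 1000,
) -> DensityTrajectory:
    """Average engaged-polymerase density (count per position bin, per gene
    copy) over runs, per gene class, plus the mean free pool over time.
    The scale is arbitrary but consistent across runs and gene lengths."""
    if len(results) < 2:
        raise ValueError("need >= 2 runs to summarise")
    cfg0 = results[0].config
    for r in results[1:]:
        if r.gene_lengths != results[0].gene_lengths or r.config.pool_size != cfg0.pool_size:
            raise ValueError("inconsistent configurations across runs")
    lengths = results[0].gene_lengths
    classes = sorted(set(lengths))
    max_len = max(classes)
    edges = np.arange(0, max_len + bin_size_bp, bin_size_bp)
    density = {cl: np.zeros((len(time_grid), len(edges) - 1)) for cl in classes}
    free = np.zeros(len(time_grid))
    copies = {cl: lengths.count(cl) for cl in classes}
    for res in results:
        for ti, t in enumerate(time_grid):
            gidx, pos = res.positions_at(t)
            free[ti] += res.config.pool_size - len(gidx)
            for cl in classes:
                sel = np.isin(gidx, [g for g, L in enumerate(lengths) if L == cl])
                h, _ = np.histogram(pos[sel], bins=edges)
                density[cl][ti] += h / copies[cl]
    n = len(results)
    return DensityTrajectory(
        time_grid=np.asarray(time_grid, float),
        bin_edges_bp=edges,
        density={cl: d / n for cl, d in density.items()},
        free_pool=free / n,
        n_runs=n,
    )
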