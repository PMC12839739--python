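"""Seeded synthetic data: Wright-Fisher haplotypes, q-tracks and toy GTFs.

The simulator is a discrete-generation haploid Wright-Fisher model on a
single autosome: each offspring copies one parent, or recombines two
(crossovers Poisson with rate ``r`` per bp per generation, breakpoints
uniform), and acquires new mutations (Poisson with rate ``mu`` per bp
per generation) at fresh uniform integer positions (infinite sites:
positions are re-drawn on collision, so every site stays biallelic).

A neutral burn-in of ``burnin_generations`` builds mutation-drift
background variation; if ``s > 0`` a single copy of a beneficial allele
is then injected at ``sweep_pos`` and carriers reproduce with relative
fitness ``1 + s`` until the allele frequency reaches ``stop_freq`` or
``max_generations`` pass. Lost sweeps restart from the post-burn-in
state (conditioning on establishment) up to a retry cap. Finally
``n_sample`` haplotypes are drawn without replacement and only sites
segregating in the sample are emitted, sorted by position.

Everything is deterministic given ``seed``. Defaults are sized so one
replicate (400-haplotype population, 2 Mb, ~1,000 sampled SNPs) runs in
seconds, which is what makes seeded many-replicate calibration and
recovery testing practical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneRecord, HaplotypeMatrix


@dataclass
class SimulationConfig:
    n_haplotypes_pop: int = 400
    n_sample: int = 30
    chrom_length: int = 2_000_000
    mu_per_bp_per_gen: float = 1.5e-7
    r_per_bp_per_gen: float = 1.0e-7
    s: float = 0.0
    sweep_pos: int = 1_025_000  # mid-window: off the 50 kb analysis grid edge
    stop_freq: float = 0.8
    max_generations: int = 2_000
    burnin_generations: int = 3_200
    seed: int = 0
    chrom: str = "1"
    max_sweep_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_sample > self.n_haplotypes_pop:
            raise ValueError("n_sample must not exceed n_haplotypes_pop")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 1 <= self.sweep_pos <= self.chrom_length:
            raise ValueError("sweep_pos must lie on the chromosome")
        if not 0 < self.stop_freq <= 1:
            raise ValueError("stop_freq must be in (0, 1]")


@dataclass
class SweepTruth:
    sweep_pos: int
    s: float
    final_freq: float
    generations_run: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.final_freq <= 1.0:
            raise ValueError("final_freq must lie in [0, 1]")


class _Population:
    """Mutable haploid population: N x capacity allele buffer + positions."""

    def __init__(self, n: int, length: int, rng: np.random.Generator,
                 capacity: int = 4096):
        self.n = n
        self.length = length
        self.rng = rng
        self.alleles = np.zeros((n, capacity), dtype=np.uint8)
        self.positions = np.zeros(capacity, dtype=np.int64)
        self.m = 0  # live columns
        self.active_positions: set[int] = set()

    def _grow(self, need: int) -> None:
        cap = self.alleles.shape[1]
        if self.m + need <= cap:
            return
        new_cap = max(2 * cap, self.m + need)
        alleles = np.zeros((self.n, new_cap), dtype=np.uint8)
        alleles[:, : self.m] = self.alleles[:, : self.m]
        positions = np.zeros(new_cap, dtype=np.int64)
        positions[: self.m] = self.positions[: self.m]
        self.alleles, self.positions = alleles, positions

    def add_mutations(self, count: int, carriers: np.ndarray) -> list[int]:
        """Add ``count`` new singleton columns, one per carrier row."""
        if count == 0:
            return []
        self._grow(count)
        draws = self.rng.integers(1, self.length + 1, size=count)
        # infinite sites: re-draw any position colliding with a live site
        # or duplicated within the batch (both rare at realistic densities)
        pos_list: list[int] = []
        for p in draws:
            p = int(p)
            while p in self.active_positions:
                p = int(self.rng.integers(1, self.length + 1))
            self.active_positions.add(p)
            pos_list.append(p)
        cols = list(range(self.m, self.m + count))
        self.positions[self.m: self.m + count] = pos_list
        self.alleles[:, self.m: self.m + count] = 0
        self.alleles[np.asarray(carriers, dtype=np.int64), cols] = 1
        self.m += count
        return cols

    def prune(self, keep_col: int | None = None) -> int | None:
        """Drop fixed and lost columns; returns the new index of keep_col."""
        counts = self.alleles[:, : self.m].sum(axis=0)
        keep = (counts > 0) & (counts < self.n)
        if keep_col is not None:
            keep[keep_col] = counts[keep_col] > 0
        idx = np.flatnonzero(keep)
        new_keep = None
        if keep_col is not None and keep[keep_col]:
            new_keep = int(np.searchsorted(idx, keep_col))
        dropped = self.positions[: self.m][~keep]
        self.active_positions.difference_update(int(p) for p in dropped)
        self.alleles[:, : idx.size] = self.alleles[:, idx]
        self.positions[: idx.size] = self.positions[idx]
        self.m = idx.size
        return new_keep

    def snapshot(self) -> tuple[np.ndarray, np.ndarray, set[int]]:
        return (self.alleles[:, : self.m].copy(),
                self.positions[: self.m].copy(),
                set(self.active_positions))

    def restore(self, snap: tuple[np.ndarray, np.ndarray, set[int]]) -> None:
        alleles, positions, active = snap
        self.m = alleles.shape[1]
        self._grow(0)
        self.alleles[:, : self.m] = alleles
        self.positions[: self.m] = positions
        self.active_positions = set(active)


def _next_generation(pop: _Population, rng: np.random.Generator,
                     mu_total: float, r_total: float,
                     fitness: np.ndarray | None = None) -> None:
    n, m = pop.n, pop.m
    if fitness is None:
        parents_a = rng.integers(0, n, size=n)
    else:
        prob = fitness / fitness.sum()
        parents_a = rng.choice(n, size=n, p=prob)
    n_cross = rng.poisson(r_total, size=n)
    child = pop.alleles[parents_a, : m]  # fancy indexing already copies
    recomb = np.flatnonzero(n_cross > 0)
    if recomb.size and m:
        pos = pop.positions[:m]
        if fitness is None:
            parents_b = rng.integers(0, n, size=recomb.size)
        else:
            parents_b = rng.choice(n, size=recomb.size, p=prob)
        single = n_cross[recomb] == 1
        if single.any():
            # one crossover: the child takes parent B beyond the breakpoint
            rows = recomb[single]
            xs = rng.integers(1, pop.length + 1, size=rows.size)
            take_b = pos[None, :] > xs[:, None]
            b_alleles = pop.alleles[parents_b[single], : m]
            child[rows] = np.where(take_b, b_alleles, child[rows])
        for i, b in zip(recomb[~single], parents_b[~single]):
            xs = np.sort(rng.integers(1, pop.length + 1, size=int(n_cross[i])))
            take_b = np.searchsorted(xs, pos, side="left") % 2 == 1
            child[i, take_b] = pop.alleles[b, : m][take_b]
    pop.alleles[:, :m] = child
    k = int(rng.poisson(mu_total * n))
    if k:
        carriers = rng.integers(0, n, size=k)
        pop.add_mutations(k, carriers)


def simulate_population(config: SimulationConfig) -> tuple[HaplotypeMatrix, SweepTruth]:
    """Run the Wright-Fisher model and sample a phased haplotype matrix.

    Returns the sampled matrix (segregating sites only, sorted positions)
    and the ground truth of the sweep (final population frequency of the
    beneficial allele and generations run in the selection phase;
    ``final_freq = 0`` for neutral runs).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_haplotypes_pop
    mu_total = cfg.mu_per_bp_per_gen * cfg.chrom_length
    r_total = cfg.r_per_bp_per_gen * cfg.chrom_length
    pop = _Population(n, cfg.chrom_length, rng)

    for gen in range(cfg.burnin_generations):
        _next_generation(pop, rng, mu_total, r_total)
        if gen % 10 == 9:
            pop.prune()
    pop.prune()

    generations_run = 0
    final_freq = 0.0
    if cfg.s > 0:
        snap = pop.snapshot()
        established = False
        for _attempt in range(cfg.max_sweep_retries):
            pop.restore(snap)
            if cfg.sweep_pos in pop.active_positions:
                # burn-in already used this position; drop that column first
                col = int(np.flatnonzero(
                    pop.positions[: pop.m] == cfg.sweep_pos)[0])
                pop.alleles[:, col: pop.m - 1] = pop.alleles[:, col + 1: pop.m]
                pop.positions[col: pop.m - 1] = pop.positions[col + 1: pop.m]
                pop.m -= 1
                pop.active_positions.discard(cfg.sweep_pos)
            carrier = np.array([int(rng.integers(0, n))])
            sweep_col = pop.add_mutations(1, carrier)[0]
            # place the sweep position explicitly (add_mutations drew random)
            pop.active_positions.discard(int(pop.positions[sweep_col]))
            pop.positions[sweep_col] = cfg.sweep_pos
            pop.active_positions.add(cfg.sweep_pos)
            generations_run = 0
            while generations_run < cfg.max_generations:
                fitness = 1.0 + cfg.s * pop.alleles[:, sweep_col].astype(float)
                _next_generation(pop, rng, mu_total, r_total, fitness=fitness)
                generations_run += 1
                count = int(pop.alleles[:, sweep_col].sum())
                if count == 0:
                    break
                if count / n >= cfg.stop_freq:
                    break
                if generations_run % 25 == 0:
                    sweep_col = pop.prune(keep_col=sweep_col)
            count = int(pop.alleles[:, sweep_col].sum()) if sweep_col is not None else 0
            if count / n >= cfg.stop_freq:
                established = True
                final_freq = count / n
                break
        if not established:
            raise RuntimeError(
                f"sweep allele never reached stop_freq in {cfg.max_sweep_retries} attempts"
            )
        pop.prune()

    sample_rows = rng.choice(n, size=cfg.n_sample, replace=False)
    sub = pop.alleles[np.ix_(sample_rows, np.arange(pop.m))]
    counts = sub.sum(axis=0)
    seg = (counts > 0) & (counts < cfg.n_sample)
    positions = pop.positions[: pop.m][seg]
    alleles = sub[:, seg]
    order = np.argsort(positions, kind="mergesort")
    matrix = HaplotypeMatrix(
        chrom=cfg.chrom,
        positions=positions[order],
        alleles=alleles[:, order],
        sample_ids=[f"S{i:03d}" for i in range(cfg.n_sample // 2)],
    )
    truth = SweepTruth(sweep_pos=cfg.sweep_pos, s=cfg.s,
                       final_freq=final_freq, generations_run=generations_run)
    return matrix, truth


def make_qtrack_fixture(blocks: list[tuple[int, float, int]],
                        chrom: str = "1", start_pos: int = 10_000) -> pd.DataFrame:
    """Deterministic SNP skeleton with only q filled, for region-builder tests.

    ``blocks`` is a list of ``(n_snps, q_value, inter_snp_spacing_bp)``
    tuples; blocks are laid out consecutively from ``start_pos``, each SNP
    offset from the previous one by the block's spacing.
    """
    if not blocks:
        raise ValueError("q-track block list must be non-empty")
    rows = []
    pos = start_pos
    first = True
    for n_snps, q, spacing in blocks:
        for _ in range(n_snps):
            if not first:
                pos += spacing
            first = False
            rows.append({"chrom": chrom, "pos": pos, "q": float(q)})
    return pd.DataFrame(rows)


def make_toy_gtf(genes: list[tuple[str, str, int, int]], path: str) -> None:
    """Write gene features as a syntactically valid GTF.

    ``genes`` holds ``(gene_id, chrom, start, end)`` tuples, 1-based
    inclusive; ``read_gtf_genes`` inverts this writer exactly.
    """
    records = [GeneRecord(gene_id=g, chrom=c, start=s, end=e)
               for g, c, s, e in genes]  # validates start <= end
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic-toy\n")
        for rec in records:
            fh.write(
                f"{rec.chrom}\tdcmscan\tgene\t{rec.start}\t{rec.end}\t.\t+\t.\t"
                f'gene_id "{rec.gene_id}"; gene_biotype "protein_coding";\n'
            )
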