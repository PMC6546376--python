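"""Forward-in-time Wright–Fisher simulation of one chromosome.

The model: a single panmictic diploid population of constant size ``N``,
discrete non-overlapping generations, an arbitrary piecewise-constant
recombination map (typically containing a coldspot), and recurrent neutral
and deleterious mutation — no beneficial mutations.  Fitness is
multiplicative across sites (heterozygote ``1 + h s``, homozygote ``1 + s``,
``s <= 0``).  After a burn-in (default ``10 N`` generations) a set of
haplotypes is sampled and handed to the genome-scan statistics.

Population-size rescaling by a factor ``Q`` (``N -> N/Q`` with ``mu``, the
map rates and ``s`` multiplied by ``Q``) preserves the products ``N mu``,
``N r`` and ``N s`` that govern diversity, linkage and the efficacy of
selection, and makes chromosome-scale runs practical on a single CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen_stats import HaplotypeMatrix, ScanTrack

__all__ = [
    "RecombinationMap",
    "DFEConfig",
    "ForwardSimParams",
    "SimSample",
    "recombine_gamete",
    "run_simulation",
    "rescale_params",
    "full_scale_params",
    "desk_scale_params",
    "coldspot_contrast",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant per-bp crossover rates covering ``[0, L)``.

    ``breaks`` has one more entry than ``rates``; interval ``i`` is
    ``[breaks[i], breaks[i+1])`` with per-bp per-generation rate
    ``rates[i]``.
    """

    breaks: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "breaks", np.asarray(self.breaks, dtype=np.float64))
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=np.float64))
        if self.breaks.ndim != 1 or self.rates.shape != (self.breaks.size - 1,):
            raise ValueError("breaks must have len(rates)+1 entries")
        if self.breaks[0] != 0:
            raise ValueError("map must start at 0")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_intervals(cls, intervals) -> "RecombinationMap":
        """Build from ordered ``(start, end, rate)`` spans covering [0, L)."""
        intervals = sorted(intervals)
        breaks = [intervals[0][0]]
        rates = []
        for start, end, rate in intervals:
            if start != breaks[-1]:
                raise ValueError("intervals must tile [0, L) without gaps/overlaps")
            breaks.append(end)
            rates.append(rate)
        return cls(np.array(breaks, float), np.array(rates, float))

    @classmethod
    def uniform(cls, length: int, rate: float) -> "RecombinationMap":
        return cls(np.array([0.0, float(length)]), np.array([rate]))

    @classmethod
    def with_coldspot(
        cls,
        length: int,
        base_rate: float,
        coldspot_start: int,
        coldspot_length: int,
        factor: float = 0.01,
    ) -> "RecombinationMap":
        """Uniform map with one interval at ``base_rate * factor``."""
        s, e = coldspot_start, coldspot_start + coldspot_length
        if not (0 <= s < e <= length):
            raise ValueError("coldspot must lie inside [0, length)")
        return cls.from_intervals(
            [(0, s, base_rate), (s, e, base_rate * factor), (e, length, base_rate)]
        )

    @property
    def length(self) -> float:
        return float(self.breaks[-1])

    @property
    def total_morgans(self) -> float:
        return float(np.sum(self.rates * np.diff(self.breaks)))

    def _cum_morgans(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.rates * np.diff(self.breaks))])

    def sample_breakpoints(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``k`` crossover positions with density proportional to rate."""
        cum = self._cum_morgans()
        u = rng.uniform(0, cum[-1], size=k)
        return np.interp(u, cum, self.breaks)

    def scaled(self, q: float) -> "RecombinationMap":
        return RecombinationMap(self.breaks.copy(), self.rates * q)


@dataclass(frozen=True)
class DFEConfig:
    """Distribution of fitness effects for new mutations.

    A fraction ``p_deleterious`` of mutations is deleterious with selection
    coefficient ``s_mean`` (< 0); the remainder is strictly neutral.  When
    ``s_shape`` is given, deleterious magnitudes are gamma-distributed with
    mean ``|s_mean|`` and the given shape.  ``h`` is the dominance
    coefficient of deleterious mutations.
    """

    p_deleterious: float = 0.3
    s_mean: float = -0.02
    s_shape: float | None = None
    h: float = 0.25

    def __post_init__(self):
        if not (0 <= self.p_deleterious <= 1):
            raise ValueError("p_deleterious must be in [0, 1]")
        if self.p_deleterious > 0 and self.s_mean >= 0:
            raise ValueError("deleterious s_mean must be negative")
        if self.s_mean <= -1:
            raise ValueError("s_mean must exceed -1 (fitness must stay positive)")

    def draw_s(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Selection coefficients for ``n`` new mutations (0 = neutral)."""
        s = np.zeros(n)
        if self.p_deleterious > 0 and n:
            deleterious = rng.random(n) < self.p_deleterious
            nd = int(deleterious.sum())
            if self.s_shape is None:
                s[deleterious] = self.s_mean
            else:
                mag = rng.gamma(
                    self.s_shape, -self.s_mean / self.s_shape, size=nd
                )
                s[deleterious] = -np.minimum(mag, 1 - 1e-9)
        return s

    def scaled(self, q: float) -> "DFEConfig":
        s = self.s_mean * q
        if s <= -1:
            raise ValueError(f"rescaled s = {s} <= -1: fitness would be non-positive")
        return dataclasses.replace(self, s_mean=s)


@dataclass(frozen=True)
class ForwardSimParams:
    """Complete specification of one forward run."""

    N: int
    L: int
    mu: float
    recomb_map: RecombinationMap
    dfe: DFEConfig = field(default_factory=DFEConfig)
    burnin: int | None = None  # default 10 N
    sample_n: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if int(self.recomb_map.length) != self.L:
            raise ValueError("recombination map must cover exactly [0, L)")
        if not (1 <= self.sample_n <= 2 * self.N):
            raise ValueError("sample_n must be in [1, 2N]")

    @property
    def burnin_generations(self) -> int:
        return 10 * self.N if self.burnin is None else self.burnin


@dataclass
class SimSample:
    """Haplotypes sampled at the end of a run, with mutation annotations."""

    haplotypes: HaplotypeMatrix
    mutations: pd.DataFrame       # position, s, origin_gen for sampled sites
    substitutions: pd.DataFrame   # fixed mutations pruned during the run
    params: ForwardSimParams


def rescale_params(params: ForwardSimParams, q: float) -> ForwardSimParams:
    """Rescale by ``Q``: N/Q, mu·Q, map·Q, s·Q; N mu, N r, N s preserved."""
    if q < 1:
        raise ValueError("Q must be >= 1")
    n = int(round(params.N / q))
    if n < 2:
        raise ValueError("N/Q must be >= 2")
    return ForwardSimParams(
        N=n,
        L=params.L,
        mu=params.mu * q,
        recomb_map=params.recomb_map.scaled(q),
        dfe=params.dfe.scaled(q),
        burnin=None if params.burnin is None else max(1, int(round(params.burnin / q))),
        sample_n=params.sample_n,
        seed=params.seed,
    )


# Design defaults for the coldspot experiment: a 20 Mb chromosome with a
# central 1.6 Mb coldspot at 1% of the background crossover rate, and 30% of
# mutations deleterious.  The desk-scale preset shortens the chromosome to
# 5 Mb (coldspot 400 kb, same proportion) and rescales by Q = 10 so a full
# replicate runs in well under five minutes on one CPU.
FULL_N = 5_000
FULL_MU = 1e-8
FULL_RATE = 1e-8
COLDSPOT_FACTOR = 0.01


def full_scale_params(deleterious: bool = True, seed: int = 0) -> ForwardSimParams:
    """20 Mb chromosome, central 1.6 Mb coldspot, unscaled population."""
    L = 20_000_000
    cold_len = 1_600_000
    dfe = DFEConfig(p_deleterious=0.3 if deleterious else 0.0)
    return ForwardSimParams(
        N=FULL_N,
        L=L,
        mu=FULL_MU,
        recomb_map=RecombinationMap.with_coldspot(
            L, FULL_RATE, (L - cold_len) // 2, cold_len, COLDSPOT_FACTOR
        ),
        dfe=dfe,
        seed=seed,
    )


def desk_scale_params(deleterious: bool = True, seed: int = 0, q: float = 10.0) -> ForwardSimParams:
    """5 Mb chromosome with a central 400 kb coldspot, rescaled by Q."""
    L = 5_000_000
    cold_len = 400_000
    dfe = DFEConfig(p_deleterious=0.3 if deleterious else 0.0)
    unscaled = ForwardSimParams(
        N=FULL_N,
        L=L,
        mu=FULL_MU,
        recomb_map=RecombinationMap.with_coldspot(
            L, FULL_RATE, (L - cold_len) // 2, cold_len, COLDSPOT_FACTOR
        ),
        dfe=dfe,
        seed=seed,
    )
    return rescale_params(unscaled, q)


def desk_coldspot_interval(params: ForwardSimParams) -> tuple[int, int]:
    """(start, end) of the lowest-rate map interval (the coldspot)."""
    i = int(np.argmin(params.recomb_map.rates))
    return int(params.recomb_map.breaks[i]), int(params.recomb_map.breaks[i + 1])


# ---------------------------------------------------------------------------
# gamete formation (reference implementation; the engine uses the kernel)
# ---------------------------------------------------------------------------


def recombine_gamete(
    parent_hap_a: np.ndarray,
    parent_hap_b: np.ndarray,
    positions: np.ndarray,
    recomb_map: RecombinationMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from two parental haplotypes.

    The crossover count is Poisson(total map length in Morgans), breakpoint
    positions have density proportional to the local rate, and the gamete
    alternates parental origin at each breakpoint, starting from a uniformly
    chosen parent.
    """
    if parent_hap_a.shape != parent_hap_b.shape:
        raise ValueError("parental haplotypes must have the same shape")
    k = rng.poisson(recomb_map.total_morgans)
    start = rng.integers(0, 2)
    first, second = (parent_hap_a, parent_hap_b) if start == 0 else (
        parent_hap_b,
        parent_hap_a,
    )
    if k == 0:
        return first.copy()
    bps = np.sort(recomb_map.sample_breakpoints(k, rng))
    parity = np.searchsorted(bps, positions, side="right") % 2
    return np.where(parity == 0, first, second).astype(first.dtype)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------
#
# Two interchangeable population representations drive the same generation
# loop (identical RNG call sequence, hence bit-identical results):
#
# * _PackedState — haplotypes bit-packed into uint64 words, with numba
#   kernels for gamete formation, fitness, column counting and compaction.
#   This is the default; a chromosome-scale replicate is memory-bandwidth
#   bound and packing cuts the traffic by 8x.
# * _DenseState — plain uint8 allele matrix in NumPy; the executable
#   reference used by the equivalence tests (use_kernel=False).
#
# Columns [0, m_sorted) are kept sorted by bp position so crossover segments
# are contiguous; newly arisen mutations accumulate in an unsorted tail and
# full sorting is restored at each prune.


class _DenseState:
    """uint8 allele-matrix population state (reference implementation)."""

    def __init__(self, n_hap: int, cap: int = 4096):
        self.n_hap = n_hap
        self.H = np.zeros((n_hap, cap), dtype=np.uint8)
        self.H2 = np.zeros((n_hap, cap), dtype=np.uint8)
        self.pos = np.zeros(cap, dtype=np.int64)
        self.sel = np.zeros(cap, dtype=np.float64)
        self.origin = np.zeros(cap, dtype=np.int64)
        self.m = 0
        self.m_sorted = 0
        self.pos_set: set[int] = set()

    def _grow_cols(self, need: int):
        cap = self.pos.size
        while cap < need:
            cap *= 2
        if cap > self.pos.size:
            for name in ("H", "H2"):
                old = getattr(self, name)
                new = np.zeros((self.n_hap, cap), dtype=old.dtype)
                new[:, : self.m] = old[:, : self.m]
                setattr(self, name, new)
            self._grow_meta(cap)

    def _grow_meta(self, cap: int):
        for name in ("pos", "sel", "origin"):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=old.dtype)
            new[: self.m] = old[: self.m]
            setattr(self, name, new)

    def seed_mutation(self, position: int, s: float, rows: np.ndarray):
        i = self.m
        self._grow_cols(i + 1)
        self.pos[i] = position
        self.sel[i] = s
        self.origin[i] = 0
        self.H[rows, i] = 1
        self.pos_set.add(int(position))
        self.m += 1
        self.m_sorted = self.m

    def make_gametes(self, parents, starts, bp_flat, bp_off):
        m = self.m
        pos = self.pos[:m]
        for g in range(parents.size):
            a = 2 * parents[g] + starts[g]
            b = 2 * parents[g] + (1 - starts[g])
            bps = bp_flat[bp_off[g] : bp_off[g + 1]]
            if bps.size == 0:
                self.H2[g, :m] = self.H[a, :m]
            else:
                parity = np.searchsorted(np.sort(bps), pos, side="right") % 2
                self.H2[g, :m] = np.where(parity == 0, self.H[a, :m], self.H[b, :m])
        self.H, self.H2 = self.H2, self.H

    def add_mutations(self, new_pos, targets, new_sel, gen: int):
        n_new = new_pos.size
        self._grow_cols(self.m + n_new)
        sl = slice(self.m, self.m + n_new)
        self.H[:, sl] = 0
        self.H2[:, sl] = 0
        self.H[targets, np.arange(self.m, self.m + n_new)] = 1
        self.pos[sl] = new_pos
        self.sel[sl] = new_sel
        self.origin[sl] = gen
        self.m += n_new

    def log_fitness(self, selcols, log_het, log_hom) -> np.ndarray:
        a = self.H[0::2, : self.m][:, selcols].astype(np.int64)
        b = self.H[1::2, : self.m][:, selcols].astype(np.int64)
        d = a + b
        return (d == 1) @ log_het + (d == 2) @ log_hom

    def column_counts(self) -> np.ndarray:
        return self.H[:, : self.m].sum(axis=0, dtype=np.int64)

    def reorder(self, order: np.ndarray):
        np.take(self.H[:, : self.m], order, axis=1, out=self.H2[:, : order.size])
        self.H, self.H2 = self.H2, self.H
        self._reorder_meta(order)

    def _reorder_meta(self, order: np.ndarray):
        nk = order.size
        rebuild = nk != self.m
        self.pos[:nk] = self.pos[: self.m][order]
        self.sel[:nk] = self.sel[: self.m][order]
        self.origin[:nk] = self.origin[: self.m][order]
        self.m = nk
        self.m_sorted = nk
        if rebuild:
            self.pos_set = set(int(p) for p in self.pos[:nk])

    def extract_rows(self, rows: np.ndarray) -> np.ndarray:
        return self.H[rows, : self.m].copy()


class _PackedState(_DenseState):
    """Bit-packed uint64 population state with numba kernels."""

    def __init__(self, n_hap: int, cap: int = 4096):
        from . import _kernels as K

        self._K = K
        self.n_hap = n_hap
        wcap = cap // 64
        self.H = np.zeros((n_hap, wcap), dtype=np.uint64)
        self.H2 = np.zeros((n_hap, wcap), dtype=np.uint64)
        self.pos = np.zeros(cap, dtype=np.int64)
        self.sel = np.zeros(cap, dtype=np.float64)
        self.origin = np.zeros(cap, dtype=np.int64)
        self.m = 0
        self.m_sorted = 0
        self.pos_set: set[int] = set()

    def _grow_cols(self, need: int):
        cap = self.pos.size
        while cap < need:
            cap *= 2
        if cap > self.pos.size:
            wcap = cap // 64
            w_act = (self.m + 63) // 64
            for name in ("H", "H2"):
                old = getattr(self, name)
                new = np.zeros((self.n_hap, wcap), dtype=np.uint64)
                new[:, :w_act] = old[:, :w_act]
                setattr(self, name, new)
            self._grow_meta(cap)

    def seed_mutation(self, position: int, s: float, rows: np.ndarray):
        i = self.m
        self._grow_cols(i + 1)
        self.pos[i] = position
        self.sel[i] = s
        self.origin[i] = 0
        self.H[rows, i // 64] |= np.uint64(1) << np.uint64(i % 64)
        self.pos_set.add(int(position))
        self.m += 1
        self.m_sorted = self.m

    def make_gametes(self, parents, starts, bp_flat, bp_off):
        self._K.make_gametes_packed(
            self.H, self.pos, self.m_sorted, self.m, parents, starts,
            bp_flat, bp_off, self.H2,
        )
        self.H, self.H2 = self.H2, self.H

    def add_mutations(self, new_pos, targets, new_sel, gen: int):
        n_new = new_pos.size
        m_new = self.m + n_new
        self._grow_cols(m_new)
        w_old = (self.m + 63) // 64
        w_new = (m_new + 63) // 64
        if w_new > w_old:
            self.H[:, w_old:w_new] = 0
        cols = np.arange(self.m, m_new)
        np.bitwise_or.at(
            self.H,
            (targets, cols >> 6),
            np.uint64(1) << (cols & 63).astype(np.uint64),
        )
        sl = slice(self.m, m_new)
        self.pos[sl] = new_pos
        self.sel[sl] = new_sel
        self.origin[sl] = gen
        self.m = m_new

    def log_fitness(self, selcols, log_het, log_hom) -> np.ndarray:
        out = np.empty(self.n_hap // 2)
        uniform = log_het.size > 0 and np.all(log_het == log_het[0]) and np.all(
            log_hom == log_hom[0]
        )
        if uniform:
            w_act = (self.m + 63) // 64
            selmask = np.zeros(w_act, dtype=np.uint64)
            np.bitwise_or.at(
                selmask,
                selcols >> 6,
                np.uint64(1) << (selcols & 63).astype(np.uint64),
            )
            self._K.log_fitness_packed_uniform(
                self.H, selmask, w_act, float(log_het[0]), float(log_hom[0]), out
            )
        else:
            self._K.log_fitness_packed_cols(self.H, selcols, log_het, log_hom, out)
        return out

    def column_counts(self) -> np.ndarray:
        return self._K.count_columns_packed(self.H, self.m)

    def reorder(self, order: np.ndarray):
        self._K.compact_columns_packed(self.H, self.H2, order)
        self.H, self.H2 = self.H2, self.H
        self._reorder_meta(order)

    def extract_rows(self, rows: np.ndarray) -> np.ndarray:
        return self._K.unpack_rows_packed(self.H, rows, self.m)


def _prune(state, gen: int, substitutions: list):
    """Drop lost/fixed columns, log fixations, restore positional sorting."""
    m = state.m
    if m == 0:
        return
    counts = state.column_counts()
    fixed = counts == state.n_hap
    keep = (counts > 0) & ~fixed
    if fixed.any():
        for i in np.where(fixed)[0]:
            substitutions.append(
                (int(state.pos[i]), float(state.sel[i]), int(state.origin[i]), gen)
            )
    kidx = np.where(keep)[0]
    order = kidx[np.argsort(state.pos[:m][kidx], kind="stable")]
    if order.size == m and state.m_sorted == m and np.array_equal(
        order, np.arange(m)
    ):
        return
    state.reorder(order)


def _unique_positions(n: int, L: int, taken: set, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` uniform integer bp positions not colliding with ``taken``.

    Discrete infinite-sites approximation: collisions are re-drawn.
    """
    if len(taken) + n > 0.9 * L:
        raise RuntimeError(
            "chromosome saturated: nearly every bp already carries a "
            "segregating mutation (increase L or decrease mu)"
        )
    out = np.empty(n, dtype=np.int64)
    got = 0
    while got < n:
        cand = rng.integers(0, L, size=n - got)
        for c in cand:
            ci = int(c)
            if ci not in taken:
                taken.add(ci)
                out[got] = ci
                got += 1
    return out


def run_simulation(
    params: ForwardSimParams,
    init_mutations: list[tuple[int, float, int]] | None = None,
    use_kernel: bool = True,
) -> SimSample:
    """Run one Wright–Fisher replicate and sample haplotypes at the end.

    ``init_mutations`` optionally seeds standing variants as
    ``(position, s, copy_count)`` triples placed on randomly chosen
    haplotypes; useful for fixation-probability experiments with ``mu = 0``.
    The run is fully deterministic given ``params.seed`` and independent of
    ``use_kernel`` (the packed/numba path and the dense NumPy path follow
    the same random-number sequence).
    """
    rng = np.random.default_rng(params.seed)
    n_hap = 2 * params.N
    state = _PackedState(n_hap) if use_kernel else _DenseState(n_hap)
    substitutions: list = []
    if init_mutations:
        for position, s, count in sorted(init_mutations):
            if not (0 < count <= n_hap):
                raise ValueError("init mutation copy count must be in (0, 2N]")
            rows = rng.choice(n_hap, size=count, replace=False)
            state.seed_mutation(int(position), float(s), rows)

    tot_morgans = params.recomb_map.total_morgans
    mu_per_gamete = params.mu * params.L
    h = params.dfe.h
    burnin = params.burnin_generations
    prune_every = 8

    for gen in range(1, burnin + 1):
        if state.m == 0 and mu_per_gamete == 0:
            break  # monomorphic and no mutation: nothing can change
        parents = _select_parents(state, params, h, rng)
        starts = rng.integers(0, 2, size=n_hap).astype(np.int64)
        ks = rng.poisson(tot_morgans, size=n_hap)
        bp_off = np.zeros(n_hap + 1, dtype=np.int64)
        np.cumsum(ks, out=bp_off[1:])
        bp_flat = params.recomb_map.sample_breakpoints(int(bp_off[-1]), rng)
        state.make_gametes(parents, starts, bp_flat, bp_off)
        n_new = rng.poisson(mu_per_gamete * n_hap)
        if n_new:
            new_pos = _unique_positions(n_new, params.L, state.pos_set, rng)
            targets = rng.integers(0, n_hap, size=n_new)
            new_sel = params.dfe.draw_s(n_new, rng)
            state.add_mutations(new_pos, targets, new_sel, gen)
        if gen % prune_every == 0:
            _prune(state, gen, substitutions)

    _prune(state, burnin, substitutions)

    # sample haplotypes without replacement; keep in-sample polymorphic sites
    idx = np.sort(rng.choice(n_hap, size=params.sample_n, replace=False))
    sub = state.extract_rows(idx)
    counts = sub.sum(axis=0, dtype=np.int64)
    poly = (counts > 0) & (counts < params.sample_n)
    sub = sub[:, poly]
    spos = state.pos[: state.m][poly]
    ssel = state.sel[: state.m][poly]
    sorig = state.origin[: state.m][poly]
    order = np.argsort(spos)
    hm = HaplotypeMatrix(sub[:, order], spos[order], chrom="sim", length=params.L)
    mutations = pd.DataFrame(
        {"position": spos[order], "s": ssel[order], "origin_gen": sorig[order]}
    )
    subs = pd.DataFrame(
        substitutions, columns=["position", "s", "origin_gen", "fixed_gen"]
    )
    return SimSample(hm, mutations, subs, params)


def _select_parents(state, params, h, rng):
    """Fitness-weighted parent draw (uniform when no selected site segregates)."""
    n_hap = 2 * params.N
    selcols = np.where(state.sel[: state.m] < 0)[0]
    if selcols.size == 0:
        return rng.integers(0, params.N, size=n_hap).astype(np.int64)
    s = state.sel[: state.m][selcols]
    logw = state.log_fitness(selcols, np.log1p(h * s), np.log1p(s))
    best = logw.max()
    if not np.isfinite(best) or best < -700:
        # even the fittest genotype's fitness would underflow a float64
        raise RuntimeError(
            "mean fitness underflow: deleterious load too high for these "
            "parameters (consider weaker s, lower p_deleterious, or less rescaling)"
        )
    w = np.exp(logw - best)
    total = w.sum()
    return rng.choice(params.N, size=n_hap, p=w / total).astype(np.int64)


# ---------------------------------------------------------------------------
# coldspot contrast
# ---------------------------------------------------------------------------


@dataclass
class ContrastSummary:
    statistic: str
    inside_mean: float
    outside_mean: float

    @property
    def ratio(self) -> float:
        return self.inside_mean / self.outside_mean


def coldspot_contrast(
    tracks: dict[str, ScanTrack],
    coldspot: tuple[int, int],
    flank_margin: int = 200_000,
    use_smoothed: tuple[str, ...] = (),
) -> dict[str, ContrastSummary]:
    """Mean of each track inside the coldspot vs the flanks.

    The flanks are everything outside ``coldspot`` widened by
    ``flank_margin`` bp on each side (the margin removes positions whose
    statistic is partly shaped by the coldspot).  For statistics named in
    ``use_smoothed`` the smoothed channel is compared instead of the raw one.
    """
    start, end = coldspot
    out = {}
    for name, track in tracks.items():
        vals = (
            track.smoothed
            if name in use_smoothed and track.smoothed is not None
            else track.raw
        )
        p = track.positions
        inside = (p >= start) & (p < end)
        outside = (p < start - flank_margin) | (p >= end + flank_margin)
        vi = vals[inside]
        vo = vals[outside]
        vi = vi[np.isfinite(vi)]
        vo = vo[np.isfinite(vo)]
        if vi.size == 0:
            raise ValueError(f"track {name!r} has no finite value in the coldspot")
        if vo.size == 0:
            raise ValueError(f"track {name!r} has no finite value in the flanks")
        out[name] = ContrastSummary(name, float(vi.mean()), float(vo.mean()))
    return out
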