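"""Multi-objective metaheuristics for formulation search.

Three population methods minimize the penalized release objectives over the
box-bounded excipient space: NSGA-III (reference-direction niching), MOGWO
(grey-wolf leaders drawn from a gridded external archive) and NSWOA (whale
operators with non-dominated sorting and crowding truncation).  Shared
machinery - fast non-dominated sorting, crowding distance, Das-Dennis
reference directions - lives here too, along with multi-run pooling into a
Table-5-style candidate table.

All runs are driven by a single integer seed through one dedicated
generator; identical seeds give identical archives.  Fitness histories
record, per generation, the best-so-far and population-mean scalarized
fitness -(Q1+Q2+Q3) (higher is better), the convention used for convergence
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import DEFAULT_BOUNDS
from .release_objectives import DEFAULT_LIMITS, ReleaseLimits

__all__ = [
    "OptimizerConfig",
    "ParetoArchive",
    "fast_nondominated_sort",
    "crowding_distance",
    "das_dennis_points",
    "run_nsga3",
    "run_mogwo",
    "run_nswoa",
    "run_all",
    "pool_candidates",
    "select_leader_indices",
]

ALGORITHMS = ("NSGA-III", "MOGWO", "NSWOA")


@dataclass(frozen=True)
class OptimizerConfig:
    """Shared and per-algorithm optimizer settings.

    Defaults follow the study protocol: population 100, 200 generations, 15
    independent runs per algorithm; NSGA-III single-point crossover Pc=0.8
    and mutation Pm=0.05; MOGWO grid inflation alpha=0.1, leader pressure
    beta=5, deletion pressure gamma=2; NSWOA progress every ishow=10
    generations.  Box bounds default to the observed component ranges of the
    reference design.
    """

    population: int = 100
    generations: int = 200
    runs: int = 15
    bounds: tuple = DEFAULT_BOUNDS
    pc: float = 0.8
    pm: float = 0.05
    reference_divisions: int = 13
    archive_size: int = 100
    grid_alpha: float = 0.1
    leader_beta: float = 5.0
    delete_gamma: float = 2.0
    grid_divisions: int = 10
    ishow: int = 10
    init_on_plane: bool = True

    def __post_init__(self):
        if self.population <= 0 or self.generations <= 0:
            raise ValueError("population and generations must be positive")
        if not (0 <= self.pc <= 1 and 0 <= self.pm <= 1):
            raise ValueError("Pc and Pm must lie in [0, 1]")
        b = np.asarray(self.bounds, dtype=float)
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("bounds need lo < hi per component")
        object.__setattr__(self, "bounds", tuple((float(lo), float(hi)) for lo, hi in b))

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class ParetoArchive:
    """Final non-dominated set of one optimizer run plus its fitness history."""

    algorithm: str
    X: np.ndarray  # (k, q) decision vectors
    F: np.ndarray  # (k, M) objective values (minimized)
    Y: np.ndarray | None  # (k, M) predicted releases, when available
    history: pd.DataFrame  # generation, best, mean
    seed: int


# ---------------------------------------------------------------------------
# Pareto machinery


def _domination_matrix(F: np.ndarray) -> np.ndarray:
    """D[i, j] True iff point i Pareto-dominates point j (minimization)."""
    le = (F[:, None, :] <= F[None, :, :]).all(axis=-1)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=-1)
    return le & lt


def fast_nondominated_sort(points, minimize: bool = True) -> list:
    """Peel points into Pareto fronts; returns a list of index arrays."""
    F = np.asarray(points, dtype=float)
    if F.ndim != 2:
        raise ValueError("points must be a 2-D array of objective vectors")
    if not minimize:
        F = -F
    n = len(F)
    D = _domination_matrix(F)
    n_dominators = D.sum(axis=0)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        front = np.flatnonzero(remaining & (n_dominators == 0))
        if len(front) == 0:  # cannot happen with consistent dominance
            front = np.flatnonzero(remaining)
        fronts.append(front)
        remaining[front] = False
        n_dominators = n_dominators - D[front].sum(axis=0)
    return fronts


def nondominated_mask(F: np.ndarray) -> np.ndarray:
    D = _domination_matrix(np.asarray(F, dtype=float))
    return ~D.any(axis=0)


def crowding_distance(front_points) -> np.ndarray:
    """Per-point crowding distance within one front.

    Boundary points per objective are infinite; interior points accumulate
    the normalized neighbor gap; zero-range objectives contribute nothing.
    """
    F = np.atleast_2d(np.asarray(front_points, dtype=float))
    n, M = F.shape
    dist = np.zeros(n)
    if n == 0:
        return dist
    for j in range(M):
        order = np.argsort(F[:, j], kind="stable")
        rng = F[order[-1], j] - F[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if rng > 0 and n > 2:
            gaps = (F[order[2:], j] - F[order[:-2], j]) / rng
            dist[order[1:-1]] += gaps
    return dist


def das_dennis_points(M: int, p: int) -> np.ndarray:
    """Uniform reference directions on the unit simplex (Das-Dennis).

    All M-vectors with non-negative components that are multiples of 1/p and
    sum to 1; count = C(p + M - 1, M - 1).
    """
    if M < 2 or p < 1:
        raise ValueError("need M >= 2 objectives and p >= 1 divisions")

    def rec(levels_left, dims_left):
        if dims_left == 1:
            return [[levels_left]]
        return [[k] + rest for k in range(levels_left + 1)
                for rest in rec(levels_left - k, dims_left - 1)]

    return np.array(rec(p, M), dtype=float) / p


# ---------------------------------------------------------------------------
# shared run helpers


def _init_population(rng, config: OptimizerConfig, objectives) -> np.ndarray:
    """Initial population; feasibility-aware for mixture problems.

    When the objective set carries a constant-sum penalty (and
    ``init_on_plane`` is enabled), starting points are box draws orthogonally
    projected onto the constant-sum plane, with out-of-box projections
    rejected - the natural way to seed a mixture search, since any point off
    the plane is dominated by the exterior penalty.  Otherwise: plain
    uniform draws within the box.
    """
    lo, hi = config.lo, config.hi
    N, q = config.population, len(lo)
    total = getattr(getattr(objectives, "penalty", None), "total", None)
    if not config.init_on_plane or total is None:
        return rng.uniform(lo, hi, size=(N, q))
    out = np.empty((0, q))
    for _ in range(200):
        x = rng.uniform(lo, hi, size=(4 * N, q))
        x += (total - x.sum(axis=1, keepdims=True)) / q
        ok = np.all((x >= lo) & (x <= hi), axis=1)
        out = np.vstack([out, x[ok]])
        if len(out) >= N:
            return out[:N]
    raise RuntimeError("could not sample the constant-sum plane inside the bounds")


def _as_batch_objective(objectives):
    """Accept a batch callable (k,q)->(k,M) or a list of scalar callables."""
    if callable(objectives):
        return objectives
    fns = list(objectives)

    def batch(X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([[f(x) for x in X] for f in fns])

    return batch


def _releases_of(objectives, X):
    rel = getattr(objectives, "releases", None)
    if rel is None or len(X) == 0:
        return None
    return np.atleast_2d(rel(X))


def _fitness(F: np.ndarray) -> np.ndarray:
    """Scalarized reporting fitness: -(Q1+...+QM), higher is better."""
    return -F.sum(axis=1)


class _History:
    def __init__(self):
        self.rows = []
        self.best = -np.inf

    def log(self, gen: int, F: np.ndarray):
        fit = _fitness(F)
        self.best = max(self.best, float(fit.max()))
        self.rows.append((gen, self.best, float(fit.mean())))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["generation", "best", "mean"])


def _finalize(algorithm, X, F, objectives, history, seed, config) -> ParetoArchive:
    mask = nondominated_mask(F)
    Xn, Fn = X[mask], F[mask]
    np.clip(Xn, config.lo, config.hi, out=Xn)
    return ParetoArchive(
        algorithm=algorithm,
        X=Xn,
        F=Fn,
        Y=_releases_of(objectives, Xn),
        history=history.frame(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# NSGA-III


def _tournament_ranks(F: np.ndarray) -> np.ndarray:
    ranks = np.empty(len(F), dtype=int)
    for r, front in enumerate(fast_nondominated_sort(F)):
        ranks[front] = r
    return ranks


def _single_point_crossover(a, b, rng, pc):
    """Tail swap of the real-coded vectors at a random locus."""
    if rng.random() >= pc or len(a) < 2:
        return a.copy(), b.copy()
    cut = rng.integers(1, len(a))
    c1 = np.concatenate([a[:cut], b[cut:]])
    c2 = np.concatenate([b[:cut], a[cut:]])
    return c1, c2


def _mutate(X, rng, pm, lo, hi):
    mask = rng.random(X.shape) < pm
    X[mask] = rng.uniform(np.broadcast_to(lo, X.shape)[mask],
                          np.broadcast_to(hi, X.shape)[mask])
    return X


def _associate(Fn: np.ndarray, dirs: np.ndarray):
    """Nearest reference direction (perpendicular distance) per point."""
    norm = np.linalg.norm(dirs, axis=1)
    proj = (Fn @ dirs.T) / norm  # scalar projections
    d2 = (Fn**2).sum(axis=1, keepdims=True) - proj**2
    d2 = np.maximum(d2, 0.0)
    dist = np.sqrt(d2)
    niche = dist.argmin(axis=1)
    return niche, dist[np.arange(len(Fn)), niche]


def _niching_select(need, last_F, niche, perp, counts, rng):
    """NSGA-III niche-preservation pick of ``need`` members of the last front."""
    chosen = []
    avail = np.ones(len(last_F), dtype=bool)
    active = set(np.unique(niche)) | set(np.flatnonzero(counts > 0))
    active = sorted(active)
    while len(chosen) < need:
        cand_niches = [j for j in active if np.any(avail & (niche == j))]
        if not cand_niches:
            left = np.flatnonzero(avail)
            pick = rng.choice(left, size=need - len(chosen), replace=False)
            chosen.extend(pick.tolist())
            break
        cmin = min(counts[j] for j in cand_niches)
        jbar = rng.choice([j for j in cand_niches if counts[j] == cmin])
        members = np.flatnonzero(avail & (niche == jbar))
        if counts[jbar] == 0:
            pick = members[np.argmin(perp[members])]
        else:
            pick = rng.choice(members)
        chosen.append(int(pick))
        avail[pick] = False
        counts[jbar] += 1
    return np.array(chosen, dtype=int)


def run_nsga3(objectives, config: OptimizerConfig, seed: int) -> ParetoArchive:
    """Reference-direction NSGA-III over the box-bounded composition space."""
    f = _as_batch_objective(objectives)
    rng = np.random.default_rng(seed)
    lo, hi = config.lo, config.hi
    N, q = config.population, len(lo)
    dirs = das_dennis_points(3, config.reference_divisions)

    X = _init_population(rng, config, objectives)
    F = np.atleast_2d(f(X))
    hist = _History()
    hist.log(0, F)

    for gen in range(1, config.generations + 1):
        ranks = _tournament_ranks(F)
        # binary tournament by front rank, random tie-break
        i1 = rng.integers(0, N, N)
        i2 = rng.integers(0, N, N)
        better = np.where(ranks[i1] < ranks[i2], i1,
                          np.where(ranks[i2] < ranks[i1], i2,
                                   np.where(rng.random(N) < 0.5, i1, i2)))
        parents = X[better]
        kids = np.empty_like(parents)
        for k in range(0, N - 1, 2):
            kids[k], kids[k + 1] = _single_point_crossover(parents[k], parents[k + 1],
                                                           rng, config.pc)
        if N % 2:
            kids[-1] = parents[-1].copy()
        kids = _mutate(kids, rng, config.pm, lo, hi)
        np.clip(kids, lo, hi, out=kids)
        Fk = np.atleast_2d(f(kids))

        Xall = np.vstack([X, kids])
        Fall = np.vstack([F, Fk])
        fronts = fast_nondominated_sort(Fall)
        keep = []
        for front in fronts:
            if len(keep) + len(front) <= N:
                keep.extend(front.tolist())
                if len(keep) == N:
                    break
            else:
                need = N - len(keep)
                considered = np.array(keep + front.tolist(), dtype=int)
                ideal = Fall[considered].min(axis=0)
                span = Fall[considered].max(axis=0) - ideal
                span[span <= 0] = 1.0
                Fn = (Fall[considered] - ideal) / span
                niche, perp = _associate(Fn, dirs)
                n_kept = len(keep)
                counts = np.bincount(niche[:n_kept], minlength=len(dirs))
                sel = _niching_select(need, Fn[n_kept:], niche[n_kept:],
                                      perp[n_kept:], counts, rng)
                keep.extend(front[sel].tolist())
                break
        X, F = Xall[keep], Fall[keep]
        hist.log(gen, F)

    return _finalize("NSGA-III", X, F, objectives, hist, seed, config)


# ---------------------------------------------------------------------------
# MOGWO


def _grid_cells(F: np.ndarray, alpha: float, divisions: int) -> np.ndarray:
    """Flat hypercube-cell index per archive member (inflated adaptive grid)."""
    lo = F.min(axis=0)
    hi = F.max(axis=0)
    span = hi - lo
    lo = lo - alpha * span
    hi = hi + alpha * span
    width = np.where(hi > lo, hi - lo, 1.0)
    ix = np.floor((F - lo) / width * divisions).astype(int)
    ix = np.clip(ix, 0, divisions - 1)
    return np.ravel_multi_index(ix.T, (divisions,) * F.shape[1])


def select_leader_indices(F: np.ndarray, config: OptimizerConfig, rng,
                          n_leaders: int = 3) -> np.ndarray:
    """Leaders via roulette over inverse grid-cell density ^ leader_beta.

    Sparse cells are favored; within the winning cell a member is drawn
    uniformly.  Repeated draws exclude already-chosen members when the
    archive is large enough; with a single occupied cell this reduces to
    uniform archive sampling.
    """
    k = len(F)
    cells = _grid_cells(F, config.grid_alpha, config.grid_divisions)
    chosen = []
    for _ in range(min(n_leaders, k)):
        avail = np.array([i for i in range(k) if i not in chosen])
        cell_of = cells[avail]
        uniq, counts = np.unique(cell_of, return_counts=True)
        w = (1.0 / counts) ** config.leader_beta
        cell = rng.choice(uniq, p=w / w.sum())
        members = avail[cell_of == cell]
        chosen.append(int(rng.choice(members)))
    while len(chosen) < n_leaders:  # tiny archive: reuse leaders
        chosen.append(int(rng.choice(k)))
    return np.array(chosen, dtype=int)


def _archive_truncate(X, F, config, rng):
    """Evict from crowded cells (roulette over density ^ delete_gamma)."""
    while len(F) > config.archive_size:
        cells = _grid_cells(F, config.grid_alpha, config.grid_divisions)
        uniq, counts = np.unique(cells, return_counts=True)
        w = counts.astype(float) ** config.delete_gamma
        cell = rng.choice(uniq, p=w / w.sum())
        members = np.flatnonzero(cells == cell)
        out = rng.choice(members)
        keep = np.ones(len(F), dtype=bool)
        keep[out] = False
        X, F = X[keep], F[keep]
    return X, F


def run_mogwo(objectives, config: OptimizerConfig, seed: int) -> ParetoArchive:
    """Multi-objective grey wolf optimizer with a gridded external archive."""
    f = _as_batch_objective(objectives)
    rng = np.random.default_rng(seed)
    lo, hi = config.lo, config.hi
    N, q = config.population, len(lo)

    X = _init_population(rng, config, objectives)
    F = np.atleast_2d(f(X))
    mask = nondominated_mask(F)
    AX, AF = X[mask].copy(), F[mask].copy()
    AX, AF = _archive_truncate(AX, AF, config, rng)
    hist = _History()
    hist.log(0, F)

    for gen in range(1, config.generations + 1):
        a = 2.0 * (1 - gen / config.generations)
        leaders = AX[select_leader_indices(AF, config, rng, 3)]  # alpha, beta, delta
        Xnew = np.empty_like(X)
        for i in range(N):
            pos = np.empty((3, q))
            for k in range(3):
                r1 = rng.random(q)
                r2 = rng.random(q)
                A = 2 * a * r1 - a
                Cc = 2 * r2
                D = np.abs(Cc * leaders[k] - X[i])
                pos[k] = leaders[k] - A * D
            Xnew[i] = pos.mean(axis=0)
        np.clip(Xnew, lo, hi, out=Xnew)
        X = Xnew
        F = np.atleast_2d(f(X))

        merged_X = np.vstack([AX, X])
        merged_F = np.vstack([AF, F])
        mask = nondominated_mask(merged_F)
        AX, AF = merged_X[mask], merged_F[mask]
        AX, AF = _archive_truncate(AX, AF, config, rng)
        hist.log(gen, F)

    np.clip(AX, lo, hi, out=AX)
    return ParetoArchive(
        algorithm="MOGWO", X=AX, F=AF, Y=_releases_of(objectives, AX),
        history=hist.frame(), seed=seed,
    )


# ---------------------------------------------------------------------------
# NSWOA


def run_nswoa(objectives, config: OptimizerConfig, seed: int,
              progress: list | None = None) -> ParetoArchive:
    """Whale operators (encircle / bubble-net spiral / random search) with
    non-dominated sorting and crowding truncation of the merged population."""
    f = _as_batch_objective(objectives)
    rng = np.random.default_rng(seed)
    lo, hi = config.lo, config.hi
    N, q = config.population, len(lo)
    b = 1.0  # logarithmic-spiral shape

    X = rng.uniform(lo, hi, size=(N, q))
    F = np.atleast_2d(f(X))
    hist = _History()
    hist.log(0, F)

    for gen in range(1, config.generations + 1):
        a = 2.0 * (1 - gen / config.generations)
        first = fast_nondominated_sort(F)[0]
        Xnew = np.empty_like(X)
        for i in range(N):
            leader = X[rng.choice(first)]
            if rng.random() < 0.5:
                r1, r2 = rng.random(q), rng.random(q)
                A = 2 * a * r1 - a
                Cc = 2 * r2
                if np.abs(A).mean() < 1:  # encircle the elite prey
                    D = np.abs(Cc * leader - X[i])
                    Xnew[i] = leader - A * D
                else:  # random-leader exploration
                    xr = X[rng.integers(N)]
                    D = np.abs(Cc * xr - X[i])
                    Xnew[i] = xr - A * D
            else:  # bubble-net logarithmic spiral
                l = rng.uniform(-1.0, 1.0)
                D = np.abs(leader - X[i])
                Xnew[i] = D * np.exp(b * l) * np.cos(2 * np.pi * l) + leader
        np.clip(Xnew, lo, hi, out=Xnew)
        Fnew = np.atleast_2d(f(Xnew))

        Xall = np.vstack([X, Xnew])
        Fall = np.vstack([F, Fnew])
        keep = []
        for front in fast_nondominated_sort(Fall):
            if len(keep) + len(front) <= N:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(Fall[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(front[order[: N - len(keep)]].tolist())
            if len(keep) >= N:
                break
        X, F = Xall[keep], Fall[keep]
        hist.log(gen, F)
        if progress is not None and gen % config.ishow == 0:
            progress.append(f"gen {gen}: best fitness {hist.best:.4f}")

    return _finalize("NSWOA", X, F, objectives, hist, seed, config)


_RUNNERS = {"NSGA-III": run_nsga3, "MOGWO": run_mogwo, "NSWOA": run_nswoa}


def run_all(objectives, config: OptimizerConfig, seed: int) -> dict:
    """All three algorithms, ``config.runs`` independent runs each.

    Per-run seeds are spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    out = {}
    for alg_seq, alg in zip(ss.spawn(len(_RUNNERS)), _RUNNERS):
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in alg_seq.spawn(config.runs)]
        out[alg] = [_RUNNERS[alg](objectives, config, s) for s in run_seeds]
    return out


# ---------------------------------------------------------------------------
# pooling


def pool_candidates(
    archives_by_algorithm: dict,
    limits: ReleaseLimits = DEFAULT_LIMITS,
    round_to: int | None = 3,
) -> pd.DataFrame:
    """One representative per run, pooled into a 45-row candidate table.

    Each run's final archive is pharmacopoeia-filtered; the representative is
    picked by equal-weight TOPSIS on the feasible release matrix (classical
    vector normalization, zero negative ideal).  Raises if any run retains no
    feasible solution.
    """
    from .mcdm_rank import EntropyWeights, topsis

    rows = []
    scheme = 0
    for alg, archives in archives_by_algorithm.items():
        for run_idx, arch in enumerate(archives):
            if arch.Y is None:
                raise ValueError("archive lacks release values; pass release objectives")
            ok = limits.contains(arch.Y)
            if not ok.any():
                raise ValueError(f"{alg} run {run_idx} has no feasible solution")
            Xf, Yf = arch.X[ok], arch.Y[ok]
            if len(Yf) == 1:
                best = 0
            else:
                w = EntropyWeights(entropy=np.zeros(Yf.shape[1]),
                                   weights=np.full(Yf.shape[1], 1 / Yf.shape[1]))
                res = topsis(Yf, w, preprocess=None, zero_negative_ideal=True)
                best = int(np.argmax(res.closeness))
            scheme += 1
            rows.append([alg, scheme, *Xf[best], *Yf[best]])

    n_comp = len(rows[0]) - 5
    cols = (["algorithm", "scheme"] + [f"X{i+1}" for i in range(n_comp)]
            + ["Y_2", "Y_8", "Y_24"])
    table = pd.DataFrame(rows, columns=cols)
    if round_to is not None:
        num = table.columns[2:]
        table[num] = table[num].round(round_to)
    return table
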