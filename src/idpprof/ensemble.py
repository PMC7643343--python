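"""Ensemble modelling of a flexible chain against a SAXS curve.

A pool of self-avoiding coarse-grained C-alpha chains (one bead per
residue, fixed 3.8 Å virtual bonds, a broad coil-like bond-angle prior,
uniform dihedrals) stands in for the conformational space of a disordered
protein.  Each conformer gets a Debye scattering profile with a constant
per-bead form factor; a genetic algorithm then picks a fixed-size
sub-ensemble (a multiset of pool members) whose averaged profile best fits
an experimental curve.  Comparing the R_g histogram of the selected
sub-ensemble with that of the unbiased pool reveals whether the data favour
more compact or more extended conformations, and whether several
conformational classes coexist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from . import config
from .saxs import SAXSCurve


@dataclass(frozen=True)
class Conformer:
    """One C-alpha chain with its cached radius of gyration."""

    coords: np.ndarray  # (N, 3) Å
    rg: float           # Å


@dataclass(frozen=True)
class ConformerPool:
    """Conformers plus their scattering profiles on a shared s-grid."""

    conformers: list[Conformer]
    s_grid: np.ndarray | None = None
    profiles: np.ndarray | None = None  # (n_conf, n_s)

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def rgs(self) -> np.ndarray:
        return np.array([c.rg for c in self.conformers])

    def rg_histogram(self, bins: int | np.ndarray = 30) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.rgs, bins=bins)

    def with_profiles(
        self, s_grid: np.ndarray, form_factor: float = 1.0,
        bin_width: float | None = config.DEBYE_BIN_WIDTH,
    ) -> "ConformerPool":
        profiles = np.array([
            debye_profile(c, s_grid, form_factor=form_factor, bin_width=bin_width)
            for c in self.conformers
        ])
        return ConformerPool(self.conformers, np.asarray(s_grid, float), profiles)


@dataclass(frozen=True)
class EnsembleSelection:
    """GA-selected multiset of pool members and its fit quality."""

    member_indices: np.ndarray  # (ensemble_size,), pool indices with repeats
    chi2: float
    scale: float
    rgs: np.ndarray             # R_g of the selected members
    history: np.ndarray = field(default=None)  # best chi2 per generation

    def rg_histogram(self, bins: int | np.ndarray = 30) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.rgs, bins=bins)


# ----------------------------------------------------------- chain builder

def radius_of_gyration(coords: np.ndarray) -> float:
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _clash_cutoffs2(k: int, clash: float, excluded: float) -> np.ndarray:
    """Squared distance floor for a bead at index k against beads 0..k-2."""
    cut2 = np.full(k - 1, excluded * excluded)
    cut2[-1] = clash * clash  # the 1-3 neighbour (|i-j| == 2)
    return cut2


def _grow_chain(
    n_res: int,
    rng: np.random.Generator,
    bond: float,
    cos_range: tuple[float, float],
    clash: float,
    excluded: float,
    max_retries: int,
) -> np.ndarray | None:
    """Grow one self-avoiding chain; None if it dead-ends."""
    coords = np.zeros((n_res, 3))
    coords[1] = bond * _random_unit(rng)
    lo, hi = cos_range
    for k in range(2, n_res):
        prev = coords[k - 1] - coords[k - 2]
        e1 = prev / np.linalg.norm(prev)
        # orthonormal frame around the previous bond
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e1[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        cut2 = _clash_cutoffs2(k, clash, excluded)
        placed = False
        for _ in range(max_retries):
            c = rng.uniform(lo, hi)          # cos(angle to previous bond)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            sin_t = np.sqrt(1.0 - c * c)
            direction = c * e1 + sin_t * (np.cos(phi) * e2 + np.sin(phi) * e3)
            candidate = coords[k - 1] + bond * direction
            d2 = np.sum((coords[: k - 1] - candidate) ** 2, axis=1)
            if np.all(d2 >= cut2):
                coords[k] = candidate
                placed = True
                break
        if not placed:
            return None
    return coords


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _pivot_equilibrate(
    coords: np.ndarray,
    rng: np.random.Generator,
    n_moves: int,
    cos_range: tuple[float, float],
    clash: float,
    excluded: float,
) -> np.ndarray:
    """Pivot-move Monte Carlo to de-bias the kinetically grown chain.

    Each proposal rigidly rotates the tail beyond a random pivot bead by a
    uniform random rotation and is accepted iff the new bond angle at the
    pivot stays inside the prior's support and no clash appears.  This is
    the standard equilibrium sampler for self-avoiding chains; growth alone
    over-represents kinetically accessible conformations.
    """
    n = len(coords)
    if n < 3:
        return coords
    lo, hi = cos_range
    cl2, ex2 = clash * clash, excluded * excluded
    for _ in range(n_moves):
        k = int(rng.integers(1, n - 1))
        R = _random_rotation(rng)
        tail = coords[k:] - coords[k]
        new_tail = tail @ R.T + coords[k]
        b1 = coords[k] - coords[k - 1]
        b2 = new_tail[1] - coords[k]
        cosang = float(b1 @ b2) / (np.linalg.norm(b1) * np.linalg.norm(b2))
        if not (lo <= cosang <= hi):
            continue
        head = coords[:k]
        d2 = cdist(head, new_tail[1:], "sqeuclidean")
        cut2 = np.full(d2.shape, ex2)
        cut2[k - 1, 0] = cl2  # the (k-1, k+1) pair is a 1-3 neighbour
        if np.any(d2 < cut2):
            continue
        coords = np.vstack([head, new_tail])
    return coords


def generate_chain(
    n_res: int,
    rng: np.random.Generator,
    bond: float = config.CHAIN_BOND_LENGTH,
    cos_range: tuple[float, float] = config.CHAIN_COS_RANGE,
    clash: float = config.CHAIN_CLASH_CUTOFF,
    excluded: float = config.CHAIN_EXCLUDED_DIAMETER,
    pivot_moves: int = config.CHAIN_PIVOT_MOVES,
    max_retries: int = config.CHAIN_MAX_STEP_RETRIES,
    max_restarts: int = config.CHAIN_MAX_RESTARTS,
) -> Conformer:
    """One self-avoiding random C-alpha chain.

    The chain is grown step by step with per-step rejection (restarting on
    dead ends) and then equilibrated with pivot moves so the pool samples
    the equilibrium coil ensemble rather than the growth-biased one.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    for _ in range(max_restarts):
        coords = _grow_chain(
            n_res, rng, bond, cos_range, clash, excluded, max_retries
        )
        if coords is not None:
            coords = _pivot_equilibrate(
                coords, rng, pivot_moves, cos_range, clash, excluded
            )
            return Conformer(coords=coords, rg=radius_of_gyration(coords))
    raise RuntimeError(
        f"failed to grow a clash-free {n_res}-residue chain after "
        f"{max_restarts} restarts"
    )


def generate_pool(
    n_res: int,
    n_conf: int,
    seed: int,
    cos_range: tuple[float, float] = config.CHAIN_COS_RANGE,
    bond: float = config.CHAIN_BOND_LENGTH,
    clash: float = config.CHAIN_CLASH_CUTOFF,
    excluded: float = config.CHAIN_EXCLUDED_DIAMETER,
    pivot_moves: int = config.CHAIN_PIVOT_MOVES,
) -> ConformerPool:
    """Deterministic pool of self-avoiding coil conformers."""
    if n_conf < 1:
        raise ValueError("need at least one conformer")
    rng = np.random.default_rng(seed)
    conformers = [
        generate_chain(
            n_res, rng, bond=bond, cos_range=cos_range, clash=clash,
            excluded=excluded, pivot_moves=pivot_moves,
        )
        for _ in range(n_conf)
    ]
    return ConformerPool(conformers)


# -------------------------------------------------------------- scattering

def debye_profile(
    conf: Conformer,
    s_grid: np.ndarray,
    form_factor: float = 1.0,
    bin_width: float | None = config.DEBYE_BIN_WIDTH,
) -> np.ndarray:
    """Debye scattering of a bead model with a constant form factor.

    I(s) = f^2 * [N + 2 * sum_{i<j} sin(s r_ij)/(s r_ij)].  With
    `bin_width` set, pairwise distances are histogrammed first (an
    approximation accurate to the bin width); bin_width=None evaluates the
    exact double sum.
    """
    s = np.asarray(s_grid, dtype=float)
    n = len(conf.coords)
    d = pdist(conf.coords)
    f2 = form_factor * form_factor
    if bin_width is None:
        sr = np.outer(s, d)
        pair_sum = np.sinc(sr / np.pi).sum(axis=1)
    else:
        n_bins = max(1, int(np.ceil(d.max() / bin_width)))
        counts, edges = np.histogram(d, bins=n_bins, range=(0.0, n_bins * bin_width))
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        sr = np.outer(s, centers[keep])
        pair_sum = np.sinc(sr / np.pi) @ counts[keep]
    return f2 * (n + 2.0 * pair_sum)


def chi_square(
    model: np.ndarray, data: SAXSCurve, fit_scale: bool = True
) -> tuple[float, float]:
    """Reduced chi^2 between a model profile and data, with optional scale.

    chi2 = (1/(N-1)) * sum(((I_data - c*I_model)/sigma)^2); the scale c is
    the analytic weighted least-squares optimum when fit_scale is true.
    The model must be sampled on the data's s-grid already.
    """
    model = np.asarray(model, dtype=float)
    if model.shape != data.i.shape:
        raise ValueError(
            f"grid mismatch: model has {model.shape[0]} points, "
            f"data has {len(data)}"
        )
    w = 1.0 / data.sigma**2
    if fit_scale:
        denom = np.sum(w * model**2)
        scale = float(np.sum(w * data.i * model) / denom) if denom > 0 else 1.0
    else:
        scale = 1.0
    resid = (data.i - scale * model) / data.sigma
    return float(np.sum(resid**2) / (len(data) - 1)), scale


# ------------------------------------------------------ genetic algorithm

def _ensemble_chi2(
    indices: np.ndarray, profiles: np.ndarray, data: SAXSCurve
) -> tuple[float, float]:
    return chi_square(profiles[indices].mean(axis=0), data)


def select_subensemble_ga(
    pool: ConformerPool,
    data: SAXSCurve,
    ensemble_size: int = config.GA_ENSEMBLE_SIZE,
    generations: int = config.GA_GENERATIONS,
    seed: int = 0,
    population: int = config.GA_POPULATION,
    crossover_prob: float = config.GA_CROSSOVER_PROB,
    mutation_prob: float = config.GA_MUTATION_PROB,
    elite: int = config.GA_ELITE,
) -> EnsembleSelection:
    """Genetic-algorithm selection of the best-fitting sub-ensemble.

    A chromosome is a multiset of `ensemble_size` pool indices; fitness is
    the (negated) reduced chi^2 of the member-averaged profile against the
    data.  Tournament selection, uniform crossover of index positions, and
    per-gene mutation to a random pool member; elitism guarantees the best
    chromosome never worsens across generations.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if pool.profiles is None:
        raise ValueError("pool has no profiles; call with_profiles() first")
    if pool.profiles.shape[1] != len(data):
        raise ValueError("pool profiles are not on the data s-grid")
    rng = np.random.default_rng(seed)
    n_pool = len(pool)
    pop = rng.integers(0, n_pool, size=(population, ensemble_size))
    scores = np.array([
        _ensemble_chi2(chrom, pool.profiles, data)[0] for chrom in pop
    ])
    history = []
    for _ in range(generations):
        order = np.argsort(scores)
        pop, scores = pop[order], scores[order]
        history.append(scores[0])
        children = [pop[i].copy() for i in range(elite)]
        while len(children) < population:
            # binary tournaments
            picks = rng.integers(0, population, size=4)
            pa = pop[picks[0]] if scores[picks[0]] < scores[picks[1]] else pop[picks[1]]
            pb = pop[picks[2]] if scores[picks[2]] < scores[picks[3]] else pop[picks[3]]
            child = pa.copy()
            swap = rng.random(ensemble_size) < crossover_prob
            child[swap] = pb[swap]
            mutate = rng.random(ensemble_size) < mutation_prob
            child[mutate] = rng.integers(0, n_pool, size=int(mutate.sum()))
            children.append(child)
        pop = np.array(children)
        scores = np.array([
            _ensemble_chi2(chrom, pool.profiles, data)[0] for chrom in pop
        ])
    best = int(np.argmin(scores))
    chi2, scale = _ensemble_chi2(pop[best], pool.profiles, data)
    history.append(chi2)
    rgs = pool.rgs[pop[best]]
    return EnsembleSelection(
        member_indices=np.sort(pop[best]),
        chi2=chi2,
        scale=scale,
        rgs=rgs,
        history=np.array(history),
    )


# ----------------------------------------------------------------- summary

def _two_means(values: np.ndarray, n_iter: int = 50) -> tuple[float, float, np.ndarray]:
    """Plain 1-D 2-means split; returns the two centers and labels."""
    c1, c2 = float(values.min()), float(values.max())
    labels = np.zeros(len(values), dtype=int)
    for _ in range(n_iter):
        labels = (np.abs(values - c2) < np.abs(values - c1)).astype(int)
        if labels.all() or not labels.any():
            break
        n1, n2 = float(values[labels == 0].mean()), float(values[labels == 1].mean())
        if (n1, n2) == (c1, c2):
            break
        c1, c2 = n1, n2
    return c1, c2, labels


def bimodality_split(values: np.ndarray) -> dict:
    """Two-component separation heuristic for a 1-D sample.

    The sample is split by 2-means; it is called bimodal when both
    components hold at least 10% of the mass and Ashman's
    D = |mu1 - mu2| / sqrt(2*(s1^2 + s2^2)) exceeds 2, the usual threshold
    for a clean separation (a unimodal Gaussian split in half scores ~1.3).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4 or np.ptp(values) == 0:
        return {"bimodal": False, "modes": [float(np.mean(values))]}
    c1, c2, labels = _two_means(values)
    g1, g2 = values[labels == 0], values[labels == 1]
    if len(g1) < max(2, 0.1 * len(values)) or len(g2) < max(2, 0.1 * len(values)):
        return {"bimodal": False, "modes": [float(np.median(values))]}
    d_ashman = abs(c2 - c1) / np.sqrt(2.0 * (g1.std() ** 2 + g2.std() ** 2))
    sep = d_ashman > 2.0
    modes = sorted([float(np.median(g1)), float(np.median(g2))])
    return {"bimodal": bool(sep), "modes": modes if sep else [float(np.median(values))]}


def rg_distribution_summary(
    pool: ConformerPool, sel: EnsembleSelection
) -> dict:
    """Compare pool and selected-ensemble R_g distributions.

    Reports mean/median/mode for both, the mean shift (selected - pool),
    and a bimodality flag with component modes for the selection.
    """
    pool_rgs = pool.rgs
    sel_rgs = sel.rgs
    bins = np.histogram_bin_edges(pool_rgs, bins=30)

    def mode_of(values: np.ndarray) -> float:
        counts, edges = np.histogram(values, bins=bins)
        j = int(np.argmax(counts))
        return float(0.5 * (edges[j] + edges[j + 1]))

    split = bimodality_split(sel_rgs)
    return {
        "pool": {
            "mean": float(pool_rgs.mean()),
            "median": float(np.median(pool_rgs)),
            "mode": mode_of(pool_rgs),
        },
        "selected": {
            "mean": float(sel_rgs.mean()),
            "median": float(np.median(sel_rgs)),
            "mode": mode_of(sel_rgs),
        },
        "shift": float(sel_rgs.mean() - pool_rgs.mean()),
        "bimodal": split["bimodal"],
        "modes": split["modes"],
        "chi2": sel.chi2,
    }


def write_ca_pdb(conf: Conformer, path: str) -> None:
    """Write a minimal C-alpha-only PDB for visual inspection."""
    with open(path, "w") as fh:
        for k, (x, y, z) in enumerate(conf.coords, start=1):
            fh.write(
                f"ATOM  {k:5d}  CA  GLY A{k:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
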