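"""Bayesian multivariate animal model for tank-level larval traits.

The phenotypic (co)variance of the four traits — daily mortality rate
and 14-day growth, each under ambient and acidified seawater — is
partitioned as P = G + M + B + R: additive genetic, maternal (dam),
block (spawning event), and residual (tank) components, each a 4x4
covariance matrix with an inverse-Wishart prior.  Records are tanks;
each tank is a pseudo-individual of the pedigree (an offspring of its
family's sire and dam), so replicate tanks of one family are full sibs
and the pedigree relationship matrix carries the expected similarity of
full sibs (0.5) and half sibs (0.25).

Each tank observes only the two traits of its own treatment.
Estimation is by a systematic-scan Gibbs sampler, partially collapsed
over the unobserved traits: trait means and all effect vectors are
drawn from conditionals under the observed-data likelihood
(pattern-wise precisions; the missing traits are integrated out, not
imputed), while the residual matrix keeps its conjugate
inverse-Wishart draw through a single imputation step.  Translation,
scale (parameter-expansion) and shear group moves accelerate mixing of
the variance components; all are posterior-invariant.  The only fixed
effects are the four trait means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
import warnings

try:
    from ._pxmoves import px_component as _px_component_nb
    from ._pxmoves import rinvwishart_nb as _rinvwishart_nb
    from ._pxmoves import sample_batch_nb as _sample_batch_nb

    _HAVE_COMPILED_PX = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_COMPILED_PX = False

from . import diagnostics
from .pedigree import Pedigree, a_inverse
from .simulate import TRAITS, TREATMENT_TRAITS

COMPONENTS = ("G", "M", "B", "R")


def chain_length(n_iter: int, burn_in: int, thin: int) -> int:
    """Number of stored samples: floor((n_iter - burn_in) / thin)."""
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    return (n_iter - burn_in) // thin


@dataclass
class PriorSpec:
    """Inverse-Wishart priors per component.

    Convention: density of Sigma is proportional to
    ``|Sigma|^-((nu+p+1)/2) * exp(-0.5 * tr(scale @ inv(Sigma)))`` with
    ``scale = nu * V0``, so the prior mode is nu*V0/(nu+p+1) and a
    degree of belief nu of 0.001 makes the prior vanishingly weak.
    """

    scale: dict[str, np.ndarray]
    nu: dict[str, float]

    def __post_init__(self):
        for comp in COMPONENTS:
            if comp not in self.scale or comp not in self.nu:
                raise ValueError(f"prior missing component {comp}")
            s = np.asarray(self.scale[comp], dtype=float)
            if s.shape != (4, 4) or not np.allclose(s, s.T, atol=1e-12):
                raise ValueError(f"prior scale for {comp} must be symmetric 4x4")
            self.scale[comp] = s
            if self.nu[comp] <= 0:
                raise ValueError("degree of belief nu must be > 0")


def prior_from_data(trait_table: pd.DataFrame, nu: float = 0.001) -> PriorSpec:
    """Weakly informative prior: each component's modal variance is a
    quarter of the observed per-trait phenotypic variance, modal
    covariances zero, degree of belief `nu` (default 0.001).
    """
    variances = np.empty(4)
    for trt, (i_mort, i_grow) in TREATMENT_TRAITS.items():
        sub = trait_table[trait_table["treatment"] == trt]
        for col, idx in (("mortality_rate", i_mort), ("growth", i_grow)):
            vals = sub[col].to_numpy(dtype=float)
            if vals.size < 2:
                raise ValueError(f"need >= 2 observations of trait {TRAITS[idx]}")
            variances[idx] = vals.var(ddof=1)
    if np.any(variances <= 0):
        raise ValueError("zero observed variance in at least one trait")
    v0 = np.diag(variances / 4.0)
    return PriorSpec(
        scale={c: nu * v0 for c in COMPONENTS}, nu={c: float(nu) for c in COMPONENTS}
    )


@dataclass
class ModelSpec:
    """Design information binding tank records to pedigree, dams, blocks."""

    traits: tuple[str, ...]
    y: np.ndarray  # (n_rec, 4), NaN where unobserved
    mask: np.ndarray  # (n_rec, 4) bool, True = observed
    record_animal: np.ndarray  # index into pedigree order
    record_dam: np.ndarray  # index into dam_levels
    record_block: np.ndarray  # index into block_levels
    dam_levels: list[str]
    block_levels: list[str]
    pedigree: Pedigree
    a_inv: sparse.csr_matrix

    @property
    def n_records(self) -> int:
        return self.y.shape[0]


def model_from_tables(trait_table: pd.DataFrame, ped: Pedigree) -> ModelSpec:
    """Assemble a ModelSpec from a tank trait table and its pedigree.

    Each tank contributes one record whose observed entries are the two
    traits of its treatment; dams and blocks become random-effect
    levels.
    """
    n = len(trait_table)
    y = np.full((n, 4), np.nan)
    mask = np.zeros((n, 4), dtype=bool)
    dam_levels = sorted(trait_table["dam_id"].unique())
    block_levels = sorted(trait_table["block"].unique())
    dam_ix = {v: k for k, v in enumerate(dam_levels)}
    blk_ix = {v: k for k, v in enumerate(block_levels)}
    rec_animal = np.empty(n, dtype=np.int64)
    rec_dam = np.empty(n, dtype=np.int64)
    rec_block = np.empty(n, dtype=np.int64)
    for k, rec in enumerate(trait_table.itertuples()):
        if rec.treatment not in TREATMENT_TRAITS:
            raise ValueError(f"unknown treatment {rec.treatment!r}")
        i_mort, i_grow = TREATMENT_TRAITS[rec.treatment]
        y[k, i_mort] = rec.mortality_rate
        y[k, i_grow] = rec.growth
        mask[k, [i_mort, i_grow]] = True
        rec_animal[k] = ped.index(rec.tank_id)
        rec_dam[k] = dam_ix[rec.dam_id]
        rec_block[k] = blk_ix[rec.block]
    if not np.all(np.isfinite(y[mask])):
        raise ValueError("non-finite trait values in observed entries")
    return ModelSpec(
        traits=TRAITS,
        y=y,
        mask=mask,
        record_animal=rec_animal,
        record_dam=rec_dam,
        record_block=rec_block,
        dam_levels=dam_levels,
        block_levels=block_levels,
        pedigree=ped,
        a_inv=sparse.csr_matrix(a_inverse(ped)),
    )


@dataclass
class PosteriorChain:
    """Thinned posterior samples of all components plus the trait means."""

    traits: tuple[str, ...]
    mu: np.ndarray  # (S, 4)
    G: np.ndarray  # (S, 4, 4)
    M: np.ndarray
    B: np.ndarray
    R: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.mu.shape[0]

    def component(self, name: str) -> np.ndarray:
        if name not in COMPONENTS:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def total(self) -> np.ndarray:
        return self.G + self.M + self.B + self.R

    def trait_index(self, trait) -> int:
        if isinstance(trait, str):
            return self.traits.index(trait)
        return int(trait)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per stored sample (documented column order:
        mu per trait, then per component the upper triangle row-major)."""
        cols: dict[str, np.ndarray] = {"sample": np.arange(len(self))}
        for t, name in enumerate(self.traits):
            cols[f"mu_{name}"] = self.mu[:, t]
        for comp in COMPONENTS:
            arr = self.component(comp)
            for i in range(4):
                for j in range(i, 4):
                    cols[f"{comp}_{i + 1}{j + 1}"] = arr[:, i, j]
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, traits=TRAITS) -> "PosteriorChain":
        S = len(df)
        mu = np.column_stack([df[f"mu_{t}"].to_numpy() for t in traits])
        comps = {}
        for comp in COMPONENTS:
            arr = np.zeros((S, 4, 4))
            for i in range(4):
                for j in range(i, 4):
                    arr[:, i, j] = arr[:, j, i] = df[f"{comp}_{i + 1}{j + 1}"].to_numpy()
            comps[comp] = arr
        return cls(traits=tuple(traits), mu=mu, **comps)

    @classmethod
    def read_csv(cls, path) -> "PosteriorChain":
        return cls.from_frame(pd.read_csv(path))


# ----------------------------------------------------------------------
# sampler internals


def _spd_cholesky(mat: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; one 1e-10*I jitter retry before giving up."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.cholesky(mat + 1e-10 * np.eye(mat.shape[-1]))
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                f"conditional scale not positive definite even after jitter: {mat!r}"
            ) from err


_tril_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _rinvwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from IW(df, scale) under the |Sigma|^-((df+p+1)/2) convention.

    Bartlett construction: W ~ Wishart(df, inv(scale)) and the draw is
    inv(W), computed via triangular solves for stability.
    """
    p = scale.shape[0]
    if df <= p - 1:
        raise ValueError("inverse-Wishart draw requires df > p - 1")
    Ls = _spd_cholesky(scale)
    Ls_inv = np.linalg.inv(Ls)
    sigma = Ls_inv.T @ Ls_inv  # inv(scale)
    C = _spd_cholesky(sigma)
    A = np.zeros((p, p))
    # floor the Bartlett chi-square draws: for df barely above p-1 the
    # smallest one underflows, producing numerically singular draws from
    # an (astronomically heavy-tailed but proper) distribution
    A[np.diag_indices(p)] = np.sqrt(np.maximum(rng.chisquare(df - np.arange(p)), 1e-12))
    rows, cols = _tril_cache.setdefault(p, np.tril_indices(p, -1))
    A[rows, cols] = rng.standard_normal(rows.size)
    T = C @ A  # lower triangular, W = T @ T.T
    invT = np.linalg.inv(T)
    draw = invT.T @ invT
    return 0.5 * (draw + draw.T)


def _px_rescale(
    rng: np.random.Generator,
    effects: np.ndarray,  # (n_levels, 4) current effect vectors
    rec_effects: np.ndarray,  # (n_rec, 4) effects mapped onto records
    partial_resid: np.ndarray,  # (n_rec, 4) masked: y - mu - all OTHER effects
    patterns: "_Patterns",
    w_list: list[np.ndarray],
    comp: np.ndarray,  # current component covariance matrix
    prior_scale: np.ndarray,
    prior_nu: float,
) -> float:
    """Per-trait parameter-expansion scale moves on (u, X).

    Generalized-Gibbs group moves (Liu & Sabatti) scaling one trait at a
    time: u[:, k] -> c u[:, k] together with row/column k of the
    component matrix (so X_kk -> c^2 X_kk).  With respect to the Haar
    measure dc/c of the multiplicative group the move density for trait
    k (holding the others at 1) is

        f(c) = exp(-(alpha c^2 - 2 beta c)/2) * c^(-nu-1)
               * exp(-kappa / (2 c^2))

    where alpha, beta collect the Gaussian likelihood's dependence on
    the rescaled trait and kappa = S_kk (X^{-1})_kk comes from the
    inverse-Wishart prior; the effect-vector prior and both Jacobians
    cancel exactly.  A slice-sampling update started at the identity is
    invariant for f, so the composite move preserves the posterior while
    letting each trait's variance scale jump in one step instead of
    diffusing through the effect vectors.  Mutates `effects` and `comp`
    in place.
    """
    t = rec_effects
    # per-pattern cross-products; the observed-data likelihood weights
    # each record by its own pattern's embedded precision
    T_p = [t[rows].T @ t[rows] for rows in patterns.rows]
    U_p = [t[rows].T @ partial_resid[rows] for rows in patterns.rows]
    comp_inv = np.linalg.inv(comp)
    for k in range(4):
        alpha = sum(W[k, k] * T[k, k] for W, T in zip(w_list, T_p))
        if alpha <= 0:
            continue
        beta = sum(
            float(W[k] @ U[k]) - (float(W[k] @ T[k]) - W[k, k] * T[k, k])
            for W, T, U in zip(w_list, T_p, U_p)
        )
        kappa = prior_scale[k, k] * comp_inv[k, k]

        def log_f(c: float) -> float:
            return (
                -0.5 * (alpha * c * c - 2.0 * beta * c)
                - (prior_nu + 1.0) * np.log(c)
                - kappa / (2.0 * c * c)
            )

        # one slice-sampling update from c0 = 1 (stepping out + shrink)
        log_y = log_f(1.0) + np.log(rng.uniform())
        width = 2.0 / np.sqrt(alpha)
        lo = max(1.0 - width * rng.uniform(), 1e-12)
        hi = lo + width
        for _ in range(20):
            if lo <= 1e-12 or log_f(lo) < log_y:
                break
            lo = max(lo - width, 1e-12)
        for _ in range(20):
            if log_f(hi) < log_y:
                break
            hi += width
        c = 1.0
        for _ in range(50):
            prop = rng.uniform(lo, hi)
            if log_f(prop) >= log_y:
                c = prop
                break
            if prop < 1.0:
                lo = prop
            else:
                hi = prop
        if c != 1.0:
            effects[:, k] *= c
            comp[k, :] *= c
            comp[:, k] *= c
            comp_inv[k, :] /= c
            comp_inv[:, k] /= c
            for T, U in zip(T_p, U_p):
                T[k, :] *= c
                T[:, k] *= c
                U[k, :] *= c
    return 1.0


def _px_shear(
    rng: np.random.Generator,
    effects: np.ndarray,  # (n_levels, 4), mutated in place
    rec_index: np.ndarray,  # record -> level map
    partial_resid: np.ndarray,  # (n_rec, 4) masked: y - mu - all OTHER effects
    patterns: "_Patterns",
    w_list: list[np.ndarray],
    comp: np.ndarray,  # component covariance, mutated in place
    prior_scale: np.ndarray,
) -> None:
    """Shear group moves on (u, X): u[:, l] += g u[:, k], X -> T X T'.

    For each ordered trait pair (k, l) the unipotent transformation
    T = I + g E_lk has unit Jacobians on both the effect vectors and the
    symmetric matrix, Lebesgue Haar measure, and leaves the effect-prior
    exponent invariant, so the generalized-Gibbs move density over g is
    exactly Gaussian: the likelihood contributes a quadratic and the
    (diagonal-scale) inverse-Wishart prior another.  One exact draw per
    pair moves the component's covariances in a single jump instead of
    diffusing them through the effect vectors.
    """
    t_p = [effects[rec_index[rows]] for rows in patterns.rows]
    e_p = [partial_resid[rows] - tp for tp, rows in zip(t_p, patterns.rows)]
    comp_inv = np.linalg.inv(comp)
    for k in range(4):
        for l in range(4):
            if l == k:
                continue
            alpha, beta = 0.0, 0.0
            for W, tp, ep in zip(w_list, t_p, e_p):
                tk = tp[:, k]
                alpha += W[l, l] * float(tk @ tk)
                beta += float(tk @ (ep @ W[:, l]))
            s_k = prior_scale[k, k]
            tau = alpha + s_k * comp_inv[l, l]
            if tau <= 0:
                continue
            g = (beta + s_k * comp_inv[k, l]) / tau + rng.standard_normal() / np.sqrt(tau)
            effects[:, l] += g * effects[:, k]
            comp[l, :] += g * comp[k, :]
            comp[:, l] += g * comp[:, k]
            # inverse of T X T' is T'^-1 X^-1 T^-1 with T^-1 = I - g E_lk
            comp_inv[k, :] -= g * comp_inv[l, :]
            comp_inv[:, k] -= g * comp_inv[:, l]
            for tp, ep in zip(t_p, e_p):
                ep[:, l] -= g * tp[:, k]
                tp[:, l] += g * tp[:, k]


def _greedy_coloring(n: int, neighbors: list[np.ndarray]) -> np.ndarray:
    order = np.argsort([-len(nb) for nb in neighbors], kind="stable")
    colors = np.full(n, -1, dtype=np.int64)
    for j in order:
        used = {colors[k] for k in neighbors[j] if colors[k] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[j] = c
    return colors


@dataclass
class _Patterns:
    """Missingness patterns: which traits each record observes."""

    obs: list[np.ndarray]  # observed trait indices per pattern
    rows: list[np.ndarray]  # record rows per pattern
    of_record: np.ndarray  # pattern id per record

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "_Patterns":
        uniq, inverse = np.unique(mask, axis=0, return_inverse=True)
        obs = [np.nonzero(row)[0] for row in uniq]
        rows = [np.nonzero(inverse == k)[0] for k in range(len(uniq))]
        return cls(obs=obs, rows=rows, of_record=inverse)

    def __len__(self) -> int:
        return len(self.obs)

    def weights(self, R: np.ndarray) -> list[np.ndarray]:
        """Per-pattern observed-data precision, embedded in 4x4.

        W_p has inv(R[obs, obs]) on the observed block and zeros on the
        missing rows/columns, so masked residuals can be used directly.
        """
        out = []
        for obs in self.obs:
            W = np.zeros((4, 4))
            if obs.size:
                W[np.ix_(obs, obs)] = np.linalg.inv(R[np.ix_(obs, obs)])
            out.append(W)
        return out


@dataclass
class _EffectBatch:
    """One jointly updatable batch of effect levels.

    All members are conditionally independent given the rest of the
    state (for additive values: a colour class of the A-inverse
    adjacency; maternal/block levels always are).  Precisions within a
    batch take few distinct values P = sum_p n_p W_p + d * CompInv
    (records counted per missingness pattern), so they are factorized
    once per unique (pattern counts, d) key and gathered per member.
    """

    members: np.ndarray  # level indices in this batch
    gid: np.ndarray  # per-member index into the unique keys
    pat_counts_u: np.ndarray  # (n_keys, n_patterns) records per pattern
    d_u: np.ndarray  # unique prior-precision multipliers


def _make_batch(members: np.ndarray, pat_counts: np.ndarray, d: np.ndarray) -> _EffectBatch:
    keys = np.column_stack([pat_counts, np.round(d, 10)])
    uniq, gid = np.unique(keys, axis=0, return_inverse=True)
    return _EffectBatch(
        members=members,
        gid=gid,
        pat_counts_u=uniq[:, :-1].copy(),
        d_u=uniq[:, -1].copy(),
    )


def _sample_batch(
    rng: np.random.Generator,
    batch: _EffectBatch,
    rhs: np.ndarray,  # (n_members, 4): W-weighted data part minus prior coupling
    w_list: list[np.ndarray],
    comp_inv: np.ndarray,
) -> np.ndarray:
    """Draw all members of a batch from their normal full conditionals.

    Per member: precision P = sum_p n_p W_p + d * CompInv, mean
    P^-1 rhs, covariance P^-1; the noise is L^-T z with L the Cholesky
    of P.  The W_p are the embedded observed-data precisions, so the
    conditional is the one given observed traits only (unobserved
    traits are integrated out, not imputed).
    """
    P_u = batch.d_u[:, None, None] * comp_inv
    for p, W in enumerate(w_list):
        P_u = P_u + batch.pat_counts_u[:, p, None, None] * W
    L_u = _spd_cholesky(P_u)
    Linv_u = np.linalg.inv(L_u)
    LinvT_u = Linv_u.transpose(0, 2, 1)
    Pinv_u = LinvT_u @ Linv_u
    z = rng.standard_normal((batch.members.size, 4))
    mean = np.einsum("mij,mj->mi", Pinv_u[batch.gid], rhs)
    noise = np.einsum("mij,mj->mi", LinvT_u[batch.gid], z)
    return mean + noise


def _build_animal_batches(
    a_inv: sparse.csr_matrix, pat_counts: np.ndarray
) -> list[_EffectBatch]:
    """Colour the A-inverse adjacency and build one batch per colour."""
    n = a_inv.shape[0]
    coo = a_inv.tocoo()
    off = (coo.row != coo.col) & (coo.data != 0.0)
    adj: list[set] = [set() for _ in range(n)]
    for i, j in zip(coo.row[off], coo.col[off]):
        adj[i].add(int(j))
    neighbors = [np.fromiter(s, dtype=np.int64) for s in adj]
    colors = _greedy_coloring(n, neighbors)
    diag = a_inv.diagonal()
    batches = []
    for c in range(colors.max() + 1):
        members = np.nonzero(colors == c)[0]
        batches.append(_make_batch(members, pat_counts[members], diag[members]))
    return batches


def run_gibbs(
    model: ModelSpec,
    prior: PriorSpec,
    n_iter: int = 150_000,
    burn_in: int = 1_000,
    thin: int = 80,
    seed: int = 0,
    components: Sequence[str] = COMPONENTS,
    fixed_mu: np.ndarray | None = None,
) -> PosteriorChain:
    """Systematic-scan Gibbs sampler for the four-trait animal model.

    Each sweep: sample the trait means from the observed-data
    likelihood; sample additive values (jointly per independence-
    coloured batch of the pedigree), maternal and block effect vectors
    from their observed-data normal conditionals, each followed by
    translation and parameter-expansion (scale + shear) group moves;
    sample G, M, B from their inverse-Wishart full conditionals
    (additive cross-product weighted by the relationship inverse);
    impute the unobserved traits and draw R conjugately from the
    completed residuals.  Every `thin`-th post-burn-in state is stored.

    `components` can exclude terms (their effects are pinned at zero and
    their matrices reported as zero), and `fixed_mu` pins the trait
    means — both are used by degenerate-model oracle checks.
    """
    components = tuple(components)
    for c in components:
        if c not in COMPONENTS:
            raise ValueError(f"unknown component {c!r}")
    if "R" not in components:
        raise ValueError("the residual component R is required")
    n_store = chain_length(n_iter, burn_in, thin)
    rng = np.random.default_rng(seed)

    level_counts = {
        "G": len(model.pedigree),
        "M": len(model.dam_levels),
        "B": len(model.block_levels),
        "R": model.n_records,
    }
    for c in components:
        df = prior.nu[c] + level_counts[c]
        if df <= 3:  # p - 1 for four traits: conditional is improper
            raise ValueError(
                f"component {c} has {level_counts[c]} levels; with prior "
                f"nu={prior.nu[c]} its inverse-Wishart full conditional has "
                f"df={df:.3f} <= 3 and the posterior is improper — provide "
                "more levels or a larger prior nu"
            )
        if df < 5:
            warnings.warn(
                f"component {c} has only {level_counts[c]} levels; its "
                "inverse-Wishart full conditional is near-degenerate and "
                "the posterior will be prior-dominated and heavy-tailed",
                stacklevel=2,
            )

    n_rec = model.n_records
    n_ped = len(model.pedigree)
    n_dam = len(model.dam_levels)
    n_blk = len(model.block_levels)
    rec_a, rec_d, rec_b = model.record_animal, model.record_dam, model.record_block
    a_inv = model.a_inv
    a_inv_diag = a_inv.diagonal()
    a_inv_off = a_inv - sparse.diags(a_inv_diag)
    mask = model.mask
    any_missing = not mask.all()
    maskf = mask.astype(float)

    # missingness patterns drive both the observed-data (collapsed)
    # likelihood weights and the imputation step used by the R update
    patterns = _Patterns.from_mask(mask)
    n_pat = len(patterns)
    impute_grids = []
    if any_missing:
        for p in range(n_pat):
            obs = patterns.obs[p]
            mis = np.setdiff1d(np.arange(4), obs)
            if mis.size:
                rows = patterns.rows[p]
                impute_grids.append(
                    (
                        rows,
                        obs,
                        mis,
                        np.ix_(rows, obs),
                        np.ix_(rows, mis),
                        np.ix_(obs, obs),
                        np.ix_(obs, mis),
                        np.ix_(mis, mis),
                    )
                )

    def pattern_counts(rec_level: np.ndarray, n_levels: int) -> np.ndarray:
        counts = np.zeros((n_levels, n_pat))
        for p, rows in enumerate(patterns.rows):
            counts[:, p] = np.bincount(rec_level[rows], minlength=n_levels)
        return counts

    animal_counts = pattern_counts(rec_a, n_ped)
    animal_batches = _build_animal_batches(a_inv, animal_counts)
    dam_batch = _make_batch(np.arange(n_dam), pattern_counts(rec_d, n_dam), np.ones(n_dam))
    blk_batch = _make_batch(np.arange(n_blk), pattern_counts(rec_b, n_blk), np.ones(n_blk))
    pat_n = np.array([rows.size for rows in patterns.rows], dtype=float)

    # quantities for the translation (interweaving) moves
    ainv_rowsum = np.asarray(a_inv.sum(axis=1)).ravel()
    ainv_total = float(ainv_rowsum.sum())

    # record-to-level incidence matrices for fast residual aggregation
    ones = np.ones(n_rec)
    rec_ix = np.arange(n_rec)
    Z_a = sparse.csr_matrix((ones, (rec_a, rec_ix)), shape=(n_ped, n_rec))
    Z_d = sparse.csr_matrix((ones, (rec_d, rec_ix)), shape=(n_dam, n_rec))
    Z_b = sparse.csr_matrix((ones, (rec_b, rec_ix)), shape=(n_blk, n_rec))

    # state; y0 holds observed values with zeros at unobserved entries
    # (the collapsed updates never look at them), while y carries the
    # current imputation-completed data used only by the R update
    y0 = np.where(mask, model.y, 0.0)
    col_means = np.array(
        [np.nanmean(model.y[:, t]) if mask[:, t].any() else 0.0 for t in range(4)]
    )
    y = np.where(mask, model.y, col_means)
    mu = col_means.copy() if fixed_mu is None else np.asarray(fixed_mu, dtype=float).copy()
    a = np.zeros((n_ped, 4))
    m = np.zeros((n_dam, 4))
    b = np.zeros((n_blk, 4))
    comp = {}
    for c in COMPONENTS:
        v0 = np.diag(np.diag(prior.scale[c])) / prior.nu[c]
        comp[c] = v0 if v0.trace() > 0 else np.eye(4) * 1e-2
    mats = {c: comp[c].copy() for c in COMPONENTS}

    store = {
        "mu": np.empty((n_store, 4)),
        "G": np.zeros((n_store, 4, 4)),
        "M": np.zeros((n_store, 4, 4)),
        "B": np.zeros((n_store, 4, 4)),
        "R": np.zeros((n_store, 4, 4)),
    }
    kept = 0

    use_g = "G" in components
    use_m = "M" in components
    use_b = "B" in components

    def weighted(resid: np.ndarray, w_list: list[np.ndarray]) -> np.ndarray:
        out = np.empty_like(resid)
        for p, rows in enumerate(patterns.rows):
            out[rows] = resid[rows] @ w_list[p]
        return out

    pat_of_rec = patterns.of_record.astype(np.int64)

    def sample_effects(batch, rhs, w_list, w_arr, comp_inv):
        if _HAVE_COMPILED_PX:
            out = np.empty_like(rhs)
            z = rng.standard_normal(rhs.shape)
            _sample_batch_nb(
                batch.gid, batch.pat_counts_u, batch.d_u, rhs, w_arr, comp_inv, z, out
            )
            return out
        return _sample_batch(rng, batch, rhs, w_list, comp_inv)

    def draw_iw(df, scale):
        if _HAVE_COMPILED_PX:
            chis = np.maximum(rng.chisquare(df - np.arange(4.0)), 1e-12)
            norms = rng.standard_normal(6)
            try:
                return _rinvwishart_nb(scale, chis, norms)
            except Exception:
                pass
        return _rinvwishart(rng, df, scale)

    def apply_px(effects, rec_level, resid, comp_name, w_list, w_arr):
        """Scale + shear parameter-expansion moves for one component."""
        s_diag = np.ascontiguousarray(np.diag(prior.scale[comp_name]))
        if _HAVE_COMPILED_PX:
            _px_component_nb(
                effects,
                rec_level,
                resid,
                pat_of_rec,
                n_pat,
                w_arr,
                mats[comp_name],
                s_diag,
                prior.nu[comp_name],
                rng.random((4, 60)),
                rng.standard_normal(12),
            )
        else:
            _px_rescale(
                rng, effects, effects[rec_level], resid, patterns, w_list,
                mats[comp_name], prior.scale[comp_name], prior.nu[comp_name],
            )
            _px_shear(
                rng, effects, rec_level, resid, patterns, w_list,
                mats[comp_name], prior.scale[comp_name],
            )

    for it in range(1, n_iter + 1):
        w_list = patterns.weights(mats["R"])
        w_arr = np.stack(w_list)

        # (1) trait means (flat prior) from the observed-data likelihood
        if fixed_mu is None:
            resid = (y0 - a[rec_a] - m[rec_d] - b[rec_b]) * maskf
            P_mu = sum(n_p * W for n_p, W in zip(pat_n, w_list))
            h = weighted(resid, w_list).sum(axis=0)
            L_mu = _spd_cholesky(P_mu)
            mu = np.linalg.solve(P_mu, h) + np.linalg.solve(
                L_mu.T, rng.standard_normal(4)
            )

        # (2) additive values, one independence colour at a time;
        # unobserved traits are integrated out of every conditional
        if use_g:
            g_inv = np.linalg.inv(mats["G"])
            resid = (y0 - mu - m[rec_d] - b[rec_b]) * maskf
            data_part = Z_a @ weighted(resid, w_list)
            for batch in animal_batches:
                neigh = a_inv_off @ a
                rhs = data_part[batch.members] - neigh[batch.members] @ g_inv
                a[batch.members] = sample_effects(batch, rhs, w_list, w_arr, g_inv)

            if fixed_mu is None:
                # translation move along the flat mu/effect-mean ridge:
                # shift d drawn from the prior conditional of the
                # A-weighted mean of breeding values, applied as
                # (mu + d, a - d); likelihood-invariant, removes the
                # random-walk confounding of the intercept with the
                # additive-effect mean
                d_mean = (ainv_rowsum @ a) / ainv_total
                d = d_mean + (_spd_cholesky(mats["G"]) @ rng.standard_normal(4)) / np.sqrt(
                    ainv_total
                )
                a -= d
                mu = mu + d
            res_px = (y0 - mu - m[rec_d] - b[rec_b]) * maskf
            apply_px(a, rec_a, res_px, "G", w_list, w_arr)

        # (3) maternal and block effect vectors
        if use_m:
            m_inv = np.linalg.inv(mats["M"])
            resid = (y0 - mu - a[rec_a] - b[rec_b]) * maskf
            m = sample_effects(dam_batch, Z_d @ weighted(resid, w_list), w_list, w_arr, m_inv)
            if fixed_mu is None:
                d = m.mean(axis=0) + (
                    _spd_cholesky(mats["M"]) @ rng.standard_normal(4)
                ) / np.sqrt(n_dam)
                m -= d
                mu = mu + d
            res_px = (y0 - mu - a[rec_a] - b[rec_b]) * maskf
            apply_px(m, rec_d, res_px, "M", w_list, w_arr)
        if use_b:
            b_inv = np.linalg.inv(mats["B"])
            resid = (y0 - mu - a[rec_a] - m[rec_d]) * maskf
            b = sample_effects(blk_batch, Z_b @ weighted(resid, w_list), w_list, w_arr, b_inv)
            if fixed_mu is None:
                d = b.mean(axis=0) + (
                    _spd_cholesky(mats["B"]) @ rng.standard_normal(4)
                ) / np.sqrt(n_blk)
                b -= d
                mu = mu + d
            res_px = (y0 - mu - a[rec_a] - m[rec_d]) * maskf
            apply_px(b, rec_b, res_px, "B", w_list, w_arr)

        # (4) G, M, B from their inverse-Wishart full conditionals
        if use_g:
            S_g = a.T @ (a_inv @ a)
            mats["G"] = draw_iw(prior.nu["G"] + n_ped, prior.scale["G"] + 0.5 * (S_g + S_g.T))
        if use_m:
            mats["M"] = draw_iw(prior.nu["M"] + n_dam, prior.scale["M"] + m.T @ m)
        if use_b:
            mats["B"] = draw_iw(prior.nu["B"] + n_blk, prior.scale["B"] + b.T @ b)

        # (5) impute unobserved traits, then draw R conjugately — the
        # only place the completed data are used
        eta = mu + a[rec_a] + m[rec_d] + b[rec_b]
        if any_missing:
            R = mats["R"]
            for rows, obs, mis, ix_ro, ix_rm, ix_oo, ix_om, ix_mm in impute_grids:
                W = np.linalg.solve(R[ix_oo], R[ix_om]).T  # (mis, obs)
                cond_cov = R[ix_mm] - W @ R[ix_om]
                Lc = _spd_cholesky(cond_cov)
                resid_obs = y[ix_ro] - eta[ix_ro]
                z = rng.standard_normal((rows.size, mis.size))
                y[ix_rm] = eta[ix_rm] + resid_obs @ W.T + z @ Lc.T
        e = y - eta
        mats["R"] = draw_iw(prior.nu["R"] + n_rec, prior.scale["R"] + e.T @ e)

        if it > burn_in and (it - burn_in) % thin == 0:
            store["mu"][kept] = mu
            for c in COMPONENTS:
                if c in components:
                    store[c][kept] = mats[c]
            kept += 1

    assert kept == n_store
    return PosteriorChain(
        traits=model.traits,
        mu=store["mu"],
        G=store["G"],
        M=store["M"],
        B=store["B"],
        R=store["R"],
        meta={
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
            "seed": seed,
            "components": list(components),
            "n_records": n_rec,
            "n_animals": n_ped,
            "n_dams": n_dam,
            "n_blocks": n_blk,
        },
    )


# ----------------------------------------------------------------------
# derived posterior quantities


@dataclass
class PosteriorSummary:
    name: str
    mean: float
    median: float
    lower: float
    upper: float
    samples: np.ndarray

    def __repr__(self):
        return (
            f"PosteriorSummary({self.name}: mean={self.mean:.4g}, "
            f"95% [{self.lower:.4g}, {self.upper:.4g}])"
        )


def _summarize(name: str, samples: np.ndarray, interval: str = "hpd") -> PosteriorSummary:
    if interval == "hpd":
        lo, hi = diagnostics.hpd_interval(samples)
    elif interval == "quantile":
        lo, hi = diagnostics.quantile_interval(samples)
    else:
        raise ValueError("interval must be 'hpd' or 'quantile'")
    return PosteriorSummary(
        name=name,
        mean=float(np.mean(samples)),
        median=float(np.median(samples)),
        lower=lo,
        upper=hi,
        samples=samples,
    )


def heritability(chain: PosteriorChain, trait, interval: str = "hpd") -> PosteriorSummary:
    """Posterior of h^2 = G_tt / (G+M+B+R)_tt for one trait."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    t = chain.trait_index(trait)
    samples = chain.G[:, t, t] / chain.total[:, t, t]
    return _summarize(f"h2[{chain.traits[t]}]", samples, interval)


def variance_proportions(chain: PosteriorChain, interval: str = "hpd") -> pd.DataFrame:
    """Posterior summaries of each component's share of total variance.

    One row per (component, trait); the four shares of a trait sum to 1
    in every posterior sample by construction.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    total = chain.total
    rows = []
    for comp in COMPONENTS:
        arr = chain.component(comp)
        for t, name in enumerate(chain.traits):
            s = _summarize(f"{comp}/{name}", arr[:, t, t] / total[:, t, t], interval)
            rows.append(
                {
                    "component": comp,
                    "trait": name,
                    "mean": s.mean,
                    "median": s.median,
                    "lower": s.lower,
                    "upper": s.upper,
                }
            )
    return pd.DataFrame(rows)


def _component_correlation(
    chain: PosteriorChain, comp: str, trait_x, trait_y, interval: str
) -> PosteriorSummary:
    if len(chain) == 0:
        raise ValueError("empty chain")
    x, y_ = chain.trait_index(trait_x), chain.trait_index(trait_y)
    arr = chain.component(comp)
    denom = np.sqrt(arr[:, x, x] * arr[:, y_, y_])
    samples = np.where(denom > 0, arr[:, x, y_] / np.where(denom > 0, denom, 1.0), 0.0)
    label = "r_G" if comp == "G" else ("r_M" if comp == "M" else f"r_{comp}")
    return _summarize(f"{label}[{chain.traits[x]},{chain.traits[y_]}]", samples, interval)


def genetic_correlation(
    chain: PosteriorChain, trait_x, trait_y, interval: str = "hpd"
) -> PosteriorSummary:
    """Posterior of r_G(x, y) = Cov_A(x, y) / sqrt(V_A(x) V_A(y))."""
    return _component_correlation(chain, "G", trait_x, trait_y, interval)


def maternal_correlation(
    chain: PosteriorChain, trait_x, trait_y, interval: str = "hpd"
) -> PosteriorSummary:
    """Posterior of the maternal-effect correlation r_M(x, y)."""
    return _component_correlation(chain, "M", trait_x, trait_y, interval)


def convergence_diagnostics(chain: PosteriorChain, alpha: float = 0.05, eps: float = 0.1) -> pd.DataFrame:
    """Per-parameter lag-1 autocorrelation and Heidelberger–Welch tests.

    Parameters are the four trait means and the unique entries of each
    sampled component matrix.
    """
    if len(chain) < 100:
        raise ValueError("need at least 100 stored samples for diagnostics")
    params: dict[str, np.ndarray] = {}
    for t, name in enumerate(chain.traits):
        params[f"mu_{name}"] = chain.mu[:, t]
    sampled = chain.meta.get("components", list(COMPONENTS))
    for comp in sampled:
        arr = chain.component(comp)
        for i in range(4):
            for j in range(i, 4):
                params[f"{comp}_{i + 1}{j + 1}"] = arr[:, i, j]
    rows = []
    for name, x in params.items():
        hw = diagnostics.heidelberger_welch(x, alpha=alpha, eps=eps)
        rows.append(
            {
                "parameter": name,
                "lag1_autocorr": diagnostics.lag1_autocorrelation(x),
                "stationarity_passed": hw.stationarity_passed,
                "cvm_pvalue": hw.cvm_pvalue,
                "mean": hw.mean,
                "halfwidth": hw.halfwidth,
                "halfwidth_passed": hw.halfwidth_passed,
                "n_used": hw.n_used,
            }
        )
    return pd.DataFrame(rows)
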