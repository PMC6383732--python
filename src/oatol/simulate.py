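"""Synthetic breeding designs and raw larval observations with known truth.

Emulates the study design the package analyzes: replicated temporal
blocks (spawning events), each containing one or two 3-sire x 3-dam full
factorial crosses; a random subset of the resulting full-sib families is
reared in duplicate tanks of 50 larvae under both an ambient and an
acidified seawater treatment; tanks are followed for 14 days with daily
survivor counts and standard-length samples at day 0 and day 14.

Tank phenotypes are generated from a four-trait model
``y = mu + a + m + b + e`` where ``a`` is the breeding value of a
tank-level pseudo-individual (an offspring of the family's sire and dam,
so replicate tanks of one family are distinct full sibs with additive
relationship 0.5), ``m`` is shared by all tanks of one dam, ``b`` by all
tanks of one block, and ``e`` is independent per tank.  The generating
G, M, B, R matrices are recorded so that every downstream estimator can
be checked against a known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

TRAITS = (
    "mortality_ambient",
    "mortality_acidified",
    "growth_ambient",
    "growth_acidified",
)
TREATMENTS = ("ambient", "acidified")
#: trait indices observed by a tank of each treatment
TREATMENT_TRAITS = {"ambient": (0, 2), "acidified": (1, 3)}


@dataclass(frozen=True)
class DesignSpec:
    """Shape of a simulated breeding design.

    Defaults reproduce the study conditions: 16 spawning-event blocks,
    two 3x3 factorial sets per block (18 candidate families), at most 12
    family slots reared per block (each slot is one tank per treatment),
    about a quarter of reared families duplicated, 50 larvae per tank for
    14 days, 10 length-sampled larvae per tank.
    """

    n_blocks: int = 16
    sets_per_block: int = 2
    sires_per_set: int = 3
    dams_per_set: int = 3
    max_tanks_per_treatment_per_block: int = 12
    duplicate_family_fraction: float = 0.25
    larvae_per_tank: int = 50
    duration_days: int = 14
    lengths_sampled_per_tank: int = 10
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_blocks,
            self.sets_per_block,
            self.sires_per_set,
            self.dams_per_set,
            self.max_tanks_per_treatment_per_block,
            self.larvae_per_tank,
            self.duration_days,
            self.lengths_sampled_per_tank,
        )
        if any(int(c) <= 0 or int(c) != c for c in counts):
            raise ValueError("all DesignSpec counts must be positive integers")
        if not 0.0 <= self.duplicate_family_fraction <= 1.0:
            raise ValueError("duplicate_family_fraction must be in [0, 1]")


def _chol_psd(mat: np.ndarray) -> np.ndarray:
    """Cholesky-like factor L with L @ L.T = mat for any PSD matrix.

    Falls back to an eigenvalue factorization when the matrix is
    singular (zero components are legitimate truths in tests).
    """
    if not mat.any():
        return np.zeros_like(mat)
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(mat)
        return v * np.sqrt(np.clip(w, 0.0, None))


def _sample_mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    return rng.standard_normal((size, cov.shape[0])) @ _chol_psd(cov).T


def _as_psd(name: str, mat) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"{name} must be 4x4")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite")
    return mat


@dataclass(frozen=True)
class TruthParams:
    """Generating means and (co)variance components for the four traits.

    Trait order is :data:`TRAITS`: daily mortality rate (ambient,
    acidified; per day) then 14-day growth (ambient, acidified; mm).
    """

    mu: np.ndarray
    G: np.ndarray
    M: np.ndarray
    B: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.mu.shape != (4,):
            raise ValueError("mu must be a 4-vector")
        for name in "GMBR":
            object.__setattr__(self, name, _as_psd(name, getattr(self, name)))
        _as_psd("P = G+M+B+R", self.G + self.M + self.B + self.R)

    @property
    def P(self) -> np.ndarray:
        return self.G + self.M + self.B + self.R

    def to_json(self, path) -> None:
        payload = {k: np.asarray(v).tolist() for k, v in dataclasses.asdict(self).items()}
        payload["traits"] = list(TRAITS)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthParams":
        d = json.loads(Path(path).read_text())
        return cls(mu=d["mu"], G=d["G"], M=d["M"], B=d["B"], R=d["R"])


def _component(total_sd: np.ndarray, props, corr) -> np.ndarray:
    """Covariance matrix with given per-trait variance share and correlations."""
    sd = total_sd * np.sqrt(np.asarray(props, dtype=float))
    return np.asarray(corr, dtype=float) * np.outer(sd, sd)


def default_truth() -> TruthParams:
    """Generating parameters emulating the grunion experiment.

    Variance proportions and the genetic/maternal correlations follow
    the published estimates (mortality h2 0.12/0.18 with r_G 0.46 and
    r_M 0.82; growth h2 ~0.1 dominated by block variance); unreported
    correlations (notably among block effects) are set to moderate
    positive values.  Total SDs: ~0.045 per day for mortality, 0.5 mm
    for growth; means 0.040/0.053 per day and 1.5 mm.
    """
    total_sd = np.array([0.045, 0.045, 0.5, 0.5])
    G = _component(
        total_sd,
        [0.120, 0.183, 0.092, 0.101],
        [
            [1.0, 0.46, 0.04, 0.0],
            [0.46, 1.0, 0.0, 0.05],
            [0.04, 0.0, 1.0, 0.135],
            [0.0, 0.05, 0.135, 1.0],
        ],
    )
    M = _component(
        total_sd,
        [0.363, 0.265, 0.080, 0.080],
        [
            [1.0, 0.82, 0.32, 0.0],
            [0.82, 1.0, 0.0, 0.28],
            [0.32, 0.0, 1.0, 0.34],
            [0.0, 0.28, 0.34, 1.0],
        ],
    )
    B = _component(
        total_sd,
        [0.426, 0.423, 0.728, 0.718],
        [
            [1.0, 0.8, 0.3, 0.3],
            [0.8, 1.0, 0.3, 0.3],
            [0.3, 0.3, 1.0, 0.8],
            [0.3, 0.3, 0.8, 1.0],
        ],
    )
    R = _component(total_sd, [0.091, 0.129, 0.100, 0.101], np.eye(4))
    mu = np.array([0.040, 0.0526, 1.5, 1.52])
    return TruthParams(mu=mu, G=G, M=M, B=B, R=R)


def truth_from_proportions(
    h2_mortality: float = 0.2,
    h2_growth: float = 0.1,
    r_g_mortality: float = 0.45,
    r_g_growth: float = 0.15,
    maternal_proportion: float = 0.3,
    block_proportion: float = 0.4,
    r_m: float = 0.8,
    r_b: float = 0.5,
    total_sd=(0.045, 0.045, 0.5, 0.5),
    mu=(0.040, 0.0526, 1.5, 1.52),
) -> TruthParams:
    """Build TruthParams from variance proportions and key correlations.

    Residual proportion is the remainder; cross trait-pair correlations
    (mortality vs growth) are zero.  Used by parameter-recovery
    harnesses where the truth must be a simple, known quantity.
    """
    total_sd = np.asarray(total_sd, dtype=float)
    h2 = np.array([h2_mortality, h2_mortality, h2_growth, h2_growth])
    resid = 1.0 - h2 - maternal_proportion - block_proportion
    if np.any(resid <= 0):
        raise ValueError("proportions exceed 1; no residual variance left")

    def pair_corr(r_pair):
        return np.array(
            [
                [1.0, r_pair, 0.0, 0.0],
                [r_pair, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, r_pair],
                [0.0, 0.0, r_pair, 1.0],
            ]
        )

    corr_g = pair_corr(0.0)
    corr_g[0, 1] = corr_g[1, 0] = r_g_mortality
    corr_g[2, 3] = corr_g[3, 2] = r_g_growth
    G = _component(total_sd, h2, corr_g)
    M = _component(total_sd, np.full(4, maternal_proportion), pair_corr(r_m))
    B = _component(total_sd, np.full(4, block_proportion), pair_corr(r_b))
    R = _component(total_sd, resid, np.eye(4))
    return TruthParams(mu=np.asarray(mu, dtype=float), G=G, M=M, B=B, R=R)


@dataclass
class TankRecord:
    """One rearing tank and (once simulated) its raw observations."""

    tank_id: str
    family_id: str
    sire_id: str
    dam_id: str
    block: str
    treatment: str
    counts: np.ndarray | None = None
    lengths_day0: np.ndarray | None = None
    lengths_day14: np.ndarray | None = None


def generate_breeding_design(spec: DesignSpec) -> tuple[Pedigree, list[TankRecord]]:
    """Create founders, factorial families, and tank stubs for one design.

    Per block and set, every sire x dam combination is a full-sib family.
    A uniform-random subset of the block's families is assigned one tank
    per treatment, respecting the per-block, per-treatment tank capacity;
    a ``duplicate_family_fraction`` of the reared families receive a
    second tank in each treatment.
    """
    if spec.max_tanks_per_treatment_per_block < 1:
        raise ValueError("capacity must allow at least one tank per treatment")
    rng = np.random.default_rng(spec.seed)
    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    tanks: list[TankRecord] = []

    for b in range(spec.n_blocks):
        block = f"blk{b + 1:02d}"
        families: list[tuple[str, str, str]] = []
        for s_set in range(spec.sets_per_block):
            set_sires = [f"{block}.set{s_set + 1}.sire{i + 1}" for i in range(spec.sires_per_set)]
            set_dams = [f"{block}.set{s_set + 1}.dam{j + 1}" for j in range(spec.dams_per_set)]
            for founder in set_sires + set_dams:
                ids.append(founder)
                sires.append(None)
                dams.append(None)
            for si in set_sires:
                for dj in set_dams:
                    fam = f"{si.rsplit('.', 1)[-1]}x{dj.rsplit('.', 1)[-1]}"
                    families.append((f"{block}.set{s_set + 1}.{fam}", si, dj))

        cap = spec.max_tanks_per_treatment_per_block
        # pick as many distinct families as capacity allows, then carve
        # out room for the requested fraction of duplicated families
        n_distinct = min(len(families), cap)
        n_dup = int(round(spec.duplicate_family_fraction * n_distinct))
        while n_distinct + n_dup > cap:
            n_distinct -= 1
            n_dup = int(round(spec.duplicate_family_fraction * n_distinct))
        order = rng.permutation(len(families))
        chosen = [families[k] for k in order[:n_distinct]]
        dup_idx = set(rng.choice(n_distinct, size=n_dup, replace=False)) if n_dup else set()

        for k, (fam_id, sire_id, dam_id) in enumerate(chosen):
            n_tanks = 2 if k in dup_idx else 1
            for rep in range(n_tanks):
                for trt in TREATMENTS:
                    tank_id = f"{fam_id}.{trt[:3]}{rep + 1}"
                    ids.append(tank_id)
                    sires.append(sire_id)
                    dams.append(dam_id)
                    tanks.append(
                        TankRecord(
                            tank_id=tank_id,
                            family_id=fam_id,
                            sire_id=sire_id,
                            dam_id=dam_id,
                            block=block,
                            treatment=trt,
                        )
                    )

    return Pedigree(ids, sires, dams), tanks


def simulate_trait_values(
    ped: Pedigree, tanks: list[TankRecord], truth: TruthParams, seed: int
) -> pd.DataFrame:
    """Draw latent four-trait values per tank; return the trait table.

    Breeding values are sampled by recursion down the pedigree (founders
    ~ N(0, G); offspring = parent midpoint + Mendelian deviate of
    covariance G/2 for non-inbred, known parents).  Each tank's row
    exposes only the two traits of its own treatment as
    ``mortality_rate`` and ``growth``.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    chol_G = _chol_psd(truth.G)
    a = np.zeros((n, 4))
    z = rng.standard_normal((n, 4))
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        if s < 0 and d < 0:
            a[j] = chol_G @ z[j]
        else:
            mid = 0.0
            var_scale = 1.0
            if s >= 0:
                mid = mid + 0.5 * a[s]
                var_scale -= 0.25
            if d >= 0:
                mid = mid + 0.5 * a[d]
                var_scale -= 0.25
            a[j] = mid + np.sqrt(var_scale) * (chol_G @ z[j])

    dams = sorted({t.dam_id for t in tanks})
    blocks = sorted({t.block for t in tanks})
    m = _sample_mvn(rng, truth.M, len(dams))
    b = _sample_mvn(rng, truth.B, len(blocks))
    e = _sample_mvn(rng, truth.R, len(tanks))
    dam_ix = {v: k for k, v in enumerate(dams)}
    blk_ix = {v: k for k, v in enumerate(blocks)}

    rows = []
    for k, t in enumerate(tanks):
        if t.tank_id not in ped._index:
            raise ValueError(f"tank {t.tank_id} missing from pedigree")
        y = truth.mu + a[ped.index(t.tank_id)] + m[dam_ix[t.dam_id]] + b[blk_ix[t.block]] + e[k]
        i_mort, i_grow = TREATMENT_TRAITS[t.treatment]
        rows.append(
            {
                "tank_id": t.tank_id,
                "family_id": t.family_id,
                "sire_id": t.sire_id,
                "dam_id": t.dam_id,
                "block": t.block,
                "treatment": t.treatment,
                "mortality_rate": y[i_mort],
                "growth": y[i_grow],
            }
        )
    return pd.DataFrame(rows)


def simulate_daily_counts(m: float, n0: int, days: int, seed) -> np.ndarray:
    """Daily binomial thinning with survival probability exp(-m) per day.

    Returns the survivor series N_0..N_days (length days+1, starting at
    n0); E[N_t] = n0 * exp(-m t), matching the continuous exponential
    decay that the log-survivor regression estimates.
    """
    if m < 0:
        raise ValueError("mortality rate must be >= 0")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = float(np.exp(-m))
    counts = np.empty(days + 1, dtype=np.int64)
    counts[0] = n0
    for t in range(days):
        counts[t + 1] = rng.binomial(counts[t], p)
    return counts


def simulate_lengths(
    growth: float, base_len: float, n: int, noise_sd: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Standard-length samples at day 0 and day 14.

    Population mean difference between the two samples equals ``growth``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    day0 = base_len + noise_sd * rng.standard_normal(n)
    day14 = base_len + growth + noise_sd * rng.standard_normal(n)
    return day0, day14


@dataclass
class SimulatedStudy:
    """A full synthetic experiment: design, truth, traits, raw tables."""

    pedigree: Pedigree
    tanks: list[TankRecord]
    truth: TruthParams
    traits: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.DataFrame


def simulate_study(
    spec: DesignSpec,
    truth: TruthParams | None = None,
    base_length_mm: float = 6.0,
    length_noise_sd: float = 0.35,
) -> SimulatedStudy:
    """Generate a complete synthetic experiment from a design and truth.

    Latent tank mortality rates feed daily binomial survivor counts
    (negative latent rates, possible under a Gaussian trait model, are
    truncated to zero for count generation); latent growth feeds the
    day-0/day-14 length samples.
    """
    truth = default_truth() if truth is None else truth
    ped, tanks = generate_breeding_design(spec)
    traits = simulate_trait_values(ped, tanks, truth, seed=spec.seed + 1)
    rng = np.random.default_rng(spec.seed + 2)

    count_rows, length_rows = [], []
    for tank, row in zip(tanks, traits.itertuples()):
        tank.counts = simulate_daily_counts(
            max(row.mortality_rate, 0.0), spec.larvae_per_tank, spec.duration_days, rng
        )
        tank.lengths_day0, tank.lengths_day14 = simulate_lengths(
            row.growth, base_length_mm, spec.lengths_sampled_per_tank, length_noise_sd, rng
        )
        for day, n_alive in enumerate(tank.counts):
            count_rows.append({"tank_id": tank.tank_id, "day": day, "n_alive": int(n_alive)})
        for day, sample in ((0, tank.lengths_day0), (spec.duration_days, tank.lengths_day14)):
            for val in sample:
                length_rows.append(
                    {"tank_id": tank.tank_id, "day": day, "length_mm": float(val)}
                )

    return SimulatedStudy(
        pedigree=ped,
        tanks=tanks,
        truth=truth,
        traits=traits,
        counts=pd.DataFrame(count_rows),
        lengths=pd.DataFrame(length_rows),
    )


def tanks_frame(tanks: list[TankRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tank_id": t.tank_id,
                "family_id": t.family_id,
                "sire_id": t.sire_id,
                "dam_id": t.dam_id,
                "block": t.block,
                "treatment": t.treatment,
            }
            for t in tanks
        ]
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write pedigree/tanks/counts/lengths CSVs plus the truth dump."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "tanks": outdir / "tanks.csv",
        "counts": outdir / "counts.csv",
        "lengths": outdir / "lengths.csv",
        "truth": outdir / "truth.json",
    }
    study.pedigree.write_csv(paths["pedigree"])
    tanks_frame(study.tanks).to_csv(paths["tanks"], index=False)
    study.counts.to_csv(paths["counts"], index=False)
    study.lengths.to_csv(paths["lengths"], index=False)
    study.truth.to_json(paths["truth"])
    return paths
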